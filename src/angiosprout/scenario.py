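"""Experiment orchestration: spheroid initialization, behavior modes,
the per-MCS simulation loop, sprout tracking and occupancy statistics.

A run starts from a spheroid of square cells, advances the CPM coupled to
the chemoattractant field (and, optionally, per-cell VEGF-Dll4-Notch
signaling with tip/stalk phenotype switching), samples cell tracks every
20 MCS, and identifies sprouts and their leader cells on each sampled
frame.  Sprouts are tracked across frames by member-set overlap so that
leader successions, overtakes and per-sprout elongation axes can be
measured over the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cpm, kinetics, signaling, sproutgraph
from .chemofield import ChemField, ChemotaxisParams, run_field_mcs
from .config import ScenarioConfig
from .cpm import (GENOTYPE_VEGFR2_HAPLOID, GENOTYPE_WT, KIND_TIP,
                  CPMParams, LatticeState)
from .signaling import SignalingState, compute_contact_map
from .sproutgraph import LeaderUndefinedError


@dataclass
class OccupancyResult:
    """WT occupancy of sprout tips with its random-mixing binomial p-value."""

    n_sprouts: int
    k_wt_led: int
    percentage: float
    p_binomial: float


@dataclass
class SproutTrack:
    """One sprout followed through time by member-set overlap."""

    sprout_id: int
    frames: list = field(default_factory=list)  # (mcs, B, E, leader, members)

    @property
    def leader_series(self):
        return [(mcs, leader) for mcs, _, _, leader, _ in self.frames]

    def axis(self):
        """Elongation axis: branch/tip positions averaged over the first
        and last frame of the sprout's existence."""
        first, last = self.frames[0], self.frames[-1]
        start = 0.5 * (np.asarray(first[1]) + np.asarray(last[1]))
        end = 0.5 * (np.asarray(first[2]) + np.asarray(last[2]))
        return kinetics.SproutAxis(start=start, end=end)


@dataclass
class RunOutputs:
    """Everything a single-seed run produces."""

    config_hash: str
    seed: int
    tracks: pd.DataFrame          # all-cell center-of-mass samples
    sprout_tracks: list           # list[SproutTrack]
    member_tracks: pd.DataFrame   # in-sprout samples (track_id per sprout-cell)
    events: list                  # OvertakeEvent list
    final_lattice: LatticeState
    final_state: SignalingState | None
    summary: dict


def init_spheroid(radius: int, cell_width: int, mosaic_ratio: float,
                  rng: np.random.Generator, shape,
                  *, target_area: float | None = None,
                  target_length: float = 0.0,
                  min_edge_sites: int | None = None) -> LatticeState:
    """Disc of radius `radius` tiled by `cell_width`-wide square cells.

    Cells clipped by the disc boundary keep their sites when at least
    about half a full cell remains; smaller fragments are absorbed into
    the nearest retained cell.  Genotypes are WT independently with
    probability ``mosaic_ratio``.
    """
    h, w = shape
    cy, cx = h // 2, w // 2
    if radius + 2 >= min(cy, cx):
        raise ValueError("spheroid does not fit in the lattice with margin")
    if min_edge_sites is None:
        min_edge_sites = (cell_width * cell_width + 1) // 2
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    by = (yy - cy + radius) // cell_width
    bx = (xx - cx + radius) // cell_width
    nb = int(np.ceil(2 * radius / cell_width)) + 1
    block = (by * nb + bx + 1).astype(np.int64)
    block[~disc] = 0
    ids, counts = np.unique(block[block > 0], return_counts=True)
    keep = ids[counts >= min_edge_sites]
    if keep.size == 0:
        raise ValueError("spheroid too small for the given cell width")
    # centers of kept blocks, for reassigning absorbed fragments
    centers = {}
    for bid in keep:
        sel = block == bid
        centers[bid] = (yy[sel].mean(), xx[sel].mean())
    keep_ids = np.asarray(sorted(centers))
    keep_pos = np.asarray([centers[b] for b in keep_ids])
    labels = np.zeros((h, w), dtype=np.int32)
    remap = {int(b): i + 1 for i, b in enumerate(keep_ids)}
    for bid in ids:
        sel = block == bid
        if bid in remap:
            labels[sel] = remap[int(bid)]
        else:
            frag_pos = np.column_stack([yy[sel], xx[sel]]).astype(float)
            d = ((frag_pos[:, None, :] - keep_pos[None, :, :]) ** 2).sum(axis=2)
            nearest = keep_ids[np.argmin(d, axis=1)]
            labels[sel] = [remap[int(b)] for b in nearest]
    n = len(keep_ids)
    genotypes = np.where(rng.random(n) < mosaic_ratio,
                         GENOTYPE_WT, GENOTYPE_VEGFR2_HAPLOID).astype(np.int8)
    if target_area is None:
        target_area = float(cell_width * cell_width)
    return LatticeState(labels, target_area=target_area,
                        target_length=target_length, genotypes=genotypes)


def apply_behavior_mode(mode: str, cpm_params: CPMParams,
                        chemo_params: ChemotaxisParams):
    """Install the differential tip/stalk parameter set for `mode`.

    ``differential_adhesion`` weakens tip-cell adhesion
    (J_stalk,stalk = 0.2, J_tip,tip = J_stalk,tip = 0.8, J to ECM = 1);
    ``differential_chemosensitivity`` makes tip cells less chemotactic
    (lambda_c 5 vs 10) with uniform adhesion (J cell-cell 0.4, cell-ECM
    0.6).  ``uniform`` leaves the base parameters untouched.
    """
    if mode == "uniform":
        return cpm_params, chemo_params
    if mode == "differential_adhesion":
        cpm_params.J = {
            ("stalk", "stalk"): 0.2, ("tip", "tip"): 0.8, ("tip", "stalk"): 0.8,
            ("stalk", "ECM"): 1.0, ("tip", "ECM"): 1.0,
        }
        return cpm_params, chemo_params
    if mode == "differential_chemosensitivity":
        cpm_params.J = {
            ("stalk", "stalk"): 0.4, ("tip", "tip"): 0.4, ("tip", "stalk"): 0.4,
            ("stalk", "ECM"): 0.6, ("tip", "ECM"): 0.6,
        }
        chemo_params.lambda_c = {"tip": 5.0, "stalk": 10.0}
        return cpm_params, chemo_params
    raise ValueError(f"unknown behavior mode {mode!r}")


def _match_sprouts(active: list, frame_sprouts: list, next_id: int,
                   min_overlap: float = 0.5):
    """Greedy member-overlap matching of this frame's sprouts to tracks.

    Overlap is |intersection| / min(|A|, |B|); a match needs >= 0.5.
    Unmatched frame sprouts open new tracks; unmatched tracks die.
    """
    pairs = []
    for fi, (_, _, _, _, members) in enumerate(frame_sprouts):
        mset = set(members)
        for track in active:
            prev = set(track.frames[-1][4])
            denom = min(len(mset), len(prev))
            if denom == 0:
                continue
            ov = len(mset & prev) / denom
            if ov >= min_overlap:
                pairs.append((ov, fi, track))
    pairs.sort(key=lambda t: -t[0])
    used_f, used_t = set(), set()
    assigned = {}
    for ov, fi, track in pairs:
        if fi in used_f or id(track) in used_t:
            continue
        used_f.add(fi)
        used_t.add(id(track))
        assigned[fi] = track
    new_tracks = []
    survivors = []
    for fi, frame in enumerate(frame_sprouts):
        track = assigned.get(fi)
        if track is None:
            track = SproutTrack(sprout_id=next_id)
            next_id += 1
            new_tracks.append(track)
        track.frames.append(frame)
        survivors.append(track)
    return survivors, new_tracks, next_id


def _analyze_frame(lattice: LatticeState, mcs: int, morph, contacts=None):
    """Sprout records (mcs, B, E, leader, members) for one sampled frame."""
    mask = lattice.labels > 0
    graph = sproutgraph.network_to_graph(mask, morph)
    adjacency = sproutgraph.cell_adjacency_graph(lattice.labels)
    if contacts is None:
        contacts = compute_contact_map(lattice)
    out = []
    for B, E in sproutgraph.sprout_endpoints(graph):
        try:
            leader = sproutgraph.identify_leader(lattice, B, E,
                                                 adjacency=adjacency)
        except LeaderUndefinedError:
            continue
        members = sproutgraph.sprout_members(lattice, leader, contacts=contacts)
        out.append((mcs, B, E, leader, members))
    return out


def run_scenario(config: ScenarioConfig, seed: int) -> RunOutputs:
    """Run one seeded simulation of the configured experiment."""
    rng = np.random.default_rng(seed)
    cpm.seed_dynamics(rng.integers(0, 2 ** 31 - 1))
    cpm_params = config.cpm
    chemo_params = config.chemotaxis
    apply_behavior_mode(config.behavior_mode, cpm_params, chemo_params)
    target_length = (config.target_length
                     if config.model_variant == "cell_elongation" else 0.0)
    lattice = init_spheroid(config.spheroid_radius, config.cell_width,
                            config.mosaic_ratio, rng, config.lattice_shape,
                            target_length=target_length)
    fld = ChemField.zeros(config.lattice_shape, alpha=config.field_alpha,
                          epsilon=config.field_epsilon, D_coef=config.field_D,
                          dt=config.field_dt,
                          steps_per_mcs=config.field_steps_per_mcs)
    sig_params = config.signaling_params
    state = None
    if config.signaling != "off":
        state = SignalingState.homogeneous(lattice.n_cells, sig_params, rng=rng)
        lattice.kind[1:] = signaling.assign_phenotypes(state, sig_params)[1:]
    lam_c = chemo_params.lambda_c_vector()
    track_rows = []
    active_tracks: list = []
    all_tracks: list = []
    next_id = 0
    lo, hi = config.analysis_window

    def sample_tracks(mcs):
        cents = lattice.centroids()
        for cid in range(1, lattice.n_cells + 1):
            if lattice.area[cid] == 0:
                continue
            row = (mcs, cid, cents[cid, 0], cents[cid, 1],
                   int(lattice.kind[cid]), int(lattice.genotype[cid]))
            if state is not None:
                row += (state.D[cid], state.N[cid], state.S[cid],
                        state.R[cid], state.A[cid])
            track_rows.append(row)

    sample_tracks(0)
    for mcs in range(1, config.duration_mcs + 1):
        cpm.run_mcs(lattice, cpm_params, chemo=fld.c, lambda_c=lam_c,
                    contact_inhibition=chemo_params.contact_inhibition)
        run_field_mcs(fld, lattice)
        contacts = None
        if state is not None:
            contacts = compute_contact_map(lattice)
            for _ in range(sig_params.iters_per_mcs):
                signaling.step_dll4_notch(state, contacts, sig_params)
                if config.signaling == "vegf_dll4_notch":
                    signaling.step_vegf_extension(state, contacts, sig_params,
                                                  lattice.genotype)
            lattice.kind[1:] = signaling.assign_phenotypes(state, sig_params)[1:]
        if mcs % 100 == 0:
            lattice.recompute_geometry()
        if mcs % config.sample_stride == 0:
            sample_tracks(mcs)
            if mcs >= lo:
                frame_sprouts = _analyze_frame(lattice, mcs, config.morph,
                                               contacts=contacts)
                active_tracks, new_tracks, next_id = _match_sprouts(
                    active_tracks, frame_sprouts, next_id)
                all_tracks.extend(new_tracks)
    columns = ["mcs", "cell_id", "x", "y", "kind", "genotype"]
    if state is not None:
        columns += ["D", "N", "S", "R", "A"]
    tracks = pd.DataFrame(track_rows, columns=columns)
    leader_series = {t.sprout_id: t.leader_series for t in all_tracks}
    events = kinetics.detect_overtakes(leader_series,
                                       stride=config.sample_stride)
    member_tracks = _member_track_table(tracks, all_tracks)
    summary = _run_summary(config, all_tracks, events, tracks, member_tracks,
                           lattice)
    return RunOutputs(config_hash=config.config_hash(), seed=seed,
                      tracks=tracks, sprout_tracks=all_tracks,
                      member_tracks=member_tracks, events=events,
                      final_lattice=lattice, final_state=state,
                      summary=summary)


def _member_track_table(tracks: pd.DataFrame, sprout_tracks: list) -> pd.DataFrame:
    """In-sprout samples: one row per (frame, member cell) with the
    sprout id and a unique per-sprout-cell track id."""
    pos = tracks.set_index(["mcs", "cell_id"])[["x", "y"]]
    rows = []
    for track in sprout_tracks:
        for mcs, _, _, _, members in track.frames:
            for cid in members:
                try:
                    x, y = pos.loc[(mcs, cid)]
                except KeyError:
                    continue
                rows.append((track.sprout_id, cid,
                             f"{track.sprout_id}:{cid}", mcs, x, y))
    return pd.DataFrame(rows, columns=["sprout_id", "cell_id", "track_id",
                                       "mcs", "x", "y"])


def _pooled_kinetics(sprout_tracks: list, member_tracks: pd.DataFrame,
                     stride: int) -> dict:
    """Axis-referenced kinetics pooled over sprouts (and callers may pool
    runs by concatenating member tables with distinct track ids)."""
    thetas = []
    n_ant = n_ret = n_stop = 0
    lag_pool: dict = {}
    for track in sprout_tracks:
        try:
            axis = track.axis()
        except ValueError:
            continue
        sub = member_tracks[member_tracks.sprout_id == track.sprout_id]
        if sub.empty:
            continue
        sub = sub.drop(columns=["cell_id"]).rename(columns={"track_id": "cell_id"})
        coord = kinetics.coordination(sub, axis)
        thetas.append(coord["theta"])
        mot = kinetics.directional_motility(sub, axis)
        n_ant += mot["anterograde"] * mot["n"] / 100.0
        n_ret += mot["retrograde"] * mot["n"] / 100.0
        n_stop += mot["stopped"] * mot["n"] / 100.0
        lag, msd, n = kinetics.msd_curve(sub, axis, stride=stride)
        for t, m, k in zip(lag, msd, n):
            lag_pool.setdefault(float(t), [0.0, 0])
            lag_pool[float(t)][0] += m * k
            lag_pool[float(t)][1] += k
    theta = np.concatenate(thetas) if thetas else np.array([])
    ant = theta[theta < np.pi / 2] / np.pi
    ret = theta[theta > np.pi / 2] / np.pi
    total = n_ant + n_ret + n_stop
    out = {
        "std_theta_anterograde": float(np.std(ant, ddof=1)) if len(ant) > 1 else np.nan,
        "std_theta_retrograde": float(np.std(ret, ddof=1)) if len(ret) > 1 else np.nan,
        "pct_anterograde": 100.0 * n_ant / total if total else np.nan,
        "pct_retrograde": 100.0 * n_ret / total if total else np.nan,
        "pct_stopped": 100.0 * n_stop / total if total else np.nan,
        "msd_pool": lag_pool,
    }
    return out


def fit_pooled_msd(lag_pools: list):
    """Weighted MSD fit over lag pools from one or more runs.

    Returns (D um^2/s, v um/s, fit covariance); raises with fewer than
    three pooled lags.
    """
    merged: dict = {}
    for pool in lag_pools:
        for t, (wsum, k) in pool.items():
            merged.setdefault(t, [0.0, 0])
            merged[t][0] += wsum
            merged[t][1] += k
    lags = np.array(sorted(t for t in merged if merged[t][1] >= 2))
    if len(lags) < 3:
        raise ValueError("insufficient pooled lag times for an MSD fit")
    msd = np.array([merged[t][0] / merged[t][1] for t in lags])
    n = np.array([merged[t][1] for t in lags])
    return kinetics._weighted_msd_fit(lags, msd, n)


def _run_summary(config, sprout_tracks, events, tracks, member_tracks,
                 lattice) -> dict:
    lo, hi = config.analysis_window
    # rate and lifetimes follow the literal definition: every sprout
    # present in the window counts.  Final-frame occupancy and the
    # axis-referenced kinetics use only sprouts tracked for at least
    # min_sprout_frames samples — shorter ones are skeleton transients
    # whose leaders and axes are not meaningful.
    persistent = [t for t in sprout_tracks
                  if len(t.frames) >= config.min_sprout_frames]
    n_sprouts = sum(1 for t in sprout_tracks
                    if any(lo <= mcs <= hi for mcs, *_ in t.frames))
    summary: dict = {"n_sprouts": n_sprouts, "n_events": len(events),
                     "n_persistent_sprouts": len(persistent)}
    if n_sprouts > 0:
        summary["overtake_rate"] = kinetics.overtake_rate(
            events, n_sprouts, window=(lo, hi))
    leader_series = {t.sprout_id: t.leader_series for t in sprout_tracks}
    lifetimes = kinetics.tip_lifetimes(leader_series,
                                       mcs_seconds=config.cpm.mcs_seconds,
                                       stride=config.sample_stride)
    summary["tip_lifetime_min_mean"] = (float(lifetimes["minutes"].mean())
                                        if len(lifetimes) else np.nan)
    # persistence-restricted variants: same statistics on the >=80-MCS
    # tracked sprouts only, immune to the transient-sprout census noise
    persistent_ids = {t.sprout_id for t in persistent}
    n_persist_window = sum(1 for t in persistent
                           if any(lo <= mcs <= hi for mcs, *_ in t.frames))
    ev_persist = [e for e in events if e.sprout_id in persistent_ids]
    if n_persist_window > 0:
        summary["overtake_rate_persistent"] = kinetics.overtake_rate(
            ev_persist, n_persist_window, window=(lo, hi))
    series_persist = {t.sprout_id: t.leader_series for t in persistent}
    lt_persist = kinetics.tip_lifetimes(series_persist,
                                        mcs_seconds=config.cpm.mcs_seconds,
                                        stride=config.sample_stride)
    summary["tip_lifetime_persistent_min_mean"] = (
        float(lt_persist["minutes"].mean()) if len(lt_persist) else np.nan)
    summary.update(_pooled_kinetics(persistent, member_tracks,
                                    config.sample_stride))
    # end-of-run sprout leaders and their genotypes; a few frames spaced
    # beyond the leader decorrelation time are pooled, which keeps the
    # steady-state expectation of a single final frame while reducing its
    # sampling noise
    final_leaders = []
    final_frame_leaders = []
    last_mcs = max((t.frames[-1][0] for t in persistent), default=None)
    if last_mcs is not None:
        gap = config.occupancy_spacing * config.sample_stride
        wanted = {last_mcs - k * gap for k in range(config.occupancy_frames)}
        for t in persistent:
            for mcs, _, _, leader, _ in t.frames:
                if mcs in wanted:
                    final_leaders.append(int(lattice.genotype[leader]))
                if mcs == last_mcs:
                    # strictly one draw per sprout: suitable for binomial
                    # tests, where the pooled frames above are correlated
                    final_frame_leaders.append(int(lattice.genotype[leader]))
    summary["final_leader_genotypes"] = final_leaders
    summary["final_frame_leader_genotypes"] = final_frame_leaders
    summary["final_kinds"] = lattice.kind[1:].tolist()
    summary["final_genotypes"] = lattice.genotype[1:].tolist()
    return summary


def wt_tip_occupancy(leader_genotypes, mixing_ratio: float) -> OccupancyResult:
    """Fraction of sprout tips led by WT cells, with the binomial tail
    probability P(X >= k) under random mixing (X ~ Binomial(n, ratio))."""
    genos = np.asarray(list(leader_genotypes))
    n = len(genos)
    if n == 0:
        raise ValueError("no sprouts to score")
    k = int((genos == GENOTYPE_WT).sum())
    p = float(stats.binom.sf(k - 1, n, mixing_ratio))
    return OccupancyResult(n_sprouts=n, k_wt_led=k,
                           percentage=100.0 * k / n, p_binomial=p)


def tip_differentiation_fraction(kinds, genotypes):
    """Fractions of WT and haploid cells (whole population) that carry the
    tip phenotype."""
    kinds = np.asarray(kinds)
    genotypes = np.asarray(genotypes)
    out = []
    for g in (GENOTYPE_WT, GENOTYPE_VEGFR2_HAPLOID):
        sel = genotypes == g
        out.append(float((kinds[sel] == KIND_TIP).mean()) if sel.any() else np.nan)
    return tuple(out)
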