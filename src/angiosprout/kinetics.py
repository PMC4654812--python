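"""Tip-cell-overtake statistics, cell-track kinetics and MSD fitting.

Leader successions are read from per-sprout leader time series sampled
every 20 MCS; an overtake is the replacement of the leader by a neighbor
where both the outgoing and incoming leader hold the tip for at least 80
consecutive MCS (shorter flickers are protrusion noise and are ignored).
Cell-track statistics (coordination angle, directional motility, MSD)
follow the sprout elongation axis, defined by the branch-node and tip
positions averaged over a sprout's first and last frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

SAMPLE_STRIDE_MCS = 20
PERSISTENCE_MCS = 80
MCS_SECONDS = 30.0
SITE_UM = 2.0


@dataclass
class OvertakeEvent:
    sprout_id: int
    mcs: int
    old_leader: int
    new_leader: int


@dataclass
class SproutAxis:
    """Elongation axis from branch (start) to tip (end), in site units."""

    start: np.ndarray  # (y, x)
    end: np.ndarray

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if np.allclose(self.start, self.end):
            raise ValueError("degenerate sprout axis (start == end)")

    @property
    def unit(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)


def _leader_runs(series, stride: int):
    """Compress an ordered (mcs, leader) series into (leader, start_mcs,
    duration_mcs, truncated_left, truncated_right) runs.

    A run of k consecutive samples covers k*stride MCS of tenure.
    """
    items = sorted(series)
    runs = []
    for mcs, leader in items:
        if runs and runs[-1][0] == leader and mcs == runs[-1][1] + runs[-1][2]:
            runs[-1][2] += stride
        else:
            runs.append([leader, mcs, stride])
    out = []
    for i, (leader, start, dur) in enumerate(runs):
        out.append((leader, start, dur, i == 0, i == len(runs) - 1))
    return out


def detect_overtakes(leader_series: dict, *,
                     persistence_mcs: int = PERSISTENCE_MCS,
                     stride: int = SAMPLE_STRIDE_MCS) -> list:
    """Overtake events from per-sprout leader time series.

    ``leader_series`` maps sprout id to an iterable of (mcs, leader_id).
    Runs shorter than ``persistence_mcs`` are dropped before counting
    transitions; consecutive persistent runs of the same leader (separated
    only by flickers) are merged, so a flicker produces no event.
    """
    if persistence_mcs % stride != 0:
        raise ValueError("sampling stride must divide the persistence window")
    events = []
    for sid, series in leader_series.items():
        persistent = [(leader, start, dur)
                      for leader, start, dur, _, _ in _leader_runs(series, stride)
                      if dur >= persistence_mcs]
        merged = []
        for leader, start, dur in persistent:
            if merged and merged[-1][0] == leader:
                continue
            merged.append((leader, start, dur))
        for (old, _, _), (new, start_new, _) in zip(merged, merged[1:]):
            events.append(OvertakeEvent(sprout_id=sid, mcs=start_new,
                                        old_leader=old, new_leader=new))
    return events


def overtake_rate(events, n_sprouts: int,
                  window=(10_000, 30_000)) -> float:
    """Mean overtakes per sprout, normalized to a 20,000-MCS window.

    Counts events with ``mcs`` inside the window and divides by the number
    of sprouts present in it; the result is rescaled to the reference
    window length of 20,000 MCS.
    """
    if n_sprouts <= 0:
        raise ValueError("no sprouts present in the analysis window")
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty analysis window")
    count = sum(1 for e in events if lo <= e.mcs <= hi)
    return count / n_sprouts * (20_000.0 / (hi - lo))


def tip_lifetimes(leader_series: dict, *, mcs_seconds: float = MCS_SECONDS,
                  stride: int = SAMPLE_STRIDE_MCS) -> pd.DataFrame:
    """Leader tenure durations in minutes, one row per tenure.

    Tenures truncated by the sprout's birth or death are included and
    flagged in the ``truncated`` column.
    """
    rows = []
    for sid, series in leader_series.items():
        for leader, start, dur, tl, tr in _leader_runs(series, stride):
            rows.append({
                "sprout_id": sid, "leader": leader, "start_mcs": start,
                "duration_mcs": dur,
                "minutes": dur * mcs_seconds / 60.0,
                "truncated": tl or tr,
            })
    return pd.DataFrame(rows, columns=["sprout_id", "leader", "start_mcs",
                                       "duration_mcs", "minutes", "truncated"])


def _displacements(tracks: pd.DataFrame):
    """Per-cell per-interval displacement vectors (y, x) in sites."""
    out = []
    for _, sub in tracks.sort_values("mcs").groupby("cell_id"):
        pos = sub[["y", "x"]].to_numpy(dtype=float)
        if len(pos) < 2:
            continue
        out.append(np.diff(pos, axis=0))
    if not out:
        return np.zeros((0, 2))
    return np.vstack(out)


def coordination(tracks: pd.DataFrame, axis: SproutAxis) -> dict:
    """Angles between per-interval cell movement and the sprout axis.

    Returns the pooled theta series (radians, in [0, pi]) and std(theta/pi)
    split into anterograde (theta < pi/2) and retrograde (theta > pi/2)
    samples.  Zero displacements carry no direction and are excluded.
    """
    disp = _displacements(tracks)
    mag = np.linalg.norm(disp, axis=1)
    moving = disp[mag > 0]
    if len(moving) == 0:
        return {"theta": np.array([]), "std_anterograde": np.nan,
                "std_retrograde": np.nan}
    u = axis.unit
    cosang = (moving @ u) / np.linalg.norm(moving, axis=1)
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    ant = theta[theta < np.pi / 2] / np.pi
    ret = theta[theta > np.pi / 2] / np.pi
    return {
        "theta": theta,
        "std_anterograde": float(np.std(ant, ddof=1)) if len(ant) > 1 else np.nan,
        "std_retrograde": float(np.std(ret, ddof=1)) if len(ret) > 1 else np.nan,
    }


def directional_motility(tracks: pd.DataFrame, axis: SproutAxis, *,
                         stopped_threshold: float = 0.5) -> dict:
    """Percentages of anterograde / retrograde / stopped interval samples.

    A sample is stopped when its full 2D displacement is below the
    threshold (0.5 sites); otherwise its axial projection decides the
    direction.  The three percentages sum to exactly 100.
    """
    disp = _displacements(tracks)
    n = len(disp)
    if n == 0:
        return {"anterograde": 0.0, "retrograde": 0.0, "stopped": 100.0, "n": 0}
    mag = np.linalg.norm(disp, axis=1)
    stopped = mag < stopped_threshold
    proj = disp @ axis.unit
    antero = (~stopped) & (proj > 0)
    retro = (~stopped) & ~antero
    return {
        "anterograde": 100.0 * antero.sum() / n,
        "retrograde": 100.0 * retro.sum() / n,
        "stopped": 100.0 * stopped.sum() / n,
        "n": n,
    }


def msd_curve(tracks: pd.DataFrame, axis: SproutAxis, *,
              stride: int = SAMPLE_STRIDE_MCS):
    """One-dimensional MSD of axis-projected positions vs sprouting time.

    Each cell's track is re-timed from its first in-sprout sample; squared
    axial displacements from that first position are averaged over cells
    at each lag.  Returns (lag_seconds, msd_um2, n_samples) arrays.
    """
    u = axis.unit
    per_lag = {}
    for _, sub in tracks.sort_values("mcs").groupby("cell_id"):
        pos = sub[["y", "x"]].to_numpy(dtype=float)
        mcs = sub["mcs"].to_numpy()
        if len(pos) < 2:
            continue
        s = (pos - axis.start) @ u * SITE_UM  # axial coordinate, um
        lags = (mcs - mcs[0]) * MCS_SECONDS
        for lag, val in zip(lags[1:], (s[1:] - s[0]) ** 2):
            per_lag.setdefault(float(lag), []).append(float(val))
    if not per_lag:
        return np.array([]), np.array([]), np.array([])
    lag = np.array(sorted(per_lag))
    msd = np.array([np.mean(per_lag[t]) for t in lag])
    n = np.array([len(per_lag[t]) for t in lag])
    return lag, msd, n


def msd_fit(tracks: pd.DataFrame, axis: SproutAxis, *,
            stride: int = SAMPLE_STRIDE_MCS):
    """Fit MSD(t) = 2 D t + (v t)^2 to the axial MSD curve.

    Returns (D um^2/s, v um/s, covariance) with both parameters
    constrained non-negative.  Raises when fewer than three lags with at
    least two samples each are available.
    """
    lag, msd, n = msd_curve(tracks, axis, stride=stride)
    ok = n >= 2
    if ok.sum() < 3:
        raise ValueError("insufficient lag times for an MSD fit")
    return _weighted_msd_fit(lag[ok], msd[ok], n[ok])


def _weighted_msd_fit(lag, msd, n):
    """WLS fit of MSD(t) = 2Dt + (vt)^2 with D, v >= 0.

    Sample-mean MSD values have variance ~ 2*MSD^2/n (squared Gaussian
    displacements), so lags are weighted by sqrt(n)/MSD; this keeps the
    short-lag diffusive regime informative when drift dominates long lags.
    """

    def model(t, D, v):
        return 2.0 * D * t + (v * t) ** 2

    scale = max(msd.max(), 1e-12)
    p0 = (scale / (2 * lag.max()), np.sqrt(scale) / lag.max())
    sigma = np.maximum(msd, 1e-3 * scale) * np.sqrt(2.0 / n)
    popt, pcov = curve_fit(model, lag, msd, p0=p0, sigma=sigma,
                           bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20_000)
    return float(popt[0]), float(popt[1]), pcov
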