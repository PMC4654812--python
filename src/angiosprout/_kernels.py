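"""Numba-compiled inner loops for the Cellular Potts dynamics.

All per-cell bookkeeping (area, raw coordinate sums for centroid and
inertia tensor) is maintained incrementally inside the Monte Carlo kernel;
sums are exact because site coordinates are integers.  The same ``ΔH``
helper backs both the fast kernel and the python-level API so that the
contract surface and the production path cannot diverge.

Cell kinds are encoded as integers: 0 = ECM, 1 = tip, 2 = stalk.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Moore neighborhood (copy neighborhood and interfacial-energy neighborhood),
# in cyclic order so the local-connectivity arc test can walk the ring.
_RING = np.array(
    [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed numba's global RNG used by the Monte Carlo kernel."""
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _cell_length(area, sx, sy, sxx, syy, sxy):
    """Length of a cell from its inertia tensor: l = 4*sqrt(lambda_max/a).

    The covariance includes the per-site moment 1/12 (each unit square's
    own second moment), so a single site has length 4/sqrt(12) ~ 1.15.
    """
    if area <= 0:
        return 0.0
    a = float(area)
    mx = sx / a
    my = sy / a
    cxx = sxx / a - mx * mx + 1.0 / 12.0
    cyy = syy / a - my * my + 1.0 / 12.0
    cxy = sxy / a - mx * my
    half_tr = 0.5 * (cxx + cyy)
    det = np.sqrt(0.25 * (cxx - cyy) ** 2 + cxy * cxy)
    lam_max = half_tr + det
    if lam_max < 0.0:
        lam_max = 0.0
    return 4.0 * np.sqrt(lam_max)


@njit(cache=True)
def _length_penalty_delta(cid, gain, y, x, area, sx, sy, sxx, syy, sxy,
                          target_length, lam_length):
    """Change in lambda_length*(L - l)^2 for cell `cid` gaining/losing (y,x)."""
    lam = lam_length[cid]
    if lam == 0.0:
        return 0.0
    a0 = area[cid]
    l0 = _cell_length(a0, sx[cid], sy[cid], sxx[cid], syy[cid], sxy[cid])
    s = 1.0 if gain else -1.0
    a1 = a0 + (1 if gain else -1)
    l1 = _cell_length(
        a1,
        sx[cid] + s * x,
        sy[cid] + s * y,
        sxx[cid] + s * x * x,
        syy[cid] + s * y * y,
        sxy[cid] + s * x * y,
    )
    L = target_length[cid]
    return lam * ((L - l1) ** 2 - (L - l0) ** 2)


@njit(cache=True)
def _local_connectivity_violated(labels, y, x, cid):
    """True if removing site (y,x) from cell `cid` would split it locally.

    Walks the Moore ring around the site and counts arcs of `cid` sites;
    more than one arc means the removal disconnects the cell in the local
    neighborhood (conservative reject-by-penalty criterion).  Zero arcs
    means the site is the cell's last one.
    """
    h, w = labels.shape
    occ = np.zeros(8, dtype=np.int64)
    n_occ = 0
    for k in range(8):
        ny = y + _RING[k, 0]
        nx = x + _RING[k, 1]
        if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] == cid:
            occ[k] = 1
            n_occ += 1
    if n_occ == 0:
        return True  # last site of the cell
    arcs = 0
    for k in range(8):
        if occ[k] == 1 and occ[(k + 1) % 8] == 0:
            arcs += 1
    return arcs >= 2


@njit(cache=True)
def _delta_h_core(labels, sy0, sx0, ty0, tx0, kind, area, target_area,
                  sx, sy, sxx, syy, sxy, target_length, lam_length,
                  J, lam_size):
    """Non-bias part of ΔH for copying label at source onto target site.

    Returns the adhesion + area + length energy change; equals the
    difference of full Hamiltonians before/after the copy.
    """
    h, w = labels.shape
    s_lab = labels[sy0, sx0]
    t_lab = labels[ty0, tx0]
    dh = 0.0
    # adhesion: interfaces of the target site within the Moore neighborhood
    ks = kind[s_lab]
    kt = kind[t_lab]
    for k in range(8):
        ny = ty0 + _RING[k, 0]
        nx = tx0 + _RING[k, 1]
        if ny < 0 or ny >= h or nx < 0 or nx >= w:
            continue
        n_lab = labels[ny, nx]
        kn = kind[n_lab]
        if n_lab != t_lab:
            dh -= J[kt, kn]
        if n_lab != s_lab:
            dh += J[ks, kn]
    # area constraint
    if s_lab > 0:
        a = area[s_lab]
        A = target_area[s_lab]
        dh += lam_size * ((A - (a + 1.0)) ** 2 - (A - a) ** 2)
    if t_lab > 0:
        a = area[t_lab]
        A = target_area[t_lab]
        dh += lam_size * ((A - (a - 1.0)) ** 2 - (A - a) ** 2)
    # length constraint
    if s_lab > 0:
        dh += _length_penalty_delta(s_lab, True, ty0, tx0, area, sx, sy,
                                    sxx, syy, sxy, target_length, lam_length)
    if t_lab > 0:
        dh += _length_penalty_delta(t_lab, False, ty0, tx0, area, sx, sy,
                                    sxx, syy, sxy, target_length, lam_length)
    return dh


@njit(cache=True)
def _apply_copy(labels, ty0, tx0, s_lab, t_lab, area, sx, sy, sxx, syy, sxy):
    labels[ty0, tx0] = s_lab
    fy = float(ty0)
    fx = float(tx0)
    area[s_lab] += 1
    area[t_lab] -= 1
    if s_lab > 0:
        sx[s_lab] += fx
        sy[s_lab] += fy
        sxx[s_lab] += fx * fx
        syy[s_lab] += fy * fy
        sxy[s_lab] += fx * fy
    if t_lab > 0:
        sx[t_lab] -= fx
        sy[t_lab] -= fy
        sxx[t_lab] -= fx * fx
        syy[t_lab] -= fy * fy
        sxy[t_lab] -= fx * fy


@njit(cache=True)
def run_mcs_kernel(labels, kind, area, target_area, sx, sy, sxx, syy, sxy,
                   target_length, lam_length, J, lam_size, mu,
                   conn_penalty, lam_c, contact_inhibition, chemo, border):
    """One Monte Carlo step: width*height copy attempts.

    lam_c is indexed by cell kind; `chemo` is the chemoattractant grid
    (pass a zero array when chemotaxis is off).  Sites within `border`
    of the lattice edge are frozen.  Returns the number of accepted copies.
    """
    h, w = labels.shape
    n_attempts = h * w
    accepted = 0
    lo_y, hi_y = border, h - border
    lo_x, hi_x = border, w - border
    for _ in range(n_attempts):
        sy0 = np.random.randint(0, h)
        sx0 = np.random.randint(0, w)
        k = np.random.randint(0, 8)
        ty0 = sy0 + _RING[k, 0]
        tx0 = sx0 + _RING[k, 1]
        if ty0 < lo_y or ty0 >= hi_y or tx0 < lo_x or tx0 >= hi_x:
            continue
        if sy0 < lo_y or sy0 >= hi_y or sx0 < lo_x or sx0 >= hi_x:
            continue
        s_lab = labels[sy0, sx0]
        t_lab = labels[ty0, tx0]
        if s_lab == t_lab:
            continue
        dh = _delta_h_core(labels, sy0, sx0, ty0, tx0, kind, area,
                           target_area, sx, sy, sxx, syy, sxy,
                           target_length, lam_length, J, lam_size)
        # chemotaxis bias: lambda_c * (c(source) - c(target)); with contact
        # inhibition it acts only where a cell meets ECM
        active_kind = kind[s_lab] if s_lab > 0 else kind[t_lab]
        lc = lam_c[active_kind]
        if lc != 0.0:
            if (not contact_inhibition) or (s_lab == 0) != (t_lab == 0):
                dh += lc * (chemo[sy0, sx0] - chemo[ty0, tx0])
        # connectivity penalty for the retracting cell
        if t_lab > 0 and conn_penalty > 0.0:
            if _local_connectivity_violated(labels, ty0, tx0, t_lab):
                dh += conn_penalty
        if dh <= 0.0 or np.random.random() < np.exp(-dh / mu):
            _apply_copy(labels, ty0, tx0, s_lab, t_lab,
                        area, sx, sy, sxx, syy, sxy)
            accepted += 1
    return accepted


@njit(cache=True)
def field_steps_kernel(c, labels, alpha, epsilon, D_dt_dx2, dt, n_steps):
    """Explicit forward-Euler steps of the secretion-decay-diffusion PDE.

    Secretion under cells, decay in ECM, 5-point Laplacian with zero-flux
    boundaries (edge value mirrored).
    """
    h, w = c.shape
    # branchless reaction coefficients: add alpha*dt under cells,
    # multiply by (1 - eps*dt) in ECM
    add = np.empty((h, w))
    keep = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            if labels[y, x] > 0:
                add[y, x] = alpha * dt
                keep[y, x] = 0.0
            else:
                add[y, x] = 0.0
                keep[y, x] = epsilon * dt
    buf = np.empty_like(c)
    src = c
    dst = buf
    for _ in range(n_steps):
        for y in range(h):
            ym = y - 1 if y > 0 else 0
            yp = y + 1 if y < h - 1 else h - 1
            for x in range(w):
                xm = x - 1 if x > 0 else 0
                xp = x + 1 if x < w - 1 else w - 1
                v = src[y, x]
                lap = (src[ym, x] + src[yp, x] + src[y, xm] + src[y, xp]
                       - 4.0 * v)
                dst[y, x] = v + add[y, x] - keep[y, x] * v + D_dt_dx2 * lap
        src, dst = dst, src
    if src is not c:
        c[:, :] = src
    return c


@njit(cache=True)
def contact_map_kernel(labels, n_cells):
    """Membrane and pairwise contact site counts (4-neighborhood).

    A site of cell i is a membrane site if any of its 4 neighbors carries a
    different label (lattice edge counts as ECM).  It contributes one count
    to (i, j) for every distinct neighboring cell j it touches.  Returns
    (membrane[n_cells+1], contacts[n_cells+1, n_cells+1]) with the one-sided
    counts; symmetrize downstream.
    """
    h, w = labels.shape
    membrane = np.zeros(n_cells + 1, dtype=np.int64)
    contacts = np.zeros((n_cells + 1, n_cells + 1), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            i = labels[y, x]
            if i == 0:
                continue
            boundary = False
            seen0 = 0
            seen1 = 0
            seen2 = 0
            seen3 = 0
            for k in range(4):
                if k == 0:
                    ny, nx = y - 1, x
                elif k == 1:
                    ny, nx = y + 1, x
                elif k == 2:
                    ny, nx = y, x - 1
                else:
                    ny, nx = y, x + 1
                if ny < 0 or ny >= h or nx < 0 or nx >= w:
                    j = 0
                else:
                    j = labels[ny, nx]
                if j != i:
                    boundary = True
                    if j > 0:
                        dup = (j == seen0) or (j == seen1) or (j == seen2) or (j == seen3)
                        if not dup:
                            contacts[i, j] += 1.0
                if k == 0:
                    seen0 = j
                elif k == 1:
                    seen1 = j
                elif k == 2:
                    seen2 = j
                else:
                    seen3 = j
            if boundary:
                membrane[i] += 1
    return membrane, contacts
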