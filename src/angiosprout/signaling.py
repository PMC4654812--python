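"""Per-cell VEGF-Dll4-Notch signaling with contact-weighted trans-interactions.

Each cell i carries Dll4 (D_i), Notch (N_i) and NICD (S_i) levels; in the
VEGF extension also VEGFR2 (R_i) and VEGF signaling activity (A_i).  Dll4
on a cell activates Notch on its neighbors (trans-signaling), producing
NICD, which represses Dll4 production — the lateral-inhibition loop that
yields alternating ("salt-and-pepper") tip/stalk fates.  Dll4 and Notch on
the same cell also deactivate one another (cis-inhibition, coefficient
k_c).  Trans terms between cells i and j are weighted by the shared
membrane fraction |P_ij|^2 / (|P_i| |P_j|) and scaled by 1/d^2:

  dS_i/dt = alpha_S * Hill_nS( (1/d^2) sum_j N_i D_j w_ij ; k_S ) - gamma_S S_i
  dD_i/dt = beta_Dc + beta_D/(1+S_i^m_D) - gamma_D D_i - D_i N_i / k_c
            - (1/(k_t d^2)) sum_j D_i N_j w_ij   [+ alpha_D Hill(A_i) with VEGF]
  dN_i/dt = beta_N - gamma_N N_i - N_i D_i / k_c - (1/(k_t d^2)) sum_j N_i D_j w_ij

With uniform external VEGF V:

  dR_i/dt = beta_Rc + beta_R/(1+S_i^m_R) - gamma_R R_i   (productions halved
            for Vegfr2+/- cells)
  dA_i/dt = alpha_A * Hill_nA( R_i V ; k_A ) - gamma_A A_i

where R_i V is the VEGF signal perceived over the membrane (the membrane
average of R_i V_j, which reduces to R_i V for a uniform field).  Cells
with NICD below a threshold adopt the tip phenotype, the rest stalk.

Equations are integrated by forward Euler, 10 substeps of dt = 3 s per MCS
(30 s), with the contact map recomputed once per MCS.  Euler overshoots
below zero are clipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import contact_map_kernel
from .cpm import GENOTYPE_VEGFR2_HAPLOID, KIND_STALK, KIND_TIP, LatticeState


class CalibrationError(RuntimeError):
    """Threshold calibration failed (no bimodal NICD distribution)."""


@dataclass
class SignalingParams:
    """Rates of the Dll4-Notch ODEs and the VEGF extension.

    All rates are per second; levels are dimensionless.  Defaults were
    calibrated once so that (a) lateral inhibition on a contact graph
    produces an alternating tip/stalk pattern and (b) Dll4 and VEGFR2
    steady levels are positively correlated across cells.
    """

    # NICD production (Hill on trans signal) and decay
    alpha_S: float = 0.012
    k_S: float = 0.01
    n_S: float = 2.0
    gamma_S: float = 0.002
    # Dll4 production (constitutive + NICD-repressed), decay
    beta_Dc: float = 0.0002
    beta_D: float = 0.004
    m_D: float = 2.0
    gamma_D: float = 0.002
    # Notch production and decay
    beta_N: float = 0.004
    gamma_N: float = 0.002
    # cis-inhibition, trans-signaling, scaling
    k_c: float = 100.0
    k_t: float = 60.0
    d: float = 0.3873
    # VEGF activity
    alpha_A: float = 0.004
    k_A: float = 0.5
    n_A: float = 2.0
    gamma_A: float = 0.002
    # VEGFR2 production (constitutive + NICD-repressed), decay
    beta_Rc: float = 0.0004
    beta_R: float = 0.004
    m_R: float = 2.0
    gamma_R: float = 0.002
    # VEGF -> Dll4 positive feedback
    alpha_D_vegf: float = 0.012
    k_D: float = 0.1
    n_D: float = 4.0
    # external VEGF (uniform scalar field)
    V_ext: float = 1.0
    # phenotype switch and integration
    nicd_threshold: float = 1.0
    ode_dt: float = 3.0
    iters_per_mcs: int = 10

    def __post_init__(self) -> None:
        if min(self.k_c, self.k_t, self.d) <= 0:
            raise ValueError("k_c, k_t and d must be positive")
        if min(self.n_S, self.m_D, self.n_A, self.m_R, self.n_D) < 1:
            raise ValueError("Hill exponents must be >= 1")


@dataclass
class SignalingState:
    """Per-cell signaling levels, indexed by cell id (row 0 unused)."""

    D: np.ndarray
    N: np.ndarray
    S: np.ndarray
    R: np.ndarray
    A: np.ndarray
    clip_count: int = 0

    @classmethod
    def homogeneous(cls, n_cells: int, params: SignalingParams,
                    rng: np.random.Generator | None = None,
                    noise: float = 0.01) -> "SignalingState":
        """Start all cells at the no-contact steady state, plus small noise.

        Without neighbors, S decays to 0, D and N settle at the cis-coupled
        fixed point of their production/decay/cis terms (solved here by
        fixed-point iteration).  1 % multiplicative noise breaks the
        symmetry that lateral inhibition then amplifies.
        """
        D, N = 1.0, 1.0
        for _ in range(10_000):
            D_new = (params.beta_Dc + params.beta_D) / (params.gamma_D + N / params.k_c)
            N_new = params.beta_N / (params.gamma_N + D / params.k_c)
            if abs(D_new - D) + abs(N_new - N) < 1e-14:
                D, N = D_new, N_new
                break
            D, N = D_new, N_new
        R0 = (params.beta_Rc + params.beta_R) / params.gamma_R
        shape = n_cells + 1
        state = cls(D=np.full(shape, D), N=np.full(shape, N),
                    S=np.zeros(shape), R=np.full(shape, R0),
                    A=np.zeros(shape))
        if rng is not None and noise > 0:
            for arr in (state.D, state.N, state.R):
                arr[1:] *= 1.0 + noise * rng.standard_normal(n_cells)
                np.maximum(arr, 0.0, out=arr)
        state.D[0] = state.N[0] = state.R[0] = 0.0
        return state

    def clip_negative(self) -> None:
        for arr in (self.D, self.N, self.S, self.R, self.A):
            neg = arr < 0
            if np.any(neg):
                self.clip_count += int(neg.sum())
                arr[neg] = 0.0


@dataclass
class ContactMap:
    """Membrane sizes |P_i| and symmetric contact sizes |P_i,j|."""

    membrane: np.ndarray            # boundary-site count per cell
    contacts: np.ndarray            # (n+1, n+1) symmetric |P_i,j|
    _weights: np.ndarray | None = None

    def neighbors(self, cid: int) -> np.ndarray:
        return np.nonzero(self.contacts[cid] > 0)[0]

    def trans_weights(self) -> np.ndarray:
        """w_ij = |P_ij|^2 / (|P_i| |P_j|), zero where a membrane is empty.

        Memoized: the map is immutable once measured.
        """
        if self._weights is not None:
            return self._weights
        P = self.membrane.astype(float)
        denom = np.outer(P, P)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > 0, self.contacts ** 2 / denom, 0.0)
        np.fill_diagonal(w, 0.0)
        w[0, :] = 0.0
        w[:, 0] = 0.0
        self._weights = w
        return w


def compute_contact_map(lattice: LatticeState) -> ContactMap:
    """Measure membranes and pairwise contacts on the 4-neighborhood.

    A cell site is a membrane site if any 4-neighbor carries another label
    (the lattice edge counts as ECM); it contributes one count to |P_i,j|
    per distinct neighboring cell j.  One-sided counts are symmetrized by
    averaging so that |P_i,j| = |P_j,i| exactly.
    """
    membrane, contacts = contact_map_kernel(lattice.labels, lattice.n_cells)
    sym = 0.5 * (contacts + contacts.T)
    return ContactMap(membrane=membrane, contacts=sym)


def _hill(x: np.ndarray, k: float, n: float) -> np.ndarray:
    xn = np.power(np.maximum(x, 0.0), n)
    return xn / (k + xn)


def dll4_notch_derivatives(state: SignalingState, w: np.ndarray,
                           params: SignalingParams):
    """Right-hand sides of the three lateral-inhibition ODEs."""
    D, N, S = state.D, state.N, state.S
    trans_D_in = w @ D          # sum_j D_j w_ij
    trans_N_in = w @ N
    sig = (N * trans_D_in) / params.d ** 2
    dS = params.alpha_S * _hill(sig, params.k_S, params.n_S) - params.gamma_S * S
    cis_DN = D * N / params.k_c
    dD = (params.beta_Dc + params.beta_D / (1.0 + np.power(np.maximum(S, 0.0), params.m_D))
          - params.gamma_D * D - cis_DN
          - (D * trans_N_in) / (params.k_t * params.d ** 2))
    dN = (params.beta_N - params.gamma_N * N - cis_DN
          - (N * trans_D_in) / (params.k_t * params.d ** 2))
    return dD, dN, dS


def step_dll4_notch(state: SignalingState, contacts: ContactMap,
                    params: SignalingParams) -> SignalingState:
    """One forward-Euler step (dt = ode_dt) of the Dll4/Notch/NICD ODEs."""
    w = contacts.trans_weights()
    if w.shape[0] != state.D.shape[0]:
        raise ValueError("signaling state and contact map cover different cells")
    dD, dN, dS = dll4_notch_derivatives(state, w, params)
    dt = params.ode_dt
    state.D += dt * dD
    state.N += dt * dN
    state.S += dt * dS
    state.D[0] = state.N[0] = state.S[0] = 0.0
    state.clip_negative()
    return state


def vegf_derivatives(state: SignalingState, contacts: ContactMap,
                     params: SignalingParams, genotypes: np.ndarray):
    """Right-hand sides of the VEGFR2/VEGF-activity ODEs + extra Dll4 term."""
    S, R, A = state.S, state.R, state.A
    prod_scale = np.where(genotypes == GENOTYPE_VEGFR2_HAPLOID, 0.5, 1.0)
    if np.any((genotypes != GENOTYPE_VEGFR2_HAPLOID) & (genotypes != 0)):
        raise ValueError("unknown genotype code")
    dR = (prod_scale * (params.beta_Rc
                        + params.beta_R / (1.0 + np.power(np.maximum(S, 0.0), params.m_R)))
          - params.gamma_R * R)
    # membrane-averaged perceived VEGF: uniform V_ext reduces to R_i * V_ext
    perceived = R * params.V_ext
    dA = params.alpha_A * _hill(perceived, params.k_A, params.n_A) - params.gamma_A * A
    dD_extra = params.alpha_D_vegf * _hill(A, params.k_D, params.n_D)
    return dR, dA, dD_extra


def step_vegf_extension(state: SignalingState, contacts: ContactMap,
                        params: SignalingParams,
                        genotypes: np.ndarray) -> SignalingState:
    """One Euler step of the VEGF arm: updates R and A, adds the
    VEGF-driven Dll4 production to D."""
    dR, dA, dD_extra = vegf_derivatives(state, contacts, params, genotypes)
    dt = params.ode_dt
    state.R += dt * dR
    state.A += dt * dA
    state.D += dt * dD_extra
    state.R[0] = state.A[0] = state.D[0] = 0.0
    state.clip_negative()
    return state


def assign_phenotypes(state: SignalingState, params: SignalingParams) -> np.ndarray:
    """Tip where NICD is below threshold, stalk otherwise (ties -> stalk).

    Returns the per-cell kind-id array (row 0 is ECM and left untouched
    by callers).
    """
    kinds = np.where(state.S < params.nicd_threshold, KIND_TIP, KIND_STALK)
    return kinds.astype(np.int8)


def calibrate_nicd_threshold(steady_states) -> float:
    """Midpoint between the two modes of a bimodal steady NICD distribution.

    Splits the sorted values by the exact two-cluster (1D 2-means)
    partition and returns the midpoint of the cluster means.  Raises
    :class:`CalibrationError` when the distribution is not bimodal
    (degenerate spread or clusters closer than the pooled within-cluster
    spread).
    """
    vals = np.sort(np.asarray(list(steady_states), dtype=float))
    n = vals.size
    if n < 2 or vals[-1] - vals[0] < 1e-12:
        raise CalibrationError("NICD distribution is degenerate; no threshold")
    best = None
    for k in range(1, n):
        left, right = vals[:k], vals[k:]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if best is None or ss < best[0]:
            best = (ss, left.mean(), right.mean())
    ss, m1, m2 = best
    within = np.sqrt(ss / n)
    if (m2 - m1) < 2.0 * within:
        raise CalibrationError(
            f"NICD distribution not bimodal (modes {m1:.3g}, {m2:.3g}, "
            f"within-cluster spread {within:.3g})")
    return float(0.5 * (m1 + m2))
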