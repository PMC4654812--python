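"""Cellular Potts model core: lattice state, Hamiltonian, copy dynamics.

Cells are patches of connected sites on a 2D square lattice; each site
carries a cell identifier sigma (0 = extracellular matrix).  The effective
energy

    H = sum_(x,x') J(tau(sigma(x)), tau(sigma(x'))) (1 - delta(sigma(x), sigma(x')))
        + lambda_size * sum_sigma (A(sigma) - a(sigma))^2
        + sum_sigma lambda_length(sigma) (L(sigma) - l(sigma))^2

is minimized by Metropolis dynamics: a randomly chosen site copies its
identifier into a random adjacent site, and the copy is accepted with
probability min(1, exp(-dH/mu)).  One Monte Carlo step (MCS) performs as
many copy attempts as there are lattice sites and corresponds to 30 s.

The interfacial sum runs over unordered pairs of sites within the Moore
(8-) neighborhood; the copy neighborhood is also Moore.  A connectivity
penalty rejects copies that would locally split the retracting cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels

KIND_ECM = 0
KIND_TIP = 1
KIND_STALK = 2
KIND_NAMES = {KIND_ECM: "ECM", KIND_TIP: "tip", KIND_STALK: "stalk"}
KIND_IDS = {v: k for k, v in KIND_NAMES.items()}

GENOTYPE_WT = 0
GENOTYPE_VEGFR2_HAPLOID = 1
GENOTYPE_NAMES = {GENOTYPE_WT: "WT", GENOTYPE_VEGFR2_HAPLOID: "VEGFR2_HAPLOID"}


class ConsistencyError(RuntimeError):
    """Lattice and cell records disagree."""


class VacuousCopyError(ValueError):
    """Proposed copy between sites with identical labels (a no-op)."""


@dataclass
class CPMParams:
    """Parameters of the CPM Hamiltonian and Metropolis dynamics.

    ``J`` maps unordered cell-kind pairs (by name, e.g. ``("tip", "ECM")``)
    to interfacial energies; higher J means weaker adhesion.  ``mu`` is the
    membrane-fluctuation temperature (1 throughout).  ``lambda_length``
    maps cell kinds to the elongation-constraint weight (0 disables it).
    """

    J: dict = field(default_factory=lambda: {
        ("tip", "tip"): 0.4, ("tip", "stalk"): 0.4, ("stalk", "stalk"): 0.4,
        ("tip", "ECM"): 0.6, ("stalk", "ECM"): 0.6,
    })
    lambda_size: float = 1.0
    lambda_length: dict = field(default_factory=lambda: {"tip": 0.0, "stalk": 0.0})
    mu: float = 1.0
    connectivity_penalty: float = 1.0e7
    neighborhood_order: int = 2  # Moore neighborhood for copies and interfaces
    mcs_seconds: float = 30.0
    border: int = 1  # frozen ECM border width (sites)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.lambda_size < 0:
            raise ValueError("lambda_size must be non-negative")

    def j_matrix(self) -> np.ndarray:
        """Symmetric 3x3 interfacial-energy matrix indexed by kind id."""
        m = np.zeros((3, 3))
        for (a, b), v in self.J.items():
            ia, ib = KIND_IDS[a], KIND_IDS[b]
            m[ia, ib] = v
            m[ib, ia] = v
        return m

    def lambda_length_vector(self) -> np.ndarray:
        v = np.zeros(3)
        for name, val in self.lambda_length.items():
            v[KIND_IDS[name]] = val
        return v


@dataclass
class CellRecord:
    """Read-only per-cell view: geometry, type and constraint targets."""

    id: int
    kind: str
    genotype: str
    area: int
    target_area: float
    target_length: float
    current_length: float
    centroid: tuple  # (x, y) in site units


class LatticeState:
    """Integer label grid plus incrementally-maintained per-cell geometry.

    Per-cell raw coordinate sums (for centroids and the inertia tensor)
    are integers accumulated in float64, hence exact; a full recomputation
    is nevertheless exposed for consistency checks.
    """

    def __init__(self, labels: np.ndarray, *, site_size: float = 2.0,
                 target_area: float | np.ndarray = 49.0,
                 target_length: float | np.ndarray = 0.0,
                 kinds: np.ndarray | None = None,
                 genotypes: np.ndarray | None = None):
        labels = np.ascontiguousarray(labels, dtype=np.int32)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2D grid")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels
        self.site_size = site_size
        n = int(labels.max())
        self.n_cells = n
        self.kind = np.full(n + 1, KIND_STALK, dtype=np.int8)
        self.kind[0] = KIND_ECM
        if kinds is not None:
            self.kind[1:] = kinds
        self.genotype = np.zeros(n + 1, dtype=np.int8)
        if genotypes is not None:
            self.genotype[1:] = genotypes
        self.target_area = np.full(n + 1, 0.0)
        self.target_area[1:] = target_area
        self.target_length = np.full(n + 1, 0.0)
        self.target_length[1:] = target_length
        self._alloc_geometry()
        self.recompute_geometry()

    def _alloc_geometry(self) -> None:
        n = self.n_cells
        self.area = np.zeros(n + 1, dtype=np.int64)
        self.sx = np.zeros(n + 1)
        self.sy = np.zeros(n + 1)
        self.sxx = np.zeros(n + 1)
        self.syy = np.zeros(n + 1)
        self.sxy = np.zeros(n + 1)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def recompute_geometry(self) -> None:
        """Rebuild areas and coordinate sums from the label grid."""
        n = self.n_cells
        lab = self.labels.ravel()
        h, w = self.labels.shape
        yy, xx = np.divmod(np.arange(h * w, dtype=np.int64), w)
        self.area = np.bincount(lab, minlength=n + 1).astype(np.int64)
        self.sx = np.bincount(lab, weights=xx, minlength=n + 1)
        self.sy = np.bincount(lab, weights=yy, minlength=n + 1)
        self.sxx = np.bincount(lab, weights=xx.astype(float) ** 2, minlength=n + 1)
        self.syy = np.bincount(lab, weights=yy.astype(float) ** 2, minlength=n + 1)
        self.sxy = np.bincount(lab, weights=xx * yy.astype(float), minlength=n + 1)
        self.sx[0] = self.sy[0] = self.sxx[0] = self.syy[0] = self.sxy[0] = 0.0

    def centroids(self) -> np.ndarray:
        """(n_cells+1, 2) array of (x, y) centroids; row 0 is unused."""
        with np.errstate(invalid="ignore", divide="ignore"):
            cx = self.sx / self.area
            cy = self.sy / self.area
        return np.column_stack([cx, cy])

    def lengths(self) -> np.ndarray:
        """Current cell lengths from the inertia tensor (ellipse convention)."""
        out = np.zeros(self.n_cells + 1)
        for cid in range(1, self.n_cells + 1):
            out[cid] = _kernels._cell_length(
                self.area[cid], self.sx[cid], self.sy[cid],
                self.sxx[cid], self.syy[cid], self.sxy[cid])
        return out

    def cell_sites(self, cid: int) -> np.ndarray:
        """(k, 2) array of (y, x) member sites of cell `cid`."""
        ys, xs = np.nonzero(self.labels == cid)
        return np.column_stack([ys, xs])

    def records(self) -> list:
        lengths = self.lengths()
        cents = self.centroids()
        out = []
        for cid in range(1, self.n_cells + 1):
            if self.area[cid] == 0:
                continue
            out.append(CellRecord(
                id=cid,
                kind=KIND_NAMES[int(self.kind[cid])],
                genotype=GENOTYPE_NAMES[int(self.genotype[cid])],
                area=int(self.area[cid]),
                target_area=float(self.target_area[cid]),
                target_length=float(self.target_length[cid]),
                current_length=float(lengths[cid]),
                centroid=(float(cents[cid, 0]), float(cents[cid, 1])),
            ))
        return out

    def check_consistency(self) -> None:
        area = np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)
        if not np.array_equal(area, self.area):
            raise ConsistencyError("per-cell areas disagree with label grid")

    def copy(self) -> "LatticeState":
        other = LatticeState.__new__(LatticeState)
        other.labels = self.labels.copy()
        other.site_size = self.site_size
        other.n_cells = self.n_cells
        for name in ("kind", "genotype", "target_area", "target_length",
                     "area", "sx", "sy", "sxx", "syy", "sxy"):
            setattr(other, name, getattr(self, name).copy())
        return other

    def _lambda_length_cells(self, params: CPMParams) -> np.ndarray:
        """Per-cell elongation weight from the per-kind table."""
        per_kind = params.lambda_length_vector()
        return per_kind[self.kind]


def estimate_cell_length(member_sites: Sequence) -> float:
    """Cell length l = 4*sqrt(lambda_max/a) from the inertia tensor.

    ``member_sites`` is an iterable of (y, x) integer sites.  The largest
    eigenvalue of the second-moment tensor about the centroid (with the
    per-site 1/12 moment included) gives the squared semi-major axis of
    the equivalent ellipse; l is twice its major axis.
    """
    sites = np.asarray(list(member_sites), dtype=float)
    if sites.size == 0:
        raise ValueError("cell has no member sites")
    a = len(sites)
    y = sites[:, 0]
    x = sites[:, 1]
    return float(_kernels._cell_length(
        a, x.sum(), y.sum(), (x ** 2).sum(), (y ** 2).sum(), (x * y).sum()))


def hamiltonian(lattice: LatticeState, params: CPMParams) -> float:
    """Total CPM energy: adhesion + area constraint + length constraint.

    The interfacial sum counts each unordered Moore-neighbor pair once.
    """
    lattice.check_consistency()
    lab = lattice.labels
    kinds = lattice.kind[lab]
    J = params.j_matrix()
    e_adh = 0.0
    # four unique shift directions cover all unordered Moore pairs once
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a_lab = lab[max(0, -dy):lab.shape[0] - max(0, dy),
                    max(0, -dx):lab.shape[1] - max(0, dx)]
        b_lab = lab[max(0, dy):lab.shape[0] + min(0, dy),
                    max(0, dx):lab.shape[1] + min(0, dx)]
        a_kind = kinds[max(0, -dy):lab.shape[0] - max(0, dy),
                       max(0, -dx):lab.shape[1] - max(0, dx)]
        b_kind = kinds[max(0, dy):lab.shape[0] + min(0, dy),
                       max(0, dx):lab.shape[1] + min(0, dx)]
        diff = a_lab != b_lab
        e_adh += J[a_kind[diff], b_kind[diff]].sum()
    alive = lattice.area[1:] > 0
    e_area = params.lambda_size * float(
        ((lattice.target_area[1:] - lattice.area[1:]) ** 2)[alive].sum())
    lam_len = lattice._lambda_length_cells(params)[1:]
    if np.any(lam_len > 0):
        lengths = lattice.lengths()[1:]
        e_len = float((lam_len * (lattice.target_length[1:] - lengths) ** 2)[alive].sum())
    else:
        e_len = 0.0
    return e_adh + e_area + e_len


def delta_h_copy(lattice: LatticeState, source_site: tuple, target_site: tuple,
                 params: CPMParams,
                 bias_terms: Iterable[Callable] = ()) -> float:
    """Energy change of copying sigma(source) onto the target site.

    The non-bias part (adhesion + area + length) equals the difference of
    full Hamiltonians before and after the copy.  ``bias_terms`` are
    callables ``f(lattice, source_site, target_site) -> float`` (e.g. the
    chemotaxis bias or the connectivity penalty) whose values are added.
    """
    sy0, sx0 = source_site
    ty0, tx0 = target_site
    if abs(sy0 - ty0) > 1 or abs(sx0 - tx0) > 1 or source_site == target_site:
        raise ValueError("target must be adjacent to source in the Moore neighborhood")
    s_lab = int(lattice.labels[sy0, sx0])
    t_lab = int(lattice.labels[ty0, tx0])
    if s_lab == t_lab:
        raise VacuousCopyError("copy between identical labels is a no-op")
    lam_len = lattice._lambda_length_cells(params)
    dh = _kernels._delta_h_core(
        lattice.labels, sy0, sx0, ty0, tx0, lattice.kind,
        lattice.area, lattice.target_area,
        lattice.sx, lattice.sy, lattice.sxx, lattice.syy, lattice.sxy,
        lattice.target_length, lam_len, params.j_matrix(), params.lambda_size)
    for term in bias_terms:
        dh += term(lattice, source_site, target_site)
    return float(dh)


def connectivity_bias(params: CPMParams) -> Callable:
    """Bias term adding the connectivity penalty for locally-splitting copies."""

    def term(lattice: LatticeState, source_site: tuple, target_site: tuple) -> float:
        ty0, tx0 = target_site
        t_lab = int(lattice.labels[ty0, tx0])
        if t_lab > 0 and _kernels._local_connectivity_violated(
                lattice.labels, ty0, tx0, t_lab):
            return params.connectivity_penalty
        return 0.0

    return term


def accept_copy(delta_h: float, params: CPMParams, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept iff dH <= 0 or with probability exp(-dH/mu)."""
    if delta_h <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_h / params.mu))


def seed_dynamics(seed: int) -> None:
    """Seed the RNG driving the compiled Monte Carlo kernel."""
    _kernels.seed_kernel_rng(int(seed) & 0x7FFFFFFF)


def run_mcs(lattice: LatticeState, params: CPMParams, *,
            chemo: np.ndarray | None = None,
            lambda_c: np.ndarray | None = None,
            contact_inhibition: bool = False,
            n_mcs: int = 1) -> int:
    """Run `n_mcs` Monte Carlo steps in place; returns accepted-copy count.

    ``chemo`` is the chemoattractant grid and ``lambda_c`` the per-kind
    chemotactic strength (indexed by kind id); both default to no
    chemotaxis.  Seed the dynamics once per simulation with
    :func:`seed_dynamics` for reproducibility.
    """
    if chemo is None:
        chemo = np.zeros(lattice.shape)
    if lambda_c is None:
        lambda_c = np.zeros(3)
    lam_len = lattice._lambda_length_cells(params)
    accepted = 0
    for _ in range(n_mcs):
        accepted += _kernels.run_mcs_kernel(
            lattice.labels, lattice.kind, lattice.area, lattice.target_area,
            lattice.sx, lattice.sy, lattice.sxx, lattice.syy, lattice.sxy,
            lattice.target_length, lam_len, params.j_matrix(),
            params.lambda_size, params.mu, params.connectivity_penalty,
            np.asarray(lambda_c, dtype=float), contact_inhibition,
            np.ascontiguousarray(chemo, dtype=float), params.border)
    return accepted
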