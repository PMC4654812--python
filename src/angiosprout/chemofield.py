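"""Secreted chemoattractant reaction-diffusion field and chemotaxis bias.

The endothelial cells secrete a short-lived diffusible attractant c(x):

    dc/dt = alpha * [inside a cell] - epsilon * [in ECM] * c + D * laplacian(c)

i.e. secretion at rate alpha (s^-1) under cells, first-order decay at rate
epsilon (s^-1) in the ECM only, and diffusion at rate D (m^2/s) everywhere.
The field lives on the CPM lattice (dx = 2 um) and is advanced by an
explicit forward-Euler / 5-point-Laplacian scheme with dt = 2 s, 15 steps
per Monte Carlo step (so 30 s of diffusion per MCS).  Boundaries are
zero-flux.  The steady-state decay length in the ECM is sqrt(D/epsilon);
with the defaults (D = 1e-13 m^2/s, epsilon = 1.8e-4 s^-1) this is about
24 um, roughly one to two cell diameters.

The chemotaxis bias lowers dH for copies up the local gradient:
dH_chemotaxis = dH + lambda_c * (c(source) - c(target)).  In the
contact-inhibition model the bias acts only where a cell meets the ECM.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .cpm import KIND_ECM, KIND_IDS, LatticeState


@dataclass
class ChemField:
    """Chemoattractant concentration grid and its PDE parameters."""

    c: np.ndarray
    alpha: float = 3.6e-4      # secretion rate, s^-1
    epsilon: float = 1.8e-4    # ECM decay rate, s^-1
    D_coef: float = 1.0e-13    # diffusion coefficient, m^2/s
    dt: float = 2.0            # s
    dx: float = 2.0e-6         # m (one lattice site)
    steps_per_mcs: int = 15

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 2:
            raise ValueError("concentration grid must be 2D")
        if self.stability_number > 0.25:
            raise ValueError(
                f"explicit scheme unstable: D*dt/dx^2 = {self.stability_number:.3f} > 0.25")
        if self.epsilon * self.dt > 1.0:
            raise ValueError("decay step epsilon*dt exceeds 1; reduce dt")

    @property
    def stability_number(self) -> float:
        return self.D_coef * self.dt / self.dx ** 2

    @classmethod
    def zeros(cls, shape, **kwargs) -> "ChemField":
        return cls(c=np.zeros(shape), **kwargs)

    def total_mass(self) -> float:
        return float(self.c.sum())


def step_field(field: ChemField, lattice: LatticeState) -> ChemField:
    """One explicit finite-difference update of the field (in place).

    Secretion under cells, decay in ECM, 5-point Laplacian diffusion with
    zero-flux (Neumann) boundaries.
    """
    c = field.c
    if c.shape != lattice.shape:
        raise ValueError("field and lattice shapes differ")
    inside = lattice.labels > 0
    pad = np.pad(c, 1, mode="edge")
    lap = (pad[:-2, 1:-1] + pad[2:, 1:-1] + pad[1:-1, :-2] + pad[1:-1, 2:]
           - 4.0 * c)
    c += field.dt * (field.alpha * inside
                     - field.epsilon * (~inside) * c) \
        + (field.D_coef * field.dt / field.dx ** 2) * lap
    return field


def run_field_mcs(field: ChemField, lattice: LatticeState) -> ChemField:
    """Advance the field over one MCS: `steps_per_mcs` explicit steps.

    Runs the compiled update; identical (to floating-point round-off in
    summation order) to composing :func:`step_field`.
    """
    if field.c.shape != lattice.shape:
        raise ValueError("field and lattice shapes differ")
    _kernels.field_steps_kernel(
        field.c, lattice.labels, field.alpha, field.epsilon,
        field.D_coef * field.dt / field.dx ** 2, field.dt,
        field.steps_per_mcs)
    return field


@dataclass
class ChemotaxisParams:
    """Chemotactic strength per cell kind and the contact-inhibition switch."""

    lambda_c: dict = dc_field(default_factory=lambda: {"tip": 10.0, "stalk": 10.0})
    contact_inhibition: bool = False

    def lambda_c_vector(self) -> np.ndarray:
        v = np.zeros(3)
        for name, val in self.lambda_c.items():
            if val < 0:
                raise ValueError("lambda_c must be non-negative")
            v[KIND_IDS[name]] = val
        return v


def chemotaxis_bias(field: ChemField, source_site, target_site,
                    source_kind: int, target_kind: int,
                    params: ChemotaxisParams) -> float:
    """dH contribution lambda_c * (c(source) - c(target)) of a copy attempt.

    ``source_kind``/``target_kind`` are kind ids of the labels at the two
    sites; the strength is that of the moving (non-ECM) cell.  With contact
    inhibition on, the bias is zero unless the copy is at a cell-ECM
    interface (exactly one side is ECM).
    """
    active = source_kind if source_kind != KIND_ECM else target_kind
    if active == KIND_ECM:
        return 0.0
    if params.contact_inhibition and (
            (source_kind == KIND_ECM) == (target_kind == KIND_ECM)):
        return 0.0
    lam = params.lambda_c_vector()[active]
    if lam == 0.0:
        return 0.0
    sy, sx = source_site
    ty, tx = target_site
    return float(lam * (field.c[sy, sx] - field.c[ty, tx]))


def make_chemotaxis_bias(field: ChemField, params: ChemotaxisParams):
    """Adapter giving a bias term usable with :func:`angiosprout.cpm.delta_h_copy`."""

    def term(lattice: LatticeState, source_site, target_site) -> float:
        s_kind = int(lattice.kind[lattice.labels[source_site]])
        t_kind = int(lattice.kind[lattice.labels[target_site]])
        return chemotaxis_bias(field, source_site, target_site,
                               s_kind, t_kind, params)

    return term
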