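"""Reaction-diffusion engine: Monod growth plus finite-difference diffusion.

The model tracks one biomass field per lineage (a lineage may be a genotype
or an individual founder) and a single shared resource field on a square
lattice, with either toroidal (periodic) or no-flux (reflecting) boundaries.
Each time step is operator-split: first the per-box Monod reaction

    dB_i/dt =  mu_i * B_i * R/(R+k)
    dR/dt   = -sum_i lam * mu_i * B_i * R/(R+k)

is integrated over dt, then each field is diffused with an explicit 5-point
forward-Euler stencil.  The diffusion step is only stable (and positivity
preserving) for dt <= 0.25*dx^2/D; runs use the stricter accuracy bound
dt <= 0.1*dx^2/D, with D the largest diffusion constant in play.

Works identically for the physical ("full") parameterization and for the
dimensionless ("scaled") one, where the resource diffusion constant, k and
lam are all 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.integrate import solve_ivp

from .scaling import FullParams, ScaledParams

__all__ = [
    "Domain",
    "SimState",
    "StepControl",
    "StabilityError",
    "stability_dt",
    "diffuse_step",
    "growth_step",
    "step",
    "run_until_consumed",
    "run_well_mixed",
]

#: fraction of the explicit-stability dt bound actually permitted (accuracy)
DT_SAFETY = 0.1
#: target max(mu)*dt per RK4 substep inside the reaction update
GROWTH_SUBSTEP_TARGET = 0.05


class StabilityError(ValueError):
    """Raised when a requested dt violates the explicit diffusion bound."""


@dataclass(frozen=True)
class Domain:
    """Lattice geometry: nx*ny boxes of width dx, torus or no-flux edges."""

    nx: int
    ny: int
    dx: float
    boundary: str = "torus"

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("lattice must be at least 3x3")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.boundary not in ("torus", "no_flux"):
            raise ValueError("boundary must be 'torus' or 'no_flux'")

    @property
    def shape(self) -> tuple[int, int]:
        # field arrays are indexed [j (y), i (x)]
        return (self.ny, self.nx)

    @property
    def n_boxes(self) -> int:
        return self.nx * self.ny

    @property
    def area(self) -> float:
        return self.nx * self.ny * self.dx**2


@dataclass
class SimState:
    """Spatial state: resource field, per-lineage biomass stack, elapsed time.

    ``B_fields`` has shape ``(n_lineages, ny, nx)``; ``lineage_genotype[l]``
    gives the genotype index (into the params' mu vector) of lineage l.
    """

    R_field: np.ndarray
    B_fields: np.ndarray
    lineage_genotype: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.R_field = np.asarray(self.R_field, dtype=float)
        self.B_fields = np.asarray(self.B_fields, dtype=float)
        self.lineage_genotype = np.asarray(self.lineage_genotype, dtype=int)
        if self.B_fields.ndim != 3 or self.B_fields.shape[1:] != self.R_field.shape:
            raise ValueError("B_fields must be (n_lineages, ny, nx) matching R_field")
        if self.lineage_genotype.shape != (self.B_fields.shape[0],):
            raise ValueError("one genotype index per lineage required")
        if np.any(self.R_field < 0) or np.any(self.B_fields < 0):
            raise ValueError("fields must be nonnegative")

    def genotype_totals(self, n_genotypes: int) -> np.ndarray:
        """Total biomass per genotype, summing lineages."""
        per_lineage = self.B_fields.sum(axis=(1, 2))
        return np.bincount(self.lineage_genotype, weights=per_lineage,
                           minlength=n_genotypes)

    def copy(self) -> "SimState":
        return SimState(self.R_field.copy(), self.B_fields.copy(),
                        self.lineage_genotype.copy(), self.t)


@dataclass(frozen=True)
class StepControl:
    """Time-stepping control.

    ``dt`` must satisfy the explicit stability bound ``dt <= 0.1*dx^2/D_max``;
    ``consumed_frac_stop`` is the resource-consumption fraction at which batch
    runs stop (0.99: run until >99% of resources are consumed); ``max_steps``
    guards against non-terminating runs.
    """

    dt: float
    consumed_frac_stop: float = 0.99
    max_steps: int = 5_000_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.consumed_frac_stop < 1:
            raise ValueError("consumed_frac_stop must be in (0, 1)")


def stability_dt(dx: float, D_max: float) -> float:
    """Largest permitted time step, 0.1*dx^2/D_max."""
    if dx <= 0 or D_max <= 0:
        raise ValueError("dx and D_max must be positive")
    return DT_SAFETY * dx**2 / D_max


def _check_dt(dt: float, dx: float, D: float) -> None:
    bound = stability_dt(dx, D)
    if dt > bound * (1 + 1e-9):
        raise StabilityError(
            f"dt={dt:g} exceeds the stability bound 0.1*dx^2/D={bound:g}; "
            "reduce dt explicitly (no silent sub-stepping is performed)")


def _laplacian(f: np.ndarray, boundary: str) -> np.ndarray:
    # acts on the last two axes so a whole lineage stack diffuses at once
    if boundary == "torus":
        return (np.roll(f, 1, -1) + np.roll(f, -1, -1)
                + np.roll(f, 1, -2) + np.roll(f, -1, -2) - 4.0 * f)
    pad = [(0, 0)] * (f.ndim - 2) + [(1, 1), (1, 1)]
    g = np.pad(f, pad, mode="edge")  # zero-gradient ghost cells: no edge flux
    return (g[..., 1:-1, :-2] + g[..., 1:-1, 2:]
            + g[..., :-2, 1:-1] + g[..., 2:, 1:-1] - 4.0 * f)


def diffuse_step(field: np.ndarray, D: float, dt: float, domain: Domain) -> np.ndarray:
    """One explicit forward-Euler diffusion step of the 5-point stencil.

    Conserves total mass on both boundary types and preserves nonnegativity
    whenever dt satisfies the stability bound (which is checked, never
    silently repaired).
    """
    field = np.asarray(field, dtype=float)
    _check_dt(dt, domain.dx, D)
    return field + (D * dt / domain.dx**2) * _laplacian(field, domain.boundary)


def growth_step(
    B_box: np.ndarray,
    R_box: Union[float, np.ndarray],
    mu: np.ndarray,
    k: float,
    lam: float,
    dt: float,
    *,
    dilution_rate: float = 0.0,
    reservoir_R: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the per-box Monod reaction over dt.

    ``B_box`` carries lineages on its leading axis and may be a vector (one
    box) or a full ``(L, ny, nx)`` stack; ``mu`` gives the per-lineage
    maximum rates.  Integration is classical RK4 with substeps chosen so
    ``max(mu)*dt_sub <= 0.05``; afterwards the resource is recomputed from
    the realized biomass gain (``R' = R - lam*sum(dB)``), so batch
    conservation holds exactly regardless of integration error.  If the gain
    would overdraw a box, the gain is capped and R clipped at 0.

    With ``dilution_rate`` > 0 a chemostat term is added to the reaction:
    ``dR/dt += delta*(reservoir_R - R)`` and ``dB_i/dt -= delta*B_i``; the
    exact-balance correction is skipped (the system is then open).
    """
    B0 = np.asarray(B_box, dtype=float)
    R0 = np.asarray(R_box, dtype=float)
    if np.any(B0 < 0) or np.any(R0 < 0):
        raise ValueError("biomass and resource must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu = np.asarray(mu, dtype=float).reshape((-1,) + (1,) * R0.ndim)
    if mu.shape[0] != B0.shape[0]:
        raise ValueError("one mu per lineage required")

    chemo = dilution_rate > 0.0
    rate_scale = max(float(mu.max()), dilution_rate)
    nsub = max(1, int(np.ceil(rate_scale * dt / GROWTH_SUBSTEP_TARGET)))
    h = dt / nsub

    def rhs(B: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # RK4 stage values of R may overshoot below 0 at a depletion front;
        # clamp so the Monod factor stays in [0, 1) (no growth without resource,
        # and no pole at R = -k)
        Rpos = np.maximum(R, 0.0)
        phi = Rpos / (Rpos + k)
        dB = mu * B * phi
        dR = -lam * dB.sum(axis=0)
        if chemo:
            dB = dB - dilution_rate * B
            dR = dR + dilution_rate * (reservoir_R - R)
        return dB, dR

    B, R = B0.copy(), R0.copy()
    for _ in range(nsub):
        k1B, k1R = rhs(B, R)
        k2B, k2R = rhs(B + 0.5 * h * k1B, R + 0.5 * h * k1R)
        k3B, k3R = rhs(B + 0.5 * h * k2B, R + 0.5 * h * k2R)
        k4B, k4R = rhs(B + h * k3B, R + h * k3R)
        B = B + (h / 6.0) * (k1B + 2.0 * k2B + 2.0 * k3B + k4B)
        R = R + (h / 6.0) * (k1R + 2.0 * k2R + 2.0 * k3R + k4R)
        R = np.maximum(R, 0.0)
        B = np.maximum(B, 0.0)

    if not chemo:
        dB = B - B0
        demand = lam * dB.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(demand > R0, R0 / np.where(demand > 0, demand, 1.0), 1.0)
        B = B0 + dB * factor
        R = np.maximum(R0 - lam * (B - B0).sum(axis=0), 0.0)
    return B, R


def _engine_params(params: Union[FullParams, ScaledParams]
                   ) -> tuple[float, float, np.ndarray, float, float]:
    """(D_B, D_R, mu, k, lam) in whichever unit system params lives in."""
    if isinstance(params, FullParams):
        return params.D_B, params.D_R, np.asarray(params.mu), params.k, params.lam
    if isinstance(params, ScaledParams):
        return params.D_c, 1.0, np.asarray(params.mu_rel), 1.0, 1.0
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def step(
    state: SimState,
    params: Union[FullParams, ScaledParams],
    ctrl: StepControl,
    domain: Domain,
    *,
    dilution_rate: float = 0.0,
    reservoir_R: float = 0.0,
) -> SimState:
    """One operator-split step: growth in every box, then diffusion of all fields."""
    D_B, D_R, mu, k, lam = _engine_params(params)
    _check_dt(ctrl.dt, domain.dx, max(D_B, D_R))
    mu_lineage = mu[state.lineage_genotype]
    B, R = growth_step(state.B_fields, state.R_field, mu_lineage, k, lam,
                       ctrl.dt, dilution_rate=dilution_rate,
                       reservoir_R=reservoir_R)
    B = B + (D_B * ctrl.dt / domain.dx**2) * _laplacian(B, domain.boundary)
    R = R + (D_R * ctrl.dt / domain.dx**2) * _laplacian(R, domain.boundary)
    return SimState(R, B, state.lineage_genotype, state.t + ctrl.dt)


def run_until_consumed(
    state: SimState,
    params: Union[FullParams, ScaledParams],
    ctrl: StepControl,
    domain: Domain,
) -> SimState:
    """Iterate :func:`step` until > ``consumed_frac_stop`` of the initial
    resource is consumed (batch/serial-transfer stop rule).

    Raises ``RuntimeError`` after ``ctrl.max_steps`` steps if the threshold is
    never reached (e.g. all-zero biomass on a full resource field).
    """
    initial = float(state.R_field.sum())
    if initial <= 0:
        raise ValueError("initial total resource must be positive")
    target = (1.0 - ctrl.consumed_frac_stop) * initial
    current = state
    for _ in range(ctrl.max_steps):
        if current.R_field.sum() <= target:
            return current
        current = step(current, params, ctrl, domain)
    raise RuntimeError(
        f"consumption threshold not reached within {ctrl.max_steps} steps")


def run_well_mixed(
    B0: np.ndarray,
    R0_total: float,
    mu: np.ndarray,
    k: float,
    lam: float,
    consumed_frac_stop: float = 0.99,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Mass-action (spaceless) batch run to the consumption stop.

    Integrates dB_i/dt = mu_i*B_i*R/(R+k), dR/dt = -lam*sum(...) until
    ``consumed_frac_stop`` of ``R0_total`` is consumed and returns the final
    per-genotype biomass.  Because every genotype shares the same Monod
    factor, ln(B_i(T)/B_i(0)) ratios equal the corresponding mu ratios
    exactly; integration is carried out in relative time tau = mu[0]*t so
    the outcome is bit-identical across absolute rates at fixed ratios.
    """
    B0 = np.asarray(B0, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(B0 < 0) or B0.sum() <= 0 or R0_total <= 0:
        raise ValueError("need nonnegative biomass with positive total and R0_total > 0")
    if np.any(mu <= 0):
        raise ValueError("growth rates must be positive")
    mu_rel = mu / mu[0]
    scale = B0.sum() + R0_total

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        B, R = y[:-1], y[-1]
        phi = R / (R + k)
        dB = mu_rel * B * phi
        return np.append(dB, -lam * dB.sum())

    def consumed(t: float, y: np.ndarray) -> float:
        return y[-1] - (1.0 - consumed_frac_stop) * R0_total

    consumed.terminal = True  # type: ignore[attr-defined]
    consumed.direction = -1  # type: ignore[attr-defined]

    # crude upper bound on the relative time needed to exhaust the resource
    b_min = B0[B0 > 0].min()
    tau_max = (np.log1p(consumed_frac_stop * R0_total / (lam * b_min))
               / mu_rel.min() + 10.0)
    sol = solve_ivp(rhs, (0.0, tau_max), np.append(B0, R0_total),
                    events=consumed, rtol=rtol, atol=1e-12 * scale,
                    method="RK45")
    if not sol.t_events[0].size:
        raise RuntimeError("consumption threshold not reached in well-mixed run")
    return sol.y_events[0][0][:-1]
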