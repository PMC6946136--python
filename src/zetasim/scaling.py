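"""Dimensional analysis for the resource-explicit competition model.

The full reaction-diffusion model is parameterized by physical constants
(diffusion constants in cm^2/h, growth rates in 1/h, resources in arbitrary
units).  Dividing each state variable by a characteristic quantity of the
same dimension collapses the model onto a dimensionless ("scaled") form in
which the resource diffusion constant is 1 and the fastest genotype grows at
rate 1.  The characteristic length

    x_c = sqrt(D_R / mu_1)

is the distance the resource diffuses in one characteristic growth time; it
sets the spatial scale over which colonies share resources.  The scaled mean
intercolony distance

    zeta = IC_bar / x_c

is the single dimensionless knob coupling growth rate, founder spacing and
resource diffusion: colonies much closer than x_c (zeta << 1) compete
globally, colonies much farther apart (zeta >> 1) compete only with their
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FullParams",
    "ScalingTransform",
    "ScaledParams",
    "SpatialSummary",
    "natural_length_scale",
    "to_scaled",
    "from_scaled",
    "compute_zeta",
    "full_params_from_config",
]

#: factor converting cm^2/s to cm^2/h
_S_TO_H = 3600.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class FullParams:
    """Physical ("full" model) parameters.

    Attributes
    ----------
    D_B : float
        Diffusion constant of the bacteria (cm^2/h).
    D_R : float
        Diffusion constant of the resource (cm^2/h).
    mu : tuple of float
        Per-genotype maximum growth rates (1/h), sorted so ``mu[0]`` is the
        fastest (the scaling divides by the fastest rate).
    k : float
        Monod half-saturation constant (resource units).
    lam : float
        Yield coefficient: resources consumed per unit of new biomass.
    R0 : float
        Initial resource per lattice box (resource units).
    """

    D_B: float
    D_R: float
    mu: tuple[float, ...]
    k: float
    lam: float
    R0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        _require_positive(D_B=self.D_B, D_R=self.D_R, k=self.k,
                          lam=self.lam, R0=self.R0)
        if len(self.mu) == 0:
            raise ValueError("mu must contain at least one growth rate")
        _require_positive(mu=self.mu)
        if self.mu[0] != max(self.mu):
            raise ValueError("mu must be sorted fastest-first (mu[0] = max)")


@dataclass(frozen=True)
class ScalingTransform:
    """Characteristic quantities linking the full and scaled models.

    ``R_c = k`` (resource), ``B_c = k/lam`` (biomass), ``t_c = 1/mu_1``
    (time, h), ``x_c = sqrt(D_R/mu_1)`` (length, cm).
    """

    R_c: float
    B_c: float
    t_c: float
    x_c: float

    def __post_init__(self) -> None:
        _require_positive(R_c=self.R_c, B_c=self.B_c, t_c=self.t_c,
                          x_c=self.x_c)


@dataclass(frozen=True)
class ScaledParams:
    """Dimensionless model parameters.

    ``D_c = D_B/D_R`` is the relative bacterial diffusion constant,
    ``mu_rel[i] = mu[i]/mu[0]`` the relative growth rates (``mu_rel[0] = 1``),
    ``R0_hat = R0/k`` the scaled initial resource per box.  In the scaled
    model the resource diffuses with constant 1, k = 1 and lam = 1.
    """

    D_c: float
    mu_rel: tuple[float, ...]
    R0_hat: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_rel", tuple(float(m) for m in self.mu_rel))
        _require_positive(D_c=self.D_c, R0_hat=self.R0_hat)
        if len(self.mu_rel) == 0:
            raise ValueError("mu_rel must contain at least one rate")
        _require_positive(mu_rel=self.mu_rel)
        if abs(self.mu_rel[0] - 1.0) > 1e-12:
            raise ValueError("mu_rel[0] must equal 1 (rates relative to the fastest)")
        if any(m > 1.0 + 1e-12 for m in self.mu_rel):
            raise ValueError("all mu_rel must lie in (0, 1]")


@dataclass(frozen=True)
class SpatialSummary:
    """Per-colony nearest-neighbor distances and their scaled mean.

    ``ic_i[i]`` is colony i's minimum center-to-center distance to any other
    colony; ``ic_bar`` is the arithmetic mean of ``ic_i``; ``zeta`` is
    ``ic_bar`` divided by the natural length scale (``None`` when no length
    scale has been attached yet).
    """

    ic_i: np.ndarray
    ic_bar: float
    zeta: float | None = None

    def __post_init__(self) -> None:
        ic = np.asarray(self.ic_i, dtype=float)
        object.__setattr__(self, "ic_i", ic)
        if np.any(ic < 0):
            raise ValueError("intercolony distances must be nonnegative")
        if not np.isclose(self.ic_bar, ic.mean(), rtol=1e-9, atol=0.0):
            raise ValueError("ic_bar must be the mean of ic_i")


def natural_length_scale(D_R: float, mu1: float) -> float:
    """Natural length scale x_c = sqrt(D_R/mu1), in cm.

    Parameters
    ----------
    D_R : float
        Resource diffusion constant (cm^2/h).
    mu1 : float
        Maximum growth rate of the fastest genotype (1/h).
    """
    _require_positive(D_R=D_R, mu1=mu1)
    return float(np.sqrt(D_R / mu1))


def to_scaled(p: FullParams) -> tuple[ScaledParams, ScalingTransform]:
    """Nondimensionalize full-model parameters.

    Returns the scaled parameters together with the transform holding the
    characteristic quantities, so the conversion can be inverted exactly with
    :func:`from_scaled`.
    """
    mu1 = p.mu[0]
    transform = ScalingTransform(
        R_c=p.k,
        B_c=p.k / p.lam,
        t_c=1.0 / mu1,
        x_c=natural_length_scale(p.D_R, mu1),
    )
    scaled = ScaledParams(
        D_c=p.D_B / p.D_R,
        mu_rel=tuple(m / mu1 for m in p.mu),
        R0_hat=p.R0 / p.k,
    )
    return scaled, transform


def from_scaled(s: ScaledParams, t: ScalingTransform) -> FullParams:
    """Exact algebraic inverse of :func:`to_scaled`."""
    mu1 = 1.0 / t.t_c
    D_R = t.x_c**2 * mu1
    k = t.R_c
    return FullParams(
        D_B=s.D_c * D_R,
        D_R=D_R,
        mu=tuple(m * mu1 for m in s.mu_rel),
        k=k,
        lam=k / t.B_c,
        R0=s.R0_hat * k,
    )


def compute_zeta(ic_bar: float, D_R: float, mu1: float) -> float:
    """Scaled mean intercolony distance zeta = ic_bar / sqrt(D_R/mu1).

    Doubling ``ic_bar`` has exactly the same effect on zeta as quadrupling
    ``mu1`` (square-root scaling of the natural length).
    """
    _require_positive(ic_bar=ic_bar)
    return float(ic_bar / natural_length_scale(D_R, mu1))


_UNIT_FACTORS = {"cm2_per_h": 1.0, "cm2_per_s": _S_TO_H}


def full_params_from_config(config: Mapping[str, object]) -> FullParams:
    """Build :class:`FullParams` from a flat config mapping.

    Expected keys: ``D_B``, ``D_R``, ``mu`` (list, fastest first), ``k``,
    ``lam``, ``R0`` and optionally ``units`` in ``{"cm2_per_h",
    "cm2_per_s"}`` (default cm^2/h) applying to both diffusion constants.
    Unknown keys are rejected.
    """
    allowed = {"D_B", "D_R", "mu", "k", "lam", "R0", "units"}
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = allowed - {"units"} - set(config)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    units = str(config.get("units", "cm2_per_h"))
    if units not in _UNIT_FACTORS:
        raise ValueError(f"units must be one of {sorted(_UNIT_FACTORS)}")
    f = _UNIT_FACTORS[units]
    mu = config["mu"]
    if not isinstance(mu, Sequence) or isinstance(mu, str):
        raise ValueError("mu must be a list of growth rates (1/h)")
    return FullParams(
        D_B=float(config["D_B"]) * f,
        D_R=float(config["D_R"]) * f,
        mu=tuple(float(m) for m in mu),
        k=float(config["k"]),
        lam=float(config["lam"]),
        R0=float(config["R0"]),
    )
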