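"""Spatial statistics: intercolony distances, Voronoi territories,
competition localization, genetic drift and the grid selection assay.

Competition localization is the OLS slope of relative colony biomass on
relative Voronoi (Dirichlet) territory area: a slope near 1 means a colony's
final size is set by its neighbors (local competition), a slope near 0 means
all colonies draw on the shared resource pool (global competition).  Because
the sweeps below run the dimensionless model, distances are already in units
of the natural length scale, so the scaled mean intercolony distance zeta is
read straight off the founder geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .protocols import (FounderMap, center_founder_index, default_step_control,
                        initial_state, seed_grid_founders, seed_random_founders)
from .rd_core import Domain, run_until_consumed
from .scaling import ScaledParams, SpatialSummary

__all__ = [
    "LocalizationResult",
    "DriftResult",
    "SelectionResult",
    "mean_nn_distance",
    "voronoi_areas",
    "competition_localization",
    "localization_sweep",
    "drift_statistic",
    "selection_assay",
]

#: geometric sweep of scaled box widths; for 49 random founders on 101x101
#: this spans zeta from roughly 0.2 to 20 (the global-to-local transition)
DEFAULT_LENGTH_SCALES = tuple(np.geomspace(0.028, 2.8, 11))


@dataclass(frozen=True)
class LocalizationResult:
    """Per-colony relative biomasses/areas and the localization slope."""

    rel_biomass: np.ndarray
    rel_area: np.ndarray
    slope: float
    intercept: float
    summary: SpatialSummary | None = None


@dataclass(frozen=True)
class DriftResult:
    """Drift signal at one length scale: per-map SD of final founder
    frequencies, their mean over maps, and that mean normalized by the
    largest mean in the sweep."""

    length_scale: float
    zeta_mean: float
    zeta_sd: float
    per_map_sd: np.ndarray
    mean_sd: float
    normalized_sd: float


@dataclass(frozen=True)
class SelectionResult:
    """Selection response at one zeta in the drift-free grid assay."""

    length_scale: float
    zeta: float
    mutant_final_freq: float
    delta_freq: float


def mean_nn_distance(fmap: FounderMap, domain: Domain) -> SpatialSummary:
    """Mean minimum center-to-center intercolony distance IC_bar.

    Euclidean distances between founder box centers; on a torus the
    minimum-image (wrap-around) convention applies via a periodic KD-tree.
    """
    if fmap.n_founders < 2:
        raise ValueError("need at least 2 founders for intercolony distances")
    pos = fmap.positions(domain)
    if domain.boundary == "torus":
        box = (domain.nx * domain.dx, domain.ny * domain.dx)
        tree = cKDTree(pos, boxsize=box)
    else:
        tree = cKDTree(pos)
    dist, _ = tree.query(pos, k=2)
    ic_i = dist[:, 1]
    return SpatialSummary(ic_i=ic_i, ic_bar=float(ic_i.mean()))


def voronoi_areas(fmap: FounderMap, domain: Domain) -> np.ndarray:
    """Discrete Dirichlet territory area per founder.

    Every lattice box is assigned to the founder whose center is nearest to
    the box center (ties to the lowest founder index); a founder's area is
    its box count times dx^2, so areas sum exactly to the domain area.  Only
    supported on no-flux (square) domains — territory polygons on a torus
    are deliberately out of scope.
    """
    if domain.boundary == "torus":
        raise ValueError("voronoi_areas supports only no_flux (square) domains")
    xs = (np.arange(domain.nx) + 0.5) * domain.dx
    ys = (np.arange(domain.ny) + 0.5) * domain.dx
    X, Y = np.meshgrid(xs, ys)
    pos = fmap.positions(domain)
    d2 = ((X[None] - pos[:, 0, None, None]) ** 2
          + (Y[None] - pos[:, 1, None, None]) ** 2)
    owner = np.argmin(d2, axis=0)  # argmin takes the lowest index on ties
    counts = np.bincount(owner.ravel(), minlength=fmap.n_founders)
    return counts * domain.dx**2


def competition_localization(
    biomasses: np.ndarray,
    areas: np.ndarray,
    summary: SpatialSummary | None = None,
) -> LocalizationResult:
    """OLS slope of relative biomass on relative territory area.

    Both inputs are normalized to fractions first, so the slope is invariant
    to rescaling either vector by a positive constant.
    """
    b = np.asarray(biomasses, dtype=float)
    a = np.asarray(areas, dtype=float)
    if b.shape != a.shape or b.size < 3:
        raise ValueError("need >= 3 colonies with matching biomass/area vectors")
    if b.sum() <= 0 or a.sum() <= 0:
        raise ValueError("totals must be positive")
    rel_b = b / b.sum()
    rel_a = a / a.sum()
    if np.ptp(rel_a) == 0:
        raise ValueError("relative areas have zero variance; slope undefined")
    fit = linregress(rel_a, rel_b)
    return LocalizationResult(rel_biomass=rel_b, rel_area=rel_a,
                              slope=float(fit.slope),
                              intercept=float(fit.intercept), summary=summary)


def _scaled_single_genotype(R0_hat: float, D_c: float) -> ScaledParams:
    return ScaledParams(D_c=D_c, mu_rel=(1.0,), R0_hat=R0_hat)


def localization_sweep(
    founder_counts: Sequence[int] = (15, 49),
    n_maps: int = 10,
    length_scales: Sequence[float] = DEFAULT_LENGTH_SCALES,
    nx: int = 101,
    R0_hat: float = 100.0,
    D_c: float = 0.001,
    rng_seed: Union[int, np.random.SeedSequence] = 0,
    consumed_frac_stop: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Competition-localization sweep on random founder maps.

    Runs the dimensionless model with per-founder lineage tracking and equal
    growth rates on a square (no-flux) nx*nx lattice.  For each founder
    count, ``n_maps`` random maps are drawn once and reused across every
    scaled box width in ``length_scales`` (varying the box width varies the
    natural length scale, i.e. the growth rate, at fixed geometry).

    Returns ``(summary, founders)``: ``summary`` has one row per simulation
    (n_founders, map_id, length_scale, zeta, slope, intercept, ic_bar);
    ``founders`` one row per colony per simulation with its relative area
    and final relative biomass (consumed downstream by
    :func:`drift_statistic`).
    """
    seed_seq = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
                else np.random.SeedSequence(rng_seed))
    params = _scaled_single_genotype(R0_hat, D_c)
    rows: list[dict] = []
    founder_rows: list[dict] = []
    children = iter(seed_seq.spawn(len(founder_counts) * n_maps))
    for n_f in founder_counts:
        for map_id in range(n_maps):
            ref_domain = Domain(nx=nx, ny=nx, dx=1.0, boundary="no_flux")
            fmap = seed_random_founders(n_f, ref_domain, np.zeros(n_f, int),
                                        np.random.default_rng(next(children)))
            for h in length_scales:
                domain = Domain(nx=nx, ny=nx, dx=float(h), boundary="no_flux")
                summary = mean_nn_distance(fmap, domain)
                # scaled model: distances are already in natural-length units
                summary = SpatialSummary(ic_i=summary.ic_i,
                                         ic_bar=summary.ic_bar,
                                         zeta=summary.ic_bar)
                state = initial_state(fmap, domain, R0_hat, track="founder")
                ctrl = default_step_control(params, domain,
                                            consumed_frac_stop=consumed_frac_stop)
                final = run_until_consumed(state, params, ctrl, domain)
                biomass = final.B_fields.sum(axis=(1, 2))
                areas = voronoi_areas(fmap, domain)
                loc = competition_localization(biomass, areas, summary)
                rows.append(dict(n_founders=n_f, map_id=map_id,
                                 length_scale=float(h), zeta=summary.zeta,
                                 slope=loc.slope, intercept=loc.intercept,
                                 ic_bar=summary.ic_bar))
                for f_id in range(n_f):
                    founder_rows.append(dict(
                        n_founders=n_f, map_id=map_id, length_scale=float(h),
                        zeta=summary.zeta, founder=f_id,
                        rel_area=loc.rel_area[f_id],
                        rel_biomass=loc.rel_biomass[f_id]))
    return pd.DataFrame(rows), pd.DataFrame(founder_rows)


def drift_statistic(founder_df: pd.DataFrame) -> tuple[pd.DataFrame, list[DriftResult]]:
    """Spatial genetic drift from an equal-growth-rate sweep.

    All founders are physiologically identical, so any spread in final
    founder frequency is drift caused purely by founder geometry.  Per map:
    the SD across founders of the final biomass fraction; per length scale:
    the mean of those SDs over maps, normalized by the sweep's maximum mean.
    """
    results: list[DriftResult] = []
    for h, group in founder_df.groupby("length_scale", sort=True):
        per_map = group.groupby("map_id")["rel_biomass"].std(ddof=0)
        zetas = group.groupby("map_id")["zeta"].first()
        results.append(DriftResult(
            length_scale=float(h),
            zeta_mean=float(zetas.mean()),
            zeta_sd=float(zetas.std(ddof=0)),
            per_map_sd=per_map.to_numpy(),
            mean_sd=float(per_map.mean()),
            normalized_sd=np.nan))
    max_sd = max(r.mean_sd for r in results)
    if max_sd <= 0:
        raise ValueError("all drift SDs are zero; cannot normalize")
    results = [DriftResult(r.length_scale, r.zeta_mean, r.zeta_sd, r.per_map_sd,
                           r.mean_sd, r.mean_sd / max_sd) for r in results]
    df = pd.DataFrame([dict(length_scale=r.length_scale, zeta_mean=r.zeta_mean,
                            zeta_sd=r.zeta_sd, mean_sd=r.mean_sd,
                            normalized_sd=r.normalized_sd) for r in results])
    return df, results


def selection_assay(
    length_scales: Sequence[float],
    nx: int = 105,
    n_founders: int = 49,
    benefit: float = 1.1,
    R0_hat: float = 100.0,
    D_c: float = 0.001,
    consumed_frac_stop: float = 0.99,
) -> tuple[pd.DataFrame, list[SelectionResult]]:
    """Drift-free selection assay: mutant in the center of a founder grid.

    Founders sit on an equally spaced grid on a toroidal nx*nx lattice, so
    every founder has identical surroundings and territory; the center
    founder grows ``benefit`` times faster than the rest.  One deterministic
    run per scaled box width; the response is the mutant's absolute
    frequency gain over its initial 1/n_founders.
    """
    if benefit < 1.0:
        raise ValueError("benefit must be >= 1 (mutant is the fastest genotype)")
    mu_rel = (1.0, 1.0 / benefit) if benefit > 1.0 else (1.0, 1.0)
    params = ScaledParams(D_c=D_c, mu_rel=mu_rel, R0_hat=R0_hat)
    results: list[SelectionResult] = []
    for h in length_scales:
        domain = Domain(nx=nx, ny=nx, dx=float(h), boundary="torus")
        base = seed_grid_founders(n_founders, domain, genotype=1)
        genotype = base.genotype.copy()
        genotype[center_founder_index(base, domain)] = 0
        fmap = FounderMap(ix=base.ix, iy=base.iy, genotype=genotype)
        summary = mean_nn_distance(fmap, domain)
        state = initial_state(fmap, domain, R0_hat, track="genotype",
                              n_genotypes=2)
        ctrl = default_step_control(params, domain,
                                    consumed_frac_stop=consumed_frac_stop)
        final = run_until_consumed(state, params, ctrl, domain)
        totals = final.genotype_totals(2)
        freq = float(totals[0] / totals.sum())
        results.append(SelectionResult(length_scale=float(h),
                                       zeta=summary.ic_bar,
                                       mutant_final_freq=freq,
                                       delta_freq=freq - 1.0 / n_founders))
    df = pd.DataFrame([dict(length_scale=r.length_scale, zeta=r.zeta,
                            mutant_final_freq=r.mutant_final_freq,
                            delta_freq=r.delta_freq) for r in results])
    return df, results
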