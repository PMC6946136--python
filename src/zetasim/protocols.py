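"""Evolutionary protocols built on the reaction-diffusion engine.

Implements the serial-transfer invasion experiment (growth to resource
exhaustion, deterministic dilution to a fixed founder number, reseeding at
fresh random locations), its well-mixed counterpart, and the continuous
chemostat variant.  The mutant genotype is always index 0 (the fastest,
matching the scaling convention); ancestors follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .rd_core import (Domain, SimState, StepControl, run_until_consumed,
                      run_well_mixed, stability_dt, step, _engine_params)
from .scaling import FullParams, ScaledParams

__all__ = [
    "FounderMap",
    "TransferSeries",
    "ChemostatParams",
    "ChemostatResult",
    "seed_random_founders",
    "seed_grid_founders",
    "initial_state",
    "bottleneck",
    "run_invasion_spatial",
    "run_invasion_well_mixed",
    "run_chemostat",
    "write_founder_map",
    "read_founder_map",
]

#: biomass deposited at each founder location ("one unit per location")
FOUNDER_BIOMASS = 1.0


@dataclass(frozen=True)
class FounderMap:
    """Founder positions (0-based box indices) and genotype labels."""

    ix: np.ndarray
    iy: np.ndarray
    genotype: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ix", np.asarray(self.ix, dtype=int))
        object.__setattr__(self, "iy", np.asarray(self.iy, dtype=int))
        object.__setattr__(self, "genotype", np.asarray(self.genotype, dtype=int))
        if not (len(self.ix) == len(self.iy) == len(self.genotype)):
            raise ValueError("ix, iy and genotype must have equal length")
        flat = {(int(i), int(j)) for i, j in zip(self.ix, self.iy)}
        if len(flat) != len(self.ix):
            raise ValueError("founder positions must be unique (max 1 founder/box)")

    @property
    def n_founders(self) -> int:
        return len(self.ix)

    def positions(self, domain: Domain) -> np.ndarray:
        """(n, 2) array of founder box-center coordinates."""
        return np.column_stack(((self.ix + 0.5) * domain.dx,
                                (self.iy + 0.5) * domain.dx))


@dataclass(frozen=True)
class TransferSeries:
    """Mutant-frequency trajectory of a serial-transfer invasion run.

    ``freqs[j]`` is the mutant biomass fraction at the end of transfer j;
    ``transfers_to_threshold`` counts the growth-dilution cycles needed for
    the frequency to reach ``threshold`` (0 when the starting founder
    frequency already meets it; ``None`` for extinction / truncated runs).
    ``outcome`` is one of ``"invaded"``, ``"extinct"``, ``"max_transfers"``.
    """

    freqs: np.ndarray
    threshold: float
    transfers_to_threshold: int | None
    outcome: str = "invaded"

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.transfers_to_threshold is not None and self.outcome == "invaded":
            n = self.transfers_to_threshold
            if n > 0 and (len(f) < n or f[n - 1] < self.threshold):
                raise ValueError("transfers_to_threshold inconsistent with freqs")


@dataclass(frozen=True)
class ChemostatParams:
    """Continuous-culture control: dilution rate delta (1/h) and per-box
    reservoir resource concentration feeding every box."""

    dilution_rate: float
    reservoir_R: float = 100.0

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution_rate must be positive")
        if self.reservoir_R <= 0:
            raise ValueError("reservoir_R must be positive")


@dataclass(frozen=True)
class ChemostatResult:
    """Outcome of a chemostat run: ``outcome`` in {"invaded", "washout",
    "max_time"}; ``time`` is the elapsed model time at the stop."""

    outcome: str
    time: float
    mutant_freq: float


def seed_random_founders(
    n: int,
    domain: Domain,
    genotypes: Sequence[int] | np.ndarray,
    rng: Union[int, np.random.Generator],
) -> FounderMap:
    """Place n founders at distinct uniformly random boxes.

    Deterministic for a given seed/generator state.  ``genotypes`` assigns a
    genotype index to each founder in draw order.
    """
    if n > domain.n_boxes:
        raise ValueError(f"cannot place {n} founders in {domain.n_boxes} boxes")
    genotypes = np.asarray(genotypes, dtype=int)
    if genotypes.shape != (n,):
        raise ValueError("genotypes must have one entry per founder")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    flat = gen.choice(domain.n_boxes, size=n, replace=False)
    return FounderMap(ix=flat % domain.nx, iy=flat // domain.nx, genotype=genotypes)


def seed_grid_founders(n: int, domain: Domain, genotype: int = 0) -> FounderMap:
    """Place a perfect-square number of founders on an equally spaced grid.

    The grid is offset by half a spacing so it is translation-symmetric on a
    torus; all founders get the same genotype label (relabel afterwards, e.g.
    via :func:`center_founder_index`, to mark a mutant).
    """
    s = int(round(np.sqrt(n)))
    if s * s != n:
        raise ValueError(f"n={n} is not a perfect square")
    if domain.nx % s or domain.ny % s:
        raise ValueError(f"grid of {s}x{s} founders does not divide "
                         f"{domain.nx}x{domain.ny} evenly")
    sx, sy = domain.nx // s, domain.ny // s
    ii, jj = np.meshgrid(sx // 2 + sx * np.arange(s), sy // 2 + sy * np.arange(s))
    return FounderMap(ix=ii.ravel(), iy=jj.ravel(),
                      genotype=np.full(n, genotype, dtype=int))


def center_founder_index(fmap: FounderMap, domain: Domain) -> int:
    """Index of the founder nearest the domain center."""
    cx, cy = domain.nx * domain.dx / 2, domain.ny * domain.dx / 2
    pos = fmap.positions(domain)
    return int(np.argmin((pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2))


def initial_state(
    fmap: FounderMap,
    domain: Domain,
    R0_per_box: float,
    *,
    track: str = "genotype",
    n_genotypes: int | None = None,
    founder_biomass: float = FOUNDER_BIOMASS,
) -> SimState:
    """Fresh state: homogeneous resource plus one biomass unit per founder.

    ``track="genotype"`` pools founders of a genotype into one field (enough
    for invasion assays); ``track="founder"`` gives every founder its own
    field (needed for territory and drift statistics).
    """
    if track not in ("genotype", "founder"):
        raise ValueError("track must be 'genotype' or 'founder'")
    R = np.full(domain.shape, float(R0_per_box))
    if track == "founder":
        L = fmap.n_founders
        lineage_genotype = fmap.genotype.copy()
        B = np.zeros((L,) + domain.shape)
        B[np.arange(L), fmap.iy, fmap.ix] = founder_biomass
    else:
        L = int(n_genotypes if n_genotypes is not None else fmap.genotype.max() + 1)
        lineage_genotype = np.arange(L)
        B = np.zeros((L,) + domain.shape)
        np.add.at(B, (fmap.genotype, fmap.iy, fmap.ix), founder_biomass)
    return SimState(R_field=R, B_fields=B, lineage_genotype=lineage_genotype)


def bottleneck(final_freqs: np.ndarray, n_founders: int) -> np.ndarray:
    """Deterministic dilution: apportion n_founders proportionally to the
    final genotype frequencies.

    Largest-remainder (Hamilton) apportionment with ties broken toward the
    faster genotype (lower index): each count differs from ``freq*n`` by less
    than 1 and counts sum exactly to ``n_founders``.
    """
    freqs = np.asarray(final_freqs, dtype=float)
    if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be nonnegative and sum to 1")
    quotas = freqs * n_founders
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    short = n_founders - counts.sum()
    # sort by remainder descending, index ascending (ties -> faster genotype)
    order = np.lexsort((np.arange(len(freqs)), -remainder))
    counts[order[:short]] += 1
    return counts


def default_step_control(params: Union[FullParams, ScaledParams],
                         domain: Domain,
                         consumed_frac_stop: float = 0.99) -> StepControl:
    """StepControl at the accuracy bound dt = 0.1*dx^2/D_max."""
    D_B, D_R, _, _, _ = _engine_params(params)
    return StepControl(dt=stability_dt(domain.dx, max(D_B, D_R)),
                       consumed_frac_stop=consumed_frac_stop)


def _counts_to_genotypes(counts: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(len(counts)), counts)


def run_invasion_spatial(
    params: Union[FullParams, ScaledParams],
    domain: Domain,
    n_founders: int = 49,
    threshold: float = 0.9,
    rng_seed: Union[int, np.random.SeedSequence] = 0,
    ctrl: StepControl | None = None,
    max_transfers: int = 1000,
    R0_per_box: float | None = None,
) -> TransferSeries:
    """Serial-transfer invasion of a faster mutant on a spatial lattice.

    Starts with one mutant founder (genotype 0) among ``n_founders``; each
    transfer seeds fresh random positions, grows until >99% consumption,
    records the mutant biomass fraction, then applies the deterministic
    :func:`bottleneck`.  Stops when the frequency reaches ``threshold``
    (outcome "invaded"), the mutant founder count hits 0 ("extinct"), or
    ``max_transfers`` is exceeded ("max_transfers").
    """
    _, _, mu, k, _ = _engine_params(params)
    n_genotypes = len(mu)
    if n_genotypes < 2:
        raise ValueError("invasion requires at least two genotypes")
    if R0_per_box is None:
        R0_per_box = params.R0 if isinstance(params, FullParams) else params.R0_hat
    if ctrl is None:
        ctrl = default_step_control(params, domain)
    seed_seq = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
                else np.random.SeedSequence(rng_seed))

    counts = np.zeros(n_genotypes, dtype=int)
    counts[0], counts[1] = 1, n_founders - 1
    if counts[0] / n_founders >= threshold:
        return TransferSeries(freqs=np.empty(0), threshold=threshold,
                              transfers_to_threshold=0)
    freqs: list[float] = []
    for transfer, child in enumerate(seed_seq.spawn(max_transfers)):
        fmap = seed_random_founders(n_founders, domain,
                                    _counts_to_genotypes(counts),
                                    np.random.default_rng(child))
        state = initial_state(fmap, domain, R0_per_box, track="genotype",
                              n_genotypes=n_genotypes)
        final = run_until_consumed(state, params, ctrl, domain)
        totals = final.genotype_totals(n_genotypes)
        freq = totals / totals.sum()
        freqs.append(float(freq[0]))
        if freq[0] >= threshold:
            return TransferSeries(freqs=np.asarray(freqs), threshold=threshold,
                                  transfers_to_threshold=transfer + 1)
        counts = bottleneck(freq, n_founders)
        if counts[0] == 0:
            return TransferSeries(freqs=np.asarray(freqs), threshold=threshold,
                                  transfers_to_threshold=None, outcome="extinct")
    return TransferSeries(freqs=np.asarray(freqs), threshold=threshold,
                          transfers_to_threshold=None, outcome="max_transfers")


def run_invasion_well_mixed(
    params: Union[FullParams, ScaledParams],
    n_boxes: int,
    n_founders: int = 49,
    threshold: float = 0.9,
    consumed_frac_stop: float = 0.99,
    max_transfers: int = 1000,
) -> TransferSeries:
    """Mass-action counterpart of :func:`run_invasion_spatial`.

    The resource total matches a spatial run of ``n_boxes`` boxes at the
    params' per-box concentration.  Fully deterministic; the transfer count
    depends only on the growth-rate ratios, never on the absolute rates.
    """
    _, _, mu, k, lam = _engine_params(params)
    R0_per_box = params.R0 if isinstance(params, FullParams) else params.R0_hat
    R_total = R0_per_box * n_boxes
    counts = np.zeros(len(mu), dtype=int)
    counts[0], counts[1] = 1, n_founders - 1
    if counts[0] / n_founders >= threshold:
        return TransferSeries(freqs=np.empty(0), threshold=threshold,
                              transfers_to_threshold=0)
    freqs: list[float] = []
    for transfer in range(max_transfers):
        B_final = run_well_mixed(counts * FOUNDER_BIOMASS, R_total, mu, k, lam,
                                 consumed_frac_stop)
        freq = B_final / B_final.sum()
        freqs.append(float(freq[0]))
        if freq[0] >= threshold:
            return TransferSeries(freqs=np.asarray(freqs), threshold=threshold,
                                  transfers_to_threshold=transfer + 1)
        counts = bottleneck(freq, n_founders)
        if counts[0] == 0:
            return TransferSeries(freqs=np.asarray(freqs), threshold=threshold,
                                  transfers_to_threshold=None, outcome="extinct")
    return TransferSeries(freqs=np.asarray(freqs), threshold=threshold,
                          transfers_to_threshold=None, outcome="max_transfers")


def run_chemostat(
    params: Union[FullParams, ScaledParams],
    domain: Domain,
    chemo: ChemostatParams,
    n_founders: int = 49,
    threshold: float = 0.9,
    rng_seed: Union[int, np.random.SeedSequence] = 0,
    ctrl: StepControl | None = None,
    max_time: float = 1e5,
    washout_biomass: float = FOUNDER_BIOMASS,
) -> ChemostatResult:
    """Continuous-culture invasion: no transfers; every box is continuously
    diluted at rate delta and replenished from a reservoir.

    Runs until the mutant biomass fraction reaches ``threshold``
    ("invaded"), total biomass falls below one founder unit ("washout" —
    guaranteed when every growth rate is below delta), or ``max_time``
    elapses ("max_time").
    """
    _, _, mu, _, _ = _engine_params(params)
    n_genotypes = len(mu)
    R0_per_box = params.R0 if isinstance(params, FullParams) else params.R0_hat
    if ctrl is None:
        ctrl = default_step_control(params, domain)
    seed_seq = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
                else np.random.SeedSequence(rng_seed))
    genotypes = np.ones(n_founders, dtype=int)
    genotypes[0] = 0
    if n_genotypes == 1:
        genotypes[:] = 0
    fmap = seed_random_founders(n_founders, domain, genotypes,
                                np.random.default_rng(seed_seq))
    state = initial_state(fmap, domain, R0_per_box, track="genotype",
                          n_genotypes=n_genotypes)
    while state.t < max_time:
        state = step(state, params, ctrl, domain,
                     dilution_rate=chemo.dilution_rate,
                     reservoir_R=chemo.reservoir_R)
        totals = state.genotype_totals(n_genotypes)
        total = totals.sum()
        if total < washout_biomass:
            return ChemostatResult("washout", state.t, 0.0)
        freq = totals[0] / total
        if n_genotypes > 1 and freq >= threshold:
            return ChemostatResult("invaded", state.t, float(freq))
    totals = state.genotype_totals(n_genotypes)
    return ChemostatResult("max_time", state.t, float(totals[0] / totals.sum()))


def write_founder_map(path: Union[str, Path], fmap: FounderMap) -> None:
    """Write a founder map as 3-column plain text: box_i box_j genotype."""
    arr = np.column_stack((fmap.ix, fmap.iy, fmap.genotype))
    np.savetxt(path, arr, fmt="%d", header="box_i box_j genotype")


def read_founder_map(path: Union[str, Path]) -> FounderMap:
    """Read a founder map written by :func:`write_founder_map`."""
    arr = np.atleast_2d(np.loadtxt(path, dtype=int))
    return FounderMap(ix=arr[:, 0], iy=arr[:, 1], genotype=arr[:, 2])
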