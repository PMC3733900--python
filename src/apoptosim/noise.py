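"""Extrinsic and combined noise: log-normal protein variation across cells.

Extrinsic noise is modeled as static cell-to-cell variation of protein
abundance: each cell draws its Cytochrome C and/or IAP level from a
log-normal distribution (arithmetic mean = the population mean,
CV = 0.25 by default) and keeps it for life.  Three regimes:

- ``extrinsic_only``: the rate equations are solved per cell with the
  drawn protein values (no reaction-event noise);
- ``intrinsic_only``: stochastic simulation with fixed protein values;
- ``combined``: stochastic simulation with drawn protein values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deterministic import IntegrationError, Trajectory, integrate
from .model import default_initial_state
from .params import CopyNumberCondition, ModelParameters
from .ssa import ssa_population
from .stats import coefficient_of_variation, response_delay, steady_state_value

__all__ = [
    "NoiseSpec",
    "CellRecord",
    "PopulationSummary",
    "sample_lognormal",
    "summarize_population",
    "run_extrinsic_population",
    "run_combined_population",
    "heatmap_cv",
]

FLUCTUATING = ("CC", "IAP")


@dataclass(frozen=True)
class NoiseSpec:
    """Which proteins fluctuate, their means, CV, and the noise regime.

    ``means`` are in μM for the extrinsic-only regime; in the combined
    regime the CC mean is interpreted in molecule counts (drawn values
    are rounded to integers) while IAP stays in μM.
    """

    proteins: tuple[str, ...] = ("CC",)
    means: dict = field(default_factory=dict)
    cv: float = 0.25
    regime: str = "extrinsic_only"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.regime not in ("extrinsic_only", "intrinsic_only", "combined"):
            raise ValueError(f"unknown regime {self.regime!r}")
        bad = set(self.proteins) - set(FLUCTUATING)
        if bad:
            raise ValueError(f"unknown fluctuating protein(s): {sorted(bad)}")
        for prot in self.proteins:
            if prot not in self.means:
                raise ValueError(f"missing mean for {prot}")
            if self.means[prot] <= 0:
                raise ValueError(f"mean for {prot} must be > 0")


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    drawn: dict
    steady_state_cea: float
    t_d: float | None
    converged: bool = True
    error: str | None = None


@dataclass
class PopulationSummary:
    """Per-cell records plus aggregate heterogeneity statistics.

    Aggregates are always recomputable from the records; T_d statistics
    cover responders only and are None with fewer than two responders.
    """

    records: list
    reference: float | None
    mean_ss: float | None = None
    sd_ss: float | None = None
    cv_ss: float | None = None
    mean_td: float | None = None
    sd_td: float | None = None
    cv_td: float | None = None
    responder_fraction: float = 0.0

    @property
    def steady_states(self) -> np.ndarray:
        return np.array([r.steady_state_cea for r in self.records
                         if r.error is None])

    @property
    def delay_times(self) -> np.ndarray:
        return np.array([r.t_d for r in self.records
                         if r.error is None and r.t_d is not None])

    def to_dict(self) -> dict:
        return {
            "n_cells": len(self.records),
            "reference": self.reference,
            "mean_ss": self.mean_ss, "sd_ss": self.sd_ss, "cv_ss": self.cv_ss,
            "mean_td": self.mean_td, "sd_td": self.sd_td, "cv_td": self.cv_td,
            "responder_fraction": self.responder_fraction,
        }


def sample_lognormal(mean: float, cv: float, n: int, seed) -> np.ndarray:
    """n log-normal draws with arithmetic mean ``mean`` and CV ``cv``.

    Parametrized via sigma² = ln(1+cv²), mu = ln(mean) − sigma²/2, so
    the distribution's arithmetic moments match exactly; cv=0 returns
    the degenerate constant sample.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv == 0:
        return np.full(n, float(mean))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(np.log(mean) - 0.5 * s2, np.sqrt(s2), size=n)


def _reference(
    ss: np.ndarray, ref_mode: str, ref_floor: float = 0.0
) -> tuple[float | None, np.ndarray]:
    """Half-max reference level and the responder pre-selection.

    ``responders`` mode: the reference is the mean steady state of the
    cells in the elevated mode — above half the population maximum and
    above ``ref_floor`` (same units as the trajectories).  When no cell
    clears the floor the population is non-responsive and there is no
    reference (the blank-region case).  ``population`` mode: the mean
    over all cells, which at sub-threshold inputs measures relaxation
    to the survival state rather than apoptotic commitment.
    """
    ok = np.isfinite(ss)
    if not ok.any() or np.nanmax(ss) <= 0:
        return None, np.zeros(len(ss), dtype=bool)
    if ref_mode == "population":
        return float(np.nanmean(ss[ok])), ok
    if ref_mode == "responders":
        sel = ok & (ss >= max(0.5 * np.nanmax(ss), ref_floor))
        if not sel.any():
            return None, sel
        return float(np.nanmean(ss[sel])), sel
    raise ValueError(f"unknown ref_mode {ref_mode!r}")


def summarize_population(
    trajectories: list[Trajectory],
    drawn: list[dict] | None = None,
    window_fraction: float = 0.1,
    ref_mode: str = "responders",
    ref_floor: float = 0.0,
) -> PopulationSummary:
    """Steady states, common half-max reference, per-cell T_d, aggregates."""
    n = len(trajectories)
    drawn = drawn or [{} for _ in range(n)]
    ss = np.full(n, np.nan)
    conv = np.zeros(n, dtype=bool)
    for i, tr in enumerate(trajectories):
        if tr is None:
            continue
        ss[i], conv[i] = steady_state_value(tr, window_fraction)
    ref, _ = _reference(ss, ref_mode, ref_floor)
    records = []
    for i, tr in enumerate(trajectories):
        if tr is None:
            records.append(CellRecord(i, drawn[i], np.nan, None,
                                      error="integration failed"))
            continue
        td = None
        if ref is not None and ref > 0:
            td = response_delay(tr, ref).t_d
        records.append(CellRecord(i, drawn[i], float(ss[i]), td,
                                  converged=bool(conv[i])))
    summ = PopulationSummary(records, ref)
    good = [r for r in records if r.error is None]
    if good:
        vals = np.array([r.steady_state_cea for r in good])
        summ.mean_ss = float(vals.mean())
        if len(vals) >= 2:
            summ.sd_ss = float(vals.std(ddof=1))
            if vals.mean() != 0:
                summ.cv_ss = float(summ.sd_ss / vals.mean())
        tds = np.array([r.t_d for r in good if r.t_d is not None])
        summ.responder_fraction = len(tds) / len(good)
        if len(tds) >= 1:
            summ.mean_td = float(tds.mean())
        if len(tds) >= 2:
            summ.sd_td = float(tds.std(ddof=1))
            if tds.mean() > 0:
                summ.cv_td = float(coefficient_of_variation(tds))
    return summ


def _draw_rng(base_seed: int) -> np.random.Generator:
    # stream disjoint from the per-cell SSA seeds
    return np.random.default_rng([int(base_seed) & 0x7FFFFFFF, 0xA5])


def run_extrinsic_population(
    params: ModelParameters,
    spec: NoiseSpec,
    n_cells: int = 150,
    base_seed: int = 0,
    t_end: float = 3000.0,
    dt_out: float = 1.0,
    eps: float = 0.1,
    ref_mode: str = "responders",
    ref_floor: float = 0.2,
) -> PopulationSummary:
    """Deterministic model per cell with drawn protein concentrations.

    ``ref_floor`` (μM) marks the minimum steady CEA that counts as an
    apoptotic (responder) steady state for the T_d reference."""
    if not spec.proteins:
        raise ValueError("extrinsic regime needs at least one protein")
    rng = _draw_rng(base_seed)
    draws = {
        prot: sample_lognormal(spec.means[prot], spec.cv, n_cells, rng)
        for prot in spec.proteins
    }
    trajs, drawn = [], []
    for i in range(n_cells):
        over = {("CC" if prot == "CC" else "IAP"): float(draws[prot][i])
                for prot in spec.proteins}
        p = params.replace(**over)
        drawn.append(over)
        try:
            trajs.append(integrate(p, default_initial_state(p, eps=eps),
                                   t_end=t_end, dt_out=dt_out))
        except IntegrationError:
            trajs.append(None)
    return summarize_population(trajs, drawn, ref_mode=ref_mode,
                                ref_floor=ref_floor)


def run_combined_population(
    params: ModelParameters,
    cond: CopyNumberCondition,
    spec: NoiseSpec,
    n_cells: int = 150,
    base_seed: int = 0,
    t_end: float = 3000.0,
    record_dt: float = 1.0,
    condition_mode: str = "initial",
    eps: float = 0.1,
    ref_mode: str = "responders",
    ref_floor: float | None = None,
    cc_count: int | None = None,
) -> PopulationSummary:
    """Stochastic simulation per cell with drawn protein abundances.

    CC draws are in molecule counts (rounded to nearest; a draw of 0 is
    resampled once); IAP draws are in μM.  With an empty protein set
    this reduces exactly to the intrinsic-only population at the same
    seeds (``cc_count`` must then be given).
    """
    rng = _draw_rng(base_seed)
    cc_draws = None
    iap_draws = None
    if "CC" in spec.proteins:
        raw = sample_lognormal(spec.means["CC"], spec.cv, n_cells, rng)
        cc_draws = np.floor(raw + 0.5).astype(int)
        for i in np.nonzero(cc_draws == 0)[0]:
            cc_draws[i] = int(np.floor(
                sample_lognormal(spec.means["CC"], spec.cv, 1, rng)[0] + 0.5))
    if "IAP" in spec.proteins:
        iap_draws = sample_lognormal(spec.means["IAP"], spec.cv, n_cells, rng)
    if cc_draws is None and cc_count is None:
        raise ValueError("cc_count required when CC does not fluctuate")
    trajs, drawn = [], []
    for i in range(n_cells):
        p = params if iap_draws is None else params.replace(
            IAP=float(iap_draws[i]))
        cci = int(cc_draws[i]) if cc_draws is not None else int(cc_count)
        tr = ssa_population(
            p, cond, cci, n_cells=1, base_seed=base_seed + i,
            condition_mode=condition_mode, eps=eps,
            t_end=t_end, record_dt=record_dt,
        )[0]
        trajs.append(tr)
        d = {}
        if cc_draws is not None:
            d["CC"] = cci
        if iap_draws is not None:
            d["IAP"] = float(iap_draws[i])
        drawn.append(d)
    if ref_floor is None:
        ref_floor = 0.2 * params.V_c  # counts
    return summarize_population(trajs, drawn, ref_mode=ref_mode,
                                ref_floor=ref_floor)


def heatmap_cv(
    params: ModelParameters,
    cc_grid,
    iap_grid,
    spec: NoiseSpec,
    n_cells: int = 150,
    base_seed: int = 0,
    cond: CopyNumberCondition | None = None,
    **kw,
) -> tuple[np.ndarray, np.ndarray]:
    """CV(T_d) over a (mean CC, mean IAP) grid, plus a responder mask.

    Each grid point runs an independent population (fresh draws); the
    CV entry is NaN where fewer than two cells respond.  Deterministic
    given ``base_seed``.
    """
    cc_grid = np.asarray(cc_grid, dtype=float)
    iap_grid = np.asarray(iap_grid, dtype=float)
    if np.any(np.diff(cc_grid) < 0) or np.any(np.diff(iap_grid) < 0):
        raise ValueError("grids must be monotone non-decreasing")
    cv = np.full((len(cc_grid), len(iap_grid)), np.nan)
    mask = np.zeros_like(cv, dtype=bool)
    for i, cc in enumerate(cc_grid):
        for j, iap in enumerate(iap_grid):
            means = dict(spec.means)
            if "CC" in spec.proteins:
                means["CC"] = float(cc)
            if "IAP" in spec.proteins:
                means["IAP"] = float(iap)
            sp = NoiseSpec(spec.proteins, means, spec.cv, spec.regime)
            p = params if "CC" in spec.proteins else params.replace(CC=float(cc))
            p = p if "IAP" in spec.proteins else p.replace(IAP=float(iap))
            seed_ij = (base_seed + 7919 * (i * len(iap_grid) + j)) & 0x7FFFFFFF
            if spec.regime == "extrinsic_only":
                summ = run_extrinsic_population(
                    p, sp, n_cells=n_cells, base_seed=seed_ij, **kw)
            else:
                if cond is None:
                    raise ValueError("combined regime needs a condition")
                summ = run_combined_population(
                    p, cond, sp, n_cells=n_cells, base_seed=seed_ij,
                    cc_count=int(round(cc)), **kw)
            mask[i, j] = summ.responder_fraction > 0
            if summ.cv_td is not None:
                cv[i, j] = summ.cv_td
    return cv, mask
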