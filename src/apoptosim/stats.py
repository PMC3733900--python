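"""Response statistics: steady states, delay times, noise measures,
bimodality, and stochastic bistability thresholds.

The per-cell timing readout is the response delay T_d — the time the
executioner caspase takes to reach half of the population's mean
steady-state level, the standard single-cell measure of apoptosis
commitment timing.  Cell-to-cell variability is quantified by the
coefficient of variation (SD/mean) and noise strength by the Fano
factor (variance/mean, 1 for a Poisson process).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deterministic import Trajectory

__all__ = [
    "DelayTime",
    "BimodalSummary",
    "steady_state_value",
    "response_delay",
    "coefficient_of_variation",
    "fano_factor",
    "classify_bimodality",
    "stochastic_bistability_thresholds",
]


@dataclass(frozen=True)
class DelayTime:
    """Half-maximal crossing time (min) or a non-responder flag."""

    t_d: float | None
    reference: float

    @property
    def responded(self) -> bool:
        return self.t_d is not None


@dataclass(frozen=True)
class BimodalSummary:
    is_bimodal: bool
    low_mode_mean: float | None = None
    high_mode_mean: float | None = None
    low_fraction: float | None = None
    threshold: float | None = None


def steady_state_value(
    traj: Trajectory,
    window_fraction: float = 0.1,
    convergence_rtol: float = 1e-4,
) -> tuple[float, bool]:
    """Mean CEA over the trailing window, plus a convergence flag.

    The flag is False when the mean over the trailing window differs
    from the mean over the preceding window of equal length by more
    than ``convergence_rtol`` relative to the overall scale (a monotone
    ramp is flagged; a stationary noisy tail is not).
    """
    if not 0 < window_fraction <= 0.5:
        raise ValueError("window_fraction must be in (0, 0.5]")
    cea = np.asarray(traj.cea, dtype=float)
    k = max(int(len(cea) * window_fraction), 1)
    tail = cea[-k:]
    value = float(tail.mean())
    prev = cea[-2 * k:-k] if len(cea) >= 2 * k else cea[:k]
    scale = max(abs(value), abs(float(prev.mean())), 1e-12)
    converged = abs(value - float(prev.mean())) / scale <= max(
        convergence_rtol, 3.0 * tail.std(ddof=0) / (np.sqrt(k) * scale)
    )
    return value, bool(converged)


def response_delay(traj: Trajectory, ref: float) -> DelayTime:
    """First time CEA reaches ref/2, linearly interpolated.

    ``ref`` is the population mean steady-state CEA; a trajectory that
    never reaches ref/2 is a non-responder.
    """
    if ref <= 0:
        raise ValueError("reference level must be > 0")
    half = 0.5 * ref
    cea = np.asarray(traj.cea, dtype=float)
    t = traj.times
    if cea[0] >= half:
        return DelayTime(0.0, ref)
    above = np.nonzero(cea >= half)[0]
    if len(above) == 0:
        return DelayTime(None, ref)
    i = above[0]
    t0, t1 = t[i - 1], t[i]
    y0, y1 = cea[i - 1], cea[i]
    td = t0 + (half - y0) / (y1 - y0) * (t1 - t0) if y1 > y0 else t1
    return DelayTime(float(td), ref)


def _check_sample(values, minimum: int) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < minimum:
        raise ValueError(f"need at least {minimum} values")
    return v


def coefficient_of_variation(values) -> float:
    """Sample SD (n−1 denominator) over mean."""
    v = _check_sample(values, 2)
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean")
    return float(v.std(ddof=1) / m)


def fano_factor(values) -> float:
    """Sample variance (n−1 denominator) over mean."""
    v = _check_sample(values, 2)
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean")
    return float(v.var(ddof=1) / m)


def classify_bimodality(
    ss_values,
    min_occupancy: float = 0.05,
    separation: float = 3.0,
) -> BimodalSummary:
    """Two-cluster split of steady-state values by exhaustive threshold.

    The threshold minimizing total within-cluster variance is found by
    scanning all midpoints of the sorted sample.  The sample is called
    bimodal when both clusters hold at least ``min_occupancy`` of the
    cells and the mode means are separated by at least ``separation``
    pooled within-cluster standard deviations.
    """
    v = np.sort(_check_sample(ss_values, 20))
    n = len(v)
    if v[0] == v[-1]:
        return BimodalSummary(False, low_mode_mean=float(v[0]),
                              high_mode_mean=float(v[0]), low_fraction=1.0)
    # prefix sums give O(n) within-cluster variance for every split
    c1 = np.cumsum(v)
    c2 = np.cumsum(v * v)
    best = (np.inf, -1)
    for k in range(1, n):
        s1, q1 = c1[k - 1], c2[k - 1]
        s2, q2 = c1[-1] - s1, c2[-1] - q1
        w = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        if w < best[0]:
            best = (w, k)
    k = best[1]
    lo, hi = v[:k], v[k:]
    pooled_var = best[0] / max(n - 2, 1)
    pooled_sd = float(np.sqrt(max(pooled_var, 0.0)))
    sep_ok = (hi.mean() - lo.mean()) >= separation * max(pooled_sd, 1e-12)
    occ_ok = min(k, n - k) >= min_occupancy * n
    return BimodalSummary(
        bool(sep_ok and occ_ok),
        low_mode_mean=float(lo.mean()),
        high_mode_mean=float(hi.mean()),
        low_fraction=k / n,
        threshold=float(0.5 * (v[k - 1] + v[k])),
    )


def stochastic_bistability_thresholds(
    cc_values,
    ss_populations,
    occupancy: float = 0.95,
    **bimodal_kw,
) -> tuple[float | None, float | None]:
    """(OFF, ON) thresholds of a CC scan of population histograms.

    ON threshold: the smallest CC whose high mode holds at least
    ``occupancy`` of the cells; OFF threshold: the largest CC whose low
    mode does.  The window between them is the bimodal (stochastically
    bistable) region; both are None when no scan point is bimodal.
    In the zero-noise limit the window collapses onto the deterministic
    saddle-node window up to grid resolution.
    """
    cc_values = np.asarray(cc_values, dtype=float)
    if len(cc_values) < 5:
        raise ValueError("need at least 5 CC grid points")
    if len(cc_values) != len(ss_populations):
        raise ValueError("one population per CC point required")
    summaries = [classify_bimodality(s, **bimodal_kw) for s in ss_populations]
    if not any(s.is_bimodal for s in summaries):
        return None, None
    # global split level from the pooled bimodal populations
    pooled = np.concatenate(
        [np.asarray(s, dtype=float)
         for s, b in zip(ss_populations, summaries) if b.is_bimodal]
    )
    level = classify_bimodality(pooled, **bimodal_kw).threshold
    off = on = None
    for cc, pop in zip(cc_values, ss_populations):
        frac_high = float(np.mean(np.asarray(pop) > level))
        if frac_high >= occupancy and on is None:
            on = float(cc)
        if (1.0 - frac_high) >= occupancy:
            off = float(cc)
    return off, on
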