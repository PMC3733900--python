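"""Deterministic analysis: ODE integration, equilibria, bifurcation diagrams.

The bifurcation structure of the modified model with respect to the
Cytochrome C input is an S-shaped curve: a survival branch with
near-zero executioner caspase activity, an apoptotic branch around
1 μM, and a connecting unstable branch, bounded by two saddle-node
(fold) points — the OFF threshold SN1 ≈ 0.08 μM and the ON threshold
SN2 ≈ 0.83 μM.  Saddle-nodes are localized by bisection on the count
of distinct equilibria rather than by fold continuation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _root

from .model import StateVector, default_initial_state, derivatives
from .params import ModelParameters

__all__ = [
    "Trajectory",
    "EquilibriumSet",
    "BifurcationResult",
    "IntegrationError",
    "integrate",
    "find_equilibria",
    "sweep_bifurcation",
    "bistability_region_2d",
    "hysteresis_sweep",
]


class IntegrationError(RuntimeError):
    """ODE solver failed; carries the solver diagnostic message."""


@dataclass
class Trajectory:
    """A time grid plus aligned state history.

    ``states`` has shape (len(times), 5) with columns ordered as
    (a1cc, c9p, c9a, c3p, CEA); units are μM for ODE output and
    molecule counts for stochastic output.
    """

    times: np.ndarray
    states: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("need at least one time sample")
        if np.any(np.diff(self.times) <= 0) and len(self.times) > 1:
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0:
            raise ValueError("times must start at 0")
        if self.states.shape != (len(self.times), 5):
            raise ValueError("states must align with times")

    @property
    def cea(self) -> np.ndarray:
        return self.states[:, 4]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times} | {
                name: self.states[:, i]
                for i, name in enumerate(("a1cc", "c9p", "c9a", "c3p", "CEA"))
            }
        )


@dataclass
class EquilibriumSet:
    """Distinct equilibria at a fixed CC, with linear stability flags."""

    cc: float
    states: list
    stable: list

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_stable(self) -> int:
        return int(sum(self.stable))

    @property
    def cea_values(self) -> np.ndarray:
        return np.array([s[4] for s in self.states])


@dataclass
class BifurcationResult:
    """Equilibrium branches over a CC grid plus saddle-node thresholds.

    ``branches`` is a list of (cc, cea, stable) records; ``sn1`` (OFF)
    and ``sn2`` (ON) are None for monostable systems.
    """

    cc_grid: np.ndarray
    branches: list
    sn1: float | None
    sn2: float | None

    @property
    def bistable(self) -> bool:
        return self.sn1 is not None and self.sn2 is not None

    def to_dict(self) -> dict:
        return {
            "sn1": self.sn1,
            "sn2": self.sn2,
            "branches": [
                {"cc": float(c), "cea": float(e), "stable": bool(s)}
                for c, e, s in self.branches
            ],
        }


def integrate(
    params: ModelParameters,
    init: StateVector | np.ndarray | None = None,
    t_end: float = 3000.0,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the rate equations on a regular output grid.

    Solutions are clipped at zero (negative excursions only ever appear
    at solver-tolerance scale).  Raises IntegrationError on failure.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if init is None:
        init = default_initial_state(params)
    x0 = init.as_array() if isinstance(init, StateVector) else np.asarray(
        init, dtype=float
    )
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    if t_end == 0:
        return Trajectory(np.array([0.0]), x0[None, :],
                          {"variant": params.variant, "cc": params.CC})

    def rhs(t, x):
        return derivatives(np.clip(x, 0.0, None), params)

    sol = solve_ivp(rhs, (0.0, t_end), x0, method="LSODA",
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(sol.message)
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(times, states, {"variant": params.variant, "cc": params.CC})


def _start_lattice(params: ModelParameters, n_starts: int) -> np.ndarray:
    """Deterministic lattice of root-search starting states.

    a1cc starts at its (decoupled) analytic steady value; the caspase
    coordinates span log-spaced seeds up to twice the synthesis-over-
    degradation scales.
    """
    p = params
    a1 = p.kf1 * p.CC / ((1.0 + p.K_H * p.CC) * (p.kr1 + p.mu1))
    s9 = p.Omega_9 / p.mu2
    s3 = p.Omega_EZ / p.mu4
    k = max(int(np.ceil(np.sqrt(n_starts))), 3)
    c9a_seeds = np.geomspace(1e-4 * s9, 2.0 * s9, k)
    cea_seeds = np.geomspace(1e-4 * s3, 2.0 * s3, k)
    starts = []
    for c9a0 in c9a_seeds:
        for cea0 in cea_seeds:
            starts.append(
                [a1, max(s9 - c9a0, 0.05 * s9), c9a0,
                 max(s3 - cea0, 0.05 * s3), cea0]
            )
    return np.array(starts)


def _reduction_seeds(params: ModelParameters, num: int = 400) -> np.ndarray:
    """Root seeds from the 1-D steady-state reduction.

    At equilibrium a1cc is fixed by CC alone, c9p and c3p follow from
    the synthesis/degradation balances, and CEA follows from c9a via
    the cleavage/removal balance — so equilibria are the sign changes
    of a scalar residual in c9a.  Scanning it catches all branches
    (including the saddle) that a coarse lattice can miss.
    """
    from scipy.optimize import brentq

    p = params
    a1 = p.kf1 * p.CC / ((1.0 + p.K_H * p.CC) * (p.kr1 + p.mu1))
    gam = p.k_u * p.IAP / (1.0 + p.IAP * p.K_U) + p.mu5
    n = p.effective_n
    cea_max = p.Omega_EZ / gam - 1e-12

    def cea_of(c9a: float) -> float:
        def h(cea):
            c3p = (p.Omega_EZ - gam * cea) / p.mu4
            return (p.kf3 * c9a ** n * p.K_P * c3p / (1.0 + p.K_P * c3p)
                    - gam * cea)
        if cea_max <= 0 or h(cea_max) > 0:
            return max(cea_max, 0.0)
        return brentq(h, 0.0, cea_max, xtol=1e-14)

    def resid(c9a: float) -> float:
        cea = cea_of(c9a)
        c9p = (p.Omega_9 - p.mu3 * c9a) / p.mu2
        if c9p <= 0:
            return -1.0
        x = np.array([a1, c9p, c9a, (p.Omega_EZ - gam * cea) / p.mu4, cea])
        return float(derivatives(x, params)[2])

    top = p.Omega_9 / p.mu3
    grid = np.concatenate([[0.0], np.geomspace(1e-7 * top, 0.999 * top, num)])
    vals = np.array([resid(c) for c in grid])
    seeds = []
    for i in range(len(grid) - 1):
        if np.sign(vals[i]) != np.sign(vals[i + 1]) or vals[i] == 0.0:
            c9a = 0.5 * (grid[i] + grid[i + 1])
            cea = cea_of(c9a)
            seeds.append([a1, (p.Omega_9 - p.mu3 * c9a) / p.mu2, c9a,
                          (p.Omega_EZ - gam * cea) / p.mu4, cea])
    return np.array(seeds) if seeds else np.empty((0, 5))


def _jacobian(x: np.ndarray, params: ModelParameters) -> np.ndarray:
    J = np.empty((5, 5))
    for j in range(5):
        h = 1e-7 * max(1.0, abs(x[j]))
        e = np.zeros(5)
        e[j] = h
        fp = derivatives(np.clip(x + e, 0, None), params)
        fm = derivatives(np.clip(x - e, 0, None), params)
        J[:, j] = (fp - fm) / (2 * h)
    return J


def find_equilibria(
    params: ModelParameters,
    cc: float | None = None,
    n_starts: int = 25,
    merge_tol: float = 1e-4,
    residual_tol: float = 1e-10,
) -> EquilibriumSet:
    """Multi-start root finding on the rate equations at fixed CC.

    Duplicate roots are merged by relative distance; stability comes
    from the sign of the dominant real eigenvalue of the local
    linearization.
    """
    if n_starts < 8:
        raise ValueError("n_starts must be >= 8")
    if cc is not None:
        params = params.replace(CC=cc)
    sols: list[np.ndarray] = []
    starts = list(_start_lattice(params, n_starts)) + list(
        _reduction_seeds(params))
    for x0 in starts:
        r = _root(lambda x: derivatives(np.clip(x, 0, None), params),
                  x0, method="hybr", tol=1e-12)
        if not r.success:
            continue
        x = np.clip(r.x, 0.0, None)
        if np.max(np.abs(derivatives(x, params))) > residual_tol:
            continue
        if any(
            np.linalg.norm(x - y) / (1.0 + np.linalg.norm(y)) < merge_tol
            for y in sols
        ):
            continue
        sols.append(x)
    sols.sort(key=lambda s: s[4])
    stable = [
        bool(np.max(np.linalg.eigvals(_jacobian(x, params)).real) < 0)
        for x in sols
    ]
    return EquilibriumSet(params.CC, sols, stable)


def _n_eq(params: ModelParameters, cc: float, n_starts: int) -> int:
    return len(find_equilibria(params, cc, n_starts=n_starts))


def sweep_bifurcation(
    params: ModelParameters,
    cc_grid: np.ndarray,
    n_starts: int = 25,
    sn_tol: float = 1e-3,
) -> BifurcationResult:
    """Equilibrium branches over a CC grid with saddle-node bisection.

    The grid must have at least 10 increasing points.  Fold thresholds
    are bisected on the change of the equilibrium count to ``sn_tol``
    (μM); both are None when no three-equilibrium window is found.
    """
    cc_grid = np.asarray(cc_grid, dtype=float)
    if cc_grid.ndim != 1 or len(cc_grid) < 10 or np.any(np.diff(cc_grid) <= 0):
        raise ValueError("cc_grid must be >= 10 strictly increasing points")
    branches = []
    counts = []
    for cc in cc_grid:
        eq = find_equilibria(params, cc, n_starts=n_starts)
        counts.append(len(eq))
        for x, st in zip(eq.states, eq.stable):
            branches.append((float(cc), float(x[4]), bool(st)))
    counts = np.array(counts)
    sn1 = sn2 = None
    multi = np.where(counts >= 3)[0]
    if len(multi) > 0:
        lo_i = multi[0]
        hi_i = multi[-1]

        def bisect(cc_lo, cc_hi, want_multi_high):
            # invariant: the three-equilibrium side is cc_hi if
            # want_multi_high else cc_lo
            while cc_hi - cc_lo > sn_tol:
                mid = 0.5 * (cc_lo + cc_hi)
                if (_n_eq(params, mid, n_starts) >= 3) == want_multi_high:
                    cc_hi = mid
                else:
                    cc_lo = mid
            return 0.5 * (cc_lo + cc_hi)

        if lo_i > 0:
            sn1 = bisect(cc_grid[lo_i - 1], cc_grid[lo_i], True)
        else:
            sn1 = float(cc_grid[0])
        if hi_i < len(cc_grid) - 1:
            sn2 = bisect(cc_grid[hi_i], cc_grid[hi_i + 1], False)
        else:
            sn2 = float(cc_grid[-1])
    return BifurcationResult(cc_grid, branches, sn1, sn2)


def bistability_region_2d(
    params: ModelParameters,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    cc_scan: np.ndarray | None = None,
    n_starts: int = 16,
) -> np.ndarray:
    """Boolean bistability map over a grid of two parameters.

    A grid cell is bistable when some CC in the scan window yields at
    least two stable equilibria.  Axis names must be ModelParameters
    fields (e.g. ``K_c``, ``n``, ``mu5``, ``k_u``).
    """
    import dataclasses as _dc

    names = {f.name for f in _dc.fields(ModelParameters)}
    (n1, g1), (n2, g2) = axis1, axis2
    for nm in (n1, n2):
        if nm not in names:
            raise ValueError(f"unknown parameter name {nm!r}")
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("axis grids must be non-empty")
    if cc_scan is None:
        cc_scan = np.geomspace(0.02, 2.0, 12)
    out = np.zeros((len(g1), len(g2)), dtype=bool)
    for i, v1 in enumerate(g1):
        for j, v2 in enumerate(g2):
            p = params.replace(**{n1: float(v1), n2: float(v2)})
            for cc in cc_scan:
                eq = find_equilibria(p, float(cc), n_starts=n_starts)
                if eq.n_stable >= 2:
                    out[i, j] = True
                    break
    return out


def hysteresis_sweep(
    params: ModelParameters,
    cc_grid: np.ndarray,
    settle_time: float = 4000.0,
    high_level: float = 0.3,
) -> tuple[float | None, float | None]:
    """Quasi-static up-then-down CC sweep of the integrated model.

    Returns (cc_on, cc_off): the grid values at which the attained CEA
    branch switches up (ON) and back down (OFF).  The state is carried
    from one grid point to the next, so switches happen at the fold
    thresholds up to grid resolution.
    """
    cc_grid = np.asarray(cc_grid, dtype=float)
    x = default_initial_state(params, eps=0.0).as_array()
    cc_on = cc_off = None
    for cc in cc_grid:
        traj = integrate(params.replace(CC=float(cc)), x,
                         t_end=settle_time, dt_out=settle_time / 4)
        x = traj.states[-1]
        if cc_on is None and x[4] > high_level:
            cc_on = float(cc)
    for cc in cc_grid[::-1]:
        traj = integrate(params.replace(CC=float(cc)), x,
                         t_end=settle_time, dt_out=settle_time / 4)
        x = traj.states[-1]
        if cc_off is None and x[4] < high_level:
            cc_off = float(cc)
    return cc_on, cc_off
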