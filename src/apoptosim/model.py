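"""Reaction network core: rate equations, propensities, unit conversion.

Five dynamic species (in order): a1cc, c9p, c9a, c3p, CEA.  The input
signal CC and the inhibitor abundance IAP are parameters, not dynamic
species; CC is held as a fixed boundary value also in the stochastic
model (apoptosome formation does not deplete it).

Deterministic rate equations
----------------------------
::

    d[a1cc]/dt = kf1·CC/(1 + K_H·CC) − (kr1 + μ1)·[a1cc]
    d[c9p]/dt  = Ω9 − A − μ2·[c9p]
    d[c9a]/dt  = A − μ3·[c9a]
    d[c3p]/dt  = Ω_EZ − B − μ4·[c3p]
    d[CEA]/dt  = B − k_u·IAP·[CEA]/(1 + IAP·K_U) − μ5·[CEA]

with the caspase-9 activation flux

    A = kf2 · Φ(CEA) · [a1cc] · G([c9p]),
    G(x) = K_K·K_L·x² / (1 + K_K·x + K_K·K_L·x²)   (two-site binding),
    Φ(CEA) = beta_act + w_fb·CEA^m/(CEA^m + K_c^m)  (modified variant)
    Φ = 1                                           (fussenegger variant)

and the caspase-3 cleavage flux

    B = kf3 · [c9a]^n · K_P·[c3p]/(1 + K_P·[c3p]),   n = 1.5 (modified),
                                                     n = 1 (fussenegger).

The stochastic model uses the same twelve lumped fluxes as reaction
propensities: each propensity is the corresponding deterministic flux
evaluated at concentrations count/V_c, multiplied by V_c, so that its
unit is events/min (the Michaelis–Menten terms are not expanded into
elementary steps).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "SPECIES",
    "StateVector",
    "CountState",
    "STOICHIOMETRY",
    "derivatives",
    "propensities",
    "to_counts",
    "to_concentration",
    "default_initial_state",
]

SPECIES = ("a1cc", "c9p", "c9a", "c3p", "CEA")

#: Net state change of reactions Rn1..Rn12, rows = reactions,
#: columns = (a1cc, c9p, c9a, c3p, CEA).
STOICHIOMETRY = np.array(
    [
        [+1, 0, 0, 0, 0],   # Rn1  apoptosome formation (CC not depleted)
        [-1, 0, 0, 0, 0],   # Rn2  apoptosome unbinding
        [-1, 0, 0, 0, 0],   # Rn3  apoptosome degradation
        [0, +1, 0, 0, 0],   # Rn4  c9p synthesis
        [0, -1, +1, 0, 0],  # Rn5  c9p -> c9a activation
        [0, -1, 0, 0, 0],   # Rn6  c9p degradation
        [0, 0, -1, 0, 0],   # Rn7  c9a degradation
        [0, 0, 0, +1, 0],   # Rn8  c3p synthesis
        [0, 0, 0, -1, +1],  # Rn9  c3p -> CEA activation
        [0, 0, 0, -1, 0],   # Rn10 c3p degradation
        [0, 0, 0, 0, -1],   # Rn11 CEA degradation
        [0, 0, 0, 0, -1],   # Rn12 CEA inhibition by IAP
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class StateVector:
    """Species concentrations in μM."""

    a1cc: float = 0.0
    c9p: float = 0.0
    c9a: float = 0.0
    c3p: float = 0.0
    CEA: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration for {name}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1cc, self.c9p, self.c9a, self.c3p, self.CEA])

    @classmethod
    def from_array(cls, x) -> "StateVector":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class CountState:
    """Species abundances in integer molecule counts, plus the CC input."""

    a1cc: int = 0
    c9p: int = 0
    c9a: int = 0
    c3p: int = 0
    CEA: int = 0
    cc_count: int = 0

    def __post_init__(self) -> None:
        for name in SPECIES + ("cc_count",):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"negative count for {name}")
            if v != int(v):
                raise ValueError(f"non-integral count for {name}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a1cc, self.c9p, self.c9a, self.c3p, self.CEA],
            dtype=np.int64,
        )

    @classmethod
    def from_array(cls, x, cc_count: int) -> "CountState":
        return cls(*(int(v) for v in x), cc_count=int(cc_count))


def _fluxes(x: np.ndarray, p: ModelParameters, cc: float):
    """The three composite fluxes (apoptosome formation, A, B) at state x."""
    a1cc, c9p, c9a, c3p, cea = x
    form = p.kf1 * cc / (1.0 + p.K_H * cc)
    g = (
        p.K_K * p.K_L * c9p * c9p
        / (1.0 + p.K_K * c9p + p.K_K * p.K_L * c9p * c9p)
    )
    if p.variant == "modified":
        hm = cea ** p.m_fb
        phi = p.beta_act + p.w_fb * hm / (hm + p.K_c ** p.m_fb)
        n = p.n
    else:
        phi, n = 1.0, 1.0
    A = p.kf2 * phi * a1cc * g
    B = p.kf3 * c9a ** n * p.K_P * c3p / (1.0 + p.K_P * c3p)
    return form, A, B


def derivatives(state, params: ModelParameters) -> np.ndarray:
    """Time derivatives (μM/min) of the five species.

    ``state`` may be a StateVector or any length-5 array-like of
    nonnegative concentrations.
    """
    x = state.as_array() if isinstance(state, StateVector) else np.asarray(
        state, dtype=float
    )
    if x.shape != (5,):
        raise ValueError("state must have five components")
    if np.any(x < 0):
        raise ValueError("negative state component")
    p = params
    form, A, B = _fluxes(x, p, p.CC)
    a1cc, c9p, c9a, c3p, cea = x
    return np.array(
        [
            form - p.kr1 * a1cc - p.mu1 * a1cc,
            p.Omega_9 - A - p.mu2 * c9p,
            A - p.mu3 * c9a,
            p.Omega_EZ - B - p.mu4 * c3p,
            B - p.k_u * p.IAP * cea / (1.0 + p.IAP * p.K_U) - p.mu5 * cea,
        ]
    )


def propensities(counts: CountState, params: ModelParameters) -> np.ndarray:
    """Propensities (events/min) of reactions Rn1..Rn12 at given counts.

    Concentrations count/V_c are substituted into the deterministic flux
    terms and multiplied by V_c.  Consuming reactions have zero
    propensity when their substrate count is zero, so counts stay
    nonnegative under the stoichiometry table.
    """
    p = params
    v = p.V_c
    x = counts.as_array() / v
    cc = counts.cc_count / v
    form, A, B = _fluxes(x, p, cc)
    a1cc, c9p, c9a, c3p, cea = x
    a = np.array(
        [
            form * v,
            p.kr1 * a1cc * v,
            p.mu1 * a1cc * v,
            p.Omega_9 * v,
            A * v,
            p.mu2 * c9p * v,
            p.mu3 * c9a * v,
            p.Omega_EZ * v,
            B * v,
            p.mu4 * c3p * v,
            p.mu5 * cea * v,
            p.k_u * p.IAP * cea / (1.0 + p.IAP * p.K_U) * v,
        ]
    )
    return a


def to_counts(state: StateVector, params: ModelParameters,
              cc_count: int | None = None) -> CountState:
    """Concentrations -> molecule counts (nearest int, ties away from zero)."""
    v = params.V_c
    vals = [int(np.floor(s * v + 0.5)) for s in state.as_array()]
    if cc_count is None:
        cc_count = int(np.floor(params.CC * v + 0.5))
    return CountState(*vals, cc_count=cc_count)


def to_concentration(counts: CountState, params: ModelParameters) -> StateVector:
    """Molecule counts -> concentrations (μM)."""
    return StateVector.from_array(counts.as_array() / params.V_c)


def default_initial_state(params: ModelParameters, eps: float = 0.1) -> StateVector:
    """Pre-stimulus state: procaspase pools at their unstimulated steady
    values, no apoptosome, and a small seed ``eps`` (μM) of active
    caspase-9 and caspase-3.

    The seed is needed because the modified model's activation flux is
    nearly shut at CEA=0; the default 0.1 μM places cells at the basin
    boundary of the bistable window, which is what makes the response
    threshold of quiescent cells sit near CC ≈ 0.2–0.3 μM.
    """
    return StateVector(
        a1cc=0.0,
        c9p=params.Omega_9 / params.mu2,
        c9a=eps,
        c3p=params.Omega_EZ / params.mu4,
        CEA=eps,
    )
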