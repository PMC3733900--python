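"""Model parameters for the intrinsic apoptosis pathway.

The model follows the caspase cascade downstream of mitochondrial
Cytochrome C (CC) release: CC binds Apaf-1 to form the apoptosome
(a1cc), which activates procaspase-9 (c9p) to caspase-9 (c9a); c9a
cleaves procaspase-3 (c3p) into active executioner caspase-3 (CEA),
which is inhibited by IAP.  All concentrations are in μM, time in
minutes.

Two variants are supported:

``modified``
    The bistable model: apoptosome-mediated caspase-9 activation is
    amplified by a steep positive feedback from CEA
    (``beta_act + w_fb * CEA^m / (CEA^m + K_c^m)``), and CEA activation
    carries a mild cooperativity ``n`` in c9a.  The feedback constants
    ``beta_act``/``w_fb``/``m_fb`` are calibrated so that the
    saddle-node thresholds of the CC bifurcation diagram sit at
    0.08 μM and 0.83 μM and the survival/apoptotic branches at
    ≈0.055 μM and ≈0.96 μM mid-window.

``fussenegger``
    The original monostable cascade: no CEA feedback (the activation
    factor is 1) and no cooperativity (n = 1).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ModelParameters",
    "CopyNumberCondition",
    "PAPER_CONDITIONS",
    "apply_condition",
]

_RATE_FIELDS = (
    "kf1", "kf2", "kf3", "kr1",
    "K_H", "K_K", "K_L", "K_P", "K_U",
    "k_u", "IAP", "K_c",
    "mu1", "mu2", "mu3", "mu4", "mu5",
    "Omega_EZ", "Omega_9",
    "beta_act", "w_fb",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and inputs of the pathway model (nominal defaults).

    Units: first-order rates 1/min; second-order rates 1/(μM·min);
    equilibrium constants 1/μM; IAP, K_c and CC in μM; synthesis rates
    in μM/min.  ``V_c`` (molecules per μM) bridges concentrations and
    molecule counts for stochastic simulation; 1000 maps the nominal
    procaspase-9 steady state (10 μM) onto 10^4 molecules per cell.
    """

    kf1: float = 0.12        # CC/Apaf-1 binding (Apaf-1 lumped in)
    kf2: float = 0.3         # caspase-9 activation catalysis
    kf3: float = 0.015       # caspase-3 activation catalysis
    kr1: float = 0.4         # apoptosome unbinding
    K_H: float = 1.0
    K_K: float = 0.5         # c9p/apoptosome binding, first site
    K_L: float = 0.3         # c9p/apoptosome binding, second site
    K_P: float = 0.1         # c9a/c3p binding
    K_U: float = 0.1         # IAP/CEA binding
    k_u: float = 0.03        # CEA inhibition by IAP
    IAP: float = 0.018       # free IAP concentration (μM)
    K_c: float = 0.1         # CEA feedback threshold (μM)
    mu1: float = 0.005       # degradation: a1cc
    mu2: float = 0.005       # degradation: c9p
    mu3: float = 0.005       # degradation: c9a
    mu4: float = 0.005       # degradation: c3p
    mu5: float = 0.005       # degradation: CEA
    Omega_EZ: float = 0.05   # basal c3p synthesis (μM/min)
    Omega_9: float = 0.05    # basal c9p synthesis (μM/min)
    n: float = 1.5           # cooperativity of CEA activation
    CC: float = 0.0          # input: cytosolic Cytochrome C (μM)
    variant: str = "modified"
    V_c: float = 1000.0      # molecules per μM
    # Feedback reconstruction constants (modified variant only).
    beta_act: float = 0.01881  # basal activation efficiency
    w_fb: float = 0.2223       # feedback amplitude
    m_fb: float = 8.0          # feedback Hill order

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.CC < 0:
            raise ValueError("CC must be >= 0")
        if self.V_c <= 0:
            raise ValueError("V_c must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.m_fb < 1:
            raise ValueError("m_fb must be >= 1")
        if self.variant not in ("modified", "fussenegger"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def effective_n(self) -> float:
        """Cooperativity actually applied (forced to 1 for fussenegger)."""
        return 1.0 if self.variant == "fussenegger" else self.n

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown parameter name(s): {sorted(bad)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class CopyNumberCondition:
    """A (procaspase-9, procaspase-3) abundance condition in molecules."""

    c9p_target: float
    c3p_target: float

    def __post_init__(self) -> None:
        if self.c9p_target <= 0 or self.c3p_target <= 0:
            raise ValueError("copy-number targets must be > 0")

    def __iter__(self) -> Iterator[float]:
        return iter((self.c9p_target, self.c3p_target))


#: The eight copy-number conditions studied: c9p ∈ {5e3, 1e4} crossed
#: with c3p ∈ {10, 1e2, 1e3, 1e4} molecules per cell.
PAPER_CONDITIONS: tuple[CopyNumberCondition, ...] = tuple(
    CopyNumberCondition(c9p, c3p)
    for c9p in (5e3, 1e4)
    for c3p in (10.0, 1e2, 1e3, 1e4)
)


def apply_condition(
    params: ModelParameters, cond: CopyNumberCondition
) -> ModelParameters:
    """Rescale synthesis rates so open-loop steady counts hit the targets.

    Omega_9 -> c9p_target*mu2/V_c and Omega_EZ -> c3p_target*mu4/V_c,
    i.e. the unstimulated steady abundances Omega/mu equal the targets.
    Other parameters are unchanged.
    """
    return params.replace(
        Omega_9=cond.c9p_target * params.mu2 / params.V_c,
        Omega_EZ=cond.c3p_target * params.mu4 / params.V_c,
    )
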