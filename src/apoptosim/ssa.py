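"""Exact stochastic simulation of the 12-reaction network (direct method).

Intrinsic noise is modeled by Gillespie's direct method over the twelve
lumped reactions: the waiting time to the next event is exponential in
the total propensity and the reaction is chosen proportionally to its
propensity (time uniform drawn first, reaction uniform second, so a
seed fully determines a trajectory).  Michaelis–Menten/Hill factors are
kept lumped in the propensities rather than expanded into elementary
steps.  Cytochrome C is a fixed boundary count: apoptosome formation
does not decrement it, mirroring its role as an input parameter of the
deterministic model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .deterministic import Trajectory
from .model import CountState, STOICHIOMETRY
from .params import CopyNumberCondition, ModelParameters, apply_condition

__all__ = ["SSAConfig", "SSATruncationError", "ssa_simulate",
           "ssa_population", "initial_counts"]


@dataclass(frozen=True)
class SSAConfig:
    t_end: float = 3000.0
    record_dt: float = 1.0
    seed: int = 0
    max_events: int = 50_000_000

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.record_dt <= 0 or self.max_events <= 0:
            raise ValueError("t_end, record_dt and max_events must be > 0")


class SSATruncationError(RuntimeError):
    """Event budget exhausted; ``trajectory`` holds the partial record."""

    def __init__(self, msg: str, trajectory: Trajectory):
        super().__init__(msg)
        self.trajectory = trajectory


def _pack(params: ModelParameters) -> np.ndarray:
    p = params
    return np.array(
        [p.kf1, p.kf2, p.kf3, p.kr1, p.K_H, p.K_K, p.K_L, p.K_P, p.K_U,
         p.k_u, p.IAP, p.K_c, p.mu1, p.mu2, p.mu3, p.mu4, p.mu5,
         p.Omega_EZ, p.Omega_9, p.effective_n, p.V_c,
         p.beta_act, p.w_fb, p.m_fb,
         1.0 if p.variant == "modified" else 0.0],
        dtype=np.float64,
    )


@njit(cache=True)
def _propensities_nb(x, cc_count, q, out):
    (kf1, kf2, kf3, kr1, KH, KK, KL, KP, KU, ku, IAP, Kc,
     mu1, mu2, mu3, mu4, mu5, OEZ, O9, n, Vc,
     beta, w, m, modified) = (
        q[0], q[1], q[2], q[3], q[4], q[5], q[6], q[7], q[8], q[9], q[10],
        q[11], q[12], q[13], q[14], q[15], q[16], q[17], q[18], q[19],
        q[20], q[21], q[22], q[23], q[24])
    a1cc = x[0] / Vc
    c9p = x[1] / Vc
    c9a = x[2] / Vc
    c3p = x[3] / Vc
    cea = x[4] / Vc
    cc = cc_count / Vc
    g = KK * KL * c9p * c9p / (1.0 + KK * c9p + KK * KL * c9p * c9p)
    if modified > 0.5:
        hm = cea ** m
        phi = beta + w * hm / (hm + Kc ** m)
    else:
        phi = 1.0
    A = kf2 * phi * a1cc * g
    B = kf3 * c9a ** n * KP * c3p / (1.0 + KP * c3p)
    out[0] = kf1 * cc / (1.0 + KH * cc) * Vc
    out[1] = kr1 * a1cc * Vc
    out[2] = mu1 * a1cc * Vc
    out[3] = O9 * Vc
    out[4] = A * Vc
    out[5] = mu2 * c9p * Vc
    out[6] = mu3 * c9a * Vc
    out[7] = OEZ * Vc
    out[8] = B * Vc
    out[9] = mu4 * c3p * Vc
    out[10] = mu5 * cea * Vc
    out[11] = ku * IAP * cea / (1.0 + IAP * KU) * Vc
    return out


@njit(cache=True)
def _ssa_core(x0, cc_count, q, stoich, t_end, record_dt, max_events, seed):
    np.random.seed(seed)
    n_rec = int(t_end / record_dt) + 1
    rec = np.empty((n_rec, 5), dtype=np.int64)
    x = x0.copy()
    a = np.empty(12)
    t = 0.0
    idx = 0
    rec[0] = x
    idx = 1
    events = 0
    while True:
        _propensities_nb(x, cc_count, q, a)
        a0 = 0.0
        for k in range(12):
            a0 += a[k]
        if a0 <= 0.0:
            break
        u1 = np.random.random()
        tau = -np.log(u1) / a0
        u2 = np.random.random()
        t_next = t + tau
        while idx < n_rec and idx * record_dt <= t_next:
            rec[idx] = x
            idx += 1
        if t_next > t_end:
            break
        t = t_next
        thr = u2 * a0
        acc = 0.0
        r = 11
        for k in range(12):
            acc += a[k]
            if acc >= thr:
                r = k
                break
        for s in range(5):
            x[s] += stoich[r, s]
        events += 1
        if events >= max_events:
            return rec, idx, events, 1
    while idx < n_rec:
        rec[idx] = x
        idx += 1
    return rec, idx, events, 0


def ssa_simulate(
    params: ModelParameters,
    init: CountState,
    cfg: SSAConfig,
) -> Trajectory:
    """One exact stochastic realization, recorded on a regular grid.

    Identical (params, init, cfg) give bit-identical trajectories.
    Raises SSATruncationError when ``cfg.max_events`` is exhausted.
    """
    q = _pack(params)
    rec, idx, events, truncated = _ssa_core(
        init.as_array(), float(init.cc_count), q, STOICHIOMETRY,
        float(cfg.t_end), float(cfg.record_dt), int(cfg.max_events),
        int(cfg.seed) & 0x7FFFFFFF,
    )
    times = np.arange(idx) * cfg.record_dt
    meta = {
        "seed": int(cfg.seed), "cc_count": int(init.cc_count),
        "variant": params.variant, "n_events": int(events),
    }
    traj = Trajectory(times, rec[:idx].astype(np.int64), meta)
    if truncated:
        raise SSATruncationError(
            f"event budget {cfg.max_events} exhausted at t={times[-1]:.1f}",
            traj,
        )
    return traj


def initial_counts(
    params: ModelParameters,
    cond: CopyNumberCondition,
    cc_count: int,
    eps: float = 0.1,
) -> CountState:
    """Initial molecule counts for a copy-number condition.

    Procaspase pools start at the condition targets; active caspases
    start at the seed eps (μM) converted to counts; no apoptosome.
    """
    seed_count = int(np.floor(eps * params.V_c + 0.5))
    return CountState(
        a1cc=0,
        c9p=int(round(cond.c9p_target)),
        c9a=seed_count,
        c3p=int(round(cond.c3p_target)),
        CEA=seed_count,
        cc_count=int(cc_count),
    )


def ssa_population(
    params: ModelParameters,
    cond: CopyNumberCondition,
    cc_count: int,
    n_cells: int = 150,
    base_seed: int = 0,
    condition_mode: str = "initial",
    eps: float = 0.1,
    t_end: float = 3000.0,
    record_dt: float = 1.0,
    max_events: int = 50_000_000,
) -> list[Trajectory]:
    """Independent single-cell realizations under a copy-number condition.

    ``condition_mode="initial"`` (default) realizes the condition as
    initial molecule counts with nominal synthesis rates — abundances
    below the open-loop steady values are transient, as after partial
    degradation or dilution.  ``condition_mode="synthesis"`` instead
    rescales the synthesis rates so the targets persist as open-loop
    steady counts (see ``apply_condition``).

    Cell i uses seed ``base_seed + i``; results are independent of
    execution order.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if condition_mode == "synthesis":
        params = apply_condition(params, cond)
    elif condition_mode != "initial":
        raise ValueError(f"unknown condition_mode {condition_mode!r}")
    init = initial_counts(params, cond, cc_count, eps=eps)
    out = []
    for i in range(n_cells):
        cfg = SSAConfig(t_end=t_end, record_dt=record_dt,
                        seed=base_seed + i, max_events=max_events)
        out.append(ssa_simulate(params, init, cfg))
    return out
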