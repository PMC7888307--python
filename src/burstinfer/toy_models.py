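"""Illustrative mechanistic promoter models.

Two small models used to illustrate how dynamic TF inputs can reshape
effective promoter behaviour:

* an interval-dependent *memory* model, where TF binding recruits activator
  molecules (I1) that push the promoter into an active state, and unbound
  promoters slowly convert activators into inhibitors (I2) that sequester the
  promoter in a silent state — short pulse intervals give positive memory,
  long intervals negative memory;

* a four-state *context-dependent* promoter with nonlinear (Hill-type)
  TF-dependent switching rates, analysed through the expected-transition-count
  matrix H(t) = \\int_0^t Q(s) diag(P(s)) ds of its forward equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _ssa
from .input_signal import InputSeconds, TFInput

__all__ = [
    "MemoryModelParams",
    "ContextModelParams",
    "context_switch_rates",
    "context_generator",
    "transition_count_matrix",
    "simulate_memory_model",
    "simulate_context_counts",
]


@dataclass(frozen=True)
class MemoryModelParams:
    """Rates (1/s) of the activator/inhibitor memory model."""

    c1: float = 0.02  # P0 -> P1, per unit u
    c2: float = 0.06  # P1 -> P0
    c3: float = 0.003  # P1 -> P2, per activator I1
    c4: float = 0.02  # P2 -> P1
    c5: float = 0.0006  # P0 -> P3, per inhibitor I2
    c6: float = 0.001  # P3 -> P0
    c7: float = 0.9  # I1 production while in P1
    c8: float = 7e-6  # I1 -> I2 conversion while in P0, per I1
    z: float = 0.6  # transcription rate in P2

    def __post_init__(self) -> None:
        if any(getattr(self, f) < 0 for f in ("c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8", "z")):
            raise ValueError("all rates must be non-negative")


@dataclass(frozen=True)
class ContextModelParams:
    """Rates and Hill parameters of the 4-state context-dependent promoter."""

    gamma1: float = 0.01
    c2: float = 0.01
    gamma3: float = 0.01
    gamma4: float = 0.01
    c6: float = 0.01
    gamma5: float = 0.1
    n3: float = 6.0
    n4: float = 2.0
    n5: float = 3.0
    V3: float = 0.5
    V4: float = 0.001
    V5: float = 1.2
    z1: float = 0.1
    z3: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n3, self.n4, self.n5) < 1:
            raise ValueError("Hill exponents must be >= 1")
        if min(self.V3, self.V4, self.V5) <= 0:
            raise ValueError("half-saturation constants must be positive")


def context_switch_rates(params: ContextModelParams, u: float) -> tuple[float, float, float, float]:
    """TF-dependent switching rates (c1, c3, c4, c5) at input level u."""
    if u < 0:
        raise ValueError("u must be non-negative")
    c1 = params.gamma1 * u
    un3, un4, un5 = u**params.n3, u**params.n4, u**params.n5
    c3 = params.gamma3 * (1.0 - un3 / (params.V3**params.n3 + un3))
    c4 = params.gamma4 * un4 / (params.V4**params.n4 + un4)
    c5 = params.gamma5 * un5 / (params.V5**params.n5 + un5)
    return c1, c3, c4, c5


def context_generator(params: ContextModelParams, u: float) -> np.ndarray:
    """Generator Q(u) of the 4-state chain, column convention dP/dt = Q P.

    Transitions: P0 -> P1 (c1), P1 -> P0 (c2), P1 -> P2 (c3), P2 -> P1 (c4),
    P1 -> P3 (c5), P3 -> P0 (c6)."""
    c1, c3, c4, c5 = context_switch_rates(params, u)
    c2, c6 = params.c2, params.c6
    return np.array(
        [
            [-c1, c2, 0.0, c6],
            [c1, -(c2 + c3 + c5), c4, 0.0],
            [0.0, c3, -c4, 0.0],
            [0.0, c5, 0.0, -c6],
        ]
    )


def transition_count_matrix(
    params: ContextModelParams,
    signal: TFInput,
    T_s: float,
    u_scale: float | None = None,
    p0: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict:
    """Expected transition counts H(T) = \\int_0^T Q(s) diag(P(s)) ds.

    The input is in arbitrary units of order one for the Hill constants;
    by default the signal is normalized to peak 1 (u_scale = 1/u0).
    Returns raw H, the display variant with zeroed diagonal, and P(T).
    """
    if T_s <= 0:
        raise ValueError("T must be positive")
    scale = (1.0 / signal.u0 if signal.u0 > 0 else 1.0) if u_scale is None else u_scale
    p0 = np.array([1.0, 0.0, 0.0, 0.0]) if p0 is None else np.asarray(p0, dtype=float)

    def rhs(t, y):
        P = y[:4]
        u = scale * float(signal(t / 60.0))
        Q = context_generator(params, u)
        dP = Q @ P
        dH = Q * P[None, :]
        return np.concatenate((dP, dH.ravel()))

    sol = solve_ivp(
        rhs,
        (0.0, float(T_s)),
        np.concatenate((p0, np.zeros(16))),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"transition-count ODE solver failed: {sol.message}")
    y = sol.y[:, -1]
    H = y[4:].reshape(4, 4)
    H_display = H.copy()
    np.fill_diagonal(H_display, 0.0)
    return {"H": H, "H_display": H_display, "P_final": y[:4], "p0": p0}


def simulate_context_counts(
    params: ContextModelParams,
    signal: TFInput,
    T_s: float,
    n_runs: int,
    seed: int,
    u_scale: float | None = None,
) -> np.ndarray:
    """SSA tally of mean transition counts (counting oracle for H)."""
    scale = (1.0 / signal.u0 if signal.u0 > 0 else 1.0) if u_scale is None else u_scale
    inp = InputSeconds(signal, T_s)
    args = inp.kernel_args()
    (seg_times, seg_levels, seg_flags, u0, k1s, k2s, break_s, u_upper) = args
    # per-piece exit-rate bounds; all switch rates are monotone in u
    u_lo = np.minimum(
        inp.u(break_s[:-1]), inp.u(break_s[1:])
    )
    rates_hi = np.array([context_switch_rates(params, scale * u) for u in u_upper])
    rates_lo = np.array([context_switch_rates(params, scale * u) for u in u_lo])
    c1b = np.maximum(rates_hi[:, 0], rates_lo[:, 0])
    c3b = np.maximum(rates_hi[:, 1], rates_lo[:, 1])
    c5b = np.maximum(rates_hi[:, 3], rates_lo[:, 3])
    bound0 = c1b
    bound1 = params.c2 + c3b + c5b
    counts = np.zeros((4, 4))
    _ssa.nb_seed(seed % 2**31)
    _ssa.context_model_counts(
        n_runs,
        float(T_s),
        params.gamma1,
        params.c2,
        params.gamma3,
        params.gamma4,
        params.c6,
        params.gamma5,
        params.n3,
        params.n4,
        params.n5,
        params.V3,
        params.V4,
        params.V5,
        scale,
        seg_times,
        seg_levels,
        seg_flags,
        u0,
        k1s,
        k2s,
        break_s,
        bound0,
        bound1,
        counts,
    )
    return counts / n_runs


def simulate_memory_model(
    params: MemoryModelParams,
    signal: TFInput,
    T_s: float,
    n_runs: int,
    seed: int,
    sample_times_s: np.ndarray | None = None,
) -> dict:
    """Ensemble-average transcription rate and cumulative output over time.

    SSA over the promoter states {P0..P3} plus unbounded activator (I1) and
    inhibitor (I2) counters; the promoter starts in P0 with I1 = I2 = 0.
    Transcription occurs at rate z while in P2.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if sample_times_s is None:
        sample_times_s = np.linspace(0.0, T_s, 301)
    sample_times_s = np.asarray(sample_times_s, dtype=float)
    inp = InputSeconds(signal, T_s)
    args = inp.kernel_args()
    rate_sum = np.zeros(len(sample_times_s))
    output_sum = np.zeros(len(sample_times_s))
    _ssa.nb_seed(seed % 2**31)
    _ssa.memory_model_ensemble(
        n_runs,
        float(T_s),
        params.c1,
        params.c2,
        params.c3,
        params.c4,
        params.c5,
        params.c6,
        params.c7,
        params.c8,
        params.z,
        *args,
        sample_times_s,
        rate_sum,
        output_sum,
    )
    return {
        "t_s": sample_times_s,
        "mean_rate": rate_sum / n_runs,
        "mean_output": output_sum / n_runs,
    }


def pulse_output_increments(
    result: dict, schedule: tuple[tuple[float, float], ...], window_min: float
) -> np.ndarray:
    """Mean-output increment over a fixed window from each pulse start."""
    t = result["t_s"]
    out = result["mean_output"]
    incs = []
    for start, _ in schedule:
        t0, t1 = start * 60.0, (start + window_min) * 60.0
        o0 = np.interp(t0, t, out)
        o1 = np.interp(t1, t, out)
        incs.append(o1 - o0)
    return np.asarray(incs)
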