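"""Deterministic nuclear transcription-factor input signal u(t).

The stress-responsive TF (Msn2 in budding yeast) is driven into the nucleus
by pulses of an inhibitor; nuclear import and export are modelled as
first-order processes.  Within a pulse that starts at ``t_s`` with nuclear
level ``u_s``,

    u(t) = u0 - (u0 - u_s) * exp(-k1 (t - t_s)),

and after a pulse ending at ``t_e`` with level ``u_e``,

    u(t) = u_e * exp(-k2 (t - t_e)).

Chaining these across an arbitrary pulse schedule gives a continuous,
piecewise-exponential input.  Rates at this interface are per minute (the
calibrated import/export table is per minute); every other module works in
seconds and converts exactly once at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TFInput",
    "AMPLITUDE_TABLE",
    "build_pulse_schedule",
    "evaluate_input",
    "fit_input_kinetics",
    "InputFitResult",
]

#: Calibrated (u0, k1 [1/min], k2 [1/min]) for the four inhibitor
#: concentrations used experimentally, keyed by the nominal percentage of
#: maximal nuclear TF they induce.
AMPLITUDE_TABLE: dict[int, tuple[float, float, float]] = {
    25: (313.2, 1.11, 0.97),
    50: (774.5, 0.61, 0.81),
    75: (1107.8, 0.59, 0.57),
    100: (1410.1, 1.07, 0.29),
}


@dataclass(frozen=True)
class TFInput:
    """Nuclear TF abundance signal defined by a pulse schedule.

    Parameters
    ----------
    u0 : float
        Maximal nuclear abundance (absolute units) for this stimulus level.
    k1, k2 : float
        Nuclear import and export rates, per minute.
    schedule : tuple of (start, end)
        Sorted, non-overlapping stimulus intervals in minutes.
    """

    u0: float
    k1: float
    k2: float
    schedule: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.u0 < 0:
            raise ValueError("u0 must be non-negative")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("import/export rates must be positive")
        sched = tuple((float(a), float(b)) for a, b in self.schedule)
        prev_end = -np.inf
        for a, b in sched:
            if b < a:
                raise ValueError(f"pulse ({a}, {b}) has negative duration")
            if a < prev_end:
                raise ValueError("pulse intervals must be sorted and non-overlapping")
            prev_end = b
        object.__setattr__(self, "schedule", sched)

    # -- breakpoint bookkeeping ------------------------------------------------
    def _segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (boundary times, entry levels, in-pulse flags).

        Segment ``i`` spans ``[t_i, t_{i+1})`` (the last one is unbounded);
        ``levels[i]`` is u at the segment start, obtained by chaining the
        import/export solutions so that u is continuous.
        """
        times, levels, flags = [], [], []
        u_cur = 0.0
        t_cur = -np.inf
        for a, b in self.schedule:
            # export (or pre-stimulus zero) segment before this pulse
            times.append(t_cur)
            levels.append(u_cur)
            flags.append(False)
            if np.isfinite(t_cur):
                u_cur = u_cur * np.exp(-self.k2 * (a - t_cur))
            times.append(a)
            levels.append(u_cur)
            flags.append(True)
            u_cur = self.u0 - (self.u0 - u_cur) * np.exp(-self.k1 * (b - a))
            t_cur = b
        times.append(t_cur)
        levels.append(u_cur)
        flags.append(False)
        return np.asarray(times), np.asarray(levels), np.asarray(flags, dtype=bool)

    def __call__(self, t_min) -> np.ndarray:
        return evaluate_input(self, t_min)

    @property
    def t_end_min(self) -> float:
        """End of the last stimulus pulse (minutes); 0 if no pulses."""
        return self.schedule[-1][1] if self.schedule else 0.0


def evaluate_input(signal: TFInput, t_min) -> np.ndarray:
    """Evaluate u(t) on a grid of times (minutes).

    Times before the first pulse evaluate to the pre-stimulus baseline 0.
    """
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    times, levels, flags = signal._segments()
    idx = np.searchsorted(times, t, side="right") - 1
    idx = np.clip(idx, 0, len(times) - 1)
    t0 = times[idx]
    us = levels[idx]
    out = np.zeros_like(t)
    pulse = flags[idx]
    dt = t - t0
    out[pulse] = signal.u0 - (signal.u0 - us[pulse]) * np.exp(-signal.k1 * dt[pulse])
    decay = ~pulse & np.isfinite(t0)
    out[decay] = us[decay] * np.exp(-signal.k2 * dt[decay])
    if np.isscalar(t_min) or np.ndim(t_min) == 0:
        return float(out[0])
    return out


def build_pulse_schedule(
    n_pulses: int,
    duration_min: float,
    interval_min: float = 0.0,
    amplitude_level: int = 100,
    start_min: float = 0.0,
) -> TFInput:
    """Build a pulse-train input at one of the calibrated amplitude levels.

    ``interval_min`` is the gap between the end of one pulse and the start of
    the next, so consecutive pulses start ``duration + interval`` apart.
    """
    if amplitude_level not in AMPLITUDE_TABLE:
        raise ValueError(
            f"unknown amplitude level {amplitude_level!r}; "
            f"valid levels are {sorted(AMPLITUDE_TABLE)} (percent of maximal nuclear TF)"
        )
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    if interval_min < 0:
        raise ValueError("interval must be non-negative")
    u0, k1, k2 = AMPLITUDE_TABLE[amplitude_level]
    period = duration_min + interval_min
    schedule = tuple(
        (start_min + i * period, start_min + i * period + duration_min)
        for i in range(n_pulses)
    )
    return TFInput(u0=u0, k1=k1, k2=k2, schedule=schedule)


@dataclass(frozen=True)
class InputFitResult:
    """Least-squares fit of (u0, k1, k2) to a measured nuclear-TF trace."""

    u0: float
    k1: float
    k2: float
    residual_norm: float
    degenerate: bool = False

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.u0, self.k1, self.k2)


def fit_input_kinetics(
    t_min: np.ndarray,
    measured: np.ndarray,
    schedule: tuple[tuple[float, float], ...],
) -> InputFitResult:
    """Fit the import/export kinetics to a measured nuclear trace.

    Bounded nonlinear least squares starting from (max(data), 1, 1); the fit
    is deterministic.  An all-zero trace is degenerate: u0 = 0 and the rates
    are unidentifiable (flagged).
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(measured, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.all(y == 0):
        return InputFitResult(0.0, 1.0, 1.0, 0.0, degenerate=True)

    def resid(p):
        sig = TFInput(u0=p[0], k1=p[1], k2=p[2], schedule=schedule)
        return evaluate_input(sig, t) - y

    x0 = np.array([max(float(np.max(y)), 1e-6), 1.0, 1.0])
    sol = least_squares(
        resid, x0, bounds=([0, 1e-6, 1e-6], [np.inf, 1e3, 1e3]), xtol=1e-14, ftol=1e-14
    )
    return InputFitResult(
        u0=float(sol.x[0]),
        k1=float(sol.x[1]),
        k2=float(sol.x[2]),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


# ---------------------------------------------------------------------------
# seconds-domain view used by the stochastic modules
# ---------------------------------------------------------------------------


class InputSeconds:
    """Seconds-domain view of a :class:`TFInput` with thinning bounds.

    Precomputes the signal's breakpoints (pulse starts/ends) plus e-folding
    subdivisions, so that on every sub-segment u is monotone and bounded by
    its endpoint values.  Used by the stochastic simulation kernels for exact
    (thinning-based) handling of the time-varying activation propensity.
    """

    def __init__(self, signal: TFInput, horizon_s: float):
        self.signal = signal
        self.horizon_s = float(horizon_s)
        times, levels, flags = signal._segments()
        k1s = signal.k1 / 60.0
        k2s = signal.k2 / 60.0
        # refined breakpoints in seconds
        bps = [0.0]
        for i in range(len(times)):
            t0 = max(times[i] * 60.0, 0.0)
            t1 = times[i + 1] * 60.0 if i + 1 < len(times) else self.horizon_s
            t1 = min(t1, self.horizon_s)
            if not np.isfinite(t0) or t1 <= t0 or t0 >= self.horizon_s:
                continue
            rate = k1s if flags[i] else k2s
            step = 1.0 / rate if rate > 0 else (t1 - t0)
            n_sub = max(int(np.ceil((t1 - t0) / step)), 1)
            for j in range(1, n_sub + 1):
                bps.append(min(t0 + j * step, t1))
        bps.append(self.horizon_s)
        bps = np.unique(np.asarray(bps))
        self.break_s = bps
        u_at = signal(bps / 60.0)
        # upper bound of u on [bps[i], bps[i+1]]: u is monotone there, but the
        # e-folding subdivision means max(endpoints) is exact anyway
        self.u_upper = np.maximum(u_at[:-1], u_at[1:])
        self.u_max = float(np.max(u_at)) if len(u_at) else 0.0
        self._times_s = times * 60.0
        self._levels = levels
        self._flags = flags
        self._k1s = k1s
        self._k2s = k2s

    def u(self, t_s) -> np.ndarray:
        return self.signal(np.asarray(t_s) / 60.0)

    def kernel_args(self):
        """Arrays consumed by the numba SSA kernels."""
        times = np.where(np.isfinite(self._times_s), self._times_s, -1e30)
        return (
            times,
            self._levels,
            self._flags.astype(np.int64),
            float(self.signal.u0),
            self._k1s,
            self._k2s,
            self.break_s,
            self.u_upper,
        )
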