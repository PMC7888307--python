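"""Stochastic three-state promoter model driving mRNA/protein expression.

The promoter is a continuous-time Markov chain over states 0 (inactive,
z0 = 0), 1 (permissive, rate z1) and 2 (enhanced, rate z2), arranged as a
chain 0 <-> 1 <-> 2.  Activation 0 -> 1 is coupled to the nuclear TF signal,
q01(t) = gamma * u(t); all other switching rates are constant.  mRNA and
protein follow a two-stage birth-death process; the translation rate A is
drawn once per cell from a population distribution (extrinsic variability).

All rates here are per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _ssa
from .input_signal import InputSeconds, TFInput

__all__ = [
    "PromoterModel",
    "GeneKinetics",
    "CellTrajectory",
    "build_generator",
    "solve_promoter_forward",
    "sample_translation_rates",
    "simulate_cell_ssa",
]


@dataclass(frozen=True)
class PromoterModel:
    """Three-state telegraph-type promoter with TF-coupled activation.

    Parameters
    ----------
    gamma : float
        Input-coupling coefficient; q01(t) = gamma * u(t)  [1/(u-unit s)].
    q10, q12, q21 : float
        Constant switching rates [1/s].
    z1, z2 : float
        Transcription rates in states 1 and 2 [molecules/s]; state 0 is silent.
    p0 : tuple
        Initial state distribution.
    """

    gamma: float
    q10: float
    q12: float
    q21: float
    z1: float
    z2: float
    p0: tuple[float, float, float] = (1.0, 0.0, 0.0)

    n_states: int = field(default=3, init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("gamma", "q10", "q12", "q21", "z1", "z2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        p0 = np.asarray(self.p0, dtype=float)
        if p0.shape != (3,) or np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("p0 must be a length-3 probability vector")
        object.__setattr__(self, "p0", tuple(p0))

    @property
    def z(self) -> np.ndarray:
        """Transcription rate per state, z[0] = 0."""
        return np.array([0.0, self.z1, self.z2])

    @property
    def theta(self) -> dict[str, float]:
        return {
            "gamma": self.gamma,
            "q10": self.q10,
            "q12": self.q12,
            "q21": self.q21,
            "z1": self.z1,
            "z2": self.z2,
        }

    def with_params(self, **kw) -> "PromoterModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class GeneKinetics:
    """mRNA/protein kinetics with extrinsic translation-rate variability.

    c1, c2 : degradation rates of mRNA and protein [1/s].
    mean_A, cv_A : population mean and CV of the per-cell translation rate A
    [1/s per mRNA].  The population distribution family is log-normal by
    default (consistent with the filter's log-normal closure); a gamma
    family is available.
    """

    c1: float
    c2: float
    mean_A: float
    cv_A: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("degradation rates must be positive")
        if self.mean_A <= 0:
            raise ValueError("mean_A must be positive")
        if self.cv_A < 0:
            raise ValueError("cv_A must be non-negative")
        if self.family not in ("lognormal", "gamma"):
            raise ValueError("family must be 'lognormal' or 'gamma'")

    @property
    def omega(self) -> dict[str, float]:
        return {"c1": self.c1, "c2": self.c2, "mean_A": self.mean_A, "cv_A": self.cv_A}

    def with_params(self, **kw) -> "GeneKinetics":
        return replace(self, **kw)


@dataclass
class CellTrajectory:
    """One exact realization of the joint process for a single cell."""

    jump_times: np.ndarray  # promoter jump times [s], excluding t=0
    states: np.ndarray  # state after each jump
    initial_state: int
    A: float
    sample_times: np.ndarray  # [s]
    sampled_state: np.ndarray
    sampled_mrna: np.ndarray
    sampled_protein: np.ndarray

    @property
    def path(self) -> tuple[np.ndarray, np.ndarray]:
        """Full piecewise-constant promoter path as (times, states) with the
        initial state at t = 0."""
        t = np.concatenate(([0.0], self.jump_times))
        s = np.concatenate(([self.initial_state], self.states)).astype(int)
        return t, s


def build_generator(model: PromoterModel, u_value: float) -> np.ndarray:
    """Generator matrix Q(u) in the column convention dP/dt = Q P."""
    if u_value < 0:
        raise ValueError("u must be non-negative")
    q01 = model.gamma * u_value
    return np.array(
        [
            [-q01, model.q10, 0.0],
            [q01, -(model.q10 + model.q12), model.q21],
            [0.0, model.q12, -model.q21],
        ]
    )


def solve_promoter_forward(
    model: PromoterModel,
    signal: TFInput,
    t_grid_s: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Solve the promoter forward equation dP/dt = Q(t) P on a grid (seconds).

    Returns an array of shape (len(t_grid_s), 3).
    """
    t_grid_s = np.asarray(t_grid_s, dtype=float)

    def rhs(t, p):
        u = float(signal(t / 60.0))
        return build_generator(model, u) @ p

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid_s[-1])),
        np.asarray(model.p0, dtype=float),
        t_eval=t_grid_s,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(
            f"forward equation solver failed: {sol.message}; try tightening rtol/atol"
        )
    return sol.y.T


def translation_rate_dist_params(kin: GeneKinetics) -> tuple[float, float]:
    """(log-mean, log-sd) of the log-normal translation-rate distribution."""
    s2 = np.log1p(kin.cv_A**2)
    mu = np.log(kin.mean_A) - 0.5 * s2
    return mu, np.sqrt(s2)


def sample_translation_rates(
    kin: GeneKinetics, n_cells: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw per-cell translation rates A from the population distribution."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if kin.cv_A == 0:
        return np.full(n_cells, kin.mean_A)
    if kin.family == "gamma":
        shape = 1.0 / kin.cv_A**2
        return rng.gamma(shape, kin.mean_A / shape, size=n_cells)
    mu, sd = translation_rate_dist_params(kin)
    return np.exp(rng.normal(mu, sd, size=n_cells))


def simulate_cell_ssa(
    model: PromoterModel,
    kin: GeneKinetics,
    signal: TFInput | InputSeconds,
    A: float,
    T_s: float,
    seed: int,
    sample_times_s: np.ndarray | None = None,
    initial_state: int | None = None,
    max_jumps: int = 200_000,
) -> CellTrajectory:
    """Exact SSA realization of the joint (promoter, mRNA, protein) process.

    The time-varying activation propensity is handled by thinning against
    piecewise bounds of u(t); the realization is statistically exact.
    Deterministic for a fixed seed.
    """
    if T_s <= 0:
        raise ValueError("T must be positive")
    if A <= 0:
        raise ValueError("A must be positive")
    inp = signal if isinstance(signal, InputSeconds) else InputSeconds(signal, T_s)
    if inp.horizon_s < T_s - 1e-9:
        raise ValueError("input horizon shorter than simulation span")
    args = inp.kernel_args()
    if sample_times_s is None:
        sample_times_s = np.array([T_s])
    sample_times_s = np.asarray(sample_times_s, dtype=float)
    out_state = np.zeros(len(sample_times_s), dtype=np.int64)
    out_m = np.zeros(len(sample_times_s), dtype=np.int64)
    out_n = np.zeros(len(sample_times_s), dtype=np.int64)
    jt = np.zeros(max_jumps)
    js = np.zeros(max_jumps, dtype=np.int64)
    if initial_state is None:
        rng = np.random.default_rng(seed)
        initial_state = int(rng.choice(3, p=np.asarray(model.p0)))
    _ssa.nb_seed(seed % 2**31)
    nj = _ssa.ssa_full(
        initial_state,
        float(T_s),
        0.0,
        model.z1,
        model.z2,
        model.gamma,
        model.q10,
        model.q12,
        model.q21,
        kin.c1,
        kin.c2,
        float(A),
        *args,
        sample_times_s,
        out_state,
        out_m,
        out_n,
        jt,
        js,
    )
    if nj < 0:  # pragma: no cover
        raise RuntimeError("promoter jump buffer overflow; increase max_jumps")
    return CellTrajectory(
        jump_times=jt[:nj].copy(),
        states=js[:nj].copy(),
        initial_state=int(initial_state),
        A=float(A),
        sample_times=sample_times_s,
        sampled_state=out_state,
        sampled_mrna=out_m,
        sampled_protein=out_n,
    )
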