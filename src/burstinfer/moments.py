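"""Conditional moment dynamics of the marginalized subsystem X = (M, N, A).

Given a fixed transcription-rate path z(t) (piecewise constant), the
conditional distribution of mRNA M, protein N and the static per-cell
translation rate A satisfies a *closed* linear system of 13 moment ODEs
(all propensities are linear, so there is no moment-closure error):

    dE[M]      = z - c1 E[M]
    dE[N]      = E[MA] - c2 E[N]
    dE[M^2]    = z + (2z + c1) E[M] - 2 c1 E[M^2]
    dE[MN]     = z E[N] + E[M^2 A] - (c1 + c2) E[MN]
    dE[MA]     = z E[A] - c1 E[MA]
    dE[N^2]    = c2 E[N] + E[MA] + 2 E[MNA] - 2 c2 E[N^2]
    dE[NA]     = E[MA^2] - c2 E[NA]
    dE[M^2 A]  = z E[A] + (2z + c1) E[MA] - 2 c1 E[M^2 A]
    dE[MNA]    = z E[NA] + E[M^2 A^2] - (c1 + c2) E[MNA]
    dE[MA^2]   = z E[A^2] - c1 E[MA^2]
    dE[M^2A^2] = z E[A^2] + (2z + c1) E[MA^2] - 2 c1 E[M^2 A^2]
    dE[A] = dE[A^2] = 0.

The filter assumes X | z(t) is multivariate log-normal with logarithmic
moments (mu, Sigma); this module provides the exact conversions between
logarithmic and raw moments and a fast per-segment propagator (the segment
system is LTI, solved by eigendecomposition of the augmented generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import _ssa
from .promoter import GeneKinetics

__all__ = [
    "LogMoments",
    "MOMENT_NAMES",
    "lognormal_to_raw_moments",
    "raw_moments_to_lognormal",
    "propagate_conditional_moments",
    "ConditionalMomentPropagator",
    "CLAMP_COUNTER",
]

#: Names/order of the 13 propagated raw moments.
MOMENT_NAMES = [
    "M", "N", "M2", "MN", "MA", "N2", "NA", "M2A", "MNA", "MA2", "M2A2", "A", "A2",
]

# exponents (p_M, p_N, p_A) of each raw moment as a monomial in (M, N, A)
_P = np.array(
    [
        [1, 0, 0],
        [0, 1, 0],
        [2, 0, 0],
        [1, 1, 0],
        [1, 0, 1],
        [0, 2, 0],
        [0, 1, 1],
        [2, 0, 1],
        [1, 1, 1],
        [1, 0, 2],
        [2, 0, 2],
        [0, 0, 1],
        [0, 0, 2],
    ],
    dtype=float,
)

_VAR_FLOOR = 1e-12

#: Counts degenerate log-variance clamps in raw->log conversion (diagnostic).
CLAMP_COUNTER = {"count": 0}


@dataclass
class LogMoments:
    """Mean and covariance of log(M, N, A) — the filter's sufficient statistics."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        sigma = np.asarray(self.sigma, dtype=float).reshape(3, 3)
        if np.abs(sigma - sigma.T).max() > 1e-8 * max(1.0, np.abs(sigma).max()):
            raise ValueError("sigma must be symmetric")
        self.sigma = ensure_psd(sigma)

    def copy(self) -> "LogMoments":
        return LogMoments(self.mu.copy(), self.sigma.copy())


def ensure_psd(sigma: np.ndarray) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues to zero."""
    sigma = 0.5 * (sigma + sigma.T)
    try:
        np.linalg.cholesky(sigma + _VAR_FLOOR * np.eye(sigma.shape[0]))
        return sigma
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sigma)
        return (v * np.clip(w, 0.0, None)) @ v.T


def _ln_to_raw(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Unchecked fast path of :func:`lognormal_to_raw_moments`."""
    PS = _P @ sigma
    log_m = _P @ mu + 0.5 * np.einsum("ij,ij->i", PS, _P)
    if np.any(log_m > 700):
        bad = MOMENT_NAMES[int(np.argmax(log_m))]
        raise OverflowError(f"raw moment E[{bad}] overflows for the given (mu, sigma)")
    return np.exp(log_m)


def lognormal_to_raw_moments(lm: LogMoments) -> np.ndarray:
    """All 13 raw moments of a log-normal (mu, Sigma) via
    E[prod X_i^{p_i}] = exp(p' mu + p' Sigma p / 2)."""
    return _ln_to_raw(lm.mu, lm.sigma)


def _raw_to_ln(rm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unchecked fast path of :func:`raw_moments_to_lognormal`."""
    m1 = rm[[0, 1, 11]]  # E[M], E[N], E[A]
    if not (m1 > 0).all() or not np.isfinite(rm).all():
        raise ValueError("first moments must be positive and finite")
    # second-moment matrix E[X_i X_j]
    m2 = np.array(
        [
            [rm[2], rm[3], rm[4]],
            [rm[3], rm[5], rm[6]],
            [rm[4], rm[6], rm[12]],
        ]
    )
    if not (m2 > 0).all():
        raise ValueError("second moments must be positive")
    sigma = np.log(m2 / np.outer(m1, m1))
    for i in range(3):
        if sigma[i, i] < _VAR_FLOOR:
            CLAMP_COUNTER["count"] += 1
            sigma[i, i] = _VAR_FLOOR
    mu = np.log(m1) - 0.5 * np.diag(sigma)
    return mu, sigma


def raw_moments_to_lognormal(rm: np.ndarray) -> LogMoments:
    """Fit log-normal logarithmic moments from first/second raw moments.

    Only the first- and second-order moments are used; any higher moments the
    propagation needs are re-derived from the fitted log-normal.  Degenerate
    implied log-variances are clamped to a small floor (counted in
    CLAMP_COUNTER).
    """
    mu, sigma = _raw_to_ln(np.asarray(rm, dtype=float))
    return LogMoments(mu, sigma)


def _segment_generator(z: float, kin: GeneKinetics) -> np.ndarray:
    """Augmented 14x14 generator G of the affine moment system m' = G m,
    where m = (13 raw moments, 1)."""
    c1, c2 = kin.c1, kin.c2
    G = np.zeros((14, 14))
    i = {name: k for k, name in enumerate(MOMENT_NAMES)}
    one = 13
    G[i["M"], i["M"]] = -c1
    G[i["M"], one] = z
    G[i["N"], i["MA"]] = 1.0
    G[i["N"], i["N"]] = -c2
    G[i["M2"], i["M"]] = 2 * z + c1
    G[i["M2"], i["M2"]] = -2 * c1
    G[i["M2"], one] = z
    G[i["MN"], i["N"]] = z
    G[i["MN"], i["M2A"]] = 1.0
    G[i["MN"], i["MN"]] = -(c1 + c2)
    G[i["MA"], i["A"]] = z
    G[i["MA"], i["MA"]] = -c1
    G[i["N2"], i["N"]] = c2
    G[i["N2"], i["MA"]] = 1.0
    G[i["N2"], i["MNA"]] = 2.0
    G[i["N2"], i["N2"]] = -2 * c2
    G[i["NA"], i["MA2"]] = 1.0
    G[i["NA"], i["NA"]] = -c2
    G[i["M2A"], i["A"]] = z
    G[i["M2A"], i["MA"]] = 2 * z + c1
    G[i["M2A"], i["M2A"]] = -2 * c1
    G[i["MNA"], i["NA"]] = z
    G[i["MNA"], i["M2A2"]] = 1.0
    G[i["MNA"], i["MNA"]] = -(c1 + c2)
    G[i["MA2"], i["A2"]] = z
    G[i["MA2"], i["MA2"]] = -c1
    G[i["M2A2"], i["A2"]] = z
    G[i["M2A2"], i["MA2"]] = 2 * z + c1
    G[i["M2A2"], i["M2A2"]] = -2 * c1
    return G


class ConditionalMomentPropagator:
    """Fast propagator of the 13-moment conditional system.

    Per promoter segment the system is linear time-invariant with a Metzler
    generator acting on non-negative moment vectors, so the matrix
    exponential action is evaluated by uniformization — a cancellation-free
    non-negative series, exact to series truncation (1e-16 relative).
    """

    def __init__(self, kin: GeneKinetics):
        self.kin = kin
        self._G: dict[float, np.ndarray] = {}

    def _G_for(self, z: float) -> np.ndarray:
        G = self._G.get(z)
        if G is None:
            G = _segment_generator(z, self.kin)
            self._G[z] = G
        return G

    def step_matrix(self, z: float, dt: float) -> np.ndarray:
        return expm(self._G_for(z) * dt)

    def propagate(self, rm: np.ndarray, z: float, dt: float) -> np.ndarray:
        if dt < 0:
            raise ValueError("dt must be non-negative")
        if dt == 0:
            return np.asarray(rm, dtype=float)
        m = np.empty(14)
        m[:13] = rm
        m[13] = 1.0
        return _ssa.expm_action_nonneg(self._G_for(z), float(dt), m)[:13]

    def propagate_path(self, rm: np.ndarray, segments) -> np.ndarray:
        """Propagate through a sequence of (z, dt) segments."""
        for z, dt in segments:
            if dt > 0:
                rm = self.propagate(rm, z, dt)
        return rm


def propagate_conditional_moments(
    rm: np.ndarray, z: float, kin: GeneKinetics, dt: float
) -> np.ndarray:
    """Propagate the 13 raw conditional moments over [0, dt] at constant z."""
    if z < 0:
        raise ValueError("z must be non-negative")
    return ConditionalMomentPropagator(kin).propagate(np.asarray(rm, dtype=float), z, dt)


def initial_log_moments(
    kin: GeneKinetics,
    pseudo_mean: float = 0.1,
    pseudo_cv: float = 1.0,
) -> LogMoments:
    """Filter initialization at t = 0.

    A log-normal cannot represent M = N = 0 exactly, so the filter starts
    from pseudo-moments E[M] = E[N] = pseudo_mean with CV = pseudo_cv
    (independent), and the population prior for A.  The influence of this
    choice washes out after the first few measurement updates.
    """
    cv_a = max(kin.cv_A, 1e-6)
    s_mm = np.log1p(pseudo_cv**2)
    s_aa = np.log1p(cv_a**2)
    mu = np.array(
        [
            np.log(pseudo_mean) - 0.5 * s_mm,
            np.log(pseudo_mean) - 0.5 * s_mm,
            np.log(kin.mean_A) - 0.5 * s_aa,
        ]
    )
    sigma = np.diag([s_mm, s_mm, s_aa])
    return LogMoments(mu, sigma)
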