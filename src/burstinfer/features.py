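"""Transcriptional features extracted from posterior path samples.

Every feature is a functional of a piecewise-constant transcription-rate
path, computed exactly (segment sums, no quadrature) on each posterior
sample and then averaged under the particle weights.  Population summaries
(percent responders, peak mean transcription rate and its timing, output
noise CV^2) and the regression/clustering analyses operate on the per-cell
feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage

from .promoter import PromoterModel
from .smc import PosteriorSample

__all__ = [
    "ActivityThreshold",
    "path_functionals",
    "classify_responder",
    "extract_cell_features",
    "posterior_rate_curve",
    "summarize_population",
    "regress_output_on_time_transcribing",
    "cluster_condition_profiles",
]

RESPONDER_PROB_CUTOFF = 0.99


@dataclass(frozen=True)
class ActivityThreshold:
    """Definition of 'significant transcriptional activity'.

    A state is significant if its transcription rate is at least ``fraction``
    of ``reference_max_rate`` (by convention the maximum rate over the
    reference long-pulse conditions, or max(z1, z2) of the generating model
    for synthetic work); a path qualifies as responding if it spends at least
    ``min_duration_min`` cumulative minutes in significant states.
    """

    reference_max_rate: float
    fraction: float = 0.2
    min_duration_min: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.min_duration_min < 0:
            raise ValueError("min_duration must be non-negative")

    def significant_states(self, model: PromoterModel) -> np.ndarray:
        return model.z >= self.fraction * self.reference_max_rate


def path_functionals(
    times: np.ndarray,
    states: np.ndarray,
    T_s: float,
    model: PromoterModel,
    thr: ActivityThreshold,
) -> dict:
    """Exact feature functionals of one piecewise-constant promoter path."""
    times = np.asarray(times, dtype=float)
    states = np.asarray(states, dtype=int)
    bounds = np.concatenate((times, [T_s]))
    durs = np.diff(bounds)
    z = model.z
    sig = thr.significant_states(model)
    active = z > 0
    time_in_state = np.zeros(model.n_states)
    np.add.at(time_in_state, states, durs)
    t_sig = float(time_in_state[sig].sum())
    qualifies = t_sig >= thr.min_duration_min * 60.0
    first_sig = np.inf
    for t, s in zip(times, states):
        if sig[s]:
            first_sig = t
            break
    return {
        "time_in_state_s": time_in_state,
        # time active: residence in significant (responsive) states, defined
        # analogously to the time to activate
        "time_active_s": t_sig,
        # time transcribing: residence in any transcriptionally permissive
        # state (z > 0), the regressor of the output scaling analysis
        "time_transcribing_s": float(time_in_state[active].sum()),
        "time_to_activate_s": float(first_sig),
        "output_molecules": float(np.sum(z[states] * durs)),
        "qualifies": bool(qualifies),
    }


def classify_responder(
    posterior: PosteriorSample, thr: ActivityThreshold, model: PromoterModel
) -> tuple[float, bool]:
    """Posterior responder probability pa and the pa > 0.99 classification."""
    if posterior.J == 0:
        raise ValueError("empty posterior")
    pa = 0.0
    for (t, s), w in zip(posterior.paths, posterior.weights):
        if w == 0:
            continue
        f = path_functionals(t, s, posterior.T_s, model, thr)
        if f["qualifies"]:
            pa += w
    pa = float(min(max(pa, 0.0), 1.0))
    return pa, pa > RESPONDER_PROB_CUTOFF


def extract_cell_features(
    posterior: PosteriorSample, thr: ActivityThreshold, model: PromoterModel
) -> dict:
    """Posterior-averaged features for one cell.

    Time-to-activate is conditioned on qualifying (responding) paths; if no
    path qualifies it is undefined (NaN).  Unstable cells carry no features.
    """
    if not posterior.stable:
        raise ValueError("cell flagged unstable; no features defined")
    n_states = model.n_states
    acc = {
        "time_active_s": 0.0,
        "time_transcribing_s": 0.0,
        "output_molecules": 0.0,
        "pa": 0.0,
    }
    tis = np.zeros(n_states)
    tta_num = 0.0
    tta_wsum = 0.0
    for (t, s), w in zip(posterior.paths, posterior.weights):
        if w == 0:
            continue
        f = path_functionals(t, s, posterior.T_s, model, thr)
        acc["time_active_s"] += w * f["time_active_s"]
        acc["time_transcribing_s"] += w * f["time_transcribing_s"]
        acc["output_molecules"] += w * f["output_molecules"]
        tis += w * f["time_in_state_s"]
        if f["qualifies"]:
            acc["pa"] += w
            tta_num += w * f["time_to_activate_s"]
            tta_wsum += w
    pa = float(min(max(acc["pa"], 0.0), 1.0))
    out = {
        "response_probability": pa,
        "responder": pa > RESPONDER_PROB_CUTOFF,
        "time_to_activate_min": (tta_num / tta_wsum / 60.0) if tta_wsum > 0 else np.nan,
        "time_active_min": acc["time_active_s"] / 60.0,
        "time_transcribing_min": acc["time_transcribing_s"] / 60.0,
        "transcriptional_output": acc["output_molecules"],
        "cell_id": posterior.cell_id,
    }
    for i in range(n_states):
        out[f"time_in_state_{i}_min"] = tis[i] / 60.0
    return out


def posterior_rate_curve(
    posterior: PosteriorSample, model: PromoterModel, t_grid_s: np.ndarray
) -> np.ndarray:
    """lambda(t) = E[Z(t) | y] on a grid, from the weighted path samples."""
    t_grid_s = np.asarray(t_grid_s, dtype=float)
    z = model.z
    lam = np.zeros_like(t_grid_s)
    for (t, s), w in zip(posterior.paths, posterior.weights):
        if w == 0:
            continue
        idx = np.searchsorted(t, t_grid_s, side="right") - 1
        lam += w * z[s[np.clip(idx, 0, len(s) - 1)]]
    return lam


def summarize_population(
    cell_features: pd.DataFrame,
    rate_curves: np.ndarray | None = None,
    t_grid_s: np.ndarray | None = None,
    cv2_population: bool = True,
) -> dict:
    """Condition-level summary over retained cells.

    The mean transcription-rate curve <lambda(t)> is averaged over responder
    cells; lambda_max / tau_max are its peak and argmax.  Output noise CV^2
    uses the population (divide-by-n) variance by default.
    """
    if len(cell_features) == 0:
        raise ValueError("no retained cells")
    df = cell_features
    responders = df["responder"].astype(bool)
    out_vals = df["transcriptional_output"].to_numpy(dtype=float)
    ddof = 0 if cv2_population else 1
    mean_out = out_vals.mean()
    cv2 = float(out_vals.var(ddof=ddof) / mean_out**2) if mean_out > 0 else np.nan
    summary = {
        "n_cells": int(len(df)),
        "percent_responders": 100.0 * float(responders.mean()),
        "mean_output": float(mean_out),
        "output_noise_cv2": cv2,
        "mean_time_active_min": float(df["time_active_min"].mean()),
        "mean_time_to_activate_min": (
            float(df.loc[responders, "time_to_activate_min"].mean())
            if responders.any()
            else np.nan
        ),
    }
    if rate_curves is not None and t_grid_s is not None and responders.any():
        lam = np.asarray(rate_curves)[responders.to_numpy()].mean(axis=0)
        summary["lambda_max"] = float(lam.max())
        summary["tau_max_min"] = float(t_grid_s[int(np.argmax(lam))] / 60.0)
    else:
        summary["lambda_max"] = np.nan
        summary["tau_max_min"] = np.nan
    return summary


def regress_output_on_time_transcribing(cell_features: pd.DataFrame) -> dict:
    """Regress transcriptional output on time transcribing across cells.

    All cells (responders and non-responders) enter.  The primary fit is the
    proportional (through-origin) model output = k * time; an ordinary
    two-parameter fit is reported alongside.  R^2 is computed about the mean
    of the response in both cases.
    """
    df = cell_features.dropna(subset=["time_transcribing_min", "transcriptional_output"])
    if len(df) < 3:
        raise ValueError("need at least 3 cells with finite features")
    x = df["time_transcribing_min"].to_numpy(dtype=float)
    y = df["transcriptional_output"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        return {"slope": np.nan, "r2": np.nan, "degenerate": True}
    sxx = float(np.sum(x * x))
    k = float(np.sum(x * y) / sxx)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - k * x) ** 2))
    if ss_tot == 0:
        r2 = 1.0
        degenerate = True
    else:
        r2 = 1.0 - ss_res / ss_tot
        degenerate = False
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": k,
        "r2": r2,
        "slope_ols": float(ols.params[1]),
        "intercept_ols": float(ols.params[0]),
        "r2_ols": float(ols.rsquared),
        "degenerate": degenerate,
        "n": int(len(df)),
    }


def regress_inferred_vs_true(inferred: np.ndarray, true: np.ndarray) -> dict:
    """Through-origin slope and R^2 of inferred against true feature values."""
    x = np.asarray(true, dtype=float)
    y = np.asarray(inferred, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.allclose(x, 0):
        return {"slope": np.nan, "r2": np.nan, "n": int(len(x))}
    k = float(np.sum(x * y) / np.sum(x * x))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - k * x) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": k, "r2": r2, "n": int(len(x))}


def cluster_condition_profiles(
    feature_matrix: pd.DataFrame,
    responder_columns: list[str] | None = None,
    n_clusters: int = 2,
    method: str = "average",
) -> dict:
    """Hierarchically cluster condition-level feature profiles.

    Rows with a zero value in any of ``responder_columns`` (percent-responder
    entries per pulse length) are excluded first, since the remaining
    features are undefined there.  Features are z-score normalized; zero
    variance features are dropped with a warning entry.  Euclidean distance,
    average linkage by default.
    """
    df = feature_matrix.copy()
    if responder_columns:
        keep = (df[responder_columns] > 0).all(axis=1)
        df = df.loc[keep]
    if len(df) < 2:
        raise ValueError("need at least 2 rows after exclusion")
    dropped = [c for c in df.columns if float(df[c].std(ddof=0)) == 0.0]
    used = df.drop(columns=dropped)
    zs = (used - used.mean()) / used.std(ddof=0)
    Z = linkage(zs.to_numpy(), method=method, metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return {
        "linkage": Z,
        "labels": pd.Series(labels, index=df.index),
        "rows": list(df.index),
        "dropped_features": dropped,
        "normalized": zs,
    }
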