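"""Model/Results interface over the calibration and reconstruction pipeline.

Two fitted-model objects cover the workflow:

* :class:`MomentCalibrationModel` — matches the population mean/variance of
  the reporter to the model's exact moment equations by MCMC; its
  :meth:`~MomentCalibrationModel.fit` returns a
  :class:`CalibrationResults` carrying MAP estimates, the posterior trace,
  acceptance diagnostics and a summary table.

* :class:`PromoterInferenceModel` — runs the Rao-Blackwellized particle
  filter on each cell given a calibrated model; its
  :meth:`~PromoterInferenceModel.fit` returns a
  :class:`PromoterInferenceResults` with per-cell posterior path samples,
  the exclusion bookkeeping, and feature extraction / population summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationConfig,
    CalibrationReport,
    MomentTargets,
    bootstrap_moment_errors,
    run_moment_mcmc,
)
from .features import (
    ActivityThreshold,
    extract_cell_features,
    posterior_rate_curve,
    regress_output_on_time_transcribing,
    summarize_population,
)
from .input_signal import InputSeconds, TFInput
from .promoter import GeneKinetics, PromoterModel
from .smc import CellMeasurement, PosteriorSample, SMCConfig, run_hybrid_smc

__all__ = [
    "MomentCalibrationModel",
    "CalibrationResults",
    "PromoterInferenceModel",
    "PromoterInferenceResults",
    "split_cells",
]


def split_cells(
    cells: list[CellMeasurement], fraction: float, seed: int
) -> tuple[list[CellMeasurement], list[CellMeasurement]]:
    """Random split into (calibration, reconstruction) subsets.

    Calibration uses a random fraction of the cells; reconstruction uses the
    complement, keeping the two stages statistically independent.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cells))
    n_cal = max(int(round(fraction * len(cells))), 1)
    cal = [cells[i] for i in idx[:n_cal]]
    rec = [cells[i] for i in idx[n_cal:]]
    return cal, rec


class MomentCalibrationModel:
    """Moment-matching calibration of (theta, omega) from reporter moments.

    Parameters
    ----------
    cells : list of CellMeasurement
        Cells of one experimental condition (shared time grid).
    signal : TFInput
        The nuclear-TF input of the condition.
    config : CalibrationConfig, optional
    init_model, init_kinetics : optional starting points; stage-2 fits pass
        the stage-1 MAP model here together with ``fixed`` omega values in
        the config.
    """

    def __init__(
        self,
        cells: list[CellMeasurement],
        signal: TFInput,
        config: CalibrationConfig | None = None,
        init_model: PromoterModel | None = None,
        init_kinetics: GeneKinetics | None = None,
    ):
        if len(cells) == 0:
            raise ValueError("no cells supplied")
        t0 = cells[0].times_s
        for c in cells[1:]:
            if len(c.times_s) != len(t0) or not np.allclose(c.times_s, t0):
                raise ValueError("all cells must share one measurement grid")
        self.cells = cells
        self.signal = signal
        self.config = config or CalibrationConfig()
        self.init_model = init_model
        self.init_kinetics = init_kinetics

    def moment_targets(self) -> MomentTargets:
        values = np.stack([c.values for c in self.cells])
        return bootstrap_moment_errors(
            values, self.cells[0].times_s, self.config.B, self.config.seed
        )

    def fit(self, free_params: tuple[str, ...] | None = None) -> "CalibrationResults":
        targets = self.moment_targets()
        report = run_moment_mcmc(
            targets,
            self.signal,
            self.config,
            init_model=self.init_model,
            init_kinetics=self.init_kinetics,
            free_params=free_params,
        )
        return CalibrationResults(model=self, targets=targets, report=report)


@dataclass
class CalibrationResults:
    """MAP parameter estimates with posterior trace and fit diagnostics."""

    model: MomentCalibrationModel
    targets: MomentTargets
    report: CalibrationReport

    @property
    def params(self) -> dict:
        return self.report.map_params

    @property
    def map_model(self) -> PromoterModel:
        return self.report.map_model

    @property
    def map_kinetics(self) -> GeneKinetics:
        return self.report.map_kinetics

    @property
    def trace(self) -> pd.DataFrame:
        return self.report.trace

    def posterior_sd(self) -> dict:
        burn = int(self.model.config.burn_in_fraction * self.model.config.n_mcmc)
        retained = self.report.trace.iloc[burn:]
        return {n: float(retained[n].std(ddof=1)) for n in self.report.map_params}

    def summary(self) -> pd.DataFrame:
        sds = self.posterior_sd()
        rows = [
            {"parameter": n, "map": v, "posterior_sd": sds[n]}
            for n, v in self.report.map_params.items()
        ]
        df = pd.DataFrame(rows).set_index("parameter")
        df.attrs["acceptance_rate"] = self.report.acceptance_rate
        df.attrs["error_mean"] = self.report.error_mean
        df.attrs["error_var"] = self.report.error_var
        return df

    def plot_fit(self, ax=None):
        """Predicted vs empirical reporter moments at the MAP."""
        import matplotlib.pyplot as plt

        from .calibration import population_moment_equations

        pred = population_moment_equations(
            self.map_model, self.map_kinetics, self.model.signal, self.targets.t_s
        )
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.2))
        t_min = self.targets.t_s / 60.0
        ax[0].errorbar(t_min, self.targets.mean, yerr=self.targets.se_mean, fmt=".", label="data")
        ax[0].plot(t_min, pred["mean_protein"], label="model")
        ax[0].set(xlabel="time (min)", ylabel="mean protein")
        ax[1].errorbar(t_min, self.targets.var, yerr=self.targets.se_var, fmt=".", label="data")
        ax[1].plot(t_min, pred["var_protein"], label="model")
        ax[1].set(xlabel="time (min)", ylabel="protein variance")
        ax[0].legend()
        return ax


class PromoterInferenceModel:
    """Per-cell reconstruction of promoter paths by the hybrid filter."""

    def __init__(
        self,
        cells: list[CellMeasurement],
        model: PromoterModel,
        kinetics: GeneKinetics,
        signal: TFInput,
        smc_config: SMCConfig | None = None,
    ):
        if len(cells) == 0:
            raise ValueError("no cells supplied")
        self.cells = cells
        self.promoter = model
        self.kinetics = kinetics
        self.signal = signal
        self.smc_config = smc_config or SMCConfig()

    def fit(
        self,
        per_cell_models: list[tuple[PromoterModel, GeneKinetics]] | None = None,
    ) -> "PromoterInferenceResults":
        """Run the filter on every cell; per-cell (model, kinetics) overrides
        support parameter-mismatch studies."""
        cfg = self.smc_config
        T_s = max(float(c.times_s[-1]) for c in self.cells)
        inp = InputSeconds(self.signal, T_s)
        posteriors: list[PosteriorSample] = []
        seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=len(self.cells))
        for i, cell in enumerate(self.cells):
            m, k = (
                per_cell_models[i] if per_cell_models is not None else (self.promoter, self.kinetics)
            )
            cell_cfg = SMCConfig(
                J=cfg.J,
                seed=int(seeds[i]),
                y_floor=cfg.y_floor,
                init_pseudo_mean=cfg.init_pseudo_mean,
                init_pseudo_cv=cfg.init_pseudo_cv,
                ess_threshold=cfg.ess_threshold,
            )
            posteriors.append(run_hybrid_smc(cell, m, k, inp, cell_cfg))
        return PromoterInferenceResults(model=self, posteriors=posteriors)


@dataclass
class PromoterInferenceResults:
    """Posterior path samples per cell plus exclusion bookkeeping."""

    model: PromoterInferenceModel
    posteriors: list[PosteriorSample]
    _features: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def stable_mask(self) -> np.ndarray:
        return np.array([p.stable for p in self.posteriors])

    @property
    def excluded_fraction(self) -> float:
        return 1.0 - float(self.stable_mask.mean())

    @property
    def log_marginal_likelihoods(self) -> np.ndarray:
        return np.array([p.log_marginal_likelihood for p in self.posteriors])

    def features(self, threshold: ActivityThreshold) -> pd.DataFrame:
        """Per-cell posterior-expected features over the retained cells."""
        rows = []
        for cell, post in zip(self.model.cells, self.posteriors):
            if not post.stable:
                continue
            f = extract_cell_features(post, threshold, self.model.promoter)
            f["cell_id"] = cell.cell_id
            f["log_marginal_likelihood"] = post.log_marginal_likelihood
            rows.append(f)
        return pd.DataFrame(rows)

    def population_summary(
        self, threshold: ActivityThreshold, n_grid: int = 151
    ) -> dict:
        feats = self.features(threshold)
        T_s = max(float(c.times_s[-1]) for c in self.model.cells)
        t_grid = np.linspace(0.0, T_s, n_grid)
        curves = np.stack(
            [
                posterior_rate_curve(p, self.model.promoter, t_grid)
                for p in self.posteriors
                if p.stable
            ]
        )
        out = summarize_population(feats, curves, t_grid)
        out["excluded_fraction"] = self.excluded_fraction
        return out

    def regression(self, threshold: ActivityThreshold) -> dict:
        return regress_output_on_time_transcribing(self.features(threshold))

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "stable": p.stable,
                "log_marginal_likelihood": p.log_marginal_likelihood,
                "min_ess": float(p.ess.min()) if len(p.ess) else np.nan,
            }
            for c, p in zip(self.model.cells, self.posteriors)
        ]
        return pd.DataFrame(rows).set_index("cell_id")

    def plot_posterior_paths(self, cell_index: int = 0, n_paths: int = 30, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 2.5))
        post = self.posteriors[cell_index]
        z = self.model.promoter.z
        t_grid = np.linspace(0, post.T_s, 400)
        rng = np.random.default_rng(0)
        idx = rng.choice(post.J, size=min(n_paths, post.J), p=post.weights)
        for j in idx:
            t, s = post.paths[j]
            k = np.clip(np.searchsorted(t, t_grid, side="right") - 1, 0, len(s) - 1)
            ax.step(t_grid / 60.0, z[s[k]], alpha=0.15, color="C0")
        ax.plot(t_grid / 60.0, posterior_rate_curve(post, self.model.promoter, t_grid), color="C1")
        ax.set(xlabel="time (min)", ylabel="transcription rate (1/s)")
        return ax
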