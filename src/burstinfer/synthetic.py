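"""Synthetic benchmark data generator.

Emulates the evaluation protocol used to validate the inference method:
30 cells simulated exactly (SSA) from the three-state model under a single
75%-level, 40-min TF pulse, protein sampled at 55 equidistant time points
over 150 min and corrupted by log-normal measurement noise with eta = 0.05.
Two presets: "slow" (kappa = 1, switch-like promoter) and "fast"
(kappa = 10) differing only in the state-1 <-> state-2 switching rates.
Ground-truth features are computed from the exact simulated paths with the
same activity threshold used at inference time, so inferred and true
features are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import ActivityThreshold, path_functionals
from .input_signal import InputSeconds, TFInput, build_pulse_schedule
from .promoter import (
    CellTrajectory,
    GeneKinetics,
    PromoterModel,
    sample_translation_rates,
    simulate_cell_ssa,
)
from .smc import CellMeasurement

__all__ = [
    "BenchmarkConfig",
    "BenchmarkDataset",
    "benchmark_model",
    "generate_benchmark_dataset",
    "perturb_parameters",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Benchmark study conditions (rates in 1/s unless noted)."""

    kappa: float = 1.0  # promoter speed multiplier; 1 = slow, 10 = fast
    n_cells: int = 30
    T_min: float = 150.0
    K: int = 55
    eta: float = 0.05
    gamma: float = 0.05
    q10: float = 0.055
    q12_base: float = 0.001  # times kappa
    q21_base: float = 0.004  # times kappa
    z1: float = 0.0035
    z2: float = 0.728
    c1: float = 0.0013
    c2: float = 1.67e-5
    mean_A: float = 0.1
    cv_A: float = 0.02
    amplitude_level: int = 75
    pulse_duration_min: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.K < 2:
            raise ValueError("K must be >= 2")


@dataclass
class BenchmarkDataset:
    cells: list[CellMeasurement]
    trajectories: list[CellTrajectory]
    true_features: pd.DataFrame
    model: PromoterModel
    kinetics: GeneKinetics
    signal: TFInput
    threshold: ActivityThreshold
    config: BenchmarkConfig

    @property
    def sample_times_s(self) -> np.ndarray:
        return self.cells[0].times_s


def benchmark_model(cfg: BenchmarkConfig) -> tuple[PromoterModel, GeneKinetics, TFInput]:
    model = PromoterModel(
        gamma=cfg.gamma,
        q10=cfg.q10,
        q12=cfg.q12_base * cfg.kappa,
        q21=cfg.q21_base * cfg.kappa,
        z1=cfg.z1,
        z2=cfg.z2,
    )
    kin = GeneKinetics(c1=cfg.c1, c2=cfg.c2, mean_A=cfg.mean_A, cv_A=cfg.cv_A)
    signal = build_pulse_schedule(
        1, cfg.pulse_duration_min, amplitude_level=cfg.amplitude_level
    )
    return model, kin, signal


def generate_benchmark_dataset(cfg: BenchmarkConfig) -> BenchmarkDataset:
    """Simulate the benchmark: exact SSA truth + log-normally noised readouts.

    y_k = n_k * exp(eta * eps_k); with eta = 0 the readout equals the true
    protein count.  Deterministic given cfg.seed.
    """
    model, kin, signal = benchmark_model(cfg)
    T_s = cfg.T_min * 60.0
    t_samp = np.linspace(0.0, T_s, cfg.K)
    rng = np.random.default_rng(cfg.seed)
    A = sample_translation_rates(kin, cfg.n_cells, rng)
    inp = InputSeconds(signal, T_s)
    thr = ActivityThreshold(reference_max_rate=max(cfg.z1, cfg.z2))
    cells: list[CellMeasurement] = []
    trajs: list[CellTrajectory] = []
    rows = []
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_cells)
    for i in range(cfg.n_cells):
        traj = simulate_cell_ssa(
            model,
            kin,
            inp,
            float(A[i]),
            T_s,
            int(seeds[i]),
            sample_times_s=t_samp,
            initial_state=0,
        )
        n = traj.sampled_protein.astype(float)
        y = n * np.exp(cfg.eta * rng.standard_normal(cfg.K)) if cfg.eta > 0 else n
        cells.append(
            CellMeasurement(times_s=t_samp, values=y, eta=max(cfg.eta, 1e-6), cell_id=f"cell_{i:03d}")
        )
        trajs.append(traj)
        pt, ps = traj.path
        f = path_functionals(pt, ps, T_s, model, thr)
        rows.append(
            {
                "cell_id": f"cell_{i:03d}",
                "A": float(A[i]),
                "time_active_min": f["time_active_s"] / 60.0,
                "time_transcribing_min": f["time_transcribing_s"] / 60.0,
                "time_to_activate_min": (
                    f["time_to_activate_s"] / 60.0 if f["qualifies"] else np.nan
                ),
                "responder": f["qualifies"],
                "transcriptional_output": f["output_molecules"],
            }
        )
    return BenchmarkDataset(
        cells=cells,
        trajectories=trajs,
        true_features=pd.DataFrame(rows),
        model=model,
        kinetics=kin,
        signal=signal,
        threshold=thr,
        config=cfg,
    )


def perturb_parameters(
    params: dict[str, float], log_sd: float = 0.1, rng: np.random.Generator | int = 0
) -> dict[str, float]:
    """Resample each parameter from LN(log(b), log_sd^2) around its value b.

    Emulates imperfect parameter knowledge at reconstruction time; the
    log-normal median equals the true value and positivity is preserved.
    """
    if log_sd < 0:
        raise ValueError("log_sd must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return {
        k: float(v * np.exp(log_sd * rng.standard_normal())) for k, v in params.items()
    }


def perturbed_model_kinetics(
    model: PromoterModel,
    kin: GeneKinetics,
    log_sd: float,
    rng: np.random.Generator,
) -> tuple[PromoterModel, GeneKinetics]:
    """Perturb every free parameter of (model, kinetics) per cell."""
    th = perturb_parameters(model.theta, log_sd, rng)
    om = perturb_parameters(
        {"c1": kin.c1, "c2": kin.c2, "mean_A": kin.mean_A, "cv_A": kin.cv_A}, log_sd, rng
    )
    return replace(model, **th), replace(kin, **om)
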