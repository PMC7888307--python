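import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import burstinfer as bi
from burstinfer.input_signal import TFInput


@pytest.fixture(scope="session")
def benchmark_slow():
    """Small slow-promoter benchmark dataset shared across tests."""
    return bi.generate_benchmark_dataset(bi.BenchmarkConfig(kappa=1.0, n_cells=6, seed=7))


@pytest.fixture(scope="session")
def lowcopy_fixture():
    """Two-state, low-copy (protein < 50) model under near-constant input.

    States 1 <-> 0 only (q12 = q21 = 0); M_ss = 5 when active; measurements
    start once protein is clearly above zero so the log-normal filter and the
    full-SSA reference see the same regime.
    """
    T_s = 3000.0
    signal = TFInput(u0=1.0, k1=100.0, k2=1.0, schedule=((0.0, T_s / 60.0),))
    model = bi.PromoterModel(gamma=0.01, q10=0.01, q12=0.0, q21=0.0, z1=0.1, z2=0.0)
    kin = bi.GeneKinetics(c1=0.02, c2=1e-4, mean_A=0.006, cv_A=0.1)
    t_samp = np.linspace(600.0, T_s, 15)
    return {"signal": signal, "model": model, "kin": kin, "t_samp": t_samp, "T_s": T_s, "eta": 0.2}


def make_lowcopy_cells(fx, n_cells, seed):
    """Simulate cells from the low-copy fixture; returns (cells, true paths)."""
    rng = np.random.default_rng(seed)
    A = bi.sample_translation_rates(fx["kin"], n_cells, rng)
    cells, paths = [], []
    for i in range(n_cells):
        traj = bi.simulate_cell_ssa(
            fx["model"], fx["kin"], fx["signal"], float(A[i]), fx["T_s"],
            seed=int(rng.integers(2**31 - 1)), sample_times_s=fx["t_samp"], initial_state=0,
        )
        n = traj.sampled_protein.astype(float)
        y = np.maximum(n, 1e-12) * np.exp(fx["eta"] * rng.standard_normal(len(n)))
        cells.append(bi.CellMeasurement(times_s=fx["t_samp"], values=y, eta=fx["eta"], cell_id=f"c{i}"))
        paths.append(traj.path)
    return cells, paths
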