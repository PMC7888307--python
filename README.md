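# burstinfer

Reconstruction of promoter switching and transcription dynamics from noisy
single-cell protein-reporter time series.

Single-cell time-lapse reporter data (e.g. YFP driven by stress-responsive
promoters in budding yeast, with the transcription factor Msn2 pulsed into
the nucleus under optogenetic/chemical control) contain rich information
about *when* a promoter was transcriptionally active in each individual cell
— but the promoter state itself is never observed. `burstinfer` infers it.

## Model

Gene expression is described by a three-state telegraph-type promoter driving
a two-stage birth–death process:

- promoter: a continuous-time Markov chain over states 0 (silent, z₀ = 0),
  1 (permissive, rate z₁) and 2 (enhanced, rate z₂), arranged 0 ⇌ 1 ⇌ 2.
  Activation is coupled to the nuclear TF signal, q₀₁(t) = γ·u(t); the other
  switching rates (q₁₀, q₁₂, q₂₁) are constant.
- u(t): deterministic nuclear-TF input built from first-order import/export
  kinetics over arbitrary pulse schedules (calibrated amplitude levels
  25/50/75/100% of maximal nuclear TF).
- mRNA M and protein N: birth–death with degradation rates c₁, c₂ and a
  per-cell random translation rate A ~ LN with mean ⟨A⟩ and CV[A]
  (extrinsic variability).
- measurements: yₖ | N(tₖ)=n ~ LN(log n, η²) at the imaging time points.

## Inference

The central algorithm is a **Rao-Blackwellized sequential Monte Carlo
filter**: promoter paths are sampled exactly by the stochastic simulation
algorithm, while the high-copy subsystem X = (M, N, A) conditional on each
path is marginalized analytically through a *closed* system of 13 conditional
moment ODEs combined with a multivariate log-normal closure. Conditioning on
an observation and the marginal likelihood of an observation are then both
closed-form log-normal operations, so a cell with tens of thousands of
protein molecules costs no more than one with fifty.

Kinetic parameters are calibrated separately by moment matching: the exact
population mean/variance of the reporter (closed linear moment ODEs — all
propensities are linear, so there is no closure error) are matched to the
empirical moments, weighted by bootstrap standard errors, with a
Metropolis–Hastings sampler under Gamma priors. Calibration uses a random
half of the cells; reconstruction uses the other half.

From the posterior path samples the package computes the transcriptional
features used to compare promoters across input conditions: responder
probability (≥ 2 min of significant activity, pₐ > 0.99), time to activate,
total time active, time per state, transcriptional output ∫z dt, population
noise CV², peak mean transcription rate and its timing, output-vs-time
regressions, and hierarchical clustering of condition profiles.

## Worked example

Generate a synthetic benchmark (slow promoter, exact SSA truth, log-normal
readout noise η = 0.05), reconstruct each cell with 400 particles, and
extract features:

```python
import burstinfer as bi

ds = bi.generate_benchmark_dataset(bi.BenchmarkConfig(kappa=1.0, n_cells=5, seed=7))
res = bi.PromoterInferenceModel(ds.cells, ds.model, ds.kinetics, ds.signal,
                                bi.SMCConfig(J=400, seed=0)).fit()
print(res.features(ds.threshold)[
    ["cell_id", "response_probability", "time_to_activate_min",
     "time_active_min", "transcriptional_output"]].round(2))
```

```
 cell_id  response_probability  time_to_activate_min  time_active_min  transcriptional_output
cell_000                   1.0                  1.23            24.47                 1075.21
cell_001                   1.0                  4.00             4.09                  188.97
cell_002                   1.0                 25.75             9.41                  420.38
cell_003                   1.0                  9.99            15.63                  690.57
cell_004                   1.0                 26.54            15.61                  689.77
```

All five cells are classified as responders; per cell the posterior says when
the promoter first reached a significantly transcribing state (e.g. cell 2 at
~26 min), how long it stayed there, and how many transcripts it produced.
The ground truth recorded by the generator for the same cells is
24.11 min active / 1059 molecules for cell 0, 8.76 / 392 for cell 2 — the
reconstructions track the truth within a few percent. Population summaries
follow the same object:

```python
res.population_summary(ds.threshold)
# percent_responders: 100, mean_time_active_min: 13.85,
# output_noise_cv2: 0.236, lambda_max: 0.555 1/s at tau_max: 32 min
```

A command-line interface mirrors the library
(`burstinfer benchmark | simulate | calibrate | infer | features | cluster |
toy-memory | toy-context`); every subcommand takes an explicit `--seed` and
stamps its outputs with the seed and a config hash.

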