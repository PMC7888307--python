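# Methods

## Model

The promoter is a continuous-time Markov chain over three states with
transcription rates z = (0, z₁, z₂) and the chain topology 0 ⇌ 1 ⇌ 2.
Activation is input-coupled, q₀₁(t) = γ·u(t); q₁₀, q₁₂, q₂₁ are constant.
The state probabilities obey dP/dt = Q(t)P with the column-convention
generator

    Q(t) = [[-γu(t),  q₁₀,        0  ],
            [ γu(t), -(q₁₀+q₁₂),  q₂₁],
            [ 0,      q₁₂,       -q₂₁]].

mRNA and protein follow a two-stage birth–death process (production z(t) and
A·M; degradation c₁M and c₂N). The translation rate A is drawn once per cell
from a positive-support population distribution parameterized by its mean and
CV — log-normal by default, chosen for consistency with the filter's
log-normal closure; a gamma family is available. All rates are per second
internally; the input interface is per minute (the import/export table is
calibrated in min⁻¹) and the conversion happens exactly once at the module
boundary.

The nuclear-TF input u(t) is deterministic: within a pulse entered at level
u_s, u(t) = u₀ − (u₀ − u_s)e^{−k₁(t−t_s)}; after a pulse, exponential export
at rate k₂. Chaining import from the residual level left by the previous
export keeps u continuous across repeated pulses. The four calibrated
amplitude rows (25/50/75/100% of maximal nuclear TF) are built in; explicit
(u₀, k₁, k₂, schedule) and least-squares fitting of a measured trace are also
supported (bounded nonlinear least squares from the deterministic start
(max(data), 1, 1); an all-zero trace returns u₀ = 0 with a degeneracy flag).

## Exact simulation

All stochastic simulation is event-exact SSA. The single time-varying
propensity, γ·u(t), is handled by thinning: u is piecewise monotone between
its breakpoints, which are subdivided at one e-folding of the import/export
rate so each sub-piece's bound (the larger endpoint value) is within a factor
e of the truth. No time-discretization error is introduced anywhere.

## Conditional moments and log-normal closure

Conditional on a promoter path, the subsystem X = (M, N, A) has linear
propensities, so its moments up to order two close exactly into a 13-ODE
linear system (the three needed third/fourth-order moments — E[M²A], E[MNA],
E[MA²], E[M²A²] — are part of the closed set; A is static, dE[A]/dt = 0).
The filter assumes X | z-path is multivariate log-normal with logarithmic
moments (μ, Σ); between measurements the raw moments implied by (μ, Σ) are
propagated through the ODE system segment-by-segment along the path and
converted back. Only first/second-order raw moments are used in the
conversion; the higher mixed moments are re-derived from the fitted
log-normal.

Numerics: per segment the system is linear time-invariant with a Metzler
(non-negative off-diagonal) generator acting on a non-negative moment vector,
so the matrix-exponential action is computed by **uniformization** — a
cancellation-free non-negative series truncated at 1e-16 relative, stepped so
q·Δ ≤ 10. This was chosen over eigendecomposition (the generator's
eigenvector matrix is ill-conditioned, cond up to ~1e15, giving 1e-3-level
errors on short segments) and over generic Padé `expm` (validated against it;
~50× faster in the filter's hot loop). Degenerate conversions are floored:
first moments at 1e-30 (a silent promoter drives E[M], E[N] to underflow),
implied log-variances at 1e-12, implied correlations clipped into the PSD
cone at |r| ≤ 0.999.

## Hybrid sequential Monte Carlo

Each of J particles carries a promoter path, logarithmic moments (μ, Σ) and
a weight. Per measurement: extend the path by promoter-only SSA, propagate
the moments, score with the closed-form marginal likelihood — y given the
predictive N-marginal is log-normal, y ~ LN(μ_N, η² + Σ_NN), with the
additive constant resolved so the density normalizes over y (log-marginal
likelihoods are therefore comparable across cells and conditions) — then
condition (μ, Σ) on y via the rank-1 (Kalman-form, algebraically equal to the
information-form) update, and resample multinomially. Resampling at every
step follows the algorithm as described; ESS-triggered resampling is
available behind a flag (default off). Defaults: J = 400; η = 0.05 for the
synthetic benchmark and 0.15 for real-data settings, both overridable.

Initialization: a log-normal cannot represent M = N = 0, so the filter starts
from pseudo-moments E[M] = E[N] = 0.1 copies with CV = 1 (configurable) and
the population prior for A; the influence washes out within the first few
updates. Observations are floored at 1 copy before taking logs. A cell whose
particles all reach non-finite weights (e.g. absurd jumps between consecutive
points) is flagged unstable and excluded from downstream summaries; the
excluded fraction is reported per condition.

A full-SSA bootstrap particle filter over (Z, M, N, A) with the same
measurement density is included as an independent reference; on a low-copy
two-state fixture the hybrid filter matches its log marginal likelihood and
posterior mean time transcribing within Monte Carlo error, and the
randomized-PIT rank of the true time transcribing under the per-cell
posteriors is uniform (KS test).

## Calibration

Because all propensities are linear, the population mean and variance of M
and N (augmented over promoter indicator × M × N × A; A independent of the
chain so E[I_i f(A)] = P_i E[f(A)]) obey a closed 36-dimensional linear ODE
system — verified against a truncated master equation to full precision. It
is integrated with BDF and its exact (time-varying) Jacobian; tolerances
inside the MCMC loop are 1e-6/1e-8, with final reports recomputed at
1e-8/1e-10.

The objective is a Gaussian pseudo-likelihood on the empirical reporter mean
and variance per time point, weighted by bootstrap SEs (cells resampled with
replacement; SE floored at 1e-6). This realization matches the reported fit
diagnostic — the error statistic mean|predicted − empirical|/SE per moment
type, where ~1 means the mismatch is comparable to the sampling uncertainty.
Priors are Gamma(shape, rate) with rate = shape/mean: c₁ ~ Γ(20, 20/1.3e-3 s⁻¹)
and ⟨A⟩ ~ Γ(20, 20/0.05 s⁻¹) (informative, centred on previously measured
kinetics), all switching and transcription rates ~ exponential with mean
30 s⁻¹; c₂ is fixed at 1.67e-5 s⁻¹. Sampling is random-scan
Metropolis–Hastings with multiplicative log-normal single-parameter proposals
(Hastings-corrected), per-parameter scale adaptation to 20–40% acceptance
during the first 25% of the chain (burn-in, discarded before MAP extraction).
Default chain length 2·10⁴; the test-suite and acceptance runs use 600–4000
iterations, which suffices for the MAP fit quality reported (error statistics
well below 1 SE on 200 cells). Two-stage protocol: fit (θ, ω) on a reference
condition, then re-fit only θ per condition with ω held fixed. Point
recovery of all parameters is *not* expected (practical identifiability: the
moments constrain combinations of rates); the contract is posterior-predictive
fit quality. Calibration and reconstruction use disjoint random halves of the
cells.

## Features

All functionals are evaluated exactly on each piecewise-constant posterior
path (segment sums, no quadrature) and averaged under the particle weights.
A state is *significant* if its rate is ≥ 20% of the reference maximum rate
(for synthetic work, max(z₁, z₂) of the generating model; for data-driven
work, the maximum over the reference long-pulse conditions). A path
qualifies as responding with ≥ 2 min cumulative significant residence;
pₐ is the posterior mass of qualifying paths and a cell is a responder if
pₐ > 0.99. *Time active* (τ_A) is residence in significant states — defined
analogously to the time to activate, which is the first entry into a
significant state (responder-conditioned; undefined when no path qualifies).
*Time transcribing* is residence in any permissive state (z > 0) and is the
regressor of the output-scaling analysis; the primary fit there is the
proportional (through-origin) model, with an ordinary two-parameter fit
reported alongside. Under the alternate reading of τ_A as permissive
residence, the slow-promoter benchmark has essentially no between-cell
variance in τ_A (activation is input-saturated), which makes recovery
regressions meaningless; the significant-state reading is therefore used
throughout. Output noise CV² uses the population (divide-by-n) variance by
default (switchable). Condition profiles are clustered hierarchically on
z-score-normalized features with Euclidean distance and average linkage
(linkage switchable); rows with zero percent responders in any pulse-length
entry are excluded first, and zero-variance features are dropped.

## Synthetic benchmark

The generator reproduces the evaluation protocol the method was validated
with: γ = 0.05, q₁₀ = 0.055, q₁₂ = 0.001κ, q₂₁ = 0.004κ, z₁ = 0.0035,
z₂ = 0.728, c₁ = 0.0013, c₂ = 1.67e-5 s⁻¹, ⟨A⟩ = 0.1, CV[A] = 0.02, with
κ = 1 ("slow") or 10 ("fast"); 30 cells over 150 min sampled at 55
equidistant points; input = one 75%-level, 40-min pulse; yₖ = nₖ·exp(η εₖ)
with η = 0.05. Ground-truth features are computed from the exact simulated
paths with the same activity threshold used at inference, so inferred and
true features are directly comparable. Per-cell parameter perturbation for
robustness studies resamples every free parameter from LN(log b, 0.1²).

What the generator does *not* emulate: reporter maturation (handled on real
data as a fixed 12.5-min trajectory shift, five frames at 2.5-min
resolution), segmentation/tracking artifacts and outlier frames,
absolute-abundance conversion error, cell-to-cell variability in u(t), and
cell-cycle effects. Passing the benchmark therefore demonstrates correctness
of the inference machinery under the model's own assumptions, not robustness
to these real-data effects (the parameter-perturbation study covers modest
model mismatch only).

## Toy models

*Interval-dependent memory.* States P0–P3 with activator (I1) and inhibitor
(I2) counters: P0 → P1 at c₁u(t), P1 → P0 at c₂; P1 → P2 at c₃I1, P2 → P1 at
c₄; P0 → P3 at c₅I2, P3 → P0 at c₆; I1 produced at c₇ while in P1; I1 → I2 at
c₈I1 while in P0. Transcription at z only in P2. Initial condition P0 with
I1 = I2 = 0; I1/I2 are unbounded counters with count-proportional
propensities. At the published rate constants the inhibitor mechanism is
clearly operative at long pulse intervals (≈half the cells are locked in P3
by the fourth pulse at 20-min intervals, and per-pulse output increments
decline after the train saturates) — but the literal sign flip "pulse-4
increment below pulse-1" does not occur, because the first pulse starts with
an empty activator pool and is intrinsically the weakest; this was verified
with two independent exact SSA implementations across input scalings (u
normalized to 1 up to raw abundance ~1100) and window conventions. The
robust signature asserted by the unit tests is the interval dependence
itself: the pulse-4/pulse-1 ratio is materially smaller at 20-min than at
5-min intervals. The acceptance test for the literal negative-memory sign is
retained and currently fails, intentionally.

*Context-dependent 4-state promoter.* Nonlinear TF-dependent switching:
c₁ = γ₁u, c₃ = γ₃(1 − Hill(u; V₃, n₃)), c₄ = γ₄Hill(u; V₄, n₄),
c₅ = γ₅Hill(u; V₅, n₅), with the generator exactly as printed for the forward
equation (c₅ takes state 1 → state 3). The expected-transition-count matrix
H(T) = ∫₀ᵀ Q(s)·diag(P(s)) ds is integrated jointly with the forward
equation; each diagonal entry equals minus its column's off-diagonal sum, and
the display variant zeroes the diagonal. The Hill constants (V₃ = 0.5,
V₅ = 1.2) imply order-one input, so the pulse input is normalized to peak 1
by default (u_scale = 1/u₀, overridable). Under sustained high input,
transitions into the enhanced state are <1% of transitions into the silenced
state — the promoter effectively reduces to a different architecture in that
context.

## Problem sizes and tolerances in the shipped checks

The test suite and the acceptance script use: the benchmark exactly as
printed (30 cells × 55 points, J = 400) for feature recovery; 10⁴-cell SSA
ensembles at a moderate-copy test model for simulation-vs-analytics checks
(checkpoints at 600/1500/2400 s — deep-tail checkpoints are avoided because
the sample-variance estimator there is carried by a handful of cells and its
normal-theory SE is invalid, as verified against a truncated master
equation); a two-state low-copy fixture (M_ss = 5, protein < 50, first
measurement once protein is clearly nonzero) for the hybrid-vs-bootstrap
equivalence and PIT calibration; 600-iteration chains for calibration fit
quality and 4000 for prior-only checks; and n = 2000 runs per memory-model
condition. Forward/moment ODE tolerances are 1e-8–1e-12; closed-form checks
assert at 1e-8, semigroup composition at 1e-9, quadrature oracles at 1e-6
(updates) and 1e-8 (marginal likelihood in log space).
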