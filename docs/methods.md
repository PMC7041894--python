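# Methods

## Model and privacy mechanism

The core object is an auxiliary-classifier GAN over flattened participant
matrices (3 variables × 12 visits = 36 features, normalized to [−1, 1]).
The generator is a dense network `latent(100) + arm-embedding(8) → 128 →
128 → 36` with ReLU hidden units and a tanh output; the discriminator is
`36 → 128 → 128 → 2` with leaky-ReLU (slope 0.2) hidden units and two linear
logits: a real-vs-synthetic source score and the auxiliary arm classifier.
Losses are binary cross-entropies: the discriminator minimizes source loss
plus arm loss on both real and fake batches, the generator minimizes the
adversarial source loss plus the arm loss on its own samples (rewarding
class-consistent fakes). Real source targets are label-smoothed to 0.9,
which keeps the discriminator from saturating early.

Differential privacy enters only through the discriminator, the sole
component that reads real records. Each step draws a Poisson lot (every
record independently with probability q = L/N), computes per-participant
gradients of the real-batch loss by explicit backprop, clips each to global
L2 norm C, sums, adds N(0, σ²C²I) noise and divides by the expected lot
size L. The fake-batch term of the discriminator loss depends only on the
generator and the current weights — both already differentially private
functions of the data — so it is added without noise as post-processing.
Both networks are updated with Adam (lr 2·10⁻⁴, β₁ = 0.5); for the
discriminator Adam consumes the already clipped-and-noised lot gradient,
which leaves the privacy analysis untouched since any per-step
post-processing of the noisy gradient is free. Nonprivate training is the
same code path with C = ∞ and σ = 0, which makes the two modes
step-for-step identical under a shared seed.

The networks and their backprop are implemented directly in NumPy
(`_nn.py`): the models are small dense stacks, and DP-SGD needs vectorized
per-example parameter gradients, which the explicit backward pass provides
via a single einsum per layer.

## Accounting

The moments accountant tracks, for integer orders λ = 1..32, the log
moments of the privacy-loss random variable of the subsampled Gaussian
mechanism. Per step,

    α_step(λ) = log max(I1, I2),
    I1 = E_{z∼μ0}[(μ0/μ)^λ],   I2 = E_{z∼μ}[(μ/μ0)^λ],

with μ0 = N(0, σ²), μ1 = N(1, σ²), μ = (1−q)μ0 + qμ1. I2 is evaluated
exactly: the ratio μ/μ0 = (1−q) + q·exp((2z−1)/2σ²) has a binomial
expansion whose Gaussian moments are closed-form, summed with log-sum-exp
(q = 0 and q = 1 handled as exact limits; at q = 1 both moments reduce to
λ(λ+1)/2σ²). I1 has no similar closed form and is integrated by adaptive
quadrature over ±40σ. Log moments add across steps; queries use the tail
bound δ(ε) = min_λ exp(α(λ) − λε), with ε(δ) recovered by bisection to
10⁻⁴. A ledger with zero steps reports δ = 0 (no data access); a
nonprivate run returns a step-counting ledger whose ε is infinite rather
than an error, so training has a uniform return type. The test suite
checks the moments against an independent quadrature oracle that evaluates
both integrals directly from the mixture densities on a log-shifted grid.

Budgets compose additively (basic composition). Checkpoint selection uses
the exponential mechanism: each of k draws (without replacement) picks a
checkpoint with probability ∝ exp(ε·u/2Δu) at (ε, 0) cost, defaults
ε = 0.05 and k = 10 for a (0.5, 0) selection total. The default utility u
is the arm-classification accuracy on the real training cohort of a
logistic model fit to the checkpoint's synthetic data; it is bounded in
[0, 1] and changing one real participant moves it by at most 1/n_train,
the sensitivity used.

The worked-example calculators use the linearized posterior bound
prior·(1+ε) — the convention that makes the customary back-of-envelope
arithmetic exact — with the exact prior·e^ε factor available by flag. The
premium bound adds the full bounded expected event cost to the stated base
premium (3000 + 30000·0.0018 = 3054), reproducing the printed convention
even though the baseline expected cost is nominally part of the base.

## Default run geometry

| parameter | default | rationale |
| --- | --- | --- |
| lot size L | 100 | q = 1/60 on a 6000-record cohort; 60 lots/epoch |
| noise multiplier σ | 7.0 | 1000 epochs then cost ε ≈ 3.0 ≤ 3.5 at δ = 10⁻⁵ |
| clip norm C | 1.0 | order of a typical per-example gradient norm here |
| epochs | 1000 | the budgeted training length |
| selection | k = 10 at ε = 0.05 | (0.5, 0), composing to a single-digit total |

Normalization ranges are fixed physiologic constants — SBP (60, 250), DBP
(30, 150), medications (0, 10) — never data-derived, so no budget is spent
estimating them. Medication counts denormalize by rounding to non-negative
integers; out-of-range inputs clamp with a warning.

## Synthetic fixtures

`simulate_trial` emulates the structure of a two-arm BP-lowering trial:
baseline SBP ~ N(140, 15²) truncated to [90, 200]; per visit the trajectory
mean-reverts toward the arm's treatment target (intensive 120, standard
135 mmHg) at rate κ = 0.35 with 6 mmHg innovation noise; DBP is
0.45·SBP + 15 + N(0, 5²); baseline medications ~ Poisson(1.8) truncated at
6; and whenever observed SBP exceeds the arm goal (120/140 mmHg) a
medication is added with probability p_add_med = 0.30, capped at 10. The
targets sit slightly below the goals so above-goal titration events keep
occurring throughout follow-up at a controllable rate, letting the
medication-addition statistic recover p_add_med. The AR(1)-style dynamics
produce cross-visit correlations that decay with lag, the qualitative
signature of real trial data. Numeric defaults are fixture constants chosen
to be physiologically plausible; they are not estimates of any real trial,
and the fixture makes no attempt to match real marginal distributions or
event rates beyond order of magnitude. Passing tests on these fixtures
demonstrate that the machinery is correct and that the pipeline preserves
their statistical structure — not that any particular utility level would
be attained on real trial data, which is noisier, skewed, and not
Markovian. `simulate_ehr` likewise emulates a 9-vital critical-care table
(≥5 timepoints for 90% of patients, case vitals shifted by a configurable
effect size, heart-failure ICD-9 codes attached to cases).

## Numerical and design choices

- **Poisson lots, not fixed-size shuffling**: the accountant's
  amplification assumption then holds exactly; noise is added to the lot
  *sum* and divided by the expected size L (both conventions appear in the
  literature; this is the one the analysis assumes).
- **ICD-9 matching is exact string match** after whitespace stripping; the
  bundled heart-failure list already enumerates decimal children, so prefix
  semantics are deliberately not applied (avoids silent over-matching).
- **Medication-addition rate** counts visit *transitions*: denominator =
  transitions with SBP above goal, numerator = those where the count
  increased; pooled and per-arm rates are both reported, and an empty
  denominator yields an absent value, never 0.
- **Correlation-structure similarity** is Spearman on the strictly lower
  triangles (diagonal excluded) of the two Pearson matrices, in
  variable-major column order.
- **Classifier settings** are scikit-learn defaults with a fixed seed
  (logistic regression with max_iter 1000, linear-kernel SVM, random
  forest, k-nearest neighbors); linear models contribute coefficient
  vectors and the forest its importances to the concordance analysis.
- **Train/test splitting** is a seeded uniform shuffle; enrollment-order
  splits can be had by slicing the cohort directly.
- **Checkpoint cadence**: every 10th epoch, densifying to every epoch over
  the final 100, bounding memory while giving selection a fine grid where
  late-training models live.
- **Degenerate inputs**: zero-variance columns get correlation 0 with a
  warning; empty arms are omitted from summaries with a warning; an empty
  Poisson lot contributes a pure-noise gradient (the mechanism still ran).

## Scale of the bundled checks

The test suite exercises training at fixture scale — 2000 participants,
200 epochs for the TSTR and discriminator-convergence checks; 600
participants, 60 epochs across 5 seeds for the nonprivate-vs-private
utility trend — sizes at which the NumPy implementation trains in about a
minute per run while leaving the measured behaviors (TSTR within 10% of
real-trained AUROC, discriminator near chance, private utility below
nonprivate on average) clearly resolved.

## Limitations

- Continuous-valued outputs only; medication counts are rounded post hoc
  rather than modeled discretely. Mixed-type EHR data would need
  discrete-data GAN variants.
- The accountant covers the subsampled Gaussian mechanism with integer
  moment orders and basic composition; no Rényi-DP conversions or optimal
  composition.
- Reproducibility is bit-exact for a fixed seed on fixed hardware and
  thread settings; BLAS-level nondeterminism across platforms can move
  float results slightly.
- The exponential-mechanism utility scorer touches real data through a
  single bounded score per checkpoint; richer scorers must re-derive their
  sensitivity.
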