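# dptrialsynth

Sharing individual-level clinical-trial data usually requires data-use
agreements that slow or block secondary analysis. `dptrialsynth` implements a
technical alternative: train a generative model on the real cohort **under
differential privacy**, then release synthetic participants (or the generator
itself) instead of the data. Post-processing invariance means unlimited
synthetic records can be generated at no additional privacy cost.

The package is aimed at biostatisticians and methodologists working with
longitudinal trial data — the built-in data model is a two-arm blood-pressure
trial (systolic BP, diastolic BP and medication count at 12 visits, arms with
<120 vs <140 mmHg systolic targets) plus a critical-care vitals table with a
heart-failure label.

## Method

- **AC-GAN** (`acgan`): a generator G(z, arm) produces normalized participant
  matrices; the discriminator jointly scores real-vs-synthetic and predicts
  the treatment arm (the auxiliary head), so samples can be generated
  conditioned on arm.
- **DP-SGD** (`dp_sgd`): the discriminator — the only component that touches
  real data — is trained on Poisson-sampled lots (rate q = L/N) with each
  participant's gradient clipped to L2 norm C and Gaussian noise σC added to
  the lot sum.
- **Moments accountant** (`accountant`): tracks the log moments
  α(λ) = T·α_step(λ) of the privacy loss for the subsampled Gaussian
  mechanism and answers δ(ε) = min_λ exp(α(λ) − λε) and its inverse. With the
  default geometry (q = 1/60, σ = 7, 60 lots/epoch), 1000 epochs of training
  cost ε ≈ 3.0 at δ = 10⁻⁵.
- **Private model selection** (`selection`): k generator checkpoints are
  chosen across epochs by the exponential mechanism at (0.05, 0) each —
  (0.5, 0) total for k = 10 — and synthetic data is pooled across them.
  Budgets compose additively: training (ε, 10⁻⁵) plus selection (0.5, 0).
- **Evaluation** (`evaluation`): pairwise Pearson correlation structure and
  its Spearman similarity across cohorts, per-arm summary tables, the rate of
  medication additions when above the arm's BP goal, train-on-synthetic /
  test-on-real (TSTR) AUROC for four classifier families, and concordance of
  fitted coefficients.

Restricted real datasets are replaced by `fixtures`: a mechanistic two-arm
trial simulator (mean-reverting SBP trajectories, above-goal medication
titration, time-decaying cross-visit correlation) and a long-format EHR
vitals generator.

## Worked example

```bash
dptrialsynth run --config cfg.yaml --out rundir/
```

with `cfg.yaml`:

```yaml
seed: 7
simulate: {n: 300}
n_train: 260
train: {epochs: 8, lot_size: 50, private: true, sigma: 4.0}
select: {k: 3}
n_synthetic: 200
```

prints

```json
{
  "manifest": "rundir/manifest.json",
  "budget": {
    "training": {"epsilon": 1.79888916015625, "delta": 1e-05},
    "selection": {"epsilon": 0.15000000000000002, "delta": 0.0},
    "total": {"epsilon": 1.94888916015625, "delta": 1e-05}
  }
}
```

The training ε is the accountant's bound at δ = 10⁻⁵ after 8 epochs × 6 lots
of noisy discriminator steps; the selection cost is 3 exponential-mechanism
draws at ε = 0.05 each; the total is their basic composition — the overall
privacy guarantee attached to `rundir/synthetic.csv`. `rundir/report.json`
holds the full evaluation suite (correlation-structure Spearman ρ, summary
tables, medication-addition rates, TSTR AUROCs and coefficient concordance).

Individual stages are available as `dptrialsynth
simulate|train|account|select|generate|evaluate`; for example

```bash
dptrialsynth account --q 0.0167 --sigma 7 --epochs 1000 --lots-per-epoch 60
# epsilon at delta=1e-05 after 1000 epochs: 2.9954
```

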