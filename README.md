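# cfskit

Tools for studying **continuous flash suppression (CFS) of moving
stimuli**: dynamic mask synthesis, a quantitative simulation of
retinotopically specific neural adaptation, adaptive staircase
psychophysics with simulated observers, and hierarchical Bayesian
analysis of contrast thresholds.

CFS suppresses a stimulus shown to one eye by flashing a Mondrian
pattern in the other eye, canonically at 10 Hz. Its effectiveness is
often attributed to the mask's continual updates preventing
retinotopically specific neural adaptation — yet for *moving* targets, a
**moving Mondrian mask** (MMM), whose elements translate smoothly and
should therefore adapt retinotopic detectors *more*, can suppress more
effectively, peaking when mask speed matches target speed. This package
implements everything needed to study that dissociation quantitatively
with synthetic observers.

## What's inside

| module | contents |
| --- | --- |
| `cfskit.stimulus` | seeded MMM / regular-CFS / moving-target frame sequences (150 squares of 0.46° in a 7.32° field, six motion directions, 10 Hz refresh, 20-frame fade-in) |
| `cfskit.adaptation` | odd-symmetric Gabor bank (0°/90°), five-way response classification (2 orientations × 2 polarities + none), per-pixel exponential adaptation (τ_decay = 4 s, τ_recover = 6 s), per-condition summaries and ranking |
| `cfskit.psychophysics` | accelerated one-up two-down staircases (converging at 70.71 % correct), Weibull simulated observers, last-20-trials thresholds, per-participant normalization, within-subject CIs |
| `cfskit.bayes` | hierarchical robust-t repeated-measures models (one- and two-way) fitted by a built-in Gibbs/slice sampler, HDI contrasts, posterior predictive checks, default-prior (JZS) ANOVA Bayes factors |
| `cfskit.synthdata` | ground-truthed threshold datasets and observer banks with a speed-tuned suppression profile |
| `cfskit.pipeline` / CLI | end-to-end experiment runs with YAML config round-trip; `cfskit stimgen / simulate-adaptation / run-exp1 / run-exp2 / fit / recover` |

### The models in brief

**Adaptation.** Each grayscale frame is convolved with two odd-symmetric
Gabors; each pixel is labelled H±, V± or *none*. Per pixel and category,
an activation a starts at 1 and follows
a ← a·exp(−Δt/τ_d) while its feature repeats (τ_d = 4 s) and
a ← 1 − (1 − a)·exp(−Δt/τ_r) otherwise (τ_r = 6 s). The trial summary is
the time-averaged activation of the *currently driven* categories — the
mask's adapted stimulus strength; higher = less adaptation.

**Thresholds.** p(correct) = γ + (1 − γ − λ)(1 − exp(−(c/α)^β)) with
γ = 0.5; the one-up two-down staircase converges where p² = ½, i.e.
70.71 % correct. Thresholds are the mean of a staircase's last 20
trials, averaged over staircases and divided by each participant's mean.

**Inference.** Normalized thresholds y_ij follow
y ~ t_ν(β₀ + α_j + s_i, σ) with zero-centred hierarchical priors on the
deflection groups, a uniform prior on ν (robustness to outliers), and —
for the two-target design — target-speed and interaction deflections.
Condition differences are judged by 95 % highest-density intervals of
posterior contrasts (no multiplicity correction needed); model selection
uses default scaled-g prior Bayes factors.

## Worked example

`python examples/04_bayes.py` generates a 20-participant synthetic
dataset with a tuning effect peaked at the 3 °/s matched mask speed,
fits the hierarchical model and prints:

```
dataset: 20 participants x 6 mask conditions (normalized thresholds)
  mmm-1  truth -0.079  posterior -0.043 +- 0.022
  mmm-2  truth +0.104  posterior +0.078 +- 0.022
  mmm-3  truth +0.174  posterior +0.183 +- 0.025
  mmm-5  truth +0.072  posterior +0.055 +- 0.028
  mmm-8  truth -0.058  posterior -0.068 +- 0.022
  cfs    truth -0.212  posterior -0.205 +- 0.028
posterior df nu: 2.3 (small = heavy-tailed residuals)
matched (3 deg/s) vs rest: 95% HDI [+0.161, +0.275] -> credible difference
posterior predictive: 2000 replicate datasets, 95.8% of observations inside 95% intervals
BF(mask-speed effect vs null) = 1394.2 (values > 1 favour the effect model)
```

Each line compares a generative condition deflection (how far that mask
condition's expected normalized threshold sits from 1) with its
posterior estimate; the matched-vs-rest contrast excluding zero and the
large Bayes factor both flag the speed-tuned suppression peak the data
were built with. The other scripts in `examples/` walk through stimulus
construction, the adaptation simulation, and staircase threshold
measurement the same way.

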