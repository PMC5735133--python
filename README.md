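# priorclarity

Tools for studying how listeners combine **prior expectations** with
**degraded sensory input** during speech perception, built around a
hierarchical Bayesian ideal-observer model of subjective clarity ratings
for noise-vocoded words. The package is aimed at psychophysicists and
cognitive neuroscientists who want to (a) generate the matched/mismatched
written-cue paradigms used in this literature, (b) fit and compare the
clarity model on per-subject behavioural data, and (c) compute the
oscillatory and connectivity statistics (beta-band congruency-contrast
latency, imaginary coherence, spectral Granger causality) used to link
the model's parameters to neural dynamics — all validated end-to-end on
synthetic cohorts with known ground truth.

## The model

A written cue sets up a prior over upcoming speech content; a vocoded
word provides degraded sensory evidence. Per subject:

- **Sensory precision** at each vocoder-channel level *c* is fixed from
  4AFC identification accuracy: `s_c = max(0, (acc_c − ¼) / ¾)`.
- **Posterior precision** combines it with the prior:
  `P = s_c · (1 + w / σ²)`, where `σ` is the prior's standard deviation
  and the congruency weighting is `w = 0.5` for a matching cue (cues are
  valid on half the trials) and `w = 0` for mismatching or uninformative
  cues — so a mismatching cue leaves the percept purely sensory.
- **Clarity**: posterior precision at or below a perceptual threshold
  `θ` is rated 1 ("completely unclear"); above it, the height is mapped
  linearly onto the rest of the 1–4 scale, anchored so the subject's
  clearest condition rates 4.

The two free parameters `(σ, θ)` are fitted per subject by global least
squares against the six condition-mean ratings (2 congruency × 3 channel
levels). A three-parameter variant additionally frees the matching-cue
weighting for 16-channel speech (psychometric saturation); variants are
compared with the small-sample-corrected Akaike information criterion,

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1).

More precise priors (smaller `σ`) predict a larger match−mismatch
clarity benefit — the signature of *inflexibly precise* predictions.

## Worked example

```python
import numpy as np
from priorclarity import design, model, simulate

# a subject with fairly precise priors (sigma = 0.4)
truth = simulate.TruePerceptualParameters(sigma_prior=0.4, threshold=0.08,
                                          rating_noise_sd=0.3)
exp1 = design.build_exp1_schedule(simulate.default_word_pool(400), "A", seed=7)
exp2 = design.build_exp2_schedule(design.default_response_sets(), seed=7)
ds = simulate.simulate_subject_behaviour(truth, exp1, exp2, seed=7)

fit = model.fit_subject(ds.condition_means(), ds.sensory_precision_measured,
                        variant="simple", seed=0)
print(f"sigma = {fit.parameters.sigma_prior:.3f}  theta = {fit.parameters.threshold:.3f}")
print(f"RSS = {fit.rss:.4f}  AICc = {fit.aicc:.2f}  "
      f"variance explained = {fit.variance_explained_pct:.1f}%")
```

prints

```
sigma = 0.492  theta = 0.377
RSS = 0.4292  AICc = -7.83  variance explained = 93.0%
```

i.e. from 648 noisy single-trial ratings and the 90-trial identification
block alone, the fit recovers the generating prior SD (0.4) well, and
the two-parameter model captures most of the condition-mean variance.
(The threshold is less tightly identified from a single subject because
its effect trades off against the sensory-precision estimates, which
here come from only 30 identification trials per channel level; across a
cohort the recovery of the prior SD is what carries the group analyses.)

The full study graph (design → simulate → fit → stats → neural → report)
runs from one seeded config:

```bash
priorclarity run --out-dir runs/demo
priorclarity report runs/demo
```

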