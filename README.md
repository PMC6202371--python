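# periprior

Bayesian coupling-prior analysis of visuo-proprioceptive integration in
peripersonal space, built around a virtual-reality reaching paradigm: people
reach toward a visual target, a proprioceptive target (their own unseen
finger), or both presented at a lateral disparity, with the reaching hand
either visually rendered or invisible. The package implements the full
observer model and analysis chain — likelihood/prior/posterior construction,
MAP decoding, the two-stage bounded multi-start model fit, the forced-fusion
(MLE) contrast — plus a trial-level synthetic cohort generator, so every
stage can be exercised and tested without access to raw human data.

It is written for computational-psychophysics researchers who want a tested,
reproducible implementation of the coupling-prior framework and of parameter
recovery under its own generative assumptions.

## The model

Targets sit at azimuths m_v (visual) and m_p (proprioceptive), in mm. The
likelihood over joint perceived locations (v, p) is a separable bivariate
Gaussian centred on the targets, with dispersions σ_v, σ_p fixed per
participant and hand-visibility condition at the SDs of their unisensory
reaches:

    l(v, p) ∝ exp( −(v − m_v)² / 2σ_v² − (p − m_p)² / 2σ_p² )

The prior mixes a Gaussian ridge along the identity line v = p with a
uniform over a bounded workspace of area A:

    P(v, p) = λ · δ(v, p) + (1 − λ) / A,
    δ(v, p) = (2πσ_c²)^(−1/2) · exp( −(v − p)² / 2σ_c² )

λ is the coupling strength (integration vs segregation); σ_c is the coupling
dispersion — the spatial range over which visual and proprioceptive signals
are expected to co-occur, read here as an index of peripersonal space. The
posterior is r(v, p) = P(v, p) · l(v, p) and the reach endpoints are its
argmax (MAP decoding): v̂ is the predicted visual reach, p̂ the predicted
proprioceptive reach. Setting λ = 1 and σ_c² = 10⁻⁴ mm² forces fusion, and
the MAP collapses onto the reliability-weighted average
(m_v/σ_v² + m_p/σ_p²)/(1/σ_v² + 1/σ_p²) — the classical MLE cue-combination
model, used as the comparison model.

Free parameters (λ, σ_c) are fitted per participant × condition by
minimizing the squared distance between mean reach endpoints and the MAP at
all nine signed disparities (0, ±25, ±50, ±100, ±200 mm) for both reach
modalities, with a two-stage multi-start bounded local descent (500 starts
with a lax stopping tolerance, then the 50 best re-descended with a
stringent one); λ is bounded to [0.01, 0.99] and σ_c to
[min(σ_v, σ_p), 2·max(σ_v, σ_p)].

## Worked example

```python
from periprior import (SensoryNoise, CouplingPriorParams, StimulusPair,
                       map_estimate, predict_mean_estimates)

noise = SensoryNoise(sigma_v=6.8, sigma_p=22.9)       # hand visible
prior = CouplingPriorParams(lam=0.44, sigma_c=16.5)

est = map_estimate(StimulusPair(m_v=0.0, m_p=25.0), noise, prior)
print(round(est.v_hat, 2), round(est.p_hat, 2))
# 1.37 9.45

print(predict_mean_estimates([25, 100, 200], noise, prior).round(2))
#    disparity_mm  v_hat_mm  p_hat_mm  visual_bias_pct  proprio_bias_pct
# 0          25.0      1.37      9.45             5.49             62.21
# 1         100.0      5.48     37.81             5.48             62.19
# 2         200.0      0.00    200.00             0.00              0.00
```

At 25 mm disparity the proprioceptive reach is pulled 62% of the way toward
the visual target (the visual reach only 5% toward the finger, vision being
the more reliable cue); at 200 mm the ridge component loses to the uniform
one, the cues are segregated, and the pull vanishes — the distance-dependent
signature the model exists to capture.

The numbered drivers under `analysis/` run the full study emulation:

```bash
python analysis/01_simulate_cohort.py        # 20 participants, seed 1
python analysis/02_descriptives.py           # accuracy/precision, bias curves
python analysis/03_fit_models.py             # coupling-prior + MLE fits
python analysis/04_parameter_recovery.py     # generating vs fitted parameters
python analysis/05_figures.py                # report figures
```

On the seed-1 cohort, `04_parameter_recovery.py` prints:

```
condition-level recovery (cohort mean of per-participant fits):
  invisible sigma_c  35.9 ->  35.4 mm   lambda 0.34 -> 0.39
  visible   sigma_c  16.5 ->  21.9 mm   lambda 0.44 -> 0.15
  invisible sigma_c > visible sigma_c: True
  folded proprioceptive bias%, invisible: |d|=25 (25.4) > |d|=200 (9.1): True
```

The qualitative core results reproduce (σ_c relaxes when the hand is
invisible; the proprioceptive pull is distance-dependent). The visible-
condition σ_c and both λ means recover imperfectly — a real identifiability
property of fitting mean-level MAP predictions to trial-level data, analysed
in `docs/methods.md`.

A `periprior` command-line tool exposes the same steps
(`simulate`, `analyze`, `fit`, `recover`, `report`); see `periprior --help`.

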