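# Methods

## Observer model

All computation happens on a single azimuthal axis (mm, positive rightward);
the depth dimension never carries disparity and is not modelled. The
likelihood for a bimodal presentation at targets (m_v, m_p) is a separable
bivariate Gaussian over joint perceived locations (v, p) with dispersions
(σ_v, σ_p). We use the proper bivariate normalization 1/(2π σ_v σ_p); the
MAP location is invariant to any positive rescaling, and the proper constant
keeps the log-density usable elsewhere.

The coupling prior is the mixture λ·δ(v, p) + (1 − λ)/A with
δ(v, p) = N(v − p; 0, σ_c²). Taken literally this object is improper on the
unbounded plane: the ridge is normalized only across the identity line, and
the uniform component needs a bounded support. We therefore treat both terms
as unnormalized scores over a bounded workspace and fix the uniform area at
A = (600 mm)² = 360 000 mm² (configurable). A never appears in the data and
cannot be estimated separately: the MAP depends on (λ, A) only through the
ratio of the two component heights, so A must be fixed and reported for
reproducibility. All analyses in this package use the default above.

MAP decoding exploits the mixture structure instead of a dense scan. The
posterior is the sum of two Gaussian-type components whose stationary points
have closed forms: the uniform × likelihood component peaks at (m_v, m_p),
and the ridge × likelihood component at the solution of a 2×2 linear system
that tends to the reliability-weighted cue average as σ_c → 0. A damped
Newton ascent on the log posterior (numba-compiled, vectorized over
presentations) is started from both component modes and their midpoint, and
the best converged peak is kept. Two peaks within 1e-12 in log score are a
tie, broken toward the point nearer the identity line — a deterministic,
documented rule. The public `map_estimate` also offers a dense
coarse-grid scan (default 0.5 mm over ±300 mm) followed by the same local
refinement; the tests show the two paths agree with an exhaustive 0.1 mm
grid argmax to within the grid resolution on random instances. The
candidate-ascent path is the default because a dense 2-D scan per MAP call
(~10 ms) would make the multi-start fit intractable, while the ascent is
~100× faster at equal accuracy.

Forced fusion (the MLE comparison model) is the λ = 1, σ_c² = 10⁻⁴ mm²
corner of the same machinery; we read the 10⁻⁴ figure as mm² (σ_c = 0.01 mm),
the only reading under which the estimate collapses onto the
reliability-weighted average.

## Parameters

| parameter | meaning | units | default / bounds |
|---|---|---|---|
| σ_v, σ_p | unisensory localization SDs, fix the likelihood | mm | measured per participant × condition |
| λ | coupling strength (ridge weight) | — | fitted, bounds [0.01, 0.99] |
| σ_c | coupling dispersion across v = p | mm | fitted, bounds [min(σ_v, σ_p), 2·max(σ_v, σ_p)] |
| A | area of the uniform prior component | mm² | 360 000, fixed |
| grid | evaluation window for MAP validation | mm | [−300, 300], step 0.5 |

## Fitting procedure

One fit concerns one participant × hand-visibility condition. The cost is
the sum over all nine signed disparities and both reach modalities of the
squared difference between the mean reach endpoint (target-relative) and the
corresponding MAP coordinate. Whether the zero-disparity cell and the
visual-reach means enter the cost are config switches, both on by default:
both biases are modelled, and the zero-disparity cell anchors accuracy.

Stage 1 launches 500 local descents (50 in desk-scale runs; the number is a
config field) from uniform random points in the bound box, each stopped once
the between-iteration decrease in the sum of squares falls below 100 mm²;
stage 2 re-descends the 50 best endpoints with tolerance 10⁻⁴ mm² and keeps
the overall best, with ties resolved toward the earlier candidate. Start
points are drawn from a generator seeded by (master seed, participant id,
condition), making every fit bit-reproducible.

The local method is a projected Levenberg–Marquardt descent on the residual
vector with forward-difference Jacobians (steps 10⁻⁶ of each parameter's
box width). Only the multi-start structure, the bounds and the stopping
tolerances are contractual; LM is the natural local scheme for a
sum-of-squares cost, and its near-quadratic convergence on small-residual
problems matters here: the cost surface is extremely anisotropic (see
Identifiability), and a line-search quasi-Newton method stopped by the same
absolute-decrease rule leaves λ 2–7% short on noiseless round trips, while
LM's final accepted iterate sits at the numerical floor.

R² is computed per modality on signed bias (% of disparity) over the eight
nonzero signed disparities, 1 − SS_res/SS_tot, with the group summary as
mean ± SEM over participants; zero-variance observations yield a missing
value rather than an exception.

## Synthetic cohort

The generator emulates the study design exactly where it matters to the
analysis: 20 participants; 48 unisensory visual and 48 unisensory
proprioceptive reaches (split evenly across hand visibility); 216
multisensory presentations in blocks of 18 with hand visibility alternating
every 9-presentation mini-block, each mini-block showing the nine signed
disparities once in random order (12 presentations per signed disparity per
visibility); targets uniform over ±150 mm azimuth. Each presentation yields
two reach rows — the visual reach first, then the proprioceptive reach —
sharing a trial index, as in the task.

Condition-level generative defaults are the group values of the study:
visible σ_v = 6.8, σ_p = 22.9, λ = 0.44, σ_c = 16.5; invisible σ_v = 12.5,
σ_p = 19.8, λ = 0.34, σ_c = 35.9 (mm). Between-participant SDs are
√20 × the printed SEMs. Which proprioceptive SD belongs to which condition
is ambiguous in the source; the default follows the sentence order of the
visual contrast and a config switch (`proprio_sd_swapped`) exposes the
alternative. Participant parameters are drawn from truncated Gaussians
(dispersions ≥ 1 mm so every simulated observer is well-posed; λ in [0, 1]).
Motor noise defaults to 0 mm and is assumed absorbed into the sensory SDs;
it is a config field.

Unisensory responses are target + N(0, σ_modality). Multisensory responses
are generated trialwise by sample-then-decode: draw x_v ~ N(m_v, σ_v),
x_p ~ N(m_p, σ_p), centre the likelihood on the samples, decode the MAP
with the participant's (λ, σ_c), and reach to (v̂, p̂). This is the natural
trial-level reading of a model whose fitting target is the mean response,
and it is deliberately not the same computation as the mean-level MAP used
in fitting — the difference has consequences, analysed below.

What the generator does not emulate: reach trajectories and reaction times,
hand-tracking jitter and rendering latency, ownership build-up across
mini-blocks, any depth-dimension structure, and any deviation of real
observers from the coupling-prior observer itself. Passing recovery tests
therefore certify the pipeline's internal consistency under the model's own
assumptions, not the model's truth for human data.

## Identifiability (what recovery can and cannot show)

Two structural properties of the mean-level MAP cost dominate parameter
recovery, and both are properties of the method, not implementation
artifacts.

**λ is only interval-identified by mean data.** The fused MAP location is,
to ~0.1 mm, the ridge-component mode, which does not involve λ; the
segregated MAP is the targets themselves. λ moves predictions almost solely
through which disparities integrate — a step change at a crossover disparity
d* with d*² = 2(σ_v² + σ_p² + σ_c²) · ln[ λA / ((1 − λ)√(2πσ_c²)) ].
Every λ that leaves the integrate/segregate classification of the four
disparity magnitudes unchanged yields predictions identical to ~0.1 mm
(an SSE tilt of order 10⁻⁹ mm²). With noiseless model-generated means the
interval collapses to a point and the two-stage fit recovers λ to well
under 1% (the identifiability tests); with noisy or trial-level data the
interval is wide (often [0.01, ~0.9]) and the fitted λ lands on a
data-dependent interval endpoint — per-participant λ̂ distributions are
bimodal at the bounds, and cohort means of λ̂ carry little information about
the generating λ.

**Sample-then-decode smooths the crossover that the mean-level fit cannot.**
Trialwise, the integrate/segregate decision is taken at the sampled
disparity d + (ε_p − ε_v), so the mean bias declines smoothly over a band of
width ≈ √(σ_v² + σ_p²) around d*, and segregated-tail trials carry large
opposite-sign bias. At the hand-visible defaults d* ≈ 139 mm sits 1.6
sampling-SDs from the 100 mm design point: the simulated mean bias at
100 mm falls well below the fused plateau, and the step-shaped mean-level
model can only respond by inflating σ_c (lowering its plateau) and/or
sliding the crossover. Condition-level recovery of the visible σ_c is
therefore biased upward by roughly +12% in homogeneous cohorts, more with
the full between-participant spread (convexity of the recovery map plus
clipping at the per-participant σ_c bounds). The invisible condition, whose
crossover sits far from the sampled disparities, recovers σ_c within a few
percent, and the invisible > visible ordering of σ_c — the scientific core
contrast — reproduces robustly, as does the distance-dependence of the
folded proprioceptive bias. The recovery driver and the acceptance script
report all of these quantities as computed; the known biases are left
visible rather than recalibrated away.

## Descriptive conventions

Accuracy is |mean signed error| per participant × condition (absolute value
of the mean, not mean of absolute values); precision is the SD of signed
errors with the n−1 denominator. Signed bias is positive toward the other
modality's target; bias% divides by the signed disparity and is missing at
d = 0 (the signed error in mm is still reported there). Direction folding
takes the absolute value of each subject's per-direction mean before
averaging the two directions — never of single trials, which would be
upward-biased under noise. Group bias summaries average cell means
unweighted by trial counts. The repeated-measures ANOVA suite of the
original analysis is out of scope; the pipeline emits descriptive tables and
the paired visible-vs-invisible contrast of the fitted parameters (t = 0 is
reported exactly when all paired differences vanish).

## Problem sizes and runtimes

Desk-scale runs (analysis drivers, acceptance script) use 50 stage-1 starts
with all survivors carried to stage 2; the noiseless identifiability tests
use the full 500-start configuration, which the LM scheme keeps at a few
seconds per fit. A full 20-participant simulate→fit round trip takes about
half a minute on one CPU. Seeds: every stochastic step (parameter draws,
trial noise, start points) derives from a single master seed through named
SeedSequence spawns, so tables, fits and figures are bit-reproducible.

## Known limitations

- λ estimates from mean-level data are interval-valued in practice (above);
  treat fitted λ as a classification of which disparities integrate, not as
  a precise weight.
- σ_c recovery is biased upward where the crossover approaches a sampled
  disparity; comparisons of σ_c across conditions are more trustworthy than
  its absolute value.
- R² on signed bias% is noise-dominated when the true bias profile is flat
  relative to cell noise (12 trials/cell), and can legitimately go negative
  for invisible-condition fits of simulated observers.
- The trial-table schema is closed; depth coordinates and rng stream ids are
  not serialized.
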