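# Methods

This note records the models implemented in `obslearn`, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not emulate.

## Behavioral statistics

Trials are binned into non-overlapping 100-trial bins (1-based: bin k
covers trials (k−1)·100+1 … k·100). Per bin, dPesc = P_T − P_F and a
z-test of independent proportions with pooled variance decide
significance at two-sided p < 0.01, with p-value 2(1 − Φ(Z)) and the
corrected numerator clipped at zero so Z ≥ 0.

**Continuity correction.** Two variants are implemented behind
`correction=`:

* `"printed"` (default): c = (n_T − n_F)/(2·n_T·n_F). This term
  vanishes for balanced bins, so for n_T = n_F the test is the plain
  uncorrected pooled z-test.
* `"yates"`: the textbook term c = ((1/n_T) + (1/n_F))/2.

Exact enumeration of the null (both classes Binomial(50, p₀)) shows the
practical consequence: at nominal two-sided 0.01 the `"yates"` variant
has true type-I error between 0.0024 and 0.0066 for p₀ ∈ [0.1, 0.7] —
the Yates correction is conservative at these counts — while the
`"printed"`/uncorrected variant sits at 0.0095–0.0120, close to nominal.
The calibration test in the acceptance suite documents this: the
Yates-flag fraction falls below the nominal Monte-Carlo band, which is a
property of the correction itself, not of the implementation.

**Criteria.** The fine criterion slides a window of 8 full bins and
stops at the first window with ≥ 7 significant bins (operationally the
7/8 rule; the equivalent fraction threshold is 0.875). The criterion bin
is the window's last bin; trials-to-criterion = 100 × its index, so the
lower bound is 800. Trailing partial bins are excluded. Robustness
variants (4/4 bins, 200-trial bins) are plain parameter changes of
`criterion_scan`/`GoNogoDiscrimination`. The coarse criterion treats a
whole day as one bin and fires on the second of two consecutive days
with significantly *positive* dPesc (one-sided direction enforced via
the dPesc sign, consistent with its phase-switching use).

**Group comparisons** use the Wilcoxon rank-sum (Mann–Whitney) test,
exact when the pooled sample has no ties, normal-approximate and flagged
`exact=False` otherwise. **Call rates** are per-class probabilities of
at least one call in the stimulus vs delay period; the per-class
difference is tested with a two-sided paired sign-rank over per-trial
flag differences (zeros dropped; all-zero differences give p = 1).

## The logistic neuron

State: weights W (init 0), running feature mean m and variance v, the
penalty λ, the reward average r̄ (init 0), all per the equations in the
README. Fixed within-trial order: standardize the six renditions with
(m_{t−1}, v_{t−1}) → decide by majority vote (escape iff Σf > 3,
strict) → determine the cue u → gradient update (f evaluated at
pre-update W) → if regularized and the decision was correct, L1 shrink →
λ update using r̄_{t−1}, then r̄ update → running-stat update. The
decision therefore depends only on pre-trial state, and in observer mode
(`regularized=False`) λ and r̄ never change (λ is pinned at 0).

Open choices and how they were resolved:

* **Variance update.** The running-variance rule is implemented in two
  readings: `"sq-mean-dev"` (default) squares the rendition-averaged
  deviation, v_t = (1−ε)v_{t−1} + ε⟨X_i − m_t⟩²; `"mean-sq-dev"`
  averages the squared deviations. The default makes v track the
  variance of the within-trial mean: for channels whose six rendition
  values vary independently (frozen noise, the rendition-specific part
  of the acoustic features) v settles near 1/6 of the per-rendition
  variance, amplifying their z-scores by ≈ √6. This amplification is
  load-bearing: it lets the high-dimensional rendition-specific channels
  outpace the single duration channel early in learning, which is what
  produces fast training-set mastery with slow generalization in the
  unregularized neuron. With the plain-variance reading the qualitative
  picture survives but is weaker.
* **Initialization of m, v.** Default is a cold start m = 0, v = 1 (no
  prior knowledge of the feature distribution). Because raw durations
  are large (tens to hundreds of ms), the duration z-score is an
  almost class-independent offset until the running mean converges
  (time constant 1/ε = 100 trials); the rendition-specific channels are
  informative immediately. This ordering — memorize first, extract
  duration later — drives the observer/experimenter contrast. A
  warm start from a silent pass over the training set
  (`init_stats="warm"`) is available and makes duration discriminative
  from trial 1, largely erasing the overfitting phase.
* **Bias channel.** Feature 22 is constant 1; it is exempt from the
  z-transform (a constant has zero variance) and from running-stat
  updates, and its standardized value is defined as 1. The bias weight
  *is* shrunk by L1 (no exemption is stated for it); `shrink_bias=False`
  excludes it.
* **Variance floor** 1e−8 before any division (frozen-noise channels
  have zero within-trial spread in degenerate configurations).
* **"Successful trial"** for shrinkage = correct decision, identical to
  the r = +1 condition.
* **Noisy-action cue.** Hypothesis that the learning cue is read off a
  demonstrator's actions: u is inverted on a pre-drawn random 30% subset
  of trials (exact count, drawn once per run from the run seed).

A useful identity: because r̄ is the exponential average of r, the λ
update telescopes to λ_t = max-clipped λ₀ + (α/(1−γ))·(r̄_t − r̄₀). The
final penalty is therefore a direct readout of the equilibrium success
EMA, λ∞ ≈ 0.0005 + 0.025·(2·s∞ − 1), and the ensemble variability of the
final λ is the variability of terminal success rates.

## Synthetic stimulus sets

Ten stimuli × six renditions. Stimulus-level mean durations are linearly
spaced over 80–260 ms (short zebra-finch-syllable range); rendition
jitter is Gaussian with sd 1% of the 20 ms inter-stimulus step, clipped
at 0.45 step so the monotone grading (every rendition of S_i longer than
every rendition of S_{i−1}) holds with certainty. The short class is
S_1–S_5; the default contingency punishes the long class
(counterbalancing is a flag). The 20 generic acoustic features are unit
Gaussians plus a per-feature class-mean offset drawn once per set with
sd 0.05 — small enough that a feature's incidental informativeness is
dominated by 60-rendition sampling noise, i.e. genuinely "informative by
chance", and that duration always carries the largest point-biserial
class correlation. Frozen noise channels are standard Gaussians drawn
once per rendition.

The generalization set models renditions of the same syllables recorded
the next day: acoustic features receive an additive day offset of sd
`jitter_scale` (default 0.5, half the within-day rendition variability);
durations drift by the proportional amount (clipped so grading
survives); frozen noise is redrawn (new renditions carry new frozen
values; `redraw_noise=False` reuses the training noise for ablation).

## Simulation experiments and measured regime

Default trial budget 10,000 trials/run, snapshots every 100 trials
(every 20 in the observer experiment, whose training-PCC crossing of 90%
happens within the first ~100 trials and would be invisible at 100-trial
resolution). PCC is the percentage of the ten stimuli classified
correctly by the majority-vote rule with frozen state, so its
granularity is 10 points. Burn-in for curve-matching comparisons is 500
trials. Weight profiles average log10(|W| + 1e−12) across runs (exact
zeros occur under L1).

Under these conditions the dynamic-λ system self-organizes to a critical
point: λ climbs until it equals the duration channel's maximum
sustainable gradient (η·6·0.5·E|z_dur| ≈ 0.02 under the linspace duration
grading), because any higher value collapses discrimination, lowers the
success EMA, and pulls λ back down. Measured consequences, all from the
acceptance suite at its stated seeds: ensemble-mean final λ ≈ 0.019–0.020
(same order as the reported 0.0127, which corresponds by the identity
above to a lower terminal success EMA of ≈ 0.75 in the original feature
space); the regularized neuron's duration weight is dominant but only
marginally so — the largest acoustic weight is duration in ≈ 78% of 50
runs, and snapshot-level PCC fluctuates by one to two stimuli, so
training and generalization curves track each other typically within 10
points but with excursions to ~20 at isolated snapshots. These are
intrinsic properties of the constants-plus-geometry regime, not free
parameters; they are reported as measured.

## What the generators do not emulate

Stimulus features are statistical stand-ins: no audio, no real SAP
feature extraction, no acoustic correlations between features (real SAP
features co-vary with duration; here all class information besides
duration is incidental by construction). Behavioral birds are
stationary-seed logistic learners: no motivation drifts, no
within-session fatigue, no latency structure beyond an optional
late-escape bias on puffed trials used to exercise the cumulative-curve
code. Cohort presets target group medians only; no per-bird
reproduction of the original animals is claimed, and analyses of the
recorded dataset are supported only through the CSV trial-log dialect.

## Problem sizes

Unit tests run hundreds of trials; the acceptance suite runs the full
10,000-trial budgets (10-seed observer pairs, 10- and 20-run regularized
ensembles, 50-run profile ensembles, 10,000 null bins) and completes in
a few minutes on one CPU.
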