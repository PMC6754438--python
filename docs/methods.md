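# Methods

## Signal model and pipeline order

Each recording is a 7 s, 1.2 Hz field-paced acquisition interleaving three
fluorescence channels frame-by-frame at 1000 fps total, i.e. 1000/3 ≈
333.33 samples/s per channel: a voltage-sensitive dye whose intensity
*decreases* on depolarization (AP), a calcium indicator (Ca), and a
membrane label whose intensity modulation tracks contraction-induced motion
(MA); contraction itself (Co) is quantified from the membrane-label frames.

The cleaning chain is fixed, in this order:

1. **Ratiometric motion-artifact correction** (AP, Ca):
   `out = signal / (ma / mean(ma))`. Division by the mean-normalized MA
   trace is the standard ratiometric form; a multiplicative motion artifact
   shared by signal and reference cancels up to a constant factor, which
   the later ΔF/F step absorbs. Requires a strictly positive MA trace.
2. **Inversion** (AP only): reflection about mid-range, `(max+min) − x`.
   Reflection rather than negation keeps the trace positive, which
   ΔF/F_min requires; it is an involution.
3. **Pseudo-ratio ΔF/F_min** (AP, Ca): `(F − F_min)/F_min`; the output
   minimum is exactly 0 and the result is invariant to intensity scaling.
   Contraction traces skip steps 1–3: the frame-difference surrogate is
   baseline-anchored and motion *is* its signal.
4. **Trailing moving average**, 2 frames by default; the first window−1
   samples average the available prefix so length and onset timing are
   preserved at the 3 ms sample period.
5. **Event detection**: peaks at roughly the pacing period (prominence
   0.4 × range), each onset at the rising crossing of 10% of the event
   amplitude above the diastolic baseline. A recording is rejected when any
   inter-onset interval deviates from the pacing period by more than 10%
   (both fractions configurable; whole-recording rejection is used because
   per-event salvage is not distinguishable from arrhythmia at this level).
6. **Averaging** of the first 5 complete events, aligned at onset, one
   pacing period long.

## Kinetic parameters (10 per recording)

All crossings use linear interpolation between samples. The diastolic
baseline of a beat is the median of its lowest-decile samples — for a paced
cyclic beat these are the late-diastolic (pre-upstroke) samples, which is
robust even though the averaged window starts at the detected onset. Two
numerical refinements matter at 333 fps: when the window starts just above
a low crossing level the crossing is back-extrapolated along the initial
upstroke slope (capped at one sample), and Ca/Co peak times use parabolic
sub-sample interpolation because argmax is ill-conditioned on flat-topped
transients. Without these the event-average phase smear biases
time-to-peak by roughly one sample.

* AP: amplitude (peak − baseline, ΔF/F), 10–90% rise time, `t_APD` = APD90
  (activation at the 50%-amplitude upstroke crossing to 90% repolarization;
  the APD level is configurable, APD90 being the common optical-AP choice),
  triangulation = APD90 − APD30 (reported positive, growing with
  triangulated repolarization).
* Ca: amplitude, time-to-peak (10% rising crossing → peak), decay time
  (peak → 50% decay; level configurable 50/90).
* Co: same three measures on the contraction trace (contraction time,
  relaxation time).

Each area's post-treatment record is divided fieldwise by its own baseline
record (ratios; 1 = no change — ratios rather than differences keep all ten
parameters dimensionless and comparable across wells); areas average into
wells. Records with any unusable (non-finite) field, non-positive
baselines, or failed interpeak checks are dropped with a logged reason.

## Probability scoring

Vehicle wells (concentration 0) define per-parameter Gaussians: mean and
*sample* standard deviation (ddof = 1) of the normalized well values. A
`sem` mode (sd/√n) exists for users who read the density's width symbol as
a standard error. The three scores partition 10 pointwise, so a negated
table cell ("NOT ↑" = anything but an increase) scores `10 − PS↑`, which is
exactly the summed score of the two admissible alternatives. The value
scored per condition is the across-well mean; per-well scoring with
averaged totals was evaluated and rejected (it lowers the mean margin of
the no-effect hypothesis — a Jensen effect — and measurably worsens null
specificity). The vehicle condition scores itself with
leave-current-well-out statistics to avoid trivial self-inflation (plain
scoring is used below 3 vehicle wells, where leave-one-out is degenerate).
Ties within 1e−6 are flagged and both candidates reported.

Known behaviour of the algorithm, reproduced by this implementation: with 5
vehicle wells the sd estimate has 4 degrees of freedom, so the z-values
entering the scores are ≈ 0.63·t₄. Under a true null this assigns "no
effect" in only ~90% of cases, with most misses going to the
myosin-increase column, whose NOT-rich hypothesis scores 70/100 at the
exact vehicle mean. This is intrinsic to the scoring construction at this
replication level, not a pipeline artifact (an idealized Gaussian-well
simulation shows the same rate), and it mirrors the published behaviour of
the method on real null compounds.

## Synthetic data generator

Waveform templates are phenomenological, not biophysical — the classifier
consumes only the ten kinetic parameters, so shape realism beyond typical
transient morphology adds nothing:

* AP: half-cosine upstroke (20 ms), stretched-exponential repolarization
  `exp(−(t/τ)^p)` with (τ, p) solved in closed form from the APD30/APD90
  targets (defaults 200/350 ms). The half-cosine's zero slope at the peak
  keeps the sampled amplitude within a fraction of a percent at 333 fps;
  shapes needing p < 0.5 are rejected as infeasible.
* Ca, Co: half-cosine rise (80/120 ms after 30/50 ms excitation-coupling
  delays), exponential decay (τ 130/140 ms, chosen so the residual at the
  next onset stays below ~1% of amplitude at 1.2 Hz).
* Intensities: AP baseline 100, amplitude 50 (emitted dimming, camera
  orientation); Ca 100/80; Co near-zero baseline as a motion surrogate.

Per-MOA perturbation maps each hypotheses-table cell onto its waveform
parameter: ×(1+m) for ↑, ×(1−m) for ↓, unchanged for =; negated cells draw
one admissible direction per drug at random (honouring the table's "might
be expected" semantics) and the realized directions are exported as ground
truth. Dose dependence is a saturating Hill-type curve with EC50 at the
median concentration, normalized so the top dose carries the full
magnitude. Replication follows the study layout: 5 wells × 3 areas per
condition, each area recorded at baseline and after treatment.
Variability: multiplicative lognormal well factors (σ = 5%, cancel in the
post/baseline ratio), lognormal recording-to-recording jitter (σ = 1%, the
effective vehicle spread), additive Gaussian photometric noise (σ = 5% of
each channel's amplitude), and an optional multiplicative motion artifact
(gain 0.1) shared by AP/Ca/MA. Everything is driven by one seeded
generator; identical seeds reproduce datasets bit-for-bit.

What the generator does **not** emulate: arrhythmic events (EADs,
alternans), beat-rate changes (pacing is fixed by design), photobleaching
and drift, spatial heterogeneity within an ROI, and the full MUSCLEMOTION
contraction algorithm — the shipped contraction quantifier is deliberately
a minimal mean-absolute-frame-difference surrogate against a fixed
reference frame. Passing tests therefore demonstrate the pipeline's
correctness and the classifier's statistical behaviour, not robustness to
those real-data effects.

## Problem sizes used in the test suite

Kinetic recovery runs a 3×3×3×3 grid of shape targets on single generator
beats (recovery within one sample period for times, 2% for amplitudes —
the full clean-and-average path adds up to ~1 further sample of alignment
smear on the slowest rises, which cancels in the post/baseline ratios).
Monte-Carlo classification uses 6 MOAs × 10 seeds plus 20 null runs, each a
vehicle plate plus one top-dose condition under the defaults above; a run
takes a fraction of a second, the whole suite well under a minute.

## Known limitations

* The contraction channel is a motion surrogate in arbitrary units; only
  its relative (post/baseline) changes are meaningful.
* The Co-only subset cannot reliably separate the myosin- from the
  calcium-mediated increase: their contraction rows differ only through a
  NOT cell, which the complement rule scores weakly dominant — the
  ambiguity is reported in the score tables rather than resolved.
* Mixed mechanisms (e.g. combined PDE-inhibiting and calcium-sensitizing
  compounds) have no column; the table is user-editable (TSV) for such
  extensions.
* No frequency correction of parameters is attempted; all comparisons
  assume the fixed 1.2 Hz pacing.
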