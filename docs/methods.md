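# Methods

This note documents the models and numerical choices behind the package:
what each measure computes, what the synthetic-session generator emulates
and deliberately does not, and where the design was genuinely open.

## Measures

**Windows and sampling.** One clock per trial in seconds; perturbation onset
`onset_s` on that clock; sample *k* of a channel covers the half-open
interval [k/rate, (k+1)/rate) and every analysis window is half-open, so no
boundary sample is counted twice at 1 kHz. The analysis phases relative to
onset are PRE [−100, 0), SLR [30, 60), MLR [60, 85), LLR [85, 120) and
RP [30, 120) ms; mechanical measures search [onset, onset + 400 ms). All
argmax-style rules break ties to the earliest sample, which makes every
measure deterministic.

**iEMG.** Rectified rectangle-rule integral over a window (mV·s), divided by
the window duration to a mean amplitude (mV) and by the muscle's MVC
reference to %MVC. The source material prints the time-normalised unit as
"mV/s"; an integral in mV·s divided by a duration in s is mV, so the
quantity is treated as a mean amplitude in mV. The MVC reference is the peak
of the 500 ms moving average of the rectified MVC recording.

**Co-contraction index.** Per sample of the rectified, MVC-normalised pair:
(lower/higher)·(lower+higher), with the 0/0 sample defined as 0 (no
activation means no co-contraction). The published definition is a bare sum
over window samples; since the window lengths are fixed (100 samples in PRE,
90 in RP at 1 kHz) the sum and the per-sample mean differ by a constant that
cancels under T1 normalisation. The mean is reported because it does not
change when the sampling rate does. The formula is symmetric and degree-1
homogeneous, so T1-normalised CCI is invariant to the MVC reference scale.

**COP and kinematics.** The COP channel is anterior-positive; for posterior
platform translations the peak search runs over the anterior direction of
the onset-referenced excursion and COP_D is its absolute value; *t* is the
time to the first maximum and COP_V = COP_D / t in mm/ms. (The published
table prints COP velocity in mm/s with values near 1.4, which is
dimensionally inconsistent with its own formula — 17 mm over 150 ms is
0.113 mm/ms; the formula governs here.) The 100 Hz COP clock snaps the
onset to the nearest earlier COP sample. Joint excursion is the maximum
absolute angle change from the onset position within the 400 ms window, so a
flipped goniometer mounting cannot change the result. A perfectly flat COP
trace has zero displacement and an undefined (NaN) peak time and velocity.

**H-reflex / M-wave.** Peak-to-peak (max − min of the raw signal) in
configurable windows after the stimulus marker: M 5–25 ms, H 25–60 ms —
conventional SOL latencies; only the extraction rule matters here, not the
physiology. The stimulus is delivered at the peak of the SOL short-latency
burst.

**Outcome rules.** A trial fails iff the safety frame was touched or the
unsupported foot lifted off; when both flags are set, frame touch is
recorded (the order the criteria are defined in). Success requires
re-stabilisation within 2 s; a trial with no failure flag and a slower
re-stabilisation is rejected as inconsistent. The exhaustion stop rule
(half of any four consecutive perturbations failed) is read as the first
trial *i* ≥ 4 with at least two failures among trials *i*−3 … *i*.

**Aggregation.** Quarters are contiguous blocks of trials with sizes
differing by at most one, larger blocks first (a deterministic convention;
quarters are meant to split each subject's session evenly in both time and
trial count, and with 4–6 s inter-trial gaps both cannot hold exactly —
binning is by count). Only successful posterior
trials contribute features; stimulation trials contribute the H/M amplitudes
and the mechanical measures but not iEMG/CCI, because the evoked response
replaces the natural reflex burst. A quarter without a valid cell is left
missing and the statistics use casewise deletion per test. Grand means
weight each subject equally (the subject is the unit of analysis of the
within-subject ANOVA), never pooled trials.

## Statistics

The repeated-measures ANOVA decomposes the subject × levels tensor of a
balanced fully-within design orthogonally: an effect's sum of squares is the
weighted squared norm of its Möbius (inclusion–exclusion) mean-difference
term, and each effect is tested against its own interaction with subjects.
One to three within factors are supported (time × protocol, plus phase,
joint segmentation or muscle pair as a third factor). Greenhouse–Geisser
ε is Box's epsilon of the sample covariance of orthonormal (Helmert)
contrast scores, clamped to [1/df, 1]; Mauchly's W uses the standard
chi-square approximation and both corrected and uncorrected p-values are
always reported, the corrected one being used when Mauchly rejects at 0.05
(or cannot be computed — singular contrast covariance — in which case the
correction is applied unconditionally and flagged). Bonferroni
multiplication is applied within explicit test families (one per results
table), never inferred. The correlation battery (failed attempts against
reflex-phase iEMG, RP co-contraction and joint excursions) uses the
two-tailed t-distribution p-value and Benjamini–Hochberg–Yekutieli step-up
control with c(m) = Σ 1/j, the variant valid under arbitrary dependence.
Effects whose sum of squares is at rounding-noise level relative to the
total variation (≤ 10⁻¹² of it) are reported as F = 0.

## Synthetic sessions

The generator targets the *statistical structure* the pipeline consumes —
per-quarter expected values of every extracted measure — not biomechanical
plausibility of waveforms. Raw EMG is modelled as x(t) = n(t)·e(t)·√(π/2)
with n standard normal, so the expected rectified value equals the envelope
e(t) exactly. Per muscle the envelope is a tonic background (the PRE level)
plus truncated-Gaussian bursts centred at 45/72/102 ms (widths 8/8/10 ms,
the window midpoints, keeping burst mass inside its window); each phase
window carries its own scaled piece whose discrete mean equals that phase's
target amplitude exactly, so the T1-normalised phase iEMG recovers the
configured multiplier with no leakage between phases — at the cost of small
envelope steps at window edges, which no measure looks at.

**Baseline activations** (%MVC at T1) are design choices, not published
values — they cancel under T1 normalisation. They are set to plausible
unipedal-stance levels (tonic plantarflexors ~7–8 %MVC, bursts ~10–45 %MVC)
with antagonist pairs kept within a factor of ~1.5 of each other, which also
widens the attainable co-contraction range (below).

**Co-contraction calibration.** The published CCI drift cannot be a
by-product of the single-muscle drift (its final-quarter multiplier exceeds
both members'), so the generator owns two dedicated dials that leave
single-muscle iEMG untouched: (i) a within-pair noise correlation ρ — the
absolute values |n_a|, |n_b| then co-vary, raising the expected per-sample
min/max term — and (ii) a burst-timing lag of the antagonist inside its
windows, whose temporal desynchronisation is the only way to push
co-contraction *below* the envelope-driven level. The expected windowed CCI
as a function of (envelope pair, ρ) is computed by kink-split Gauss–Legendre
quadrature on the folded bivariate normal density (verified against Monte
Carlo to ~0.2%), and per subject, pair, window and quarter the dials are
solved by root-finding so the expected CCI matches the drawn target ratio;
baselines ρ = 0.45 and lag = 5 ms leave room in both directions. Targets
outside the attainable range are clamped, which truncates the drawn spread:
the recovered reflex-phase CCI means sit within a few percent of their
targets, while the pre-activation CCI cells — whose printed values lie well
below the pairs' joint activation drift — retain an upward bias of roughly
0.1–0.2. This is a known limitation of the dials, reported rather than
hidden.

**Mechanics, H-reflex, failures.** Posterior trials carry an anterior
raised-cosine COP excursion (peak 150 ms after onset, inside the 400 ms
window; the exact value cancels in COP_D) on a small random walk
(0.05 mm steps), and analogous angle excursions; amplitudes are
subject-quarter draws times small trial-level jitter. Stimulation trials
(every second posterior trial) suppress the natural SOL bursts after the
stimulus and add biphasic M and H waves (full sine cycles, so the
peak-to-peak amplitude is exact by construction) with a 3 mV H-reflex
baseline, large against background EMG so the extraction bias on normalised
amplitudes stays ~2%. Failures are Bernoulli per quarter at the subject's
drawn rate, with the criterion chosen 50/50 (no published split) and
applied uniformly over directions (no published split either).

**Session length and the stop rule.** Each subject's fatigue-session length
is drawn first (uniform 10–16 sets of 8, i.e. roughly 7–11 min of
perturbations — a realistic time to exhaustion) and outcomes are Bernoulli
per quarter of that realized length. Truncating sessions at the stop rule is
available (`truncate_at_stop`) and is exercised when configured failure
rates actually approach the 50%-in-four regime; the shipped preset disables
it, because independent Bernoulli draws at the *printed* quarter rates
(~16% at most) inevitably produce occasional early 2-in-4 clusters that the
real, non-independent, experimenter-adjudicated process did not — truncating
and re-binning at those clusters would systematically distort the very
failure rates the preset is calibrated to (design simulations showed the
final-quarter rate dropping from ~15.9% to ~11%). The control session runs
the full 16 sets and is volume-matched by truncation downstream, sharing the
fatigue session's direction schedule so the i-th trials match.

**Cohort draws.** All between-subject per-quarter targets are exact-mean
lognormal (positive, mean exactly the configured value, SD the printed
between-subject SD). Two refinements shape the joint structure without
touching either moment: a persistent subject factor carries 70% of the
smallest quarter's log-variance across quarters (real subjects keep an
individual level; the log-variance split is exact, so each quarter's
marginal mean and SD are unchanged), and draws are Latin-hypercube
stratified across the cohort (one quantile stratum per subject per target
cell), which removes most finite-cohort Monte-Carlo error from grand means
while leaving the marginal distribution intact. Determinism: a cohort is a
pure function of (config, seed), with independent substreams per subject and
trial spawned from one SeedSequence.

**What passing tests do and do not show.** The generator reproduces means
and between-subject SDs of the published tables and the qualitative
time × protocol structure; it does not model electrode artefacts, true
burst morphology, direction-dependent responses of non-posterior trials
(generated as background activity, as they are never analysed),
biomechanical coupling between joints, or the full within-subject
correlation of quarter trajectories — the printed grand means ± SDs do not
constrain the latter, so interaction F values for raw-unit parameters (COP)
and for the H-reflex come out conservative relative to the study even though
the means match. Recovery of the calibration targets therefore validates the
pipeline's measures and aggregation, not any physiological claim.

## Problem sizes

The shipped analyses use the study's own dimensions: 24 subjects, sets of 8
with 10–16 sets per fatigue session, 0.6 s trial records at 1 kHz (COP at
100 Hz). A full cohort generates in ~15 s and the complete pipeline runs in
under a second; the ANOVA oracle-equivalence and null-calibration checks use
1000 random small designs and 2000 null simulations respectively.

## Known limitations

* Pre-activation CCI cells are biased high when their targets lie far below
  the pair's activation drift (dial clamping, above).
* Trial-level measurement noise adds ~1% upward Jensen bias to
  T1-normalised ratios (the T1 denominator is estimated from ~2 trials).
* Mixed (between × within) designs, post-hoc pairwise batteries, EMG onset
  detection, frequency-domain fatigue indices and 2-D COP statistics are out
  of scope.
* The jump-force preset treats the published post-fatigue force table as
  unreliable (it contradicts the accompanying text in both protocols) and
  encodes a 50% peak-force loss after fatigue with unchanged control values,
  per the narrative description.
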