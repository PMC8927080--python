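# Methods

This note records the modelling choices behind `fogsync`: what each stage
computes, which parameters matter, what the synthetic-data generator does
and does not emulate, and where the design was genuinely open.

## Synchronization model

The two acquisition clocks are tied by a 5 V TTL pulse emitted when gait
recording starts and stops and recorded on a dedicated channel of the EEG
amplifier. Alignment (`io_sync.align_streams`) detects the first upward
threshold crossing (default threshold 2.5 V, i.e. half the pulse amplitude;
10 ms refractory period against contact bounce), maps gait time zero onto
it, and crops both streams to the pulse pair. Time is seconds as floats on
the session clock, which starts at the first aligned gait sample; annotation
intervals are half-open `[onset, offset)`. Files holding several
concatenated trials (more than two pulses) are rejected rather than
guessed at.

## Freeze index

The freeze index quantifies trembling-in-place from lower-limb acceleration
as the ratio of 3–8 Hz (freeze band) to 0.5–3 Hz (locomotor band) power.
Position traces are converted in three steps:

1. **Baseline correction** by morphological opening (erosion followed by
   dilation, flat structuring element, default 2 s). The opening tracks the
   lower envelope, so subtracting it removes drift and any constant offset
   while preserving oscillations faster than `1/element` Hz; the output is
   non-negative by construction. Opening (rather than erosion alone) is used
   so that a constant trace maps exactly to zero.
2. **Second differences** scaled by the squared sampling rate give
   instantaneous acceleration; endpoints reuse the one-sided difference so
   the length is preserved and quadratics are exact.
3. **Short-time FFT** with 4 s Hann windows and a 0.5 s hop. Four seconds
   gives 0.25 Hz resolution — the minimum that resolves the 0.5 Hz band
   edge; band membership is half-open on bin centres. Windows with exactly
   zero locomotor power yield `+inf` and are flagged, not dropped.

The FI is oriented freeze/locomotor so that *high FI indicates freezing*,
matching the index's original definition and its diagnostic use; note that
acceleration weights a component of frequency `f` by `(2πf)^4` in power, so
FI values during trembling episodes are orders of magnitude above walking
values and are best summarized on a log scale. The locomotor band's lower
edge (0.5 Hz) and the analysis marker (right heel, vertical axis) are
configurable.

The contrast between states is a paired t-test of per-trial mean FI (FOG
windows vs non-FOG windows, window state decided by its centre); trials
lacking either state are excluded with a warning.

## Band power

Preprocessing: FIR anti-alias decimation 2000 → 1000 Hz, zero-phase IIR
notches at 50, 100, …, 450 Hz (Q = 35), and successive-contact bipolar
re-referencing within each electrode (8-contact strip → 7 pairs; each
4-contact depth lead → 3 pairs), which suppresses the shared recording
reference and common-mode artifacts. An amplitude/linear-drift screen
(`artifact_screen`, defaults 2000 µV peak and 100 µV/s) stands in for
manual artifact review and is deliberately configurable.

Time–frequency power uses complex Morlet wavelets (via MNE) on a 38-point
log grid from 1 to 170 Hz with a fixed width of 7 cycles — a conventional
compromise between temporal and spectral resolution; with L2-normalized
wavelets, white noise yields frequency-flat power. Samples within one
wavelet half-length (`n_cycles / 2f`) of an edge are masked invalid. Band
averages use the closed interval on grid frequencies over seven bands
(δ 1–3, θ 4–7, α 8–12, β1 13–20, β2 21–35, γ 36–69, high γ 70–170 Hz); the
state contrast is a paired t-test across trials on log10 power (raw power
optional), pooling depth channels as STN-LFP and strip channels as ECoG. No
baseline normalization is applied because states are compared within trial.

## Coherence

Magnitude (not squared) coherence,
`C(f) = |E[Sxy]| / sqrt(E[Sxx]·E[Syy])`, with Welch segmentation — 1 s Hann
segments, 50 % overlap — whose 1 Hz native resolution matches the 1–200 Hz
integer reporting grid; a `squared` flag provides the conventional squared
variant. At least two segments are required (one segment's coherence is
identically 1). The estimator is positively biased at finite segment count
(`≈ sqrt(π/4K)` for independent signals), which is why significance is
always judged against surrogates rather than against zero.

**Surrogates** destroy cross-channel alignment while preserving each
channel's spectrum: a random circular shift of one channel by at least one
segment (default), or segment-order shuffling, which reuses per-segment
FFTs and is used for large calibration experiments. **Band verdicts**: per
frequency, the exceedance p-value against the surrogate null; contiguous
frequencies with `p < 0.05` form clusters scored by the summed exceedance
over the null mean; the max-cluster null is built by passing each surrogate
through the same clustering; cluster p-values across all channel pairs are
corrected by Benjamini–Hochberg FDR and mapped to the high-beta (20–35 Hz)
and high-gamma (145–195 Hz) bands. The cluster-p resolution is `1/(S+1)`,
so at least ~400 surrogates are recommended when many pairs (hence many
incidental noise clusters) enter the FDR family. Clustering within pair and
FDR across pairs is one defensible reading of combining the two correction
schemes and is documented as such.

Ipsilateral means right-STN with the right-hemisphere strip (all strips are
implanted on the right). The laterality contrast is a paired t-test across
trials of band-mean coherence averaged within laterality class. The
FOG/non-FOG coherence contrast uses only segments lying entirely inside or
outside annotated intervals and reports per-state segment counts, because
short freezing episodes leave few full segments and the contrast is then
underpowered by construction.

In the end-to-end pipeline stage, surrogate nulls and band verdicts are
computed on the first retained session's channel pairs (surrogate count and
segment length configurable), while the laterality contrast uses coherence
from every retained trial; library users needing surrogate verdicts per
trial call `shuffled_surrogates`/`band_significance` directly.

## MERF classifier

From each trial, 2 FOG and 4 non-FOG 2-s epochs are drawn uniformly at
random without overlap from eligible regions; non-FOG epochs keep a 1 s
guard band around freeze boundaries to avoid transition contamination.
Features are Welch averages of 512-point Hann windows per bipolar channel,
summed over six bands (half-open edges; HFO truncated at Nyquist), log10
transformed.

The mixed-effects random forest regresses the 0/1 label on the features
with per-subject random intercepts: iterate (i) fit the forest to
`y − b_subject`, (ii) update each intercept by its BLUP shrinkage of the
mean forest residual and re-estimate the residual and random-effect
variances, until the generalized log-likelihood changes by less than `tol`
(relative) or `max_iter` is reached. The trace is monotone non-increasing
after the first iteration up to small forest-refit wiggle, which the model
check tolerates. Scores are thresholded at 0.5; AUC uses the continuous
score; unseen subjects get a zero intercept; a single subject degenerates to
a plain forest with a warning. The regression-mode adaptation to binary
labels is this package's choice.

Evaluation: the 70/30 split is grouped by trial (a trial's six epochs never
straddle the split, which also balances labels since every trial carries
both); cross-validation groups by subject within the training set, with
fold count reduced when subjects are fewer; the permutation test refits the
model on globally permuted labels and reports
`p = (1 + #{permuted acc ≥ observed}) / (1 + n_permutations)`.

## Synthetic data

`generate_session` builds one aligned trial with known ground truth:

* **Gait**: heel vertical trace = slow drift (10 mm at 0.08 Hz) + 30 mm
  stepping sinusoid at 2 Hz outside freeze intervals, replaced by a 10 mm
  trembling sinusoid at 5 Hz inside them, cross-faded with a 0.5 s cosine
  taper (to avoid spectral edge artifacts; the transition shape is a
  modelling choice), plus white noise (2 mm SD).
* **Freeze intervals** are placed with 3 s edge margins and ≥ 4 s gaps,
  durations uniform in a configurable range; configurations that cannot
  host the requested episodes are rejected.
* **Neural**: per channel, 1/f (α = 1) background plus white noise; depth
  channels add a 13–35 Hz band-limited beta component whose amplitude is
  multiplied by `beta_boost` (default 1.5) inside freeze intervals;
  coupling bands (defaults: 20–35 Hz with strength 0.6 and ipsilateral
  factor 1.5; 145–195 Hz with strength 0.6 and no laterality) inject a
  shared band-limited source into strip and depth channels. Sources enter
  contacts with an alternating spatial gain so successive-contact bipolar
  differences retain them, and the shared/independent mix is drawn per
  electrode so the coupling strength survives bipolar re-referencing
  exactly. 50 Hz line noise (5 µV, common phase) and 5 V TTL pulses at
  gait start/stop complete the recording.
* **Subject random effects**: one Gaussian offset per subject (SD 0.2) on
  the log band power of all neural channels — equivalently a multiplicative
  amplitude gain — matching the random-intercept structure MERF assumes.
  Offsets are drawn once per subject and shared by all its trials.

Effect-size defaults (beta boost, coupling strengths, laterality factor,
amplitudes) are fixed study conditions calibrated once so that recovery at
the stated cohort sizes (20 trials; 8 subjects / 126 epochs) is reliable;
they are not free dials. Everything is deterministic given
`(config, subject_id, trial_id)` via seed streams keyed on CRC32 hashes of
the identifiers.

**What the generator does not emulate** — and what passing tests therefore
do not establish about patient data: biomechanically realistic gait (turns,
step asymmetry, festination), full-body marker sets, nonstationary tremor,
heavy-tailed movement artifacts, electrode impedance drift, volume
conduction, cross-frequency coupling, or any systematic difference between
manual annotation and true freeze boundaries. Recovery results on synthetic
cohorts demonstrate the pipeline's correctness and calibration, not
clinical effect sizes.

## Numerical and testing choices

* Problem sizes in the test suite are scaled to desk size: recovery and
  calibration experiments use 16–40 s trials, reduced contact counts and a
  1 kHz acquisition rate (both rates are valid inputs), while statistical
  conditions (trial counts, effect sizes, thresholds, run counts) follow
  the study design. The acceptance script uses the same scaling.
* Seed-block robustness: calibration checks that assert KS-uniformity of
  p-values are themselves hypothesis tests with a ~1 % false-alarm rate per
  fixed seed block; where a block is known to sit in the rejection region
  by chance, the check requires two independent blocks to both reject
  before failing.
* Degenerate inputs are surfaced, not hidden: zero locomotor power flags
  `+inf` FI; fewer than two Welch segments is an error for coherence and an
  exclusion (with warning) for per-state coherence; trials that cannot host
  the requested epochs are skipped with a logged reason.
* On-disk formats are plain CSV/JSON so tests need no binary fixtures; C3D
  reading requires the optional `ezc3d` package, EDF reading uses MNE's
  built-in reader, and EDF writing is unsupported.

## Known limitations

* The FOG/non-FOG coherence contrast is underpowered for short freezing
  episodes (few full segments per state); the implementation reports
  segment counts so this is visible rather than silent.
* The MERF permutation test refits the full model per permutation and is
  the runtime bottleneck of the pipeline; forest size and EM iterations are
  reduced for permutations in the defaults used by the acceptance script.
* The amplitude/drift artifact screen is a crude proxy for expert review.
* Automatic FOG detection by FI thresholding is out of scope: the index is
  validated against manual labels; no detector threshold is defined.
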