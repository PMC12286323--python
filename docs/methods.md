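# Methods

## Pipeline model and assumptions

The decoder treats each fNIRS channel of each trial independently until
the classification stage. Trials of unequal duration (reading is
self-paced) are mapped to a common length by linear interpolation on a
uniform index grid with pinned endpoints; the default target is the
set-wide maximum sample count (1300 for study-conformant recordings) and
can be overridden for scaled runs. No band-pass filtering, baseline
correction or motion correction is applied before decomposition — the
decomposition itself is relied on to separate drifts, physiological
oscillations and response-band activity.

### ICEEMDAN

ICEEMDAN estimates each residue as the ensemble-average local mean of
noise-perturbed copies of the previous residue, where the stage-j
perturbation is the j-th EMD mode of a white-noise realization scaled to
a target SNR (ε0 = 0.2 relative amplitude, L = 100 realizations — the
standard biomedical settings). The same L seeded noise sequences are
reused across stages; their EMD mode banks are computed once per signal.
The construction telescopes, so `x = Σ IMF_j + residue` holds to
floating point; tests assert < 1e−9 relative error.

Sifting internals are classical choices that the ensemble estimator
itself does not prescribe:

* envelopes: natural cubic splines through local extrema, with up to two
  extrema mirrored about each signal end (plateaus count once, at their
  midpoint);
* stop rule: Cauchy criterion Σm²/Σh² < 0.2 with at most 100 siftings;
* mode loop ends when the residue has fewer than three interior extrema;
  `max_imfs` defaults to 8 so IMF 5 exists for 1300-sample signals.

Noise seeds are derived per (global seed, trial id, channel) by a
counter-based hash, so serial, parallel and re-ordered batch runs agree
bit-for-bit. β scales with std(x), making the decomposition exactly
scale-covariant (tested). If a requested IMF index exceeds the extracted
count, selection returns zeros and logs a warning rather than aborting a
batch.

The kernels are written in njit-compatible numpy and compiled with
numba when available (~0.2 ms per EMD of a 260-sample signal); without
numba the identical code runs as plain Python, only slower.

### SAX and features

z-normalization uses the population (1/n) standard deviation, the
classical SAX convention, with an all-zero guard for (near-)constant
input. PAA uses exact block means when the word length divides the
sample count and proportional fractional weights otherwise. Breakpoints
are Φ⁻¹(i/a), built antisymmetric exactly; a value lying exactly on a
breakpoint takes the lower symbol (a measure-zero tie, fixed for
determinism). Triple window shifting takes three windows at offsets
{0, s, 2s} with default stride s = 10% of the word length (80% windows);
"augment" mode (default) makes each window a training instance
inheriting the trial's label — all three always land on the same side of
the train/test split because splitting is by trial id. A "concat" mode
is available since the window geometry is not uniquely determined by its
figure-level description.

The five statistics are population moments; skewness m₃/var^{3/2} and
kurtosis m₄/std⁴ (non-excess) repair two evident misprints in the
printed formulas (a stray x̄ and a missing 4th power), with 0 as the
degenerate-sequence guard. Sequential forward selection greedily adds
the feature group (one column per channel) that maximizes 5-fold
stratified CV accuracy of the downstream k-NN on the training split,
stopping at no improvement, ties broken by menu order.

### Classification and evaluation

The k-NN is Euclidean with majority vote. Determinism rules: distance
ties keep training insertion order (stable argsort); vote ties go to the
tied class with the smaller summed neighbor distance, then to the
earlier class in sorted order (the negative class, *not_understood*,
sorts first). k is tuned in 1–25 by 5-fold stratified CV on the training
split only; the query score (positive-class neighbor fraction) feeds a
Mann–Whitney/trapezoidal AUC. Features are z-scored per dimension with
training-split statistics before distance computation (raw features are
a config option). Model selection never sees the test split; the
"best combination by test CA" ranking that mirrors the original
protocol is reported as such and flagged optimistic in summaries.

PAM places CA, SE, SP, AUC, J, FM on the hexagon spokes in that cyclic
order — the order matters and this arrangement reproduces reference PAM
values within ~0.2 percentage points of input rounding. PAM is
restricted to two-class tasks; three-class (SAS-binned) runs report
accuracy and the full confusion matrix only.

Stratified 70/30 splitting assigns round(0.7·n) trials per class to
training, which reproduces the reference marginals (e.g. 248 → 174/74,
202 → 141/61, 174 → 122/52).

## Synthetic data

The generator emulates temporal-lobe recordings of self-paced reading:

* **Response**: neural drive = boxcar over [S1, S2) **plus discrete
  event transients at jittered sentence boundaries** (4–8 per text,
  shared times across channels, channel-specific gains), convolved with
  a canonical difference-of-gammas HRF (peak ~6 s, undershoot ~16 s).
  The sustained plateau alone is invisible to the downstream
  representation (it decomposes into the residue, and z-normalization
  erases scale); the event transients put class-dependent
  impulsive-vs-continuous *shape* into the oscillatory band the
  decomposition isolates, which is exactly what symbol-sequence moments
  can detect. Event-related responses are the standard model of
  stimulus-locked hemodynamics, so this is realism and recoverability at
  once.
* **Class effect**: on informative channels, *understood* trials scale
  the whole response component by (1 + effect_size). effect_size = 0
  makes the classes exchangeable by construction (verified by a
  permutation test).
* **Noise**: Mayer-wave (0.1 Hz, amp 0.2) and cardiac (1 Hz, amp 0.25)
  sinusoids with random phases, random-walk drift (amp 0.35), white
  noise (σ 0.4) — all relative to unit response amplitude.
* **Metadata**: SAS and multiple-choice correctness agree with the true
  class except with probability `sas_noise` each (default 0.15), so the
  three labeling strategies disagree realistically; blanks are optional.
* OxyHb carries the positive response, DeoxyHb a −0.4-scaled inverted
  one; TotalHb is their sum. Per-participant RNG substreams make the
  generator deterministic and chromophore views consistent.

What it does **not** model: optical physics (Beer–Lambert, partial
volume), motion artifacts, participant-level anatomy or habituation,
spatially correlated noise. Passing recovery tests therefore shows the
pipeline recovers class structure of this kind from realistic noise —
not that real recordings contain such structure.

## Scaled experiment sizes

End-to-end checks run on a 450-trial cohort (15 × 30) with 6 channels
(4 informative) at 2.5 Hz and 180–260 samples per trial (72–104 s). The
scale-down preserves trial *duration* rather than sampling rate: the
discriminative band must sit below the HRF low-pass (~0.15 Hz), so
shortening trials in seconds would squeeze it against the trial length,
while lowering the rate keeps ~10 cycles of that band per trial.
ICEEMDAN keeps ε0 = 0.2, L = 100. SAX uses w = 100, a = 8; the channel
search covers all 56 combinations of size ≤ 4; the IMF index is swept
1–5 with shared decompositions and the best test CA reported (the
original protocol). The null-effect arm instead uses one fixed,
pre-registered configuration (IMF 3, one fixed combination, fixed
feature menu) and balanced classes: max-over-grid selection is
optimistically biased even under exchangeable classes, so only a fixed
configuration can be compared against the exact binomial chance band,
which is computed at trial (not augmented-instance) resolution because
windows of one trial are correlated.

## Known limitations

* EMD/ICEEMDAN internals (envelope type, boundary rule, stop criteria)
  vary across implementations; mode indices are not guaranteed to align
  across channels or trials when mode counts differ, and the zero-fill
  fallback for missing modes silently contributes empty features.
* The printed-table reference checks inherit the rounding of their
  sources (see the stated tolerances in the tests); AUC cannot be
  recomputed from confusion counts and is taken as reported.
* The optimistic "best of grid by test CA" protocol is reproduced for
  comparability but overstates generalization; the summary labels it.
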