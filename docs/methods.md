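# Methods

This note documents the models, numerical choices and limitations behind
`sigdict`, in the spirit of a package's own methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and partitioning

A record is a channels-by-samples array in microvolts with a sampling rate
(256 Hz by default) and half-open seizure annotations in seconds. Records
are cut into non-overlapping 4-s windows (1,024 samples at 256 Hz); the
trailing partial window is dropped rather than padded, because padding
would distort decomposition statistics near the edge. A window is labeled
*seizure* when at least half of its duration overlaps an annotated
interval. The half-overlap rule is a design choice (the boundary behaviour
of a segment straddling a seizure onset is genuinely ambiguous) and is
exposed as `label_overlap_fraction`.

Per channel, the seizure segments are split strictly in temporal order:
the first 15 % feed dictionary creation and learning, the next 5 %
validation, the next 30 % classifier training, the remaining 50 % testing.
Non-seizure segments contribute *equal counts* to the first three pools,
taken from the start of the record, and everything else goes to testing —
so the test pool is realistically unbalanced. Pool sizes round down; the
remainder always lands in testing. Partitioning is deterministic and uses
no randomisation anywhere.

No pre-processing is applied by default; a zero-phase second-order
Butterworth band-pass (1–60 Hz) is available for robustness experiments
only.

## Decomposition

**EMD.** Plain empirical mode decomposition (no ensemble or variational
extensions): cubic-spline upper/lower envelopes through the local extrema,
with the two extrema nearest each boundary mirrored about the edge to
suppress end effects (plus an edge clamp when an endpoint escapes the
envelope band). Sifting of a candidate mode stops by the classical
two-threshold rule — σ(t) = |envelope mean| / envelope amplitude must be
below θ₁ = 0.05 on at least 95 % of samples (α = 0.05) and below θ₂ = 0.5
everywhere — together with the extrema/zero-crossing IMF condition. A
safety cap of 100 siftings per mode guards degenerate inputs. Extraction
stops when the residual has fewer than two maxima or minima, or after
log₂(n) modes; the residual trend is appended as the final component so
additivity is exact by construction. Constant or very short inputs are
rejected (nothing to sift).

**MODWT-MRA.** The maximal-overlap (undecimated, energy-preserving)
discrete wavelet transform's multiresolution analysis, computed through
PyWavelets' stationary-transform MRA with periodic boundary extension:
J detail series plus the level-J smooth, each full length and summing to
the input. Defaults are `db4` and J = 7, so Q = 8 components — comparable
to the typical EMD mode count on 1,024-sample EEG-like segments. The MRA
components (time-domain series) are used as atoms rather than raw MODWT
coefficients, because atoms must live in the signal's time domain with
length n and sum to the signal, exactly mirroring the IMFs. Periodic
extension makes the transform deterministic and exactly invertible; its
wrap-around does affect atoms near segment edges, which is acceptable at
4-s windows. The implementation is cross-checked in the test suite against
an independent, deliberately naive Percival–Walden pyramid (direct circular
filtering and inversion) to 1e-6.

## Dictionary learning

All decomposition components of the dictionary-pool segments of *all*
channels, both classes, are unit-ℓ₂-normalised into a combined raw
dictionary (seizure atoms first). Identically zero components (e.g. a flat
detail from a zero stretch) cannot be normalised and are dropped with a
log entry.

The greedy learner follows the matching-pursuit reading of the algorithm:

* every learning signal owns a private index mask over the shared atom
  matrix and a private residue, and **both persist across outer
  iterations** — otherwise the residue update would have no effect from one
  iteration to the next;
* atom identity is by atom id, not numerical equality: two numerically
  identical components from different segments are distinct atoms;
* ties between equal |projection| values break toward the lowest atom id
  (deterministic and order-stable);
* the learning signals are the same segments whose components built the
  raw dictionary;
* after each iteration the validation distance d = ‖Γ_c₁ − Γ_c₂‖₂² is
  computed with validation signals paired positionally in temporal order
  (the pairing is arbitrary by design), and the earliest snapshot with the
  largest d is returned — ties favour the smaller dictionary.

Because selections within an iteration are independent across signals, the
per-signal projections batch into one matrix product per iteration; the
result is identical to the sequential loop, which the test suite verifies
against a straight-line brute-force transcription on 100 small instances.

With k learning signals per class, at most 2k atoms join per iteration, so
P ≤ 14k < M = 16k for the 7-level wavelet route — shrinkage is guaranteed,
not merely typical.

## Features and the pseudo-inverse tolerance

F1 is max_m |⟨x, ψ_m⟩| (the magnitude convention matches the learning
stage; a signed variant exists behind `signed_f1`). F2 = D⁺x and
F3 = ‖x − D D⁺x‖₂ share one SVD pseudo-inverse per trained dictionary,
computed once and cached — recomputing per segment is the naive O(nP²)
trap.

The truncation tolerance deserves its own paragraph. The feature functions
default to `rtol = 1e-10` (an essentially exact minimum-norm least-squares
solution; the Pythagorean identity ε² + ‖DD⁺x‖² = ‖x‖² then holds to 1e-6
relative). But a pooled-channel trained dictionary routinely has more atoms
than samples (P > n), and at numerical rank n the projector is the
identity: F3 ≈ 0 for *every* input and the feature is uninformative — the
implementation emits a rank warning in that regime. The dictionary's
singular spectrum, however, splits into a dominant cluster (roughly the
repeatedly-sampled background and rhythm modes) and a long noise-like
tail. The end-to-end workflow therefore uses a *coarse* reconstruction:
`PipelineConfig.rtol = 0.1` keeps only singular directions within one
decade of the leading one, which preserves a discriminative reconstruction
error for arbitrarily large dictionaries. The knob is first-class config;
nothing else in the workflow depends on it.

Feature matrices are standardised (zero mean, unit variance, fitted on
training rows only) inside the scale-sensitive classifiers (SVM, 1-NN);
LDA, naive Bayes and trees are scale-equivariant and take raw features.

## Classification

Five families with fixed, configurable hyperparameters: LDA; RBF-SVM with
C = 1 and γ = 1/(dim · var) on standardised features; Gaussian naive
Bayes; 1-nearest-neighbour; CART tree with Gini impurity and no depth cap.
Continuous decision scores (decision function, else class-1 posterior,
else hard labels) feed a midrank AUC. The best channel is the AUC argmax,
ties broken by montage order. The 2-of-3 vote over the three highest-AUC
channels triggers only when best-channel sensitivity or specificity falls
below 80 %, and is adopted only if it improves the metric that triggered
it — it can therefore never degrade that metric. Stratified 5-fold
cross-validation (seeded shuffle, pooled confusion counts) is available as
a robustness check on the per-channel classification stage.

All randomness — classifier internals and CV shuffling — derives from the
single config seed through named sub-seeds (`SeedSequence` on the seed and
a stage tag), so identical config + seed reproduces the whole report
bit-exactly on the wavelet route; the EMD route is deterministic as well,
it simply involves far more floating-point spline arithmetic.

## Synthetic data: what it emulates and what it does not

The generator produces per-channel background as Gaussian noise given a
1/f spectral tilt (β = 1) and AR(1) temporal correlation (a = 0.9),
normalised to a 20 µV RMS — broadly the spectral character of resting
scalp EEG with no biophysics behind it. During each annotated event it
adds rhythmic activity made of several frequency components (4, 8, 12 Hz
by default), with a linear amplitude ramp over the first 10 % of the
event, scaled relative to background RMS and attenuated per channel by a
seeded gain profile with one clearly dominant channel, so channel
selection has a true target.

Each event realises its *own* rhythm: per-event frequency jitter (±15 %),
a slow linear frequency drift (±5 % across the event), random phases, and
30 % sinusoidal amplitude modulation. This variability is essential, not
decorative: exactly periodic integer-frequency sinusoids span a ~6-D
linear subspace, so a dictionary containing two events' atoms would
reconstruct every later seizure perfectly and the reconstruction-error
feature would degenerate — real ictal rhythms are quasi-periodic and vary
between events.

The reference evaluation corpus (`benchmark_params`) uses 8 channels, 40
minutes, and 16 one-minute events. Two statistical considerations set the
scale: the per-channel test pools (~120 seizure / ~230 background
segments) give a null-AUC standard error of ≈ 0.033, so the *maximum* AUC
over channels — the statistic channel selection reports — concentrates
within a few hundredths of 0.5 on zero-amplitude records; and one-minute
events keep ramp-on/boundary segments (the genuinely ambiguous ones) a
small fraction of the seizure class. Problem sizes throughout the tests
and the acceptance script follow this corpus.

What passing tests on this generator show: the decomposition, dictionary,
feature and classification machinery discriminates when spectral structure
distinguishes the classes, finds the informative channel, and leaks no
label information (chance-level AUC at zero amplitude, even after
channel selection). What they do not show: performance on real scalp EEG,
with its artifacts (EMG, eye blinks, electrode pops), inter-seizure
morphology drift, spike-wave complexes and non-stationary background —
none of which the generator models.

## Known limitations

* EMD is the basic algorithm; mode mixing is not mitigated (by design —
  the dictionary does not assign physical meaning to components), and
  end effects are only reduced, not eliminated, by extrema mirroring.
* Patients with few or very short seizures may not populate the
  dictionary/validation/training pools; partitioning fails loudly naming
  the deficient pool rather than silently rebalancing.
* The EDF writer is minimal (16-bit, one record per second) — sufficient
  for the synthetic path and round-trip testing, not a general exporter.
* One trained dictionary per patient (channels pooled) but one classifier
  per channel is a deliberate asymmetry; patient-independent detection is
  out of scope.
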