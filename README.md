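# sigdict — patient-specific seizure detection with signal-derived empirical dictionaries

`sigdict` detects epileptic seizures in long-term multichannel scalp EEG by
learning a small dictionary of waveforms from a patient's *own* historical
recordings, instead of hand-crafting features. It targets clinical-style
data (CHB-MIT-like 23-channel bipolar montage at 256 Hz, EDF files with
seizure-interval annotations) and ships a synthetic EEG generator so the
whole workflow is testable without any data download. The intended users
are biomedical-signal-processing researchers and engineers prototyping
patient-specific detectors.

## Method

Recordings are cut into 4-s segments (1,024 samples at 256 Hz) and labeled
seizure / non-seizure from the annotations. Each segment `x ∈ ℝⁿ` is
decomposed into additive components, either

* **EMD** — intrinsic mode functions from empirical mode decomposition,
  `x[n] = Σⱼ aⱼ[n]` (plus the residual trend), or
* **MODWT-MRA** — the undecimated (maximal-overlap) discrete wavelet
  transform's multiresolution analysis with `db4`, J = 7 levels: details
  `D₁..D₇` plus the smooth, Q = 8 components of length n that sum to `x`.

**Raw dictionary.** The components of the earliest 15 % of seizure segments
and an equal number of non-seizure segments — all channels pooled — are
normalized to unit ℓ₂ norm and become the atoms `ψ_m` of a combined raw
dictionary `D_raw` with `M = 2L`, `L = k·Q` atoms.

**Dictionary learning.** A greedy, matching-pursuit-style pass shrinks
`D_raw` to a trained dictionary `D` with `P ≪ M` atoms: each learning signal
keeps a private copy of the raw dictionary and a private residue; per
iteration it selects the atom maximizing `|⟨x, ψ_m⟩|`, adds it to the shared
trained dictionary if new, removes it from its private copy, and updates
`x ← x − ψ̃⟨x, ψ̃⟩`. After each of up to 7 iterations a validation distance
`d = ‖Γ_c₁ − Γ_c₂‖₂²` is computed from held-out signals (`Γ_c` collects each
validation signal's largest `|⟨x̂, ψ⟩|`); the snapshot with the largest `d`
is kept.

**Features.** For every classifier-training/testing segment:
`F1 = max_m |⟨x, ψ_m⟩|`; `F2 = a = D⁺x` (coefficient vector, length P);
`F3 = ε = ‖x − D D⁺ x‖₂` (reconstruction error), with `D⁺` a truncated SVD
pseudo-inverse. Any of the seven feature combinations can feed the
classifiers.

**Classification.** One classifier per channel (LDA, RBF-SVM, Gaussian
naive Bayes, 1-NN, or a classification tree), trained on the next 30 % of
seizure segments plus an equal number of non-seizure segments, tested on
everything later in time. The channel with the highest AUC performs
detection; patients whose best channel has sensitivity or specificity
below 80 % get a 2-of-3 majority vote over the three highest-AUC channels,
adopted only if it improves the triggering metric. Metrics are
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total.

## Worked example

```python
from sigdict import PipelineConfig, generate_record, run_patient_pipeline
from sigdict.synthetic import benchmark_params

record = generate_record(benchmark_params(seed=1, seizure_amplitude=3.0))
config = PipelineConfig(method="emd", feature_set="F3", classifier="svm", seed=1)
report = run_patient_pipeline(record, config)
print(report.metrics)
print("best channel:", report.selected_channels,
      "AUC %.3f" % report.auc,
      "raw M =", report.raw_dictionary_size,
      "trained P =", report.trained_dictionary_size)
```

Output:

```
Metrics(sensitivity=97.52066115702479, specificity=99.16317991631799, accuracy=98.61111111111111)
best channel: ['CH01'] AUC 0.999 raw M = 3949 trained P = 327
```

The synthetic patient has 16 one-minute seizure events whose rhythmic
activity is 3× the background RMS on its best channel. The workflow finds
that channel, shrinks the 3,949-atom raw dictionary to 327 trained atoms,
and recovers the held-out seizures with ~98 % sensitivity and ~99 %
specificity. Setting `seizure_amplitude=0.0` (no seizure signal at all)
drives the best-channel AUC to ~0.55, i.e. chance level — the pipeline
has no access to the labels other than through the signal.

The same workflow runs from the shell:

```bash
sigdict simulate --seed 7 --duration 1200 --n-channels 6 \
    --out-edf p1.edf --out-annotations ann.csv
sigdict pipeline --config config.toml --out report.json
```

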