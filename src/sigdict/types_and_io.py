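"""Core data model and I/O for multichannel scalp EEG.

Records are held as a channels-by-samples array with an ordered label list
(bipolar 10-20 montage names; the standard 23-channel pediatric scalp montage
contains "T8-P8" twice, so labels are positional, not unique keys). Seizure
intervals are half-open ``[start_s, end_s)`` annotations in seconds from
record start. Fixed-length segmentation, overlap-based labeling and the
strictly temporal dictionary/validation/train/test partition live here, along
with EDF ingestion (via MNE) and a minimal 16-bit EDF writer so synthetic
records can exercise the same file path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger("sigdict")

SEIZURE = "seizure"
NON_SEIZURE = "non-seizure"
CLASSES = (SEIZURE, NON_SEIZURE)

#: The 23 bipolar channels shared by all CHB-MIT recordings, in the order the
#: montage is conventionally listed. "T8-P8" legitimately appears twice
#: (files disambiguate the two as T8-P8-0 / T8-P8-1).
MONTAGE_23 = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9",
    "FT9-FT10", "FT10-T8", "T8-P8",
)


@dataclass(frozen=True)
class SeizureAnnotation:
    """A seizure interval in seconds from record start; ``start_s < end_s``."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"annotation start {self.start_s} must precede end {self.end_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def normalize_annotations(
    annotations: Sequence[SeizureAnnotation], duration_s: float | None = None
) -> list[SeizureAnnotation]:
    """Sort annotations, merge overlaps/abutments, and bound-check them."""
    if not annotations:
        return []
    anns = sorted(annotations, key=lambda a: a.start_s)
    merged = [anns[0]]
    for a in anns[1:]:
        last = merged[-1]
        if a.start_s <= last.end_s:
            merged[-1] = SeizureAnnotation(last.start_s, max(last.end_s, a.end_s))
        else:
            merged.append(a)
    if duration_s is not None:
        for a in merged:
            if a.start_s < 0 or a.end_s > duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{a.start_s}, {a.end_s}) outside record "
                    f"duration {duration_s} s"
                )
    return merged


@dataclass
class EEGRecord:
    """A multichannel EEG record.

    samples : (n_channels, n_samples) float array in microvolts
    channel_labels : ordered montage names, aligned with the rows of samples
    sampling_rate : Hz
    annotations : normalized, non-overlapping seizure intervals
    patient_id : identifier string
    """

    samples: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: int = 256
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        self.annotations = normalize_annotations(self.annotations, self.duration_s)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Segment:
    """A fixed-length single-channel window of an EEG record."""

    values: np.ndarray
    channel: str
    t_index: int
    label: str | None = None
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("segment values must be 1-D")
        if self.t_index < 0:
            raise ValueError("t_index must be non-negative")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class DataSplit:
    """Per-class segment pools for the four stages of the workflow.

    Each field maps class name -> list of Segments sorted by t_index. The
    dictionary, validation and classifier-training pools are class-balanced;
    testing keeps every remaining segment (so it is typically unbalanced, with
    many more non-seizure segments).
    """

    dict_segments: dict[str, list[Segment]]
    validation_segments: dict[str, list[Segment]]
    train_segments: dict[str, list[Segment]]
    test_segments: dict[str, list[Segment]]

    def pools(self):
        return (
            ("dict", self.dict_segments),
            ("validation", self.validation_segments),
            ("train", self.train_segments),
            ("test", self.test_segments),
        )


# ---------------------------------------------------------------------------
# Segmentation, labeling, partitioning
# ---------------------------------------------------------------------------

def segment_record(record: EEGRecord, seg_seconds: float = 4.0) -> list[list[Segment]]:
    """Cut a record into consecutive non-overlapping fixed-length windows.

    Returns one list of Segments per channel, aligned with
    ``record.channel_labels``. A 4-s window at 256 Hz holds 1,024 samples.
    The trailing partial window is discarded.
    """
    if seg_seconds <= 0:
        raise ValueError("seg_seconds must be positive")
    n_float = seg_seconds * record.sampling_rate
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n <= 0:
        raise ValueError(
            f"seg_seconds * sampling_rate = {n_float} is not a positive integer"
        )
    count = record.n_samples // n
    if count == 0:
        logger.warning(
            "record %s shorter than one %g-s window; no segments",
            record.patient_id, seg_seconds,
        )
        return [[] for _ in record.channel_labels]
    out: list[list[Segment]] = []
    for ch, label in enumerate(record.channel_labels):
        out.append([
            Segment(
                values=record.samples[ch, i * n:(i + 1) * n].copy(),
                channel=label,
                t_index=i,
                patient_id=record.patient_id,
            )
            for i in range(count)
        ])
    return out


def label_segments(
    segments: Sequence[Segment],
    annotations: Sequence[SeizureAnnotation],
    sampling_rate: int = 256,
    overlap_fraction: float = 0.5,
) -> list[Segment]:
    """Label segments seizure/non-seizure by temporal overlap.

    A segment is labeled seizure iff at least ``overlap_fraction`` of its
    duration lies inside an annotated seizure interval (default one half;
    configurable because the boundary rule is a modeling choice).
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    anns = normalize_annotations(annotations)
    out = []
    for seg in segments:
        dur = seg.n / sampling_rate
        start = seg.t_index * dur
        end = start + dur
        overlap = sum(
            max(0.0, min(end, a.end_s) - max(start, a.start_s)) for a in anns
        )
        label = SEIZURE if overlap >= overlap_fraction * dur - 1e-12 else NON_SEIZURE
        out.append(replace(seg, label=label))
    return out


def partition_segments(
    segments: Sequence[Segment],
    fractions: tuple[float, float, float] = (0.15, 0.05, 0.30),
) -> DataSplit:
    """Split labeled segments temporally into dict/validation/train/test pools.

    Seizure segments, in temporal order, go: first 15% to dictionary creation,
    next 5% to validation, next 30% to classifier training, the remaining 50%
    to testing (floor rounding for the first three pools; the remainder is
    never starved from testing). Non-seizure segments contribute *equal
    counts* to each of the first three pools, taken from the start of the
    record in temporal order; every remaining non-seizure segment is kept
    for testing. Deterministic: no randomization anywhere.
    """
    f_dict, f_val, f_train = fractions
    if min(fractions) < 0 or sum(fractions) >= 1.0:
        raise ValueError("fractions must be non-negative and sum to < 1")
    seiz = sorted((s for s in segments if s.label == SEIZURE), key=lambda s: s.t_index)
    nons = sorted(
        (s for s in segments if s.label == NON_SEIZURE), key=lambda s: s.t_index
    )
    n_s = len(seiz)
    n_dict = int(n_s * f_dict)
    n_val = int(n_s * f_val)
    n_train = int(n_s * f_train)
    counts = {"dict": n_dict, "validation": n_val, "train": n_train}
    for pool, c in counts.items():
        if c < 1:
            raise ValueError(
                f"too few seizure segments ({n_s}) for a non-empty "
                f"'{pool}' pool at fractions {fractions}"
            )
    if n_dict + n_val + n_train > len(nons):
        raise ValueError(
            f"too few non-seizure segments ({len(nons)}) to balance the "
            f"dict/validation/train pools ({n_dict}+{n_val}+{n_train})"
        )
    b1, b2, b3 = n_dict, n_dict + n_val, n_dict + n_val + n_train
    return DataSplit(
        dict_segments={SEIZURE: seiz[:b1], NON_SEIZURE: nons[:b1]},
        validation_segments={SEIZURE: seiz[b1:b2], NON_SEIZURE: nons[b1:b2]},
        train_segments={SEIZURE: seiz[b2:b3], NON_SEIZURE: nons[b2:b3]},
        test_segments={SEIZURE: seiz[b3:], NON_SEIZURE: nons[b3:]},
    )


# ---------------------------------------------------------------------------
# Optional band-pass (robustness experiment only; the method needs none)
# ---------------------------------------------------------------------------

def bandpass_filter(
    record: EEGRecord, low_hz: float = 1.0, high_hz: float = 60.0, order: int = 2
) -> EEGRecord:
    """Zero-phase Butterworth band-pass, applied per channel; length preserved."""
    nyq = record.sampling_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=record.sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, record.samples, axis=1)
    return EEGRecord(
        samples=filtered,
        channel_labels=record.channel_labels,
        sampling_rate=record.sampling_rate,
        annotations=list(record.annotations),
        patient_id=record.patient_id,
    )


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, montage: Sequence[str] | str = "auto") -> EEGRecord:
    """Read an EDF file, restricted to a channel montage when one applies.

    With ``montage="auto"`` (default) the record is restricted to the
    standard 23-channel bipolar montage if the file provides it, and taken
    as-is otherwise. Passing an explicit montage sequence is strict: missing
    channels raise with their names. Montage entries are matched greedily
    against the file's channels in file order (case-insensitive; a trailing
    "-0"/"-1" disambiguator on the file label is accepted), so the duplicated
    "T8-P8" montage entry binds to the second matching channel.
    """
    import mne

    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise IOError(f"cannot read EDF file: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    file_labels = [str(ch) for ch in raw.ch_names]

    auto = isinstance(montage, str) and montage == "auto"
    if auto:
        montage = MONTAGE_23

    def base(label: str) -> str:
        up = label.strip().upper()
        for suf in ("-0", "-1", "-2"):
            if up.endswith(suf):
                return up[: -len(suf)]
        return up

    used = [False] * len(file_labels)
    rows, missing = [], []
    for want in montage:
        found = None
        for i, lab in enumerate(file_labels):
            if not used[i] and base(lab) == want.upper():
                found = i
                break
        if found is None:
            missing.append(want)
        else:
            used[found] = True
            rows.append(found)
    if missing:
        if auto:
            logger.info("EDF %s lacks the standard montage; using all %d "
                        "file channels", path.name, len(file_labels))
            return EEGRecord(
                samples=data,
                channel_labels=tuple(file_labels),
                sampling_rate=int(round(raw.info["sfreq"])),
                patient_id=path.stem,
            )
        raise ValueError(f"EDF file {path} missing montage channels: {missing}")
    return EEGRecord(
        samples=data[rows],
        channel_labels=tuple(montage),
        sampling_rate=int(round(raw.info["sfreq"])),
        patient_id=path.stem,
    )


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write a record as EDF (16-bit, one data record per second).

    Minimal but standard-conforming writer used by the synthetic-data path
    and round-trip tests; amplitudes are quantized to the 16-bit EDF grid
    over each channel's physical range.
    """
    path = Path(path)
    fs = record.sampling_rate
    n_full_sec = record.n_samples // fs
    if n_full_sec == 0:
        raise ValueError("record shorter than one second; cannot write EDF")
    data = record.samples[:, : n_full_sec * fs]
    nch = record.n_channels

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid a zero physical range (flat channel)
    flat = phys_max - phys_min < 1e-9
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {record.patient_id}", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + nch * 256), 8),
        pad("", 44),
        pad(str(n_full_sec), 8),
        pad("1", 8),
        pad(str(nch), 4),
    ])
    labels = b"".join(pad(lab, 16) for lab in record.channel_labels)
    transducer = b"".join(pad("", 80) for _ in range(nch))
    phys_dim = b"".join(pad("uV", 8) for _ in range(nch))
    pmin = b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_min)
    pmax = b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_max)
    dmin = b"".join(pad(str(dig_min), 8) for _ in range(nch))
    dmax = b"".join(pad(str(dig_max), 8) for _ in range(nch))
    prefilter = b"".join(pad("", 80) for _ in range(nch))
    n_samp = b"".join(pad(str(fs), 8) for _ in range(nch))
    reserved = b"".join(pad("", 32) for _ in range(nch))

    # physical ranges as re-parsed from the truncated 8-char header fields,
    # so quantization round-trips through exactly what a reader will see
    pmin_hdr = np.array([float(pmin[i * 8:(i + 1) * 8]) for i in range(nch)])
    pmax_hdr = np.array([float(pmax[i * 8:(i + 1) * 8]) for i in range(nch)])
    scale = (pmax_hdr - pmin_hdr) / (dig_max - dig_min)
    digital = np.clip(
        np.round((data - pmin_hdr[:, None]) / scale[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + pmin + pmax
                 + dmin + dmax + prefilter + n_samp + reserved)
        for sec in range(n_full_sec):
            block = digital[:, sec * fs:(sec + 1) * fs]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# Annotation CSV
# ---------------------------------------------------------------------------

def read_annotations_csv(path: str | Path) -> pd.DataFrame:
    """Read a seizure-annotation table (patient_id, record_id, start_s, end_s)."""
    df = pd.read_csv(path)
    required = {"patient_id", "record_id", "start_s", "end_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV {path} missing columns: {sorted(missing)}")
    return df


def annotations_for_record(df: pd.DataFrame, record_id: str) -> list[SeizureAnnotation]:
    sel = df[df["record_id"].astype(str) == str(record_id)]
    return [SeizureAnnotation(float(r.start_s), float(r.end_s))
            for r in sel.itertuples()]


def write_annotations_csv(
    path: str | Path, patient_id: str, record_id: str,
    annotations: Sequence[SeizureAnnotation],
) -> None:
    pd.DataFrame({
        "patient_id": [patient_id] * len(annotations),
        "record_id": [record_id] * len(annotations),
        "start_s": [a.start_s for a in annotations],
        "end_s": [a.end_s for a in annotations],
    }).to_csv(path, index=False)
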