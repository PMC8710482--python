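"""Additive decomposition of EEG segments: EMD and undecimated wavelet MRA.

Two routes produce the component sets whose normalized components later serve
as dictionary atoms:

* **EMD** — empirical mode decomposition by iterative sifting with
  cubic-spline envelopes. The stopping rule is the two-threshold criterion of
  Rilling's reference implementation: sifting of a candidate mode stops when
  the normalized envelope-mean amplitude sigma(t) = |mean(t)| / amp(t) is
  below theta_1 on at least (1 - alpha) of the samples and below theta_2
  everywhere, and the extrema/zero-crossing counts differ by at most one.
  Boundaries are handled by mirroring the two extrema nearest each edge.
  The final residual trend is appended as the last component so the
  components always sum to the input exactly.

* **MODWT-MRA** — the maximal overlap (undecimated, energy-preserving)
  discrete wavelet transform's multiresolution analysis: J time-domain detail
  series plus the level-J smooth, each the length of the input, summing to
  the input. Computed with PyWavelets' stationary-transform MRA, which uses
  periodic boundary extension; db4 with J = 7 levels by default so a
  1,024-sample segment yields Q = 8 components, comparable to the typical
  EMD mode count.

Both routes are deterministic given their input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .types_and_io import Segment

__all__ = [
    "DecompositionConfig",
    "ComponentSet",
    "emd_decompose",
    "modwt_mra",
    "decompose",
]


@dataclass(frozen=True)
class DecompositionConfig:
    """Decomposition settings.

    method : "emd" or "dwt"
    wavelet_name : mother wavelet for the MODWT route (default "db4")
    levels : J, number of wavelet levels (default 7 -> Q = 8 components)
    emd_theta1, emd_theta2, emd_alpha : Rilling sifting-stop thresholds
    max_imfs : optional cap on extracted modes (residual still appended)
    max_siftings : safety cap on sifting iterations per mode
    """

    method: str = "emd"
    wavelet_name: str = "db4"
    levels: int = 7
    emd_theta1: float = 0.05
    emd_theta2: float = 0.5
    emd_alpha: float = 0.05
    max_imfs: int | None = None
    max_siftings: int = 100

    def __post_init__(self) -> None:
        if self.method not in ("emd", "dwt"):
            raise ValueError(f"method must be 'emd' or 'dwt', got {self.method!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if min(self.emd_theta1, self.emd_theta2, self.emd_alpha) <= 0:
            raise ValueError("sifting thresholds must be positive")


@dataclass
class ComponentSet:
    """Ordered additive components of one segment.

    For EMD: IMFs in decreasing-frequency order, residual trend last.
    For the wavelet route: details D1..DJ (fine to coarse), smooth last.
    Components are stacked as a (Q, n) array and sum to the source values.
    """

    components: np.ndarray
    method: str
    source: Segment | None = None

    def __post_init__(self) -> None:
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))

    @property
    def Q(self) -> int:
        return self.components.shape[0]

    @property
    def n(self) -> int:
        return self.components.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.components.sum(axis=0)


def _as_array(segment) -> np.ndarray:
    if isinstance(segment, Segment):
        return segment.values
    return np.asarray(segment, dtype=float)


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (flat tops take midpoint)."""
    d = np.diff(x)
    # collapse zero slopes onto the sign of the next nonzero slope so flat
    # plateaus register a single extremum
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    # forward-fill zeros with the previous nonzero sign
    idx = np.where(nz, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0)
    sc = np.diff(filled)
    maxima = np.where(sc < 0)[0] + 1
    minima = np.where(sc > 0)[0] + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[:-1] * s[1:] < 0))


def _mirror_extrema(
    x: np.ndarray, maxima: np.ndarray, minima: np.ndarray, n_mirror: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extend extrema beyond both ends by mirroring, to anchor the envelopes.

    Returns (t_max, v_max, t_min, v_min) sample positions (may be negative or
    beyond n-1) and values, with `n_mirror` mirrored extrema on each side.
    """
    n = len(x)
    tmax, tmin = maxima.astype(float), minima.astype(float)
    vmax, vmin = x[maxima], x[minima]

    # reflect the extrema nearest each edge about the edge sample position
    lt_max, lv_max = (-tmax[:n_mirror])[::-1], vmax[:n_mirror][::-1]
    lt_min, lv_min = (-tmin[:n_mirror])[::-1], vmin[:n_mirror][::-1]
    rt_max = (2 * (n - 1) - tmax[-n_mirror:])[::-1]
    rv_max = vmax[-n_mirror:][::-1]
    rt_min = (2 * (n - 1) - tmin[-n_mirror:])[::-1]
    rv_min = vmin[-n_mirror:][::-1]

    # guard: the edge sample must lie inside the mirrored envelopes,
    # otherwise clamp the edge in as an extremum (standard end-effect fix)
    if x[0] > max(lv_max.max(initial=-np.inf), vmax[0]):
        lt_max, lv_max = np.array([0.0]), np.array([x[0]])
    if x[0] < min(lv_min.min(initial=np.inf), vmin[0]):
        lt_min, lv_min = np.array([0.0]), np.array([x[0]])
    if x[-1] > max(rv_max.max(initial=-np.inf), vmax[-1]):
        rt_max, rv_max = np.array([float(n - 1)]), np.array([x[-1]])
    if x[-1] < min(rv_min.min(initial=np.inf), vmin[-1]):
        rt_min, rv_min = np.array([float(n - 1)]), np.array([x[-1]])

    t_max = np.concatenate([lt_max, tmax, rt_max])
    v_max = np.concatenate([lv_max, vmax, rv_max])
    t_min = np.concatenate([lt_min, tmin, rt_min])
    v_min = np.concatenate([lv_min, vmin, rv_min])
    # cubic splines need strictly increasing knots; drop degenerate mirrors
    keep_max = np.concatenate([[True], np.diff(t_max) > 0])
    keep_min = np.concatenate([[True], np.diff(t_min) > 0])
    return t_max[keep_max], v_max[keep_max], t_min[keep_min], v_min[keep_min]


def _envelope_mean(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean of the cubic-spline upper/lower envelopes and their half-range.

    Returns (mean, amplitude, n_extrema); amplitude is the envelope
    half-width used by the sifting stop criterion.
    """
    maxima, minima = _local_extrema(x)
    n_ext = len(maxima) + len(minima)
    if len(maxima) < 2 or len(minima) < 2:
        return np.zeros_like(x), np.ones_like(x), n_ext
    t_max, v_max, t_min, v_min = _mirror_extrema(x, maxima, minima)
    t = np.arange(len(x), dtype=float)
    upper = CubicSpline(t_max, v_max)(t)
    lower = CubicSpline(t_min, v_min)(t)
    mean = 0.5 * (upper + lower)
    amp = 0.5 * (upper - lower)
    return mean, amp, n_ext


def _is_imf(candidate: np.ndarray) -> bool:
    maxima, minima = _local_extrema(candidate)
    n_ext = len(maxima) + len(minima)
    return abs(n_ext - _zero_crossings(candidate)) <= 1


def _sift(x: np.ndarray, cfg: DecompositionConfig) -> np.ndarray:
    """Extract one IMF from x by sifting with the two-threshold stop rule."""
    h = x.copy()
    for _ in range(cfg.max_siftings):
        mean, amp, n_ext = _envelope_mean(h)
        if n_ext < 4:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = np.abs(mean) / np.maximum(np.abs(amp), 1e-30)
        ok = (
            np.mean(sigma > cfg.emd_theta1) < cfg.emd_alpha
            and np.all(sigma < cfg.emd_theta2)
            and _is_imf(h)
        )
        if ok:
            break
        h = h - mean
    return h


def emd_decompose(segment, config: DecompositionConfig | None = None) -> ComponentSet:
    """Decompose a segment into IMFs plus the residual trend.

    Components are ordered from the fastest mode to the residual; they sum to
    the input exactly because the residual is what remains after subtracting
    all extracted modes. Raises on constant or too-short input (nothing to
    sift).
    """
    cfg = config or DecompositionConfig(method="emd")
    x = _as_array(segment)
    n = len(x)
    if n < 8:
        raise ValueError(f"segment too short for EMD ({n} samples)")
    if np.ptp(x) == 0:
        raise ValueError("constant segment has no extrema to sift")
    max_modes = int(np.log2(n))
    if cfg.max_imfs is not None:
        max_modes = min(max_modes, cfg.max_imfs)

    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_modes):
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        imf = _sift(residual, cfg)
        if not np.any(imf):
            break
        imfs.append(imf)
        residual = residual - imf
    components = np.vstack(imfs + [residual]) if imfs else residual[None, :]
    src = segment if isinstance(segment, Segment) else None
    return ComponentSet(components=components, method="emd", source=src)


# ---------------------------------------------------------------------------
# MODWT multiresolution analysis
# ---------------------------------------------------------------------------

def modwt_mra(segment, config: DecompositionConfig | None = None) -> ComponentSet:
    """Undecimated wavelet MRA: J details + smooth, fine-to-coarse order.

    All components have the input's length and sum to it (periodic boundary
    extension). Requires the input length to be divisible by 2**levels.
    """
    cfg = config or DecompositionConfig(method="dwt")
    x = _as_array(segment)
    n = len(x)
    if 2 ** cfg.levels > n or n % (2 ** cfg.levels) != 0:
        raise ValueError(
            f"levels={cfg.levels} too large for length {n} "
            f"(need n divisible by 2^levels)"
        )
    comps = pywt.mra(x, cfg.wavelet_name, level=cfg.levels, transform="swt",
                     mode="periodization")
    # pywt returns [smooth_J, D_J, ..., D_1]; flip to D_1..D_J, smooth last
    ordered = np.vstack(comps[::-1])
    src = segment if isinstance(segment, Segment) else None
    return ComponentSet(components=ordered, method="dwt", source=src)


def decompose(segment, config: DecompositionConfig) -> ComponentSet:
    """Dispatch on config.method."""
    if config.method == "emd":
        return emd_decompose(segment, config)
    return modwt_mra(segment, config)
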