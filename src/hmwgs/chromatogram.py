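"""Chromatogram traces and peak detection.

A trace is a pair of equal-length arrays (time in minutes, absorbance in
arbitrary units).  Peak detection works on a moving-average-smoothed,
baseline-subtracted copy of the signal: local maxima inside the query
window are kept, apex positions are refined by quadratic interpolation
through the three samples around each maximum (reference SDs of ~0.08
min sit near plausible sampling steps, so sub-grid precision matters),
and areas are trapezoids of the baseline-subtracted raw signal between
flanking minima.  The baseline is the straight line joining the smoothed
signal values at the window endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import FormatError, ValidationError

#: default moving-average width, minutes
DEFAULT_SMOOTH_WIDTH = 0.05
#: default detection threshold as a fraction of the window maximum
DEFAULT_MIN_HEIGHT_FRACTION = 0.05

_MAX_STEP_RATIO = 1.5


@dataclass
class Chromatogram:
    """A sampled absorbance trace."""

    time: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.absorbance.shape:
            raise ValidationError("time and absorbance must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValidationError("trace needs at least 2 samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValidationError("time must be strictly increasing")
        if steps.max() / steps.min() > _MAX_STEP_RATIO:
            raise ValidationError(
                f"non-uniform sampling: max/min step ratio "
                f"{steps.max() / steps.min():.2f} > {_MAX_STEP_RATIO}"
            )

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class Peak:
    """A detected apex with height above baseline and integrated area."""

    apex_rt: float
    height: float
    area: float
    left_rt: float
    right_rt: float

    def __post_init__(self) -> None:
        if not (self.left_rt < self.apex_rt < self.right_rt):
            raise ValidationError("peak bounds must bracket the apex")
        if self.height <= 0 or self.area <= 0:
            raise ValidationError("peak height and area must be positive")


def read_trace(path, sample_id: str | None = None) -> Chromatogram:
    """Read a two-column CSV (``time_min,absorbance``; header optional)."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns, got {df.shape[1]}")
    df = df.iloc[:, :2]
    # headerless files: first row was consumed as header; re-read raw
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(path, header=None, comment="#").iloc[:, :2]
    except ValueError:
        pass
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = int(np.argwhere(np.isnan(values))[0, 0]) + 1
        raise FormatError(f"{path}: non-numeric value near data row {bad}")
    if values.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 data rows")
    sid = sample_id if sample_id is not None else ""
    try:
        return Chromatogram(values[:, 0], values[:, 1], sample_id=sid)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_trace(trace: Chromatogram, path) -> None:
    """Write a trace as ``time_min,absorbance`` CSV."""
    pd.DataFrame({"time_min": trace.time, "absorbance": trace.absorbance}).to_csv(
        path, index=False, float_format="%.6f"
    )


def _smooth(y: np.ndarray, width_min: float, step: float) -> np.ndarray:
    n = max(1, int(round(width_min / step)))
    if n % 2 == 0:
        n += 1  # keep the kernel symmetric so apexes do not shift
    if n == 1:
        return y.astype(float)
    kernel = np.ones(n) / n
    return np.convolve(y, kernel, mode="same")


def _quadratic_apex(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through samples i-1, i, i+1 (falls back to t[i])."""
    if i == 0 or i == len(y) - 1:
        return float(t[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    h = 0.5 * (t[i + 1] - t[i - 1])
    return float(t[i] + delta * h)


def detect_peaks(
    trace: Chromatogram,
    window: tuple[float, float] = (25.0, 42.0),
    min_height: float | None = None,
    smooth_width: float = DEFAULT_SMOOTH_WIDTH,
) -> list[Peak]:
    """Detect peaks inside ``window``, sorted by apex RT ascending.

    ``min_height`` is an absolute threshold in AU above baseline; when
    None it defaults to 5% of the baseline-subtracted window maximum.
    """
    lo, hi = window
    if not lo < hi:
        raise ValidationError(f"empty window {window}")
    t, y = trace.time, trace.absorbance
    if lo < t[0] or hi > t[-1]:
        raise ValidationError(f"window {window} outside trace range [{t[0]}, {t[-1]}]")

    ys = _smooth(y, smooth_width, trace.step)
    i_lo = int(np.searchsorted(t, lo, side="left"))
    i_hi = int(np.searchsorted(t, hi, side="right")) - 1
    if i_hi - i_lo < 2:
        raise ValidationError("window contains fewer than 3 samples")

    # two-point linear baseline anchored at the window endpoints
    slope = (ys[i_hi] - ys[i_lo]) / (t[i_hi] - t[i_lo])
    baseline = ys[i_lo] + slope * (t - t[i_lo])
    cs = ys - baseline  # smoothed, baseline-subtracted
    cr = y - baseline  # raw, baseline-subtracted (for areas)

    maxima, _ = find_peaks(cs)
    maxima = [m for m in maxima if lo <= t[m] <= hi]
    if min_height is None:
        win_max = float(cs[i_lo : i_hi + 1].max(initial=0.0))
        min_height = DEFAULT_MIN_HEIGHT_FRACTION * win_max
    maxima = [m for m in maxima if cs[m] >= min_height and cs[m] > 0]
    if not maxima:
        return []

    # integration bounds: window edges and the minima between neighbours
    bounds = [i_lo]
    for a, b in zip(maxima[:-1], maxima[1:]):
        bounds.append(a + int(np.argmin(cs[a : b + 1])))
    bounds.append(i_hi)

    peaks: list[Peak] = []
    for left, m, right in zip(bounds[:-1], maxima, bounds[1:]):
        apex = _quadratic_apex(t, cs, m)
        area = float(np.trapezoid(np.clip(cr[left : right + 1], 0.0, None), t[left : right + 1]))
        if area <= 0:
            continue
        peaks.append(
            Peak(
                apex_rt=apex,
                height=float(cs[m]),
                area=area,
                left_rt=float(t[left]) if t[left] < apex else apex - trace.step,
                right_rt=float(t[right]) if t[right] > apex else apex + trace.step,
            )
        )
    return sorted(peaks, key=lambda p: p.apex_rt)
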