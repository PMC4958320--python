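"""FRAP half-recovery estimation for cortical myosin turnover.

The analysis mirrors the standard confocal FRAP workflow for the furrow
cortex: per frame, 50% of the cytoplasmic Sqh-GFP level is subtracted as
background (50% rather than 100% so that the earliest cortical recovery is
not clipped), the z-sections are combined by a weighted sum whose per-slice
weights are proportional to the background-corrected signal in the
unbleached control region, and mean intensities are extracted for the
bleached and control rectangles.  Each region's series is min-max
normalized to [0, 1]; since the bleached region recovers nearly fully under
single-exponential cortical exchange, the normalization anchors the
post-bleach plateau at 1.  The half-recovery time t_1/2 is the first time
the bleached/control ratio reaches 0.5 (linear interpolation between
frames; the frame-quantized crossing is recorded alongside).

The ratio used for thresholding is formed from the raw region series
*before* normalization (then min-max normalized), so any per-frame gain
common to the whole stack cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import ImageStack, _rects_overlap

__all__ = ["FRAPCurve", "FRAPConfigError", "NormalizationError",
           "frap_normalize", "estimate_half_time"]


class FRAPConfigError(ValueError):
    """Invalid region definitions."""


class NormalizationError(ValueError):
    """Degenerate intensity series."""


@dataclass
class FRAPCurve:
    """Normalized FRAP recovery curve.

    ``time`` is in seconds relative to the bleach frame; ``ratio`` is the
    normalized bleached/control ratio whose first crossing of 0.5 defines
    t_half.  ``t_half`` is NaN until estimated (or if never reached).
    """

    time: np.ndarray
    bleached: np.ndarray      # min-max normalized bleached-region series
    control: np.ndarray       # normalized control-region series
    ratio: np.ndarray
    bleach_frame: int
    frame_interval: float
    t_half: float = np.nan
    t_half_frame: float = np.nan


def _region_mean(frames: np.ndarray, rect) -> np.ndarray:
    x0, y0, x1, y1 = rect
    return frames[..., y0:y1, x0:x1].mean(axis=(-2, -1))


def _minmax_with_guard(series: np.ndarray, bleach_frame: int,
                       rel_range: float = 0.05) -> np.ndarray:
    """Min-max normalize; near-constant series are scaled by their
    pre-bleach mean instead (min-max of pure noise is meaningless)."""
    lo, hi = series.min(), series.max()
    scale = max(abs(hi), abs(lo), 1e-30)
    if (hi - lo) < rel_range * scale:
        ref = series[:bleach_frame].mean() if bleach_frame > 0 \
            else series.mean()
        if abs(ref) < 1e-30:
            raise NormalizationError("region series is identically zero")
        return series / ref
    return (series - lo) / (hi - lo)


def frap_normalize(stack: ImageStack, bleach_rect, control_rect,
                   cytoplasm_level: float, bleach_frame: int = None
                   ) -> FRAPCurve:
    """Build the normalized FRAP curve from a (T[,Z],Y,X) movie.

    ``bleach_frame`` defaults to the frame with minimal raw bleached-region
    intensity.  Rectangles are (x0, y0, x1, y1) pixel boxes and must be
    disjoint.
    """
    if _rects_overlap(bleach_rect, control_rect):
        raise FRAPConfigError("bleach and control rectangles overlap")
    if not cytoplasm_level > 0:
        raise FRAPConfigError("cytoplasm_level must be > 0")
    data = np.asarray(stack.data, dtype=float)
    if data.ndim == 3:
        data = data[:, None]
    if data.ndim != 4:
        raise FRAPConfigError("expected a (T, Y, X) or (T, Z, Y, X) stack")

    sub = data - 0.5 * cytoplasm_level
    # per-frame slice weights from the control region
    wz = np.clip(_region_mean(sub, control_rect), 0.0, None)   # (T, Z)
    wsum = wz.sum(axis=1)
    if np.all(wsum <= 0):
        raise NormalizationError("control region carries no signal")
    wsum[wsum <= 0] = 1.0
    wz = wz / wsum[:, None]
    proj = (sub * wz[:, :, None, None]).sum(axis=1)            # (T, Y, X)

    raw_b = _region_mean(proj, bleach_rect)
    raw_c = _region_mean(proj, control_rect)
    if bleach_frame is None:
        bleach_frame = int(np.argmin(raw_b))

    bleached = _minmax_with_guard(raw_b, bleach_frame)
    control = _minmax_with_guard(raw_c, bleach_frame)

    # gain-invariant ratio: divide raw series first, then normalize
    safe_c = np.where(np.abs(raw_c) > 1e-30, raw_c, np.nan)
    ratio = _minmax_with_guard(raw_b / safe_c, bleach_frame)

    t = (np.arange(len(raw_b)) - bleach_frame) * stack.frame_interval
    return FRAPCurve(time=t, bleached=bleached, control=control, ratio=ratio,
                     bleach_frame=bleach_frame,
                     frame_interval=stack.frame_interval)


def estimate_half_time(curve: FRAPCurve) -> float:
    """First time (s, post-bleach) at which the ratio reaches 0.5.

    Linear interpolation between the bracketing frames; NaN sentinel when
    the ratio never reaches 0.5.  The frame-resolution crossing time is
    stored on the curve as ``t_half_frame``.
    """
    post = curve.time >= 0
    if post.sum() < 2:
        raise ValueError("need at least 2 post-bleach samples")
    t = curve.time[post]
    r = curve.ratio[post]
    if len(r) >= 3:
        # 3-frame moving average guards the first-crossing rule against
        # single-frame noise spikes; ends are kept as-is
        sm = r.copy()
        sm[1:-1] = (r[:-2] + r[1:-1] + r[2:]) / 3.0
        r = sm
    crossing = np.flatnonzero(r >= 0.5)
    if len(crossing) == 0:
        curve.t_half = np.nan
        curve.t_half_frame = np.nan
        return np.nan
    i = int(crossing[0])
    if i == 0:
        t_half = float(t[0])
    else:
        r0, r1 = r[i - 1], r[i]
        frac = (0.5 - r0) / (r1 - r0) if r1 > r0 else 1.0
        t_half = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    curve.t_half = t_half
    curve.t_half_frame = float(t[i])
    return t_half
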