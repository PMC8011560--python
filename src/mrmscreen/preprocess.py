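"""Smoothing, baseline correction and retention-time alignment.

Raw MRM traces carry instrument noise, slowly rising background from column
bleed, and run-to-run retention-time drift.  The correction sequence is
fixed: Savitzky-Golay smoothing, then windowed-quantile baseline subtraction,
then a rigid per-channel shift anchoring the injected standards to their
calibration retention times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .io_mrm import Chromatogram, require_same_grid


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay window geometry.

    ``half_width`` d gives a window of 2d+1 samples; ``poly_order`` N is the
    local least-squares polynomial order.  The defaults (d=5, N=3, an 11-point
    cubic) keep narrow, low-intensity peaks intact while suppressing
    point-to-point instrument noise.
    """

    half_width: int = 5
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.poly_order >= 2 * self.half_width + 1:
            raise ValueError("poly_order must be < window length 2*half_width+1")

    @property
    def window(self) -> int:
        return 2 * self.half_width + 1


@dataclass(frozen=True)
class BaselineConfig:
    """Windowed-quantile baseline estimation parameters.

    The trace is cut into consecutive windows of ``window`` samples; the
    ``quantile`` order statistic of each window becomes a baseline knot at the
    window's central retention time.  Defaults follow the 400-sample window
    and 0.05 quantile that work well for column-bleed backgrounds.
    """

    window: int = 400
    quantile: float = 0.05

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3 samples")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie strictly between 0 and 1")


def savgol_smooth(chrom: Chromatogram, cfg: SmoothingConfig | None = None) -> Chromatogram:
    """Savitzky-Golay smoothing of one trace.

    Each point is replaced by the centre value of the least-squares polynomial
    of order ``poly_order`` fitted over the surrounding 2d+1 samples.  Edges
    are handled by polynomial extension: the polynomial fitted to the first
    (last) full window is evaluated at the edge offsets.
    """
    cfg = cfg or SmoothingConfig()
    if len(chrom) <= cfg.window:
        raise ValueError(
            f"trace of {len(chrom)} points too short for window {cfg.window}"
        )
    smoothed = savgol_filter(
        chrom.intensity, window_length=cfg.window, polyorder=cfg.poly_order, mode="interp"
    )
    return chrom.with_intensity(smoothed)


def baseline_knots(
    intensity: np.ndarray, rt: np.ndarray, cfg: BaselineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed-quantile knots: (knot_rt, knot_value) arrays.

    Consecutive windows of ``cfg.window`` samples (the last may be short);
    one knot per window at the window's central rt, valued at the window's
    ``cfg.quantile`` order statistic (linear interpolation between order
    statistics).
    """
    n = intensity.size
    starts = np.arange(0, n, cfg.window)
    knot_rt = np.empty(starts.size)
    knot_val = np.empty(starts.size)
    for i, s in enumerate(starts):
        seg = intensity[s : s + cfg.window]
        center = s + (seg.size - 1) // 2
        knot_rt[i] = rt[center]
        knot_val[i] = np.quantile(seg, cfg.quantile)
    return knot_rt, knot_val


def estimate_baseline(chrom: Chromatogram, cfg: BaselineConfig | None = None) -> Chromatogram:
    """Estimate the slowly varying background of one trace.

    A shape-preserving (monotonicity-preserving) piecewise-cubic interpolant
    is drawn through the windowed-quantile knots and evaluated on the full
    grid, clipped below at zero.  The first and last knots are duplicated at
    the trace ends so the interpolant spans the whole grid without
    extrapolation.
    """
    cfg = cfg or BaselineConfig()
    if len(chrom) < cfg.window:
        raise ValueError(
            f"trace of {len(chrom)} points shorter than baseline window {cfg.window}"
        )
    knot_rt, knot_val = baseline_knots(chrom.intensity, chrom.rt, cfg)
    if knot_rt.size < 2:
        raise ValueError("need at least 2 baseline knots")
    # anchor the interpolant at the trace ends
    if knot_rt[0] > chrom.rt[0]:
        knot_rt = np.concatenate([[chrom.rt[0]], knot_rt])
        knot_val = np.concatenate([[knot_val[0]], knot_val])
    if knot_rt[-1] < chrom.rt[-1]:
        knot_rt = np.concatenate([knot_rt, [chrom.rt[-1]]])
        knot_val = np.concatenate([knot_val, [knot_val[-1]]])
    interp = PchipInterpolator(knot_rt, knot_val)
    baseline = np.clip(interp(chrom.rt), 0.0, None)
    return chrom.with_intensity(baseline)


def subtract_baseline(chrom: Chromatogram, baseline: Chromatogram) -> Chromatogram:
    """Subtract an estimated baseline, clipping negatives to zero.

    Clipping enforces the physical constraint that corrected relative
    intensities are nonnegative.
    """
    require_same_grid(chrom, baseline)
    return chrom.with_intensity(np.clip(chrom.intensity - baseline.intensity, 0.0, None))


def align_to_standards(
    chrom: Chromatogram,
    sample_standards: Sequence[float],
    calib_standards: Sequence[float],
) -> Chromatogram:
    """Rigidly shift one channel so its standard matches the calibration run.

    The offset is taken from the first listed standard of the channel:
    delta = calibration rt - sample rt.  Intensities are re-interpolated back
    onto the original retention-time grid, so a feature recorded at time t in
    the sample appears at t + delta afterwards.
    """
    if not len(sample_standards) or not len(calib_standards):
        raise KeyError("channel missing a standard in sample or calibration table")
    delta = float(calib_standards[0]) - float(sample_standards[0])
    if delta == 0.0:
        return chrom.with_intensity(chrom.intensity.copy())
    shifted = np.interp(
        chrom.rt - delta,
        chrom.rt,
        chrom.intensity,
        left=chrom.intensity[0],
        right=chrom.intensity[-1],
    )
    return chrom.with_intensity(shifted)


def preprocess_trace(
    chrom: Chromatogram,
    smoothing: SmoothingConfig | None = None,
    baseline: BaselineConfig | None = None,
    sample_standards: Sequence[float] | None = None,
    calib_standards: Sequence[float] | None = None,
) -> Chromatogram:
    """Full correction chain: smooth -> baseline-subtract -> align.

    Alignment is skipped when either standards list is omitted (e.g. for the
    calibration run itself, which defines the reference rt axis).
    """
    out = savgol_smooth(chrom, smoothing)
    out = subtract_baseline(out, estimate_baseline(out, baseline))
    if sample_standards is not None and calib_standards is not None:
        out = align_to_standards(out, sample_standards, calib_standards)
    return out
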