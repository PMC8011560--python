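"""Peak-region segmentation and iterative multi-Gaussian deconvolution.

Coelution merges neighbouring congener peaks into one chromatographic bump.
Each above-threshold region of a baseline-corrected trace is modelled as a
sum of Gaussians

    y(x) = sum_i  beta_i * exp(-((x - B_i) / c_i)^2)

fitted by bounded trust-region nonlinear least squares.  The number of
components starts at the count of calibration congeners expected in the
region and grows until the coefficient of determination (R^2, the
goodness of fit) exceeds a target, 0.90 by default.

The ``c`` parameter above follows the common curve-fitting convention; the
Gaussian standard deviation is sigma = c / sqrt(2), so a component's area is
beta * c * sqrt(pi) = beta * sigma * sqrt(2*pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .io_mrm import Chromatogram

_SQRT2 = math.sqrt(2.0)
_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class FittedPeak:
    """One Gaussian component of a deconvolved region.

    ``amplitude`` is the apex height beta (relative intensity), ``centroid``
    the apex retention time B in minutes, and ``width`` the fit parameter c
    in minutes (sigma = c/sqrt(2)).
    """

    amplitude: float
    centroid: float
    width: float
    channel_id: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be strictly positive")
        if self.width <= 0:
            raise ValueError("width must be strictly positive")

    @property
    def height(self) -> float:
        return self.amplitude

    @property
    def sigma(self) -> float:
        return self.width / _SQRT2

    @property
    def area(self) -> float:
        """Analytic integral: amplitude * width * sqrt(pi)."""
        return self.amplitude * self.width * _SQRT_PI

    @property
    def rt(self) -> float:
        return self.centroid


@dataclass(frozen=True)
class FitResult:
    """Outcome of iterative Gaussian fitting for one region."""

    peaks: tuple[FittedPeak, ...]
    gof: float
    converged: bool
    n_attempts: int = 1

    @property
    def n_components(self) -> int:
        return len(self.peaks)


def gaussian_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Evaluate a sum of Gaussians; params is [b1,B1,c1, b2,B2,c2, ...]."""
    p = np.asarray(params, dtype=float).reshape(-1, 3)
    out = np.zeros_like(x, dtype=float)
    for beta, b, c in p:
        out += beta * np.exp(-(((x - b) / c) ** 2))
    return out


def goodness_of_fit(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination R^2 = 1 - SSE/SST.

    Raises for a constant observed trace, where R^2 is undefined.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.size != fitted.size or observed.size < 2:
        raise ValueError("observed and fitted must share a length >= 2")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("goodness of fit undefined for a constant observed trace")
    sse = float(np.sum((observed - fitted) ** 2))
    return 1.0 - sse / sst


def detect_peak_regions(
    chrom: Chromatogram, min_height: float, min_gap: float
) -> list[tuple[float, float]]:
    """Segment a baseline-corrected trace into candidate peak regions.

    Returns sorted, disjoint half-open rt intervals where the intensity stays
    at or above ``min_height``, merging intervals separated by less than
    ``min_gap`` minutes.
    """
    mask = chrom.intensity >= min_height
    if not mask.any():
        return []
    step = chrom.grid_step
    regions: list[list[float]] = []
    idx = np.flatnonzero(mask)
    # contiguous runs of above-threshold samples
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_bounds = zip(
        np.concatenate([[0], breaks + 1]), np.concatenate([breaks, [idx.size - 1]])
    )
    for a, b in run_bounds:
        lo = chrom.rt[idx[a]]
        hi = chrom.rt[idx[b]] + step  # half-open end just past the last sample
        if regions and lo - regions[-1][1] < min_gap:
            regions[-1][1] = hi
        else:
            regions.append([lo, hi])
    return [(lo, hi) for lo, hi in regions]


def initial_component_count(
    region: tuple[float, float],
    calib,
    channel_id: int,
    rt_tolerance: float = 0.0,
) -> int:
    """Expected component count: calibration congeners near the region.

    Counts calibration entries on the channel whose retention time falls in
    [rt_start - tol, rt_end + tol]; at least 1 so a fit is always attempted.
    """
    lo, hi = region
    entries = calib.entries_for_channel(channel_id)
    count = int(
        ((entries["rt"] >= lo - rt_tolerance) & (entries["rt"] <= hi + rt_tolerance)).sum()
    )
    return max(count, 1)


def _initial_guess(
    x: np.ndarray, y: np.ndarray, n: int
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Deterministic start: centroids at the n tallest local maxima, extra
    centroids spread evenly over the signal's support (y >= 25% of max);
    amplitudes at the trace values there, widths from the support span."""
    span = x[-1] - x[0]
    step = float(np.median(np.diff(x)))
    ymax = max(float(y.max()), 1e-12)
    support = x[y >= 0.25 * ymax]
    s_lo = float(support[0]) if support.size else x[0]
    s_hi = float(support[-1]) if support.size else x[-1]
    s_span = max(s_hi - s_lo, 2 * step)
    peaks_idx, _ = find_peaks(y, height=0.0)
    order = np.argsort(y[peaks_idx])[::-1] if peaks_idx.size else np.array([], int)
    centroids = list(x[peaks_idx[order[:n]]])
    n_missing = n - len(centroids)
    if n_missing > 0:
        fillers = [s_lo + s_span * (k + 0.5) / n_missing for k in range(n_missing)]
        centroids.extend(fillers)
    centroids = sorted(centroids)
    c0 = max(s_span / (2.0 * n), step)
    p0 = []
    for b in centroids:
        amp = float(np.interp(b, x, y))
        p0.extend([max(amp, 1e-3 * ymax), b, c0])
    lower = np.tile([0.0, x[0], step], n)
    upper = np.tile([2.0 * ymax, x[-1], max(span, 2 * step)], n)
    return np.asarray(p0), (lower, upper)


def fit_gaussians(
    chrom: Chromatogram,
    region: tuple[float, float],
    n_start: int = 1,
    gof_target: float = 0.90,
    n_max: int = 6,
    amplitude_floor: float = 1e-3,
) -> FitResult:
    """Iteratively fit a region with a growing sum of Gaussians.

    Starting from ``n_start`` components, the model is refitted with one more
    component until the goodness of fit reaches ``gof_target`` or ``n_max``
    components have been tried; the first passing fit is returned, otherwise
    the best attempt with ``converged=False``.  Components whose amplitude
    falls below ``amplitude_floor`` times the region maximum are pruned.
    """
    lo, hi = region
    sel = (chrom.rt >= lo) & (chrom.rt < hi)
    x = chrom.rt[sel]
    y = chrom.intensity[sel]
    if x.size < 3 * n_start:
        raise ValueError(
            f"region has {x.size} samples; need at least {3 * n_start} for {n_start} components"
        )
    ymax = float(y.max()) if y.size else 0.0
    sst = float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0
    if ymax <= 0.0 or sst == 0.0:
        return FitResult(peaks=(), gof=-np.inf, converged=False, n_attempts=0)

    best_params: np.ndarray | None = None
    best_gof = -np.inf
    attempts = 0
    converged = False
    for n in range(n_start, n_max + 1):
        attempts += 1
        p0, bounds = _initial_guess(x, y, n)
        try:
            res = least_squares(
                lambda p: gaussian_sum(x, p) - y,
                p0,
                bounds=bounds,
                method="trf",
                max_nfev=400 * n,
            )
        except Exception:
            continue
        gof = goodness_of_fit(y, gaussian_sum(x, res.x))
        if gof > best_gof:
            best_gof = gof
            best_params = res.x
        if gof >= gof_target:
            converged = True
            break

    if best_params is None:
        return FitResult(peaks=(), gof=-np.inf, converged=False, n_attempts=attempts)

    kept = [
        (beta, b, c)
        for beta, b, c in np.asarray(best_params).reshape(-1, 3)
        if beta >= amplitude_floor * ymax and c > 0
    ]
    if kept:
        pruned = np.asarray(kept).ravel()
        best_gof = goodness_of_fit(y, gaussian_sum(x, pruned))
    peaks = tuple(
        FittedPeak(
            amplitude=float(beta),
            centroid=float(np.clip(b, x[0], x[-1])),
            width=float(c),
            channel_id=chrom.channel_id,
            sample_id=chrom.sample_id,
        )
        for beta, b, c in sorted(kept, key=lambda t: t[1])
    )
    return FitResult(peaks=peaks, gof=best_gof, converged=converged, n_attempts=attempts)


def fit_all_regions(
    chrom: Chromatogram,
    calib,
    min_height: float,
    min_gap: float,
    rt_tolerance: float = 0.05,
    gof_target: float = 0.90,
    n_max: int = 6,
) -> list[FitResult]:
    """Segment a trace and deconvolve every region, seeding each fit with the
    calibration-informed component count."""
    results = []
    for region in detect_peak_regions(chrom, min_height, min_gap):
        sel = (chrom.rt >= region[0]) & (chrom.rt < region[1])
        if int(sel.sum()) < 3:  # too narrow to be a credible peak
            continue
        n0 = initial_component_count(region, calib, chrom.channel_id, rt_tolerance)
        n0 = min(n0, max(int(sel.sum()) // 3, 1))
        results.append(
            fit_gaussians(chrom, region, n_start=n0, gof_target=gof_target, n_max=n_max)
        )
    return results
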