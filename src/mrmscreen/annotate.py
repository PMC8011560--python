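"""Target-peak selection, non-target screening and location templates.

After classification, several fitted peaks may share one congener class in a
sample.  The annotated (target) peak of the class is the one maximizing an
L2-norm score combining peak height, peak area and closeness in retention
time to the calibration retention time r_j:

    G = sqrt( (height/height_scale)^2 + (area/area_scale)^2
              + (1 / max(|t - r_j|, eps))^2 )

Height and area are rescaled (by the calibration run's maxima by default)
because the three terms carry incompatible units; the reciprocal
retention-time distance dominates for well-aligned peaks, matching the
intended priority on rt closeness, while height and area break ties between
heavily coeluted candidates.

Peaks classified to a class but never selected for it, recurring at one
retention time across many samples, are surfaced as candidate non-target
compounds.  Per-location signal templates average annotated-peak intensities
over a location's samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_mrm import CalibrationTable
from .peakfit import FittedPeak


@dataclass(frozen=True)
class AnnotatedPeak:
    """The selected target peak of one class in one sample."""

    class_id: int
    sample_id: str
    peak: FittedPeak
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be nonnegative")


@dataclass(frozen=True)
class NonTargetPeak:
    """A recurring co-classified peak that is never the annotated target."""

    associated_class_id: int
    mean_rt: float
    occurrence_fraction: float
    member_peaks: tuple[FittedPeak, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.occurrence_fraction <= 1.0:
            raise ValueError("occurrence_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class LocationTemplate:
    """Mean annotated-peak intensity per class at one sampling location."""

    location: str
    n_samples: int
    intensities: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("a template needs at least one sample")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("template intensities must be nonnegative")


def eq_l2_score(
    peak: FittedPeak,
    calib_rt: float,
    scaling: tuple[float, float],
    epsilon: float,
) -> float:
    """L2-norm selection score of one candidate peak for one class."""
    height_scale, area_scale = scaling
    if height_scale <= 0 or area_scale <= 0:
        raise ValueError("height and area scales must be strictly positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    dt = max(abs(peak.rt - calib_rt), epsilon)
    return math.sqrt(
        (peak.height / height_scale) ** 2
        + (peak.area / area_scale) ** 2
        + (1.0 / dt) ** 2
    )


def default_scaling(calibration_peaks: Sequence[FittedPeak]) -> tuple[float, float]:
    """Height/area scales from a calibration run's fitted peaks (their maxima)."""
    if not calibration_peaks:
        return (1.0, 1.0)
    return (
        max(p.height for p in calibration_peaks),
        max(p.area for p in calibration_peaks),
    )


def select_target_peaks(
    classified: Sequence[tuple[FittedPeak, int]],
    calib: CalibrationTable,
    scaling: tuple[float, float],
    epsilon: float,
) -> list[AnnotatedPeak]:
    """Pick the annotated target peak of every class present in one sample.

    For each class with at least one classified peak the score maximizer is
    selected; ties break deterministically by smaller |t - r_j|, then larger
    height, then lower retention time.
    """
    by_class: dict[int, list[FittedPeak]] = {}
    for peak, class_id in classified:
        by_class.setdefault(int(class_id), []).append(peak)
    out: list[AnnotatedPeak] = []
    for class_id in sorted(by_class):
        try:
            r_j = calib.rt_of(class_id)
        except KeyError:
            continue
        candidates = by_class[class_id]
        scored = [
            (
                eq_l2_score(p, r_j, scaling, epsilon),
                -abs(p.rt - r_j),
                p.height,
                -p.rt,
                p,
            )
            for p in candidates
        ]
        scored.sort(key=lambda t: t[:4], reverse=True)
        best_score, _, _, _, best = scored[0]
        sample_id = best.sample_id
        out.append(
            AnnotatedPeak(class_id=class_id, sample_id=sample_id, peak=best, score=best_score)
        )
    return out


def find_nontarget_peaks(
    classified_by_sample: Mapping[str, Sequence[tuple[FittedPeak, int]]],
    annotated: Sequence[AnnotatedPeak],
    rt_tolerance: float,
    min_occurrence: float,
) -> list[NonTargetPeak]:
    """Cluster residual co-classified peaks recurring across samples.

    Peaks classified to a class but not selected as its annotated peak are
    single-linkage clustered along retention time (link when consecutive rts
    are within ``rt_tolerance``), per class.  Clusters observed in at least
    ``min_occurrence`` of the samples are reported with their mean rt and
    distinct-sample occurrence fraction.
    """
    n_samples = len(classified_by_sample)
    if n_samples < 2:
        raise ValueError("non-target screening needs at least 2 samples")
    selected = {(a.sample_id, a.class_id, a.peak.rt) for a in annotated}
    residual: dict[int, list[tuple[float, str, FittedPeak]]] = {}
    for sample_id, pairs in classified_by_sample.items():
        for peak, class_id in pairs:
            if (sample_id, int(class_id), peak.rt) in selected:
                continue
            residual.setdefault(int(class_id), []).append((peak.rt, sample_id, peak))

    out: list[NonTargetPeak] = []
    for class_id in sorted(residual):
        members = sorted(residual[class_id], key=lambda t: t[0])
        cluster: list[tuple[float, str, FittedPeak]] = []
        clusters: list[list[tuple[float, str, FittedPeak]]] = []
        for item in members:
            if cluster and item[0] - cluster[-1][0] > rt_tolerance:
                clusters.append(cluster)
                cluster = []
            cluster.append(item)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            distinct = {sid for _, sid, _ in cl}
            occ = len(distinct) / n_samples
            if occ >= min_occurrence:
                out.append(
                    NonTargetPeak(
                        associated_class_id=class_id,
                        mean_rt=float(np.mean([rt for rt, _, _ in cl])),
                        occurrence_fraction=occ,
                        member_peaks=tuple(p for _, _, p in cl),
                    )
                )
    return out


def build_template(
    annotated: Sequence[AnnotatedPeak],
    location: str,
    sample_locations: Mapping[str, str],
    use_area: bool = False,
) -> LocationTemplate:
    """Average annotated-peak intensities over one location's samples.

    Per class, annotated heights (areas with ``use_area``) are summed over
    the location's samples and divided by the total number of samples at the
    location, so a class absent from a sample contributes zero.  Injected
    standards never appear here because only class-annotated peaks enter.
    """
    loc_samples = {sid for sid, loc in sample_locations.items() if loc == location}
    if not loc_samples:
        raise KeyError(f"no samples at location {location!r}")
    n = len(loc_samples)
    sums: dict[int, float] = {}
    for a in annotated:
        if a.sample_id in loc_samples:
            value = a.peak.area if use_area else a.peak.height
            sums[a.class_id] = sums.get(a.class_id, 0.0) + value
    return LocationTemplate(
        location=location,
        n_samples=n,
        intensities={cid: total / n for cid, total in sorted(sums.items())},
    )
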