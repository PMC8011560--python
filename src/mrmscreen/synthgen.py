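"""Seeded synthetic MRM chromatogram batches with full ground truth.

The generator emulates what the correction pipeline must undo in real
GC-MS/MS air-sample data: Gaussian congener peaks (possibly coeluted),
additive instrument noise, a drifting baseline with exponential column
bleed, a rigid per-sample retention-time shift, and tall injected standard
peaks shared by every channel.  A noise-free, shift-free calibration run
accompanies each batch so target retention times are exact.

Intensities are arbitrary relative units.  Every simulated component is
recorded in the ground truth so tests can score recovery exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classify import LabeledPeak, PeakFeatureVector
from .io_mrm import (
    CALIBRATION_OWNER,
    CalibrationTable,
    Chromatogram,
    SampleMeta,
    StandardTable,
)
from .peakfit import FittedPeak

LOCATIONS = ("Addams", "Metcalfe", "St. Sabina", "Rey Gonzales")


@dataclass(frozen=True)
class TruePeak:
    """Ground-truth target congener peak (calibration-frame parameters)."""

    class_id: int
    channel_id: int
    rt: float
    height: float
    width: float  # Gaussian c parameter, minutes


@dataclass(frozen=True)
class Interferent:
    """A planted non-target peak recurring across samples."""

    channel_id: int
    rt: float
    height: float
    width: float = 0.03
    occurrence: float = 0.9  # fraction of samples carrying the peak


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated batch.

    Twelve MRM channels per sample mirror a typical congener-group
    acquisition (ten homolog transitions plus two labelled-standard
    transitions); the 0-40 min grid at 0.005 min steps gives 8001 points per
    trace.  ``noise_sd`` of 10 against target heights of 200+ keeps peak SNR
    at 20 or better; drift up to +/-0.3 min is the rigid shift range typical
    of run-to-run column variation.
    """

    n_samples: int = 10
    n_channels: int = 12
    rt_start: float = 0.0
    rt_stop: float = 40.0
    rt_step: float = 0.005
    peaks: tuple[TruePeak, ...] = ()
    standard_rts: tuple[float, float, float] = (5.0, 20.0, 35.0)
    standard_height: float = 5000.0
    standard_width: float = 0.03
    noise_sd: float = 10.0
    drift_range: tuple[float, float] = (-0.3, 0.3)
    baseline_slope: float = 2.0  # intensity units per minute
    bleed_amplitude: float = 60.0
    bleed_rate: float = 0.06  # per minute, exponential column bleed
    interferents: tuple[Interferent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_step <= 0:
            raise ValueError("rt_step must be positive")
        if self.n_samples < 1 or self.n_channels < 1:
            raise ValueError("need at least one sample and one channel")
        lo, hi = self.rt_start, self.rt_stop
        for p in self.peaks:
            if not lo <= p.rt <= hi:
                raise ValueError(f"true peak rt {p.rt} outside the grid")
            if p.height <= self.noise_sd:
                raise ValueError("true peak heights must exceed the noise level")

    @property
    def rt_grid(self) -> np.ndarray:
        n = int(round((self.rt_stop - self.rt_start) / self.rt_step)) + 1
        return self.rt_start + self.rt_step * np.arange(n)


def default_target_peaks(n_channels: int = 12, per_channel: int = 3) -> tuple[TruePeak, ...]:
    """Deterministic target layout: ``per_channel`` congeners per channel.

    Retention times are staggered per channel and kept clear of the injected
    standards; heights and widths cycle over realistic ranges (heights
    200-700, widths 0.02-0.04 min).
    """
    base_rts = (8.0, 14.0, 25.0)
    peaks = []
    class_id = 1
    for ch in range(1, n_channels + 1):
        for k in range(per_channel):
            rt = base_rts[k % 3] + 0.4 * (ch - 1) + 1.3 * (k // 3)
            height = 200.0 + 50.0 * ((ch * 7 + k * 13) % 11)
            width = 0.022 + 0.004 * ((ch + k) % 5)
            peaks.append(
                TruePeak(class_id=class_id, channel_id=ch, rt=rt, height=height, width=width)
            )
            class_id += 1
    return tuple(peaks)


def default_sim_config(seed: int = 0, n_samples: int = 10, n_channels: int = 12) -> SimConfig:
    """The batch conditions used throughout the package's own studies.

    Includes one planted interferent trailing the first congener of channel 1
    by 0.12 min at 90% occurrence, mimicking a co-classified non-target
    contaminant.
    """
    peaks = default_target_peaks(n_channels)
    first = peaks[0]
    interferent = Interferent(
        channel_id=first.channel_id,
        rt=first.rt + 0.12,
        height=150.0,
        width=0.025,
        occurrence=0.9,
    )
    return SimConfig(
        n_samples=n_samples,
        n_channels=n_channels,
        peaks=peaks,
        interferents=(interferent,),
        seed=seed,
    )


@dataclass(frozen=True)
class PlacedPeak:
    """One realized peak in one sample trace (sample-frame rt)."""

    sample_id: str
    channel_id: int
    rt: float
    height: float
    width: float
    kind: str  # "target" | "standard" | "interferent"
    class_id: int | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Complete record of everything the generator put into a batch."""

    shifts: dict[str, float]
    placements: tuple[PlacedPeak, ...]

    def targets_of(self, sample_id: str) -> list[PlacedPeak]:
        return [
            p for p in self.placements if p.sample_id == sample_id and p.kind == "target"
        ]

    def interferents_of(self, sample_id: str) -> list[PlacedPeak]:
        return [
            p
            for p in self.placements
            if p.sample_id == sample_id and p.kind == "interferent"
        ]


@dataclass(frozen=True)
class SimBatch:
    """A simulated batch: sample traces, tables, calibration run and truth."""

    samples: dict[str, list[Chromatogram]]
    sample_meta: dict[str, SampleMeta]
    calibration: list[Chromatogram]
    standards: StandardTable
    calibration_table: CalibrationTable
    truth: GroundTruth


def _gaussian(x: np.ndarray, height: float, rt: float, width: float) -> np.ndarray:
    return height * np.exp(-(((x - rt) / width) ** 2))


def _baseline(x: np.ndarray, cfg: SimConfig) -> np.ndarray:
    return cfg.baseline_slope * (x - cfg.rt_start) + cfg.bleed_amplitude * (
        np.exp(cfg.bleed_rate * (x - cfg.rt_start)) - 1.0
    )


def simulate_batch(cfg: SimConfig) -> SimBatch:
    """Generate one seeded batch of MRM samples with ground truth.

    Each channel trace is the sum of its true Gaussians, the baseline and
    Gaussian noise, with one rigid retention-time shift per sample applied
    to peaks and standards alike.  Standards are emitted into the standards
    table at their shifted (as-recorded) retention times; the calibration
    run is generated noise-free, shift-free and baseline-free.  Identical
    seeds give bit-identical batches.
    """
    rng = np.random.default_rng(cfg.seed)
    peaks = cfg.peaks if cfg.peaks else default_target_peaks(cfg.n_channels)
    x = cfg.rt_grid

    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    meta = {
        sid: SampleMeta(
            sample_id=sid,
            location=LOCATIONS[i % len(LOCATIONS)],
            date=_dt.date(2007, 1, 1) + _dt.timedelta(days=30 * i),
        )
        for i, sid in enumerate(sample_ids)
    }

    shifts = {
        sid: float(rng.uniform(cfg.drift_range[0], cfg.drift_range[1]))
        for sid in sample_ids
    }

    # interferent occurrence realized exactly: round(occ * n) samples each
    interferent_carriers: list[set[str]] = []
    for itf in cfg.interferents:
        n_carry = int(round(itf.occurrence * cfg.n_samples))
        carriers = set(rng.choice(sample_ids, size=n_carry, replace=False))
        interferent_carriers.append(carriers)

    placements: list[PlacedPeak] = []
    samples: dict[str, list[Chromatogram]] = {}
    std_rows: list[tuple[str, int, float]] = []

    by_channel: dict[int, list[TruePeak]] = {}
    for p in peaks:
        by_channel.setdefault(p.channel_id, []).append(p)

    for sid in sample_ids:
        delta = shifts[sid]
        traces: list[Chromatogram] = []
        for ch in range(1, cfg.n_channels + 1):
            signal = _baseline(x, cfg).copy()
            for p in by_channel.get(ch, []):
                rt_s = p.rt + delta
                signal += _gaussian(x, p.height, rt_s, p.width)
                placements.append(
                    PlacedPeak(
                        sample_id=sid,
                        channel_id=ch,
                        rt=rt_s,
                        height=p.height,
                        width=p.width,
                        kind="target",
                        class_id=p.class_id,
                    )
                )
            for std_rt in cfg.standard_rts:
                rt_s = std_rt + delta
                signal += _gaussian(x, cfg.standard_height, rt_s, cfg.standard_width)
                std_rows.append((sid, ch, rt_s))
                placements.append(
                    PlacedPeak(
                        sample_id=sid,
                        channel_id=ch,
                        rt=rt_s,
                        height=cfg.standard_height,
                        width=cfg.standard_width,
                        kind="standard",
                    )
                )
            for itf, carriers in zip(cfg.interferents, interferent_carriers):
                if itf.channel_id == ch and sid in carriers:
                    rt_s = itf.rt + delta
                    signal += _gaussian(x, itf.height, rt_s, itf.width)
                    placements.append(
                        PlacedPeak(
                            sample_id=sid,
                            channel_id=ch,
                            rt=rt_s,
                            height=itf.height,
                            width=itf.width,
                            kind="interferent",
                        )
                    )
            signal = signal + rng.normal(0.0, cfg.noise_sd, size=x.size)
            traces.append(
                Chromatogram(rt=x.copy(), intensity=signal, channel_id=ch, sample=meta[sid])
            )
        samples[sid] = traces

    # calibration run: exact peaks and standards, no noise/shift/baseline
    calibration: list[Chromatogram] = []
    calib_rows: list[tuple[int, str, int, float]] = []
    for ch in range(1, cfg.n_channels + 1):
        signal = np.zeros_like(x)
        for p in by_channel.get(ch, []):
            signal += _gaussian(x, p.height, p.rt, p.width)
            calib_rows.append((p.class_id, f"PCB {p.class_id}", ch, p.rt))
        for std_rt in cfg.standard_rts:
            signal += _gaussian(x, cfg.standard_height, std_rt, cfg.standard_width)
            std_rows.append((CALIBRATION_OWNER, ch, std_rt))
        calibration.append(Chromatogram(rt=x.copy(), intensity=signal, channel_id=ch))

    calib_rows.sort(key=lambda r: r[0])
    return SimBatch(
        samples=samples,
        sample_meta=meta,
        calibration=calibration,
        standards=StandardTable.from_rows(std_rows),
        calibration_table=CalibrationTable.from_rows(calib_rows),
        truth=GroundTruth(shifts=shifts, placements=tuple(placements)),
    )


def simulate_coeluted_region(
    seed: int = 0,
    separation_widths: float = 1.5,
    snr: float = 20.0,
    rt_step: float = 0.005,
) -> tuple[Chromatogram, tuple[TruePeak, TruePeak]]:
    """A single region holding two overlapping Gaussians plus noise.

    The centroid separation is ``separation_widths`` times the Gaussian width
    parameter and the additive noise standard deviation is the smaller peak
    height divided by ``snr``.  Used to exercise the iterative fitter's
    goodness-of-fit stopping rule on a genuinely coeluted pair.
    """
    rng = np.random.default_rng(seed)
    width = float(rng.uniform(0.03, 0.06))
    rt_a = 10.0
    rt_b = rt_a + separation_widths * width
    h_a = float(rng.uniform(300.0, 900.0))
    h_b = float(rng.uniform(0.4, 0.9)) * h_a
    noise_sd = min(h_a, h_b) / snr
    x = np.arange(rt_a - 12 * width, rt_b + 12 * width, rt_step)
    y = (
        _gaussian(x, h_a, rt_a, width)
        + _gaussian(x, h_b, rt_b, width)
        + rng.normal(0.0, noise_sd, size=x.size)
    )
    chrom = Chromatogram(rt=x, intensity=np.clip(y, 0.0, None), channel_id=1)
    truth = (
        TruePeak(class_id=1, channel_id=1, rt=rt_a, height=h_a, width=width),
        TruePeak(class_id=2, channel_id=1, rt=rt_b, height=h_b, width=width),
    )
    return chrom, truth


def separable_feature_benchmark(
    n_classes: int,
    n_per_class: int,
    separation: float,
    seed: int = 0,
    n_channels: int = 12,
) -> list[LabeledPeak]:
    """Gaussian feature clouds with controllable class separation.

    Class means sit on a 3-D lattice with spacing ``separation`` (in units of
    the unit within-class standard deviation) in retention-time-difference
    space; the channel feature is drawn uniformly at random, independent of
    class, so at separation 0 the features carry no class information at all.
    With separation >= 10 the clouds are effectively disjoint and a
    nearest-mean rule is better than 99% accurate by construction.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n_classes ** (1.0 / 3.0)))
    coords = [
        (i, j, k) for i in range(side + 1) for j in range(side + 1) for k in range(side + 1)
    ][:n_classes]
    out: list[LabeledPeak] = []
    idx = 0
    for class_id, coord in enumerate(coords, start=1):
        mean = separation * np.asarray(coord, dtype=float)
        for _ in range(n_per_class):
            drt = mean + rng.standard_normal(3)
            channel = int(rng.integers(1, n_channels + 1))
            source = FittedPeak(
                amplitude=1.0,
                centroid=10.0,
                width=0.03,
                channel_id=channel,
                sample_id=f"bench-{idx:05d}",
            )
            out.append(
                LabeledPeak(
                    features=PeakFeatureVector(
                        drt1=float(drt[0]),
                        drt2=float(drt[1]),
                        drt3=float(drt[2]),
                        channel_id=channel,
                    ),
                    label=class_id,
                    source_peak=source,
                )
            )
            idx += 1
    return out
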