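"""Readers, writers and containers for MRM chromatograms and annotation tables.

An MRM (multiple reaction monitoring) acquisition yields one selective
chromatogram per monitored precursor->product mass transition.  The total ion
chromatogram (TIC) is the elementwise sum of the per-transition traces.  This
module holds the plain-trace data model used throughout the package: a
chromatogram is a strictly increasing retention-time grid (minutes) paired
with relative-intensity values, tagged with an integer transition channel and
optional sample metadata.

CSV is the canonical interchange format; mzML reading is a convenience for
instrument exports that carry SRM/MRM chromatogram entries.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GridMismatchError,
    LengthMismatchError,
    NonMonotoneRTError,
    ParseError,
)

#: Reserved channel id for the accumulated total ion chromatogram.
TIC_CHANNEL = -1

#: Owner key identifying the calibration run in a standards table.
CALIBRATION_OWNER = "calibration"


@dataclass(frozen=True)
class SampleMeta:
    """Identity and provenance of one field sample."""

    sample_id: str
    location: str = ""
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")


@dataclass(frozen=True)
class Chromatogram:
    """One transition channel's retention-time/intensity trace.

    Parameters
    ----------
    rt
        Strictly increasing retention-time grid, in minutes.
    intensity
        Relative intensities, same length as ``rt``.
    channel_id
        Integer MRM transition index; ``TIC_CHANNEL`` marks an accumulated TIC.
    sample
        Metadata of the originating sample, or ``None`` for a calibration run.
    """

    rt: np.ndarray
    intensity: np.ndarray
    channel_id: int
    sample: SampleMeta | None = None

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", intensity)
        if rt.ndim != 1 or intensity.ndim != 1:
            raise ParseError("rt and intensity must be one-dimensional")
        if rt.size != intensity.size:
            raise LengthMismatchError(
                f"rt has {rt.size} points but intensity has {intensity.size}"
            )
        if rt.size < 2:
            raise ParseError("a chromatogram needs at least 2 points")
        if not np.all(np.diff(rt) > 0):
            raise NonMonotoneRTError("retention-time grid must be strictly increasing")
        if not np.all(np.isfinite(intensity)) or not np.all(np.isfinite(rt)):
            raise ParseError("rt and intensity values must be finite")

    def __len__(self) -> int:
        return int(self.rt.size)

    @property
    def grid_step(self) -> float:
        """Median grid spacing in minutes."""
        return float(np.median(np.diff(self.rt)))

    @property
    def sample_id(self) -> str:
        return self.sample.sample_id if self.sample is not None else CALIBRATION_OWNER

    def with_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        """Copy of this trace with a replaced intensity array."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))


def _same_grid(a: Chromatogram, b: Chromatogram) -> bool:
    return a.rt.shape == b.rt.shape and np.allclose(a.rt, b.rt, rtol=0.0, atol=1e-12)


def require_same_grid(a: Chromatogram, b: Chromatogram) -> None:
    if not _same_grid(a, b):
        raise GridMismatchError(
            f"channels {a.channel_id} and {b.channel_id} are not on one rt grid"
        )


# ---------------------------------------------------------------------------
# chromatogram I/O
# ---------------------------------------------------------------------------

def read_chromatogram(
    path: str | Path,
    dialect: str = "csv",
    channel_id: int = 0,
    sample: SampleMeta | None = None,
) -> Chromatogram:
    """Read a single chromatogram from ``path``.

    The ``csv`` dialect expects a two-column ``rt,intensity`` file with a
    header; ``mzml`` extracts the first SRM/MRM chromatogram trace (use
    :func:`read_mzml_chromatograms` for all transitions of a file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        if not {"rt", "intensity"}.issubset(df.columns):
            raise ParseError(f"{path}: expected 'rt,intensity' header")
        return Chromatogram(
            rt=df["rt"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            channel_id=channel_id,
            sample=sample,
        )
    if dialect == "mzml":
        traces = read_mzml_chromatograms(path, sample=sample)
        if not traces:
            raise ParseError(f"{path}: no SRM/MRM chromatogram entries")
        return traces[0]
    raise ValueError(f"unknown dialect {dialect!r}")


def _decode_binary_array(elem) -> tuple[str | None, str | None, np.ndarray]:
    """Decode one mzML ``binaryDataArray``: (array kind, time unit, values)."""
    import base64
    import zlib

    dtype = np.float64
    compressed = False
    kind: str | None = None
    unit: str | None = None
    payload = b""
    for child in elem:
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000523":
                dtype = np.float64
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000595":
                kind = "time"
                unit = child.get("unitName")
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            payload = base64.b64decode(child.text or "")
    if compressed:
        payload = zlib.decompress(payload)
    return kind, unit, np.frombuffer(payload, dtype=dtype).astype(float)


def read_mzml_chromatograms(
    path: str | Path, sample: SampleMeta | None = None
) -> list[Chromatogram]:
    """Extract every chromatogram trace of an mzML file, one per transition.

    A minimal reader for the mzML ``chromatogramList`` section (64/32-bit
    float arrays, zlib or no compression).  Time arrays declared in seconds
    are converted to minutes.  The TIC entry, when present, is tagged with
    ``TIC_CHANNEL``; SRM transitions are numbered in file order starting
    at 1.
    """
    from lxml import etree

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = etree.parse(str(path))
    out: list[Chromatogram] = []
    n_srm = 0
    for chrom in tree.iter("{*}chromatogram"):
        time = inten = None
        time_unit = None
        is_tic = "TIC" in (chrom.get("id") or "")
        for cv in chrom.iterchildren("{*}cvParam"):
            if cv.get("accession") == "MS:1000235":  # total ion current chromatogram
                is_tic = True
        for arr in chrom.iter("{*}binaryDataArray"):
            kind, unit, values = _decode_binary_array(arr)
            if kind == "time":
                time, time_unit = values, unit
            elif kind == "intensity":
                inten = values
        if time is None or inten is None:
            raise ParseError(f"{path}: chromatogram entry without time/intensity arrays")
        if time_unit and "second" in time_unit:
            time = time / 60.0
        if is_tic:
            cid = TIC_CHANNEL
        else:
            n_srm += 1
            cid = n_srm
        out.append(Chromatogram(rt=time, intensity=inten, channel_id=cid, sample=sample))
    return out


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    """Write a trace as the canonical two-column CSV."""
    pd.DataFrame({"rt": chrom.rt, "intensity": chrom.intensity}).to_csv(
        path, index=False
    )


def accumulate_tic(channels: Sequence[Chromatogram]) -> Chromatogram:
    """Sum per-transition MRM traces into the total ion chromatogram.

    All channels must share one retention-time grid; no resampling is done
    here (readers are responsible for putting a sample onto one grid).
    """
    if not channels:
        raise ValueError("need at least one channel")
    first = channels[0]
    total = np.zeros_like(first.intensity)
    for ch in channels:
        require_same_grid(first, ch)
        total = total + ch.intensity
    return Chromatogram(
        rt=first.rt.copy(), intensity=total, channel_id=TIC_CHANNEL, sample=first.sample
    )


def regrid_sample(channels: Sequence[Chromatogram]) -> list[Chromatogram]:
    """Resample a sample's channels onto the grid of its first channel.

    Linear interpolation; a warning is logged when any grid differs.  After
    this every channel shares one index, as TIC accumulation requires.
    """
    import logging

    if not channels:
        return []
    ref = channels[0]
    out = [ref]
    for ch in channels[1:]:
        if _same_grid(ref, ch):
            out.append(ch)
        else:
            logging.getLogger(__name__).warning(
                "resampling channel %d onto the grid of channel %d",
                ch.channel_id,
                ref.channel_id,
            )
            out.append(
                Chromatogram(
                    rt=ref.rt.copy(),
                    intensity=np.interp(ref.rt, ch.rt, ch.intensity),
                    channel_id=ch.channel_id,
                    sample=ch.sample,
                )
            )
    return out


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_transition_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read an MRM mass-transition table (one row per Cl homolog group).

    With no ``path`` the packaged table of the ten PCB homolog transitions is
    returned.  Columns: ``cl_homolog``, ``precursor_mz``, ``product_mz``.
    """
    if path is None:
        with resources.files("mrmscreen.data").joinpath("transitions.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path)
    expected = ["cl_homolog", "precursor_mz", "product_mz"]
    if list(df.columns) != expected:
        raise ParseError(f"expected columns {expected}, got {list(df.columns)}")
    if df["cl_homolog"].duplicated().any():
        raise ParseError("duplicate cl_homolog values")
    if (df[["precursor_mz", "product_mz"]] <= 0).any().any():
        raise ParseError("mass-to-charge values must be positive")
    return df


@dataclass(frozen=True)
class CalibrationTable:
    """Known target congeners: class id, label, channel, calibration rt.

    Each row fixes the retention time r_j at which congener class j elutes in
    the calibration run, on one MRM channel.  Class ids are the semantic key
    (class 1 = target congener 1); labels are free text.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        expected = ["class_id", "congener_label", "channel_id", "rt"]
        if list(self.table.columns) != expected:
            raise ParseError(f"expected columns {expected}")
        if self.table["class_id"].duplicated().any():
            raise ParseError("duplicate class_id values")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def class_ids(self) -> list[int]:
        return [int(c) for c in self.table["class_id"]]

    def rt_of(self, class_id: int) -> float:
        row = self.table[self.table["class_id"] == class_id]
        if row.empty:
            raise KeyError(f"class {class_id} not in calibration table")
        return float(row["rt"].iloc[0])

    def channel_of(self, class_id: int) -> int:
        row = self.table[self.table["class_id"] == class_id]
        if row.empty:
            raise KeyError(f"class {class_id} not in calibration table")
        return int(row["channel_id"].iloc[0])

    def entries_for_channel(self, channel_id: int) -> pd.DataFrame:
        return self.table[self.table["channel_id"] == channel_id]

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[int, str, int, float]]
    ) -> "CalibrationTable":
        return cls(
            pd.DataFrame(
                rows, columns=["class_id", "congener_label", "channel_id", "rt"]
            )
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "CalibrationTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class StandardTable:
    """Retention times of the injected standards, per owner and channel.

    Standards are high-intensity known compounds spiked into every sample;
    their recorded apex retention times anchor the rigid per-channel
    retention-time alignment.  ``owner_id`` is either a sample id or the
    reserved ``"calibration"`` key.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        expected = ["owner_id", "channel_id", "rt"]
        if list(self.table.columns) != expected:
            raise ParseError(f"expected columns {expected}")

    def rts(self, owner_id: str, channel_id: int) -> list[float]:
        sel = self.table[
            (self.table["owner_id"] == owner_id)
            & (self.table["channel_id"] == channel_id)
        ]
        if sel.empty:
            raise KeyError(f"no standards for owner {owner_id!r} channel {channel_id}")
        return [float(r) for r in sel["rt"]]

    def owners(self) -> list[str]:
        return sorted(self.table["owner_id"].unique())

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, float]]) -> "StandardTable":
        return cls(pd.DataFrame(rows, columns=["owner_id", "channel_id", "rt"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "StandardTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
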