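"""Centroid peak-list and spot-manifest I/O.

A MALDI spot is represented by its centroid peak list: one (m/z, intensity)
pair per detected peak, exported by the instrument software as a two-column
comma-delimited text file with an optional header line.  A spot manifest ties
peak-list files to class labels (positive/negative), roles (train/score) and
acquisition modes (intact/digested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("intact", "digested")
LABELS = ("positive", "negative")
ROLES = ("train", "score")

MANIFEST_COLUMNS = ("spot_id", "file", "label", "role", "mode")


class PeakListParseError(ValueError):
    """Raised when a peak-list file cannot be parsed."""


class Peak(NamedTuple):
    """A single centroid peak: m/z in Da (singly-charged assumption) and
    intensity in arbitrary signal units."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class PeakList:
    """One MALDI spot's centroid peaks, strictly sorted ascending by m/z.

    Duplicate m/z rows are merged keeping the maximum intensity, so the
    representation is idempotent and order-independent.
    """

    spot_id: str
    mode: str
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and mz.min() <= 0:
            raise ValueError("all m/z values must be > 0")
        if intensity.size and intensity.min() < 0:
            raise ValueError("all intensities must be >= 0")
        mz, intensity = _merge_sorted(mz, intensity)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.mz.size

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @classmethod
    def from_peaks(cls, spot_id: str, mode: str, peaks: Iterable[tuple[float, float]]) -> "PeakList":
        pairs = list(peaks)
        mz = np.array([p[0] for p in pairs], dtype=float)
        inten = np.array([p[1] for p in pairs], dtype=float)
        return cls(spot_id=spot_id, mode=mode, mz=mz, intensity=inten)


def _merge_sorted(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and merge exact duplicate m/z values by max intensity."""
    if mz.size == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size == mz.size:
        return mz, intensity
    merged = np.full(uniq.size, -np.inf)
    np.maximum.at(merged, inverse, intensity)
    return uniq, merged


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_peaklist(path: str | Path, mode: str, spot_id: str | None = None) -> PeakList:
    """Read a comma-delimited centroid peak list.

    Rows are ``mz,intensity``; a single non-numeric first row is treated as a
    header; blank lines are skipped; extra columns are ignored with a warning.
    """
    path = Path(path)
    if spot_id is None:
        spot_id = path.stem
    mzs: list[float] = []
    intens: list[float] = []
    warned_extra = False
    with open(path, "r", encoding="utf-8") as fh:
        first_data_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if not first_data_seen and not _looks_numeric(fields[0]):
                first_data_seen = True  # header line
                continue
            first_data_seen = True
            if len(fields) < 2:
                raise PeakListParseError(
                    f"{path}: line {lineno}: expected 'mz,intensity', got {line!r}"
                )
            if len(fields) > 2 and not warned_extra:
                logger.warning("%s: line %d has extra columns; ignoring them", path, lineno)
                warned_extra = True
            try:
                mz = float(fields[0])
                inten = float(fields[1])
            except ValueError as exc:
                raise PeakListParseError(
                    f"{path}: line {lineno}: non-numeric data row {line!r}"
                ) from exc
            if mz <= 0:
                raise ValueError(f"{path}: line {lineno}: m/z must be > 0 (got {mz})")
            if inten < 0:
                raise ValueError(
                    f"{path}: line {lineno}: intensity must be >= 0 (got {inten})"
                )
            mzs.append(mz)
            intens.append(inten)
    if not mzs:
        logger.warning("%s: empty peak list", path)
    return PeakList(spot_id=spot_id, mode=mode, mz=np.array(mzs), intensity=np.array(intens))


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    """Write a peak list in the two-column CSV dialect (round-trip exact)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(pl.mz, pl.intensity):
            # repr of a Python float is shortest round-trip exact
            fh.write(f"{float(m)!r},{float(i)!r}\n")


@dataclass(frozen=True)
class ManifestEntry:
    spot_id: str
    file: Path
    label: str
    role: str
    mode: str


@dataclass(frozen=True)
class SpotManifest:
    """Validated mapping of spot files to class labels and train/score roles."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.spot_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate spot_id(s) in manifest: {sorted(dupes)}")
        for e in self.entries:
            if e.label not in LABELS:
                raise ValueError(f"spot {e.spot_id}: unknown label {e.label!r}")
            if e.role not in ROLES:
                raise ValueError(f"spot {e.spot_id}: unknown role {e.role!r}")
            if e.mode not in MODES:
                raise ValueError(f"spot {e.spot_id}: unknown mode {e.mode!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def select(self, role: str | None = None, mode: str | None = None,
               label: str | None = None) -> list[ManifestEntry]:
        out = list(self.entries)
        if role is not None:
            out = [e for e in out if e.role == role]
        if mode is not None:
            out = [e for e in out if e.mode == mode]
        if label is not None:
            out = [e for e in out if e.label == label]
        return out

    def counts(self) -> dict[tuple[str, str, str], int]:
        """Counts per (mode, role, label)."""
        out: dict[tuple[str, str, str], int] = {}
        for e in self.entries:
            key = (e.mode, e.role, e.label)
            out[key] = out.get(key, 0) + 1
        return out


def read_manifest(path: str | Path, check_files: bool = True) -> SpotManifest:
    """Read and validate a manifest CSV with columns spot_id,file,label,role,mode.

    File paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    base = path.parent
    entries = []
    for row in df.itertuples(index=False):
        fpath = Path(getattr(row, "file"))
        if not fpath.is_absolute():
            fpath = base / fpath
        entries.append(
            ManifestEntry(
                spot_id=str(row.spot_id),
                file=fpath,
                label=str(row.label),
                role=str(row.role),
                mode=str(row.mode),
            )
        )
    manifest = SpotManifest(entries=tuple(entries))
    if check_files:
        absent = [str(e.file) for e in manifest.entries if not e.file.exists()]
        if absent:
            raise FileNotFoundError(
                f"{path}: {len(absent)} referenced file(s) missing, e.g. {absent[0]}"
            )
    for (mode, role, label), n in sorted(manifest.counts().items()):
        logger.info("manifest %s: %s/%s/%s -> %d spots", path.name, mode, role, label, n)
    return manifest


def write_manifest(manifest: SpotManifest, path: str | Path,
                   relative_to: str | Path | None = None) -> None:
    path = Path(path)
    rows = []
    for e in manifest.entries:
        f = e.file
        if relative_to is not None:
            try:
                f = f.relative_to(relative_to)
            except ValueError:
                pass
        rows.append((e.spot_id, str(f), e.label, e.role, e.mode))
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)


def load_peaklists(manifest: SpotManifest,
                   entries: Sequence[ManifestEntry] | None = None) -> list[PeakList]:
    """Read the peak lists for the given entries (default: all)."""
    entries = list(manifest.entries) if entries is None else list(entries)
    return [read_peaklist(e.file, mode=e.mode, spot_id=e.spot_id) for e in entries]
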