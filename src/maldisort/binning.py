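"""Fixed m/z binning of centroid peaks and feature-table construction.

The mass axis is divided into ordered, non-overlapping ranges.  Within each
range, bin centers are anchored at the range start and step by the range's
center spacing (dM); a peak is assigned to the nearest center of its
containing range iff it lies within half the bin width (the tolerance) of
that center.  Exact midpoint ties go to the lower center.  The set of bin
labels is fixed by the scheme alone, so feature tables built from disjoint
data always share an identical column set — the property the downstream
classifier relies on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peaklist_io import PeakList, SpotManifest, read_peaklist

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinSpec:
    """One mass range: [start, end) in Da, full bin width (tolerance) in Da,
    and spacing between adjacent bin centers (dM) in Da."""

    range_start: float
    range_end: float
    width: float
    spacing: float

    def __post_init__(self) -> None:
        if not self.range_start < self.range_end:
            raise ValueError("range_start must be < range_end")
        if self.width <= 0 or self.spacing <= 0:
            raise ValueError("width and spacing must be > 0")

    @property
    def n_centers(self) -> int:
        # centers are range_start + k*spacing for k >= 0 with center < range_end
        return int(math.ceil((self.range_end - self.range_start) / self.spacing - 1e-9))

    def centers(self) -> np.ndarray:
        return self.range_start + self.spacing * np.arange(self.n_centers)


def _format_center(center: float, spacing: float) -> str:
    if float(center).is_integer() and float(spacing).is_integer():
        return str(int(center))
    # enough decimals to be unique at this spacing
    decimals = max(0, -int(math.floor(math.log10(spacing))))
    return f"{center:.{decimals}f}"


@dataclass(frozen=True)
class BinningScheme:
    """Ordered, non-overlapping bin ranges defining a fixed feature space.

    ``mode`` tags which acquisition mode the scheme is meant for ("intact" or
    "digested"); None for custom schemes.
    """

    specs: tuple[BinSpec, ...]
    mode: str | None = None
    _starts: np.ndarray = field(init=False, repr=False, compare=False)
    _ends: np.ndarray = field(init=False, repr=False, compare=False)
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        specs = tuple(self.specs)
        if not specs:
            raise ValueError("scheme needs at least one range")
        for a, b in zip(specs, specs[1:]):
            if b.range_start < a.range_end:
                raise ValueError("ranges must be ascending and non-overlapping")
        object.__setattr__(self, "specs", specs)
        object.__setattr__(self, "_starts", np.array([s.range_start for s in specs]))
        object.__setattr__(self, "_ends", np.array([s.range_end for s in specs]))
        counts = [s.n_centers for s in specs]
        object.__setattr__(self, "_offsets", np.concatenate([[0], np.cumsum(counts)]))

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    def centers(self) -> np.ndarray:
        return np.concatenate([s.centers() for s in self.specs])

    def labels(self) -> list[str]:
        out: list[str] = []
        for s in self.specs:
            out.extend(_format_center(c, s.spacing) for c in s.centers())
        if len(set(out)) != len(out):
            raise ValueError("bin labels are not unique for this scheme")
        return out

    def assign_index(self, mz: np.ndarray) -> np.ndarray:
        """Vectorized assignment: global bin index per m/z, or -1 if unassigned."""
        mz = np.asarray(mz, dtype=float)
        out = np.full(mz.shape, -1, dtype=np.int64)
        ridx = np.searchsorted(self._starts, mz, side="right") - 1
        in_range = (ridx >= 0) & (mz < self._ends[np.clip(ridx, 0, None)])
        if not np.any(in_range):
            return out
        for i, spec in enumerate(self.specs):
            sel = in_range & (ridx == i)
            if not np.any(sel):
                continue
            m = mz[sel]
            q = (m - spec.range_start) / spec.spacing
            k0 = np.clip(np.floor(q).astype(np.int64), 0, spec.n_centers - 1)
            k1 = np.clip(k0 + 1, 0, spec.n_centers - 1)
            d0 = np.abs(m - (spec.range_start + k0 * spec.spacing))
            d1 = np.abs(m - (spec.range_start + k1 * spec.spacing))
            k = np.where(d0 <= d1, k0, k1)  # tie -> lower center
            dist = np.minimum(d0, d1)
            idx = np.where(dist <= spec.width / 2.0, self._offsets[i] + k, -1)
            out[sel] = idx
        return out

    def to_text(self, path: str | Path) -> None:
        """Serialize as plain text, one 'start,end,width,spacing' line per range."""
        with open(path, "w", encoding="utf-8") as fh:
            for s in self.specs:
                fh.write(f"{s.range_start!r},{s.range_end!r},{s.width!r},{s.spacing!r}\n")

    @classmethod
    def from_text(cls, path: str | Path, mode: str | None = None) -> "BinningScheme":
        specs = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                start, end, width, spacing = (float(x) for x in line.split(","))
                specs.append(BinSpec(start, end, width, spacing))
        return cls(specs=tuple(specs), mode=mode)


def default_intact_scheme() -> BinningScheme:
    """Binning for intact-protein (linear-mode) spectra, 500-20,000 Da.

    Five ranges with widths 1.25, 2.2, 3.5, 8 and 35 Da and center spacings
    1, 2, 5, 10 and 50 Da; 3060 bins total.
    """
    specs = (
        BinSpec(500, 1500, 1.25, 1),
        BinSpec(1500, 2500, 2.2, 2),
        BinSpec(2500, 7000, 3.5, 5),
        BinSpec(7000, 12000, 8, 10),
        BinSpec(12000, 20000, 35, 50),
    )
    return BinningScheme(specs=specs, mode="intact")


def default_digested_scheme() -> BinningScheme:
    """Binning for tryptic-digest (reflectron-mode) spectra, 200-6,999 Da.

    Six ranges, all with width 0.5 Da and spacing 1 Da; 6794 bins total.
    """
    specs = tuple(
        BinSpec(start, end, 0.5, 1)
        for start, end in ((200, 999), (1000, 1999), (2000, 2999),
                           (3000, 3999), (4000, 4999), (5000, 6999))
    )
    return BinningScheme(specs=specs, mode="digested")


def assign_bin(mz: float, scheme: BinningScheme) -> str | None:
    """Label of the bin the peak falls in, or None if it lies in no window."""
    if mz <= 0:
        raise ValueError("mz must be > 0")
    idx = int(scheme.assign_index(np.array([mz]))[0])
    if idx < 0:
        return None
    return scheme.labels()[idx]


def check_jitter_compatibility(scheme: BinningScheme, jitter_coeff: float) -> list[str]:
    """Guiding-principle validator: the bin width should exceed the m/z
    variability of identical peaks.  Warns for every range whose width is
    below 4 sigma of the jitter at the range midpoint (sigma = jitter_coeff *
    m/z).  Returns the warning messages."""
    warnings: list[str] = []
    for s in scheme.specs:
        midpoint = 0.5 * (s.range_start + s.range_end)
        four_sigma = 4.0 * jitter_coeff * midpoint
        if s.width < four_sigma:
            msg = (
                f"range {s.range_start:g}-{s.range_end:g}: width {s.width:g} Da < "
                f"4*sigma_jitter {four_sigma:.3g} Da at midpoint {midpoint:g}"
            )
            warnings.append(msg)
            logger.warning("jitter check: %s", msg)
    return warnings


ENCODINGS = ("binary", "intensity")
AGGREGATES = ("max", "sum")


def encode(pl: PeakList, scheme: BinningScheme, encoding: str,
           aggregate: str = "max") -> np.ndarray:
    """One feature value per bin label.

    binary: 1 iff at least one peak is assigned to the bin.  intensity: the
    maximum (or, optionally, sum of) assigned peak intensity, 0 if none.
    Peaks falling in no bin window contribute nothing.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}")
    if aggregate not in AGGREGATES:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    row = np.zeros(scheme.n_bins)
    if len(pl) == 0:
        return row
    idx = scheme.assign_index(pl.mz)
    keep = idx >= 0
    if not np.any(keep):
        return row
    idx = idx[keep]
    if encoding == "binary":
        row[idx] = 1.0
    elif aggregate == "max":
        np.maximum.at(row, idx, pl.intensity[keep])
    else:
        np.add.at(row, idx, pl.intensity[keep])
    return row


@dataclass
class FeatureTable:
    """Spots x bins matrix with per-spot class labels.

    ``data`` is indexed by spot_id with one column per bin label in scheme
    order; ``labels`` holds 'positive'/'negative' per spot; ``encoding`` tags
    how values were derived.
    """

    data: pd.DataFrame
    labels: pd.Series
    encoding: str

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels must share the same spot index")
        if self.encoding == "binary":
            vals = self.data.to_numpy()
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("binary feature table contains non-0/1 values")

    @property
    def n_spots(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="spot_id")

    @classmethod
    def from_csv(cls, path: str | Path, encoding: str) -> "FeatureTable":
        df = pd.read_csv(path, index_col="spot_id")
        labels = df.pop("label")
        return cls(data=df, labels=labels, encoding=encoding)


def build_feature_table(manifest: SpotManifest, role: str, scheme: BinningScheme,
                        encoding: str, mode: str | None = None,
                        aggregate: str = "max", force: bool = False) -> FeatureTable:
    """Bin every spot of the requested role (and mode) into the scheme's
    fixed feature space, in manifest order.

    The spots' acquisition mode must match the scheme's mode tag unless
    ``force`` is set.
    """
    if mode is None:
        mode = scheme.mode
    entries = manifest.select(role=role, mode=mode)
    if not entries:
        raise ValueError(f"no spots with role={role!r}, mode={mode!r} in manifest")
    if scheme.mode is not None and mode is not None and scheme.mode != mode and not force:
        raise ValueError(
            f"mode/scheme mismatch: {mode} spots with a {scheme.mode} scheme "
            "(pass force=True to override)"
        )
    columns = scheme.labels()
    rows = np.empty((len(entries), scheme.n_bins))
    labels = []
    for i, e in enumerate(entries):
        if scheme.mode is not None and e.mode != scheme.mode and not force:
            raise ValueError(
                f"spot {e.spot_id} has mode {e.mode} but scheme is {scheme.mode}"
            )
        pl = read_peaklist(e.file, mode=e.mode, spot_id=e.spot_id)
        row = encode(pl, scheme, encoding, aggregate=aggregate)
        if len(pl) and not row.any():
            logger.warning("spot %s: all peaks outside the scheme's ranges", e.spot_id)
        rows[i] = row
        labels.append(e.label)
    index = pd.Index([e.spot_id for e in entries], name="spot_id")
    data = pd.DataFrame(rows, index=index, columns=columns)
    return FeatureTable(data=data, labels=pd.Series(labels, index=index, name="label"),
                        encoding=encoding)


def feature_table_from_peaklists(peaklists: Sequence[PeakList], labels: Sequence[str],
                                 scheme: BinningScheme, encoding: str,
                                 aggregate: str = "max") -> FeatureTable:
    """In-memory variant of build_feature_table (no manifest round-trip)."""
    if len(peaklists) != len(labels):
        raise ValueError("peaklists and labels must have equal length")
    columns = scheme.labels()
    rows = np.empty((len(peaklists), scheme.n_bins))
    for i, pl in enumerate(peaklists):
        rows[i] = encode(pl, scheme, encoding, aggregate=aggregate)
    index = pd.Index([pl.spot_id for pl in peaklists], name="spot_id")
    data = pd.DataFrame(rows, index=index, columns=columns)
    return FeatureTable(data=data, labels=pd.Series(list(labels), index=index, name="label"),
                        encoding=encoding)
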