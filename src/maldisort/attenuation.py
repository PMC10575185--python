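"""Mass-dependent MALDI signal attenuation and digestion enhancement.

MALDI-TOF signal per spotted amount falls off steeply with analyte mass —
empirically close to two orders of magnitude per decade of molecular weight.
On a log-log plot of mass-normalized peak height against m/z this is a
straight line of slope about -2, fitted here by ordinary least squares.

The same power law predicts the fold-gain from detecting a proteolytic
fragment of mass m in place of its parent protein of mass M:

    enhancement = (M / m) ** |slope|

so a ~3-4 kDa parent digested to a 1 kDa peptide gains roughly 10x signal,
and 10-100 kDa parents gain 100-10,000x.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Reference peptide/protein calibrant masses (Da): angiotensin II,
#: angiotensin I, neurotensin, ACTH 1-17, ACTH 18-39, bovine insulin chain B,
#: bovine insulin, aprotinin, bovine ubiquitin, horse heart cytochrome c,
#: horse myoglobin, trypsinogen, yeast enolase, bovine serum albumin.
CALIBRANT_MASSES_DA = (
    1046.2, 1296.5, 1672.9, 2093.5, 2465.7,
    3495.9, 5733.6, 6511.5, 8564.8,
    12360.1, 16951.5, 23980.9, 46670.9, 66429.9,
)


@dataclass(frozen=True)
class CalibrantObservation:
    """A known analyte spotted in a known amount: mass (Da), spotted amount
    (any consistent unit; it cancels in the slope) and observed peak height."""

    mass: float
    spotted_amount: float
    peak_height: float

    def __post_init__(self) -> None:
        if min(self.mass, self.spotted_amount, self.peak_height) <= 0:
            raise ValueError("mass, spotted_amount and peak_height must be > 0")


@dataclass(frozen=True)
class AttenuationFit:
    """OLS fit of log10(peak_height / spotted_amount) on log10(mass)."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def slope_magnitude(self) -> float:
        return abs(self.slope)


def fit_attenuation(obs: Sequence[CalibrantObservation]) -> AttenuationFit:
    """Least-squares attenuation line through calibrant observations.

    Requires at least 3 observations with a non-zero mass span; warns if the
    span is below one decade (the slope is then poorly constrained).
    """
    if len(obs) < 3:
        raise ValueError("fit_attenuation needs at least 3 observations")
    masses = np.array([o.mass for o in obs])
    if masses.min() == masses.max():
        raise ValueError("observations span zero mass range")
    span = math.log10(masses.max() / masses.min())
    if span < 1.0:
        logger.warning("mass span is only %.2f decades (< 1); slope poorly constrained",
                       span)
    x = np.log10(masses)
    y = np.log10([o.peak_height / o.spotted_amount for o in obs])
    fit = stats.linregress(x, y)
    return AttenuationFit(slope=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue**2))


def enhancement_factor(parent_mass: float, fragment_mass: float,
                       slope_magnitude: float) -> float:
    """Predicted fold-gain in signal from detecting a fragment in place of
    its parent protein: (parent_mass / fragment_mass) ** slope_magnitude."""
    if parent_mass <= 0 or fragment_mass <= 0:
        raise ValueError("masses must be > 0")
    if slope_magnitude < 0:
        raise ValueError("slope_magnitude must be >= 0")
    return (parent_mass / fragment_mass) ** slope_magnitude


@dataclass(frozen=True)
class MassSummary:
    fraction_above: float
    threshold: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]


def proteome_mass_summary(masses: Sequence[float], threshold: float = 10_000.0) -> MassSummary:
    """Fraction of protein masses above a threshold plus a histogram over
    decade-spaced (log10) bins covering the data."""
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        raise ValueError("empty mass list")
    fraction = float((masses > threshold).mean())
    lo = math.floor(math.log10(masses.min()))
    hi = math.ceil(math.log10(masses.max()))
    hi = max(hi, lo + 1)
    edges = np.logspace(lo, hi, num=(hi - lo) + 1)
    counts, _ = np.histogram(masses, bins=edges)
    # np.histogram excludes values above the last edge only if > edge; edges cover all
    return MassSummary(fraction_above=fraction, threshold=threshold,
                       bin_edges=tuple(edges), counts=tuple(int(c) for c in counts))


def synthetic_calibrant_observations(seed: int, slope: float = -2.0,
                                     intercept: float = 6.0,
                                     sigma_log10: float = 0.1,
                                     masses: Sequence[float] = CALIBRANT_MASSES_DA,
                                     spotted_amount: float = 1.0,
                                     ) -> list[CalibrantObservation]:
    """Seeded synthetic calibrant series following the attenuation power law.

    Synthetic stand-in for a real dilution series: heights follow
    10**(intercept + slope*log10(mass)) with lognormal scatter of the given
    log10 standard deviation.
    """
    rng = np.random.default_rng(seed)
    obs = []
    for m in masses:
        log10_h = intercept + slope * math.log10(m) + rng.normal(0.0, sigma_log10)
        obs.append(CalibrantObservation(mass=float(m), spotted_amount=spotted_amount,
                                        peak_height=spotted_amount * 10.0**log10_h))
    return obs
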