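"""Synthetic two-class proteomes and their intact/digested MALDI spot peak lists.

The generator emulates the statistical structure that makes tryptic digestion
matter for machine-learning sorting of MALDI-TOF spectra:

* a bacterial proteome's mass distribution — log10(mass) ~ Normal(4.46, 0.55)
  truncated to [3.0, 5.3] (1-200 kDa), so roughly 80 % of proteins sit above
  10 kDa;
* lognormal relative abundances, log10(abundance) ~ Normal(0, 0.8);
* mass-dependent signal attenuation — expected peak height falls as
  (mass / 1 kDa) ** -slope_magnitude with a default slope magnitude of 2
  (two orders of magnitude lost per decade of molecular weight);
* a detection limit, so high-mass/low-abundance proteins vanish from intact
  spectra (defaults are calibrated so an intact spot keeps <= 10 peaks above
  10 kDa);
* spot-to-spot multiplicative lognormal intensity noise with ~80 % RSD and
  mass-proportional m/z jitter;
* mass-level tryptic digestion: each protein deterministically yields the
  same peptide fragments (drawn around 1.1 kDa) in every sample, so digested
  spectra carry learnable cross-sample patterns.

Digested-mode detection additionally models peptide-specific MALDI
ionization efficiency: only a deterministic "flyer" subset of fragments
ionizes detectably, and the low-mass (reflectron) acquisition has its own,
lower detection limit.  Without both, a whole-proteome digest would either
saturate every m/z bin in every spot or hide low-abundance fragments
entirely; with them, digested spectra are rich but sparse, the way real
reflectron digests look.

Class difficulty presets mirror easy vs. hard sorting problems: the easy
preset gives each class 50 class-specific proteins drawn abundance-weighted
(chemically dissimilar samples differ in their abundant constituents, so
some differences are instrument-visible even intact); the hard preset gives each
class only 5 class-specific proteins constrained to mass > 20 kDa and
bottom-quartile abundance — exactly the proteins intact-mode MALDI cannot
see, so any sorting signal must come from their digestion fragments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .peaklist_io import LABELS, ManifestEntry, PeakList, SpotManifest, write_manifest, write_peaklist

logger = logging.getLogger(__name__)

PRESETS = ("easy", "hard")


@dataclass(frozen=True)
class SimProtein:
    id: str
    mass: float
    abundance: float
    biomarker: bool = False


@dataclass(frozen=True)
class NoiseModel:
    """Spot-to-spot noise: multiplicative lognormal intensity scatter
    (sigma 0.7033 <=> 80 % RSD), m/z jitter proportional to mass, and
    per-acquisition-mode detection limits in signal units."""

    intensity_sigma_log: float = 0.7033
    jitter_coeff: float = 5.0e-5
    lod_intact: float = 1.0
    lod_digested: float = 0.02

    @property
    def rsd(self) -> float:
        """Relative standard deviation implied by the lognormal sigma."""
        return float(np.sqrt(np.exp(self.intensity_sigma_log**2) - 1.0))


@dataclass(frozen=True)
class DigestionModel:
    """Mass-level tryptic digestion.

    Fragment masses are drawn from Normal(1100, 300) clipped to [500, 3000]
    Da until the undigested remainder falls below the lower clip; a
    remainder of at least 200 Da becomes the final fragment, smaller
    remainders are merged into the last fragment.  Each protein's fragment
    list (and which fragments are detectable "flyers") is a deterministic
    function of the protein id and digest_seed, identical in every sample.
    """

    fragment_mean: float = 1100.0
    fragment_sd: float = 300.0
    fragment_clip: tuple[float, float] = (500.0, 3000.0)
    min_fragment: float = 200.0
    flyer_fraction: float = 0.005
    digest_seed: int = 0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    n_proteins: int = 5445
    log10_mass_mu: float = 4.46
    log10_mass_sigma: float = 0.55
    log10_mass_bounds: tuple[float, float] = (3.0, 5.3)
    log10_abundance_sigma: float = 0.8
    preset: str = "easy"
    spots_per_class_train: int = 48
    spots_per_class_score: int = 48
    slope_magnitude: float = 2.0
    intact_window: tuple[float, float] = (500.0, 20000.0)
    digested_window: tuple[float, float] = (200.0, 7000.0)
    easy_markers_per_class: int = 50
    hard_markers_per_class: int = 5
    hard_marker_min_mass: float = 20000.0
    hard_marker_abundance_quantile: float = 0.25
    noise: NoiseModel = field(default_factory=NoiseModel)
    digestion: DigestionModel = field(default_factory=DigestionModel)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")
        if min(self.n_proteins, self.spots_per_class_train, self.spots_per_class_score) < 1:
            raise ValueError("counts must be >= 1")
        if self.log10_mass_sigma <= 0 or self.log10_abundance_sigma <= 0:
            raise ValueError("distribution sigmas must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _seed_roots(config: SimConfig) -> tuple[np.random.SeedSequence, ...]:
    """Independent, reproducible seed streams for proteome, marker choice
    and spot rendering (same config -> same streams)."""
    return tuple(np.random.SeedSequence(config.seed).spawn(3))


def sample_masses(config: SimConfig, n: int, seed=None) -> np.ndarray:
    """Draw n protein masses (Da) from the truncated lognormal mass model."""
    if seed is None:
        seed = _seed_roots(config)[0]
    rng = np.random.default_rng(seed)
    lo, hi = config.log10_mass_bounds
    a = (lo - config.log10_mass_mu) / config.log10_mass_sigma
    b = (hi - config.log10_mass_mu) / config.log10_mass_sigma
    log10_mass = stats.truncnorm.rvs(a, b, loc=config.log10_mass_mu,
                                     scale=config.log10_mass_sigma, size=n,
                                     random_state=rng)
    return 10.0 ** log10_mass


def sample_proteome(config: SimConfig, seed=None, n: int | None = None) -> list[SimProtein]:
    """Sample a proteome: n_proteins with masses and relative abundances
    drawn as configured.  Deterministic per seed."""
    if n is None:
        n = config.n_proteins
    if seed is None:
        seed = _seed_roots(config)[0]
    seed = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    rng = np.random.default_rng(seed)
    lo, hi = config.log10_mass_bounds
    a = (lo - config.log10_mass_mu) / config.log10_mass_sigma
    b = (hi - config.log10_mass_mu) / config.log10_mass_sigma
    log10_mass = stats.truncnorm.rvs(a, b, loc=config.log10_mass_mu,
                                     scale=config.log10_mass_sigma, size=n,
                                     random_state=rng)
    log10_abund = rng.normal(0.0, config.log10_abundance_sigma, size=n)
    return [
        SimProtein(id=f"P{i:05d}", mass=float(10.0**m), abundance=float(10.0**a_))
        for i, (m, a_) in enumerate(zip(log10_mass, log10_abund))
    ]


@dataclass
class ClassPair:
    """A shared proteome plus disjoint class-specific protein sets."""

    shared: tuple[SimProtein, ...]
    class_a: tuple[SimProtein, ...]
    class_b: tuple[SimProtein, ...]
    preset: str
    _intact_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _digest_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = lambda ps: {p.id for p in ps}  # noqa: E731
        if ids(self.class_a) & ids(self.class_b):
            raise ValueError("class-specific sets must be disjoint")
        if ids(self.shared) & (ids(self.class_a) | ids(self.class_b)):
            raise ValueError("shared set must be disjoint from class-specific sets")

    def proteins_for(self, label: str) -> tuple[SimProtein, ...]:
        if label == "positive":
            return self.shared + self.class_a
        if label == "negative":
            return self.shared + self.class_b
        raise ValueError(f"unknown class label {label!r}")

    def intact_arrays(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(masses, abundances) for all proteins present in the class."""
        if label not in self._intact_cache:
            ps = self.proteins_for(label)
            self._intact_cache[label] = (
                np.array([p.mass for p in ps]),
                np.array([p.abundance for p in ps]),
            )
        return self._intact_cache[label]

    def flyer_fragment_arrays(self, label: str, model: DigestionModel
                              ) -> tuple[np.ndarray, np.ndarray]:
        """(fragment masses, parent abundances) of detectable (flyer)
        fragments for all proteins present in the class."""
        key = (label, model)
        if key not in self._digest_cache:
            masses: list[np.ndarray] = []
            abunds: list[np.ndarray] = []
            for p in self.proteins_for(label):
                frags, flyers = _digest_with_flyers(p, model)
                if flyers.any():
                    masses.append(frags[flyers])
                    abunds.append(np.full(int(flyers.sum()), p.abundance))
            if masses:
                self._digest_cache[key] = (np.concatenate(masses), np.concatenate(abunds))
            else:
                self._digest_cache[key] = (np.empty(0), np.empty(0))
        return self._digest_cache[key]


def make_class_pair(config: SimConfig) -> ClassPair:
    """Sample a proteome and split out class-specific marker proteins
    according to the difficulty preset."""
    proteome_ss, marker_ss, _ = _seed_roots(config)
    proteome = sample_proteome(config, seed=proteome_ss)
    rng = np.random.default_rng(marker_ss)
    n = len(proteome)
    if config.preset == "easy":
        per_class = config.easy_markers_per_class
        # chemically dissimilar samples differ in their abundant constituents:
        # class-specific proteins are drawn abundance-weighted (no mass or
        # abundance cutoff), so some differences are instrument-visible intact
        weights = np.array([p.abundance for p in proteome])
        chosen = rng.choice(n, size=2 * per_class, replace=False,
                            p=weights / weights.sum())
    else:
        per_class = config.hard_markers_per_class
        abundances = np.array([p.abundance for p in proteome])
        cutoff = np.quantile(abundances, config.hard_marker_abundance_quantile)
        eligible = np.flatnonzero(
            (np.array([p.mass for p in proteome]) > config.hard_marker_min_mass)
            & (abundances <= cutoff)
        )
        if eligible.size < 2 * per_class:
            raise ValueError(
                f"only {eligible.size} proteins satisfy the hard-preset "
                f"constraints; need {2 * per_class}"
            )
        chosen = rng.choice(eligible, size=2 * per_class, replace=False)
    chosen_set = set(int(i) for i in chosen)
    mark = lambda p: dataclasses.replace(p, biomarker=True)  # noqa: E731
    class_a = tuple(mark(proteome[int(i)]) for i in chosen[:per_class])
    class_b = tuple(mark(proteome[int(i)]) for i in chosen[per_class:])
    shared = tuple(p for i, p in enumerate(proteome) if i not in chosen_set)
    return ClassPair(shared=shared, class_a=class_a, class_b=class_b,
                     preset=config.preset)


def _protein_rng(p: SimProtein, model: DigestionModel) -> np.random.Generator:
    # fragment identity is a property of the protein: sub-seed by a stable
    # hash of its id so every sample sees the same fragments
    ss = np.random.SeedSequence([model.digest_seed, zlib.crc32(p.id.encode())])
    return np.random.default_rng(ss)


def _digest_with_flyers(p: SimProtein, model: DigestionModel
                        ) -> tuple[np.ndarray, np.ndarray]:
    if p.mass < model.min_fragment:
        raise ValueError(f"protein {p.id} lighter than the minimum fragment mass")
    rng = _protein_rng(p, model)
    lo, hi = model.fragment_clip
    frags: list[float] = []
    remaining = p.mass
    while remaining >= lo:
        f = rng.normal(model.fragment_mean, model.fragment_sd)
        while not (lo <= f <= hi):
            f = rng.normal(model.fragment_mean, model.fragment_sd)
        f = min(f, remaining)
        frags.append(f)
        remaining -= f
    if remaining > 1e-9:
        if remaining >= model.min_fragment or not frags:
            frags.append(remaining)
        else:
            frags[-1] += remaining
    masses = np.array(frags)
    flyers = rng.random(masses.size) < model.flyer_fraction
    return masses, flyers


def digest_protein(p: SimProtein, model: DigestionModel) -> np.ndarray:
    """Deterministic fragment masses for one protein (same list on every
    call and in every sample)."""
    return _digest_with_flyers(p, model)[0]


def render_spot(class_label: str, mode: str, pair: ClassPair, noise: NoiseModel,
                config: SimConfig, spot_seed, spot_id: str | None = None) -> PeakList:
    """Render one MALDI spot as a centroid peak list.

    intact mode: one candidate peak per protein at its (jittered) mass with
    expected height abundance * (mass/1 kDa)**-slope.  digested mode: one
    candidate peak per detectable fragment with expected height
    abundance * (fragment/1 kDa)**-slope.  Candidates survive iff the noisy
    height reaches the mode's detection limit and the jittered m/z falls in
    the mode's acquisition window.
    """
    rng = np.random.default_rng(spot_seed)
    if mode == "intact":
        mz0, abund = pair.intact_arrays(class_label)
        lod, window = noise.lod_intact, config.intact_window
    elif mode == "digested":
        mz0, abund = pair.flyer_fragment_arrays(class_label, config.digestion)
        lod, window = noise.lod_digested, config.digested_window
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if spot_id is None:
        spot_id = f"{mode}_{class_label}"
    if mz0.size == 0:
        return PeakList(spot_id=spot_id, mode=mode)
    expected = abund * (mz0 / 1000.0) ** (-config.slope_magnitude)
    heights = expected * rng.lognormal(0.0, noise.intensity_sigma_log, size=mz0.size)
    mz = mz0 + rng.normal(0.0, 1.0, size=mz0.size) * (noise.jitter_coeff * mz0)
    keep = (heights >= lod) & (mz >= window[0]) & (mz < window[1]) & (mz > 0)
    return PeakList(spot_id=spot_id, mode=mode, mz=mz[keep], intensity=heights[keep])


def replicate_peak_intensities(expected_height: float, noise: NoiseModel,
                               n: int, seed) -> np.ndarray:
    """n replicate intensities of one peak under the spot-to-spot noise
    model (used to verify the ~80 % RSD default)."""
    rng = np.random.default_rng(seed)
    return expected_height * rng.lognormal(0.0, noise.intensity_sigma_log, size=n)


def generate_dataset(config: SimConfig, out_dir: str | Path) -> tuple[SpotManifest, Path]:
    """Write per-spot peak-list CSVs for both modes and both roles plus a
    manifest; the whole tree is a pure function of config (byte-identical
    reruns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair = make_class_pair(config)
    spots_ss = _seed_roots(config)[2]
    layout = []
    for mode in ("intact", "digested"):
        for role, n_spots in (("train", config.spots_per_class_train),
                              ("score", config.spots_per_class_score)):
            for label in LABELS:
                for k in range(n_spots):
                    layout.append((mode, role, label, k))
    spot_seeds = spots_ss.spawn(len(layout))
    entries = []
    for (mode, role, label, k), seed in zip(layout, spot_seeds):
        spot_id = f"{mode}_{role}_{label}_{k:03d}"
        pl = render_spot(label, mode, pair, config.noise, config, seed, spot_id=spot_id)
        fname = f"{spot_id}.csv"
        write_peaklist(pl, out / fname)
        entries.append(ManifestEntry(spot_id=spot_id, file=out / fname,
                                     label=label, role=role, mode=mode))
    manifest = SpotManifest(entries=tuple(entries))
    manifest_path = out / "manifest.csv"
    write_manifest(manifest, manifest_path, relative_to=out)
    config.save_json(out / "simconfig.json")
    logger.info("wrote %d spots under %s (%s preset)", len(entries), out, config.preset)
    return manifest, manifest_path
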