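# Methods

`maldisort` models and tests a single question: when two classes of samples
differ only in a handful of high-mass, low-abundance proteins, does tryptic
digestion before MALDI-TOF analysis rescue machine-learning-based
dichotomous sorting?  The package implements the full analysis chain —
centroid peak lists → fixed m/z binning → binary/intensity feature tables →
gradient-boosted-tree trial grid → sensitivity/specificity/Youden
evaluation — together with a generative model of intact and digested
spectra that makes the question answerable without instrument data.

## Diagnostic metrics

Each trial scores a held-out spot set and reports

    sens = TP / (TP + FN),    spc = TN / (TN + FP),    J = sens + spc - 1.

J = 1 is perfect dichotomous sorting, J = 0 chance, J < 0 systematic
inversion.  A condition (e.g. digested, binary encoding) is summarised by
the arithmetic mean of per-trial J values, always computed at full
precision from per-trial results — applying the Youden identity to rounded
average sens/spc can legitimately disagree with the mean of per-trial Js,
so both are reported under distinct names (`mean_j`,
`j_of_mean_sens_spc`).  Two conditions are compared by the ratio of mean
Js and a two-sided Welch (unequal-variance) two-sample t-test at
alpha = 0.05.  The test choice is recorded in the result object; Welch is
the conservative default for small trial sets with no variance-equality
assumption.  Degenerate zero-variance identical inputs return p = 1 by
convention.  "ROC" output is a scatter of dichotomous trials — unique
(1 − spc, sens) points annotated with trial multiplicities — not a
threshold-swept curve, so no AUC is computed.

## Binning

The mass axis is covered by ordered ranges, each with a bin-center spacing
(dM) and a full bin width (tolerance):

* intact (linear mode): 500–1500, 1500–2500, 2500–7000, 7000–12000,
  12000–20000 Da with widths 1.25, 2.2, 3.5, 8, 35 Da and spacings
  1, 2, 5, 10, 50 Da → 3060 bins;
* digested (reflectron mode): 200–999, 1000–1999, …, 5000–6999 Da, all
  with width 0.5 Da and spacing 1 Da → 6794 bins.

Bin centers are anchored at each range start (the anchor is otherwise
unidentified; anchoring at the printed range boundary is reproducible and
auditable).  A peak joins the nearest center of its containing range iff
its distance is at most width/2; exact midpoint ties go to the lower
center.  Where width > spacing (first intact range) windows overlap and
nearest-center assignment resolves the overlap deterministically; where
width < spacing (digested ranges) the windows cover only width/spacing of
the axis and off-window peaks are dropped.  Ranges are half-open
[start, end), so the digested scheme's 999 → 1000 seam leaves
998.25–999.75 Da uncovered, exactly as the printed ranges imply.  Binary
encoding records peak presence per bin; intensity encoding records the
maximum assigned peak intensity (sum is available as an option; the
aggregation rule is otherwise unidentified and max is robust to split
centroids).  A validator enforces the guiding principle that the bin width
should exceed the m/z variability of identical peaks: it warns for any
range whose width is below 4σ of the jitter model at the range midpoint.

## Classifier and trial grid

The classifier is a histogram gradient-boosted decision-tree ensemble
(scikit-learn's `HistGradientBoostingClassifier`).  The trial grid crosses
number of trees {50, 101, 401, 701} × feature-histogram bins {20, 40} ×
learning rate {0.01, 1e-4, 1e-5}, 24 trials; a 12-trial preset fixes the
bin count at 20 (which 12 of the 24 combinations constituted the original
12-trial runs is not identifiable, so both presets exist).  "Number of
bins" is the histogram discretization granularity of feature values during
tree construction (`max_bins`); it is a no-op for binary tables, which is
logged.  `min_samples_leaf` is set to 5 because spot datasets have tens of
rows per class, where the backend's big-data default (20) would forbid any
split on small tables.  Training rows are canonically sorted by spot id
before fitting, making predictions invariant to row order; with early
stopping disabled the fit is deterministic given config and seed.  The
dichotomous call is positive-class probability ≥ 0.5.  Even at learning
rate 1e-5 the boosted score moves in the correct direction for separable
data, so tiny learning rates still sort — they simply move the score a
tiny distance from 0.5.

## Generative model

One simulated experiment is a pure function of a master seed and a config:

* **Proteome.** 5445 proteins; log10(mass) ~ Normal(4.46, 0.55) truncated
  to [3.0, 5.3] (1–200 kDa), calibrated so ≈80 % of proteins exceed
  10 kDa; log10(abundance) ~ Normal(0, 0.8) (relative molar units — the
  abundance law is a modelling choice, no empirical curve being
  available).
* **Attenuation.** Expected intact peak height is
  abundance × (mass / 1 kDa)^−s with slope magnitude s = 2 by default
  (two orders of magnitude of signal lost per decade of molecular weight),
  overridable from a fitted attenuation line.  The identical law applied
  to a fragment of mass m instead of its parent of mass M yields the
  enhancement factor (M/m)^s.
* **Noise.** Intensities are multiplied per spot by lognormal noise with
  σ = 0.7033, chosen by inverting RSD = sqrt(exp(σ²) − 1) for RSD = 0.80
  (the ~80 % spot-to-spot irreproducibility of MALDI signal intensity);
  m/z jitter is Normal with σ = 5×10⁻⁵ × m/z (50 ppm, typical
  calibrated-TOF mass accuracy).  At 50 ppm the binning guiding principle
  (width > 4σ of jitter) holds for every intact range and every digested
  range below 3 kDa — i.e. everywhere fragments occur; the validator flags
  the empty digested ranges above 3 kDa.
* **Detection.** A peak survives iff its noisy height reaches the
  acquisition mode's detection limit and its jittered m/z lies in the
  mode's window (intact 500–20000 Da, digested 200–7000 Da).
  lod_intact = 1.0 is calibrated (and test-asserted) so a default intact
  spot retains ≤ 10 peaks above 10 kDa while showing on the order of a
  hundred peaks in the low-mass region — the canonical look of a bacterial
  linear-mode spectrum.  lod_digested = 0.02 reflects the higher
  sensitivity of low-mass reflectron acquisition, the same physical fact
  the enhancement model encodes.
* **Digestion.** Mass-level, not sequence-level: fragment masses are drawn
  from Normal(1100, 300) clipped to [500, 3000] Da until the undigested
  remainder falls below 500 Da; remainders ≥ 200 Da become the final
  fragment, smaller ones merge into the last fragment (which may therefore
  reach ~3.2 kDa).  Masses are conserved.  Each protein's fragments are
  drawn from a generator sub-seeded by a stable hash of the protein id, so
  the same protein yields identical fragment m/z in every sample — without
  this there would be no cross-sample pattern to learn.  Sequence-based
  trypsin rules (cleave after K/R, not before P) are a documented
  extension point, not implemented: every quantity the analysis uses lives
  in mass space.
* **Ionization efficiency.** Only a deterministic "flyer" subset of
  fragments (default 0.5 %) ionizes detectably, modelling strongly
  peptide-dependent MALDI ionization in an unseparated digest.  This knob
  is essential: a 5445-protein proteome yields ~1.6×10⁵ fragments
  concentrated in a ~2.5 kDa span, and without the gate every digested
  bin is occupied in every spot (an all-ones feature table carries no
  class information), while any detection threshold high enough to thin
  the table hides low-abundance marker peptides entirely.  With the gate,
  digested spots carry ≈1000 peaks — rich but sparse, the way real
  reflectron digests look.
* **Class presets.** Both classes share the proteome except for
  class-specific marker proteins.  *easy* (chemically dissimilar samples):
  50 markers per class drawn abundance-weighted with no mass or abundance
  cutoff — compositional differences involve abundant constituents, so
  several markers per class are visible even intact.  *hard* (fundamentally
  similar samples): 5 markers per class constrained to mass > 20 kDa and
  bottom-quartile abundance — outside the intact window and below the
  intact detection limit by construction, so intact sorting is chance and
  any signal must come from digestion fragments.
* **Layout.** 48 spots per class for each of the train and score roles, in
  both modes: 384 spot peak lists per dataset, written in the package's
  CSV dialect with a manifest and the serialized config; reruns are
  byte-identical.

Singly-charged ions only; no isotope envelopes, adducts, matrix clusters,
profile spectra, or ion suppression beyond the lognormal noise and the
flyer gate.

## What the simulation does and does not show

On the seeded default datasets (master seed 42, full 24-trial grid, binary
encoding) the pipeline reproduces the qualitative phenomenon the package
exists to test: easy preset — mean J = 1.000 in both modes; hard preset —
mean J = 0.049 intact (chance) versus 1.000 digested, J_dig/J_intact ≈ 21,
Welch p ≈ 2×10⁻³². The hard preset sits at the detection margin by design:
with 5 bottom-quartile markers among 5445 proteins and a 0.5 % flyer rate,
the expected number of detectable marker peptides per class is of order
one.  Across independent master seeds the digested advantage therefore
appears in most but not all replicates (when no marker peptide ionizes,
digested J collapses to chance as well); the committed fixture exhibits it
clearly, and nothing about the committed seed was selected retroactively.
Real spectra add biology the generator omits — correlated strain
backgrounds, variable digestion yield, ion suppression, isotope structure,
calibration drift — so passing these tests demonstrates the soundness of
the analysis chain and the plausibility of the mechanism, not field
performance.

## Numerical details

* Duplicate m/z rows in a peak list merge keeping the maximum intensity
  (idempotent, order-independent); peak lists are strictly sorted.
* Peak-list and feature-table CSVs round-trip exactly (shortest-repr float
  formatting).
* Bin assignment is O(1) per peak (range lookup + center arithmetic); a
  brute-force linear scan over all centers with identical eligibility,
  tolerance and tie rules serves as the test oracle.
* Empty score-set classes raise rather than silently reporting 0 for an
  undefined metric; failed grid trials are recorded per-trial, not fatal.
* All randomness flows from `numpy.random.SeedSequence` spawns of one
  master seed: proteome, marker choice, and every spot get independent,
  reproducible streams; per-protein digestion streams are keyed by
  (digest seed, CRC32 of protein id) and are independent of which sample
  is being rendered.
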