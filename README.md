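# maldisort

Tools for studying when **tryptic digestion improves machine-learning
sorting of MALDI-TOF mass spectra** — aimed at people building
MALDI-plus-ML diagnostic workflows (bacterial typing, antimicrobial-
resistance screening, food-matrix discrimination) who need to decide
whether a digestion step is worth adding.

MALDI-TOF signal falls steeply with analyte mass: on a log-log plot of
mass-normalized peak height against m/z the response is close to a line of
slope −2, i.e. ~two orders of magnitude of signal lost per decade of
molecular weight. Detecting a tryptic fragment of mass *m* in place of its
parent protein of mass *M* therefore promises a fold-enhancement

    E = (M / m)^|slope|

of roughly 10× for a 3–4 kDa parent and 100–10 000× for 10–100 kDa
parents (1 kDa fragment, slope magnitude 2). When the proteins that
distinguish two sample classes are high-mass and low-abundance, they are
invisible in intact-protein spectra but their peptides are not — and
dichotomous sorting by a classifier should succeed only after digestion.

The package implements the complete analysis chain and a generative model
to test that prediction end-to-end:

* `maldisort.peaklist_io` — centroid peak-list CSVs and spot manifests;
* `maldisort.binning` — fixed m/z binning (intact: 3060 bins over
  500–20 000 Da; digested: 6794 bins over 200–6 999 Da) and
  binary/intensity feature tables;
* `maldisort.classify` — gradient-boosted-tree trials over the grid
  trees {50, 101, 401, 701} × feature bins {20, 40} × learning rate
  {0.01, 1e-4, 1e-5};
* `maldisort.evaluate` — sensitivity, specificity, Youden index
  J = sens + spc − 1, ROC scatter with trial multiplicities, Welch
  comparison of conditions;
* `maldisort.attenuation` — attenuation-line fitting and enhancement
  factors;
* `maldisort.simulate` — seeded two-class proteomes and their intact vs
  digested spot peak lists (attenuation, detection limits, 80 % RSD
  intensity noise, m/z jitter, deterministic in-silico digestion);
* `maldisort.cli` — `maldisort simulate | bin | run | report`.

See `docs/methods.md` for the model and its assumptions.

## Worked example

Simulate the "hard" condition — the two classes differ only in 5 proteins
per class, all heavier than 20 kDa and in the bottom abundance quartile —
then run the full trial grid on both acquisition modes:

```sh
maldisort simulate --preset hard --seed 42 --out scratch/hard
maldisort run --manifest scratch/hard/manifest.csv --out scratch/results --encoding binary
```

Equivalently in Python (this is what `analysis/02_simulate_datasets.py`
and `analysis/03_sorting_trials.py` do):

```python
from maldisort import SimConfig, generate_dataset, build_feature_table, \
    default_intact_scheme, default_digested_scheme, default_grid, run_grid

manifest, _ = generate_dataset(SimConfig(seed=42, preset="hard"), "scratch/hard")
for mode, scheme in [("intact", default_intact_scheme()),
                     ("digested", default_digested_scheme())]:
    train = build_feature_table(manifest, "train", scheme, "binary")
    score = build_feature_table(manifest, "score", scheme, "binary")
    result = run_grid(train, score, default_grid(seed=0))
    print(mode, sum(result.js) / len(result.js))
```

Output of the analysis scripts on this seed:

```
hard/intact (binary): mean J = +0.049 over 24 trials, max J = +0.104
hard/digested (binary): mean J = +1.000 over 24 trials, max J = +1.000
hard: J_dig/J_intact = 20.57, Welch p = 1.70e-32 (significant at 0.05)
```

Intact spectra cannot sort the classes (mean Youden index J ≈ 0.05,
chance level — the marker proteins are outside the intact detection
reach), while the same samples after in-silico digestion sort perfectly in
all 24 trials. On the "easy" preset (50 abundance-weighted marker proteins
per class, emulating chemically dissimilar samples) both modes reach
mean J = 1.000 and digestion buys nothing — together the two presets
reproduce the qualitative rule: digest when the classes are fundamentally
similar, skip the digestion step when they are not.

The numbered scripts under `analysis/` run the whole study:
`01_attenuation_model.py` (attenuation fit: slope −1.942, r² = 0.994 on
the seeded synthetic calibrant series; enhancement table; proteome mass
summary), `02_simulate_datasets.py` (384-spot datasets per preset), and
`03_sorting_trials.py` (the grid comparison above), writing tables under
`results/`.

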