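# sealscape

Tools for asking whether anthropogenic sea-floor structures — pipelines,
cable routes, oil/gas wells and shipwrecks — shape where a central-place
benthic marine predator forages. The motivating system is the Australian fur
seal (*Arctocephalus pusillus doriferus*) in Bass Strait: a benthic forager
on a shallow (~60 m), near-featureless shelf where industrial structures act
as *de facto* artificial reefs. The package takes the raw biologging inputs
(GPS fixes and time-depth records per individual, structure geometries, a
250 m bathymetry grid) and carries them through to the cohort statistics.

## What it computes

1. **Dive classification.** After zero-offset correction and 5 m
   minimum-depth dive detection, each dive gets a score
   *s = p<sub>bottom</sub> · d<sub>max</sub>* (proportion of the dive in its
   bottom phase times maximum depth). The score density of a benthic forager
   is bimodal; the nadir of a Gaussian KDE between the two modes splits
   pelagic (*s* below the nadir) from benthic dives.
2. **Track processing.** McConnell-style iterative speed filtering of GPS
   fixes, linear regularisation to 10-min intervals, and dive positioning by
   time interpolation.
3. **First-passage diving (FPD).** A first-passage-time variant that
   accumulates time *underwater* (rather than elapsed time) from first entry
   to first exit of a circle of radius *r* around each track point. The
   operational scale is the *r* maximising Var[log FPD]; points above the
   per-trip 75th percentile of FPD at that scale mark intensive foraging,
   and their benthic dives — deduplicated to one event per 250 m grid cell —
   become presence records.
4. **Habitat model.** A presence-background maximum-entropy model
   *P(x) ∝ exp(w·f(x))* over a seven-layer covariate stack (depth, terrain
   complexity, and Euclidean distances to colony, coast, pipes/cables, wells,
   shipwrecks), fitted by L1-regularised coordinate-wise Newton ascent with a
   70/30 train/test split, rank-AUC evaluation, and per-variable percent
   contributions from training-gain attribution.
5. **Association statistics.** Time within a 250 m buffer of each structure
   type per trip; cohort visitation summaries; tie-corrected Kruskal–Wallis
   comparison of structure-type contributions; AICc comparison (with Akaike
   weights and full model averaging) of linear models linking morphometrics —
   mass, flipper-length/standard-length (FL/SL), axis/SL — to structure
   importance.

A synthetic-data generator (`sealscape.simulate`) produces ground-truthed
seascapes and trips — a two-state correlated random walk with foraging bouts
whose placement can be biased toward structures — so every stage is testable
without field data. The published per-seal summary for the 36-animal Kanowna
Island cohort ships as `sealscape.datasets.load_kanowna_seals()`.

## Worked example

```python
from sealscape.datasets import load_kanowna_seals, STRUCTURE_COLUMNS
from sealscape.association import kruskal_wallis, arcsin_transform, aicc_model_set

seals = load_kanowna_seals(modelled_only=True)   # 34 seals with habitat models
H, df, p = kruskal_wallis(*[seals[c] for c in STRUCTURE_COLUMNS])
print(f"structure-type contributions: H = {H:.2f}, df = {df}, p = {p:.4f}")
print("combined contribution > 30%:",
      int((seals["structure_sum"] > 30).sum()), "of", len(seals), "seals")

seals = seals.assign(response=arcsin_transform(seals["structure_sum"] / 100, sqrt=False))
mc = aicc_model_set(seals, "response", predictors=["mass_kg", "fl_sl", "axis_sl"])
print(mc.summary())
```

prints

```
structure-type contributions: H = 10.46, df = 2, p = 0.0054
combined contribution > 30%: 20 of 34 seals
AICc model comparison (n = 34)
========================================================
model                           df   dAICc  weight    R2
--------------------------------------------------------
fl_sl                            3    0.00   0.409  0.12
mass_kg + fl_sl                  4    1.75   0.171  0.15
(intercept)                      2    2.11   0.142  0.00
fl_sl + axis_sl                  4    2.26   0.132  0.13
mass_kg + fl_sl + axis_sl        5    4.29   0.048  0.15
...
model-averaged coefficients (full average):
  const           -1.59297
  axis_sl         -0.20986
  fl_sl            7.26142
  mass_kg          0.00087
```

The structure types differ in their mean influence on foraging-habitat
models (pipes/cables > wells > shipwrecks), more than half the cohort puts
over 30 % of model contribution on structure distances, and among the
morphometric models the flipper-length/standard-length ratio — a
manoeuvrability proxy — carries the most support, with a positive averaged
coefficient.

An end-to-end synthetic run from the shell:

```bash
sealscape simulate --out demo --n-seals 6 --seed 1 --attraction 3
sealscape all --config demo/config.ini
```

writes per-seal dive tables, regularised tracks, foraging events
(CSV + GeoJSON), fitted habitat models (JSON), occupancy tables and a cohort
summary under `demo/output/`, with a manifest recording inputs, parameters
and seed.

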