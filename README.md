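# iegmap

Brain-wide immediate-early-gene (IEG) activation mapping and fiber-photometry
evoked-response analysis for small-cohort pharmacology studies, with a seeded
synthetic-data backbone so the entire pipeline is testable without any
experimental download.

The package targets the analysis design used to ask *which brain region
distinguishes a drug-treated brain*: per-animal IEG⁺ cell counts over a
couple of dozen parcellated regions (three treatment groups, ~5 animals
each), and single-wavelength GCaMP photometry recorded during social
investigation. Written for computational neuroscientists who want the two
bespoke statistics of that design — decoder-weight forward models and
contact-evoked z-score responses — as tested, composable library code.

## What it computes

**Region nomination via forward models.** Counts are z-scored per region
across the full cohort, a soft-margin linear SVM is fitted to each two-group
comparison (drug vs vehicle; drug vs enantiomer), and the backward-model
weights *W* are transformed into a forward-model activation pattern

```
A = Σₓ W Σŝ⁻¹,   Σŝ = Wᵀ Σₓ W
```

where Σₓ is the data covariance of the features used for the fit and Σŝ the
(scalar, for a binary decoder) variance of the latent decision value. Unlike
raw decoder weights, *A* is interpretable per region; regions are ranked by
|A| and the top region is nominated as the discriminator. Insular-cortex
cell coordinates are additionally binned along the anteroposterior axis
(aIC = +2.50 to +1.45 mm anterior to bregma).

**Photometry.** 100 Hz fluorescence traces are baseline-corrected with
airPLS (adaptive iteratively reweighted penalized least squares — a
Whittaker smoother whose weights are re-estimated each pass so samples above
the running baseline, i.e. calcium transients, are ignored), z-scored
against a designated 5-min home-cage baseline segment, and scored per
investigation bout: only *nonsequential* bouts (onset ≥ 10 s after the end
of the preceding bout) are kept, and each contributes

```
Δz = mean z over [onset, onset+3 s) − mean z over [onset−3 s, onset)
```

Session statistics are the paired mouse-vs-object *t* contrast across
animals and the Spearman correlation between Δz and subsequent contact
duration.

Both tracks are exposed as scikit-learn-style estimators
(`CountStandardizer`, `ActivationPatternMapper`, `AirPLSBaseline`) plus
plain functions, a CLI (`iegmap simulate|classify|apdist|photom|run`), and a
one-command pipeline with byte-deterministic report bundles.

## Worked example

```python
from iegmap import CountSimConfig, gen_cell_counts, classify_and_map

table, truth = gen_cell_counts(CountSimConfig(
    n_per_group=20, effect_regions=("IC",), effect_size=4.0, seed=42))
results, joint = classify_and_map(table)
for res in results:
    top3 = ", ".join(f"{r}={v:.3f}" for r, v in res.ranking[:3])
    print(f"{res.comparison[0]} vs {res.comparison[1]}: "
          f"nominated={res.nominated_region}  |A| top3: {top3}")
print(joint.head(3).round(3))
```

prints

```
R-ket vs saline: nominated=IC  |A| top3: IC=0.346, OFC=0.161, S2=0.156
R-ket vs S-ket: nominated=IC  |A| top3: IC=0.502, S2=0.213, VTA=0.205
    R-ket_vs_saline  R-ket_vs_S-ket  min_abs
IC            0.346           0.502    0.346
S2            0.156           0.213    0.156
MD            0.140           0.144    0.140
```

Here a 4-SD insular-cortex effect was planted in the simulated R-ketamine
group; the forward-model pattern puts the IC on top in both comparisons
(the `joint` table is the tabular form of the two-classification scatter:
its `min_abs` column scores contribution to *both* discriminations). At the
original study's size (n = 5 per group) the same ranking is intrinsically
noisy — see `docs/methods.md` for the power analysis.

The full synthetic study (counts → classification → coordinates →
photometry cohort → statistics) is one call:

```sh
iegmap run --seed 1 --out out/
```

which reports the nominated region and writes the report bundle (all input
CSVs, ground truth, per-comparison JSON, AP histogram, z-traces, per-event
Δz, session statistics, provenance).

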