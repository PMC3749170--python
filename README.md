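# paleoallom

Allometric inference of reproductive traits across the extant
phylogenetic bracket of non-avian dinosaurs — and its application to the
fossil record.

Egg-laying amniotes invest in reproduction along power laws of body
mass: egg mass (EM), clutch mass (CM = EM × CS, with CS the clutch
size) and annual clutch mass (ACM = CM × CY, with CY the clutches laid
per year) all scale as

    Y = c · BM^b,

a straight line on log10–log10 axes. `paleoallom` fits these laws by
OLS for extant calibration groups (birds, crocodiles, tortoises), tests
whether the groups' lines are statistically homogeneous (ANCOVA
slope-interaction and group F-tests), merges homogeneous models into
common-slope or fully pooled "reptile"-style models, and computes 95%
prediction intervals for a single new observation. The merged model set
is then applied to fossil dinosaur taxa, for which body mass, egg
size/mass and clutch size are documented but breeding frequency is not:

    CS_model = CM(BM) / EM    — clutch size implied by an extant model
    AEN      = ACM(BM) / EM   — annual egg number
    CY       = AEN / CS_fossil — clutches per year

with min/mean/max fossil ranges propagated, CY brackets from the fossil
clutch-size extremes, and each fossil trait value classified against
every model's prediction band. It is aimed at comparative
life-history and paleobiology work where a reproducible, tested version
of this chain — rather than a spreadsheet — is wanted.

## Worked example

Fit and merge models on a synthetic calibration table, then estimate
reproductive output for a titanosaur oospecies using the bundled models
recovered from published estimates:

```bash
$ paleoallom simulate --seed 1 --out sim
$ paleoallom fit --extant sim/extant.csv --out models.yaml
EM: 3 model(s): bird, crocodile, tortoise
CM: 3 model(s): bird, crocodile, tortoise
ACM: 2 model(s): bird, reptile
```

The merge stage found bird egg mass to scale differently from the two
reptile groups, one common clutch-mass slope with three distinct
normalization constants, and crocodile/tortoise annual clutch mass
indistinguishable — hence a pooled reptile ACM model (2 models instead
of 3).

```python
>>> from paleoallom import propagate_ranges
>>> from paleoallom.datasets import load_dinosaur_taxa, reference_model_sets
>>> from paleoallom.reporting import render_tables
>>> models = reference_model_sets()
>>> taxa = {t.taxon: t for t in load_dinosaur_taxa()}
>>> print(render_tables(propagate_ranges(taxa["Megaloolithus patagonicus"], models)).to_string(index=False))
                    taxon BM_kg EM_kg CS_fossil CS_tortoise AEN_reptile       CY_reptile CS_crocodile CS_bird AEN_bird           CY_bird
Megaloolithus patagonicus  5000 1.741        28        16.0        47.8   1.7 [1.2, 3.2]         45.9   107.1    119.1    4.3 [3.0, 7.9]
Megaloolithus patagonicus 22399 1.741        28        46.5       141.7   5.1 [3.5, 9.4]        134.4   313.3    353.0  12.6 [8.8, 23.5]
Megaloolithus patagonicus 75000 1.741        28       110.1       340.1 12.1 [8.5, 22.7]        319.5   743.9    847.3 30.3 [21.2, 56.5]
```

Reading the middle row: a 22,399 kg sauropod laying 1.741 kg eggs would
produce about 142 eggs per year if its annual reproductive investment
scaled like an extant reptile's (353 under the bird model). Divided by
the 28-egg fossil clutch, that implies roughly five clutches per year
(reptile model), between 3.5 and 9.4 given the reported clutch-size
range of 15–40 eggs. Even the largest (75,000 kg) producer never
exceeds ~850 eggs per year under any model.

The full pipeline (`paleoallom run --extant ... --fossil ... --out ...`)
writes a report bundle: homogeneity p-values, serialized models,
full-precision and formatted estimate tables, prediction-band
classifications and a run log.

## Layout

| module | contents |
| --- | --- |
| `paleoallom.records` | validated record types (extant species, fossil taxa, egg specs) |
| `paleoallom.io` | delimited-table readers/writers with unit handling |
| `paleoallom.allometry` | log-log OLS, fixed-slope refits, prediction intervals |
| `paleoallom.model_selection` | ANCOVA homogeneity tests, merging decision tree, serialization |
| `paleoallom.fossil` | egg mass from dimensions, CS/AEN/CY estimators, classification |
| `paleoallom.simulate` | seeded synthetic calibration data and fossil taxa with ground truth |
| `paleoallom.datasets` | bundled dinosaur table and recovered reference models |
| `paleoallom.reporting`, `.pipeline`, `.cli` | report tables, pipeline, command line |

See `docs/methods.md` for the statistical conventions (merging rules,
interval degrees of freedom, rounding) and known limitations.
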