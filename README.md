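# uvcblink

Integrative chemical–biological characterization and grouping of complex
(UVCB-type) substances: nontarget ion-mobility mass-spectrometry feature
annotation, concentration–response potency derivation, ToxPi-style
bioactivity scoring, hierarchical grouping, and penalized-regression
association between chemistry and bioactivity — plus a fully seeded
synthetic data generator with recoverable ground truth.

## Why

Petroleum-derived and other complex substances contain hundreds of
constituents that cannot be enumerated analytically, yet regulatory
grouping and read-across need a defensible, quantitative link between
what a substance *is* (its constituent profile) and what it *does* (its
bioactivity across cell types). This package implements that workflow end
to end:

1. **Chemistry** — filter nontarget features, anchor them to known
   constituents (±5 ppm m/z, ±1 % CCS), organize them into CH₂ homologous
   series by Kendrick mass defect, propagate molecular formulas along
   validated series (CCS must increase with mass), and summarize
   composition (percent abundance, ≥1 %/0.1–1 %/<0.1 % bins, 80 %
   characterization coverage, carbon × DBE classes).
2. **Bioassay** — normalize plate readouts to method blanks (vehicle =
   100 %), run QC gates, fit Hill curves, and derive EC10 points of
   departure with explicit two-sided censoring rules.
3. **Scoring** — per-cell-type ToxPi slices from log-scaled PODs and an
   equal-weight overall bioactivity score.
4. **Grouping** — agglomerative clustering on standardized
   homologous-series share profiles, Newick export, ARI concordance.
5. **Association** — multivariate ridge regression (features > 1 %
   predicting bioactivity scores), leave-one-out tuning over
   λ ∈ 10^(−1…6), permutation z-test on cross-validated prediction
   correlations with Benjamini–Hochberg correction, and per-feature
   attribution.

See [`docs/methods.md`](docs/methods.md) for precise definitions,
conventions and limitations.

## Worked example

A synthetic 25-substance panel carries a planted driver cluster — seven
co-occurring heavy-aromatic homologues whose content drives potency. The
association stage recovers both the chemistry→bioactivity link and the
drivers themselves (`examples/05_associate_chem_bio.py`):

```text
predictors: 25 substances x 143 features (> 1%)

selected lambda: 63.1

permutation test per response:
                    r       z       p       q
cardiomyocyte  0.7014  3.1038  0.0019  0.0023
endothelial    0.7320  3.2602  0.0011  0.0022
hepatocyte     0.7011  3.1462  0.0017  0.0023
huvec          0.8355  3.7656  0.0010  0.0022
neuron         0.8524  3.9894  0.0010  0.0022
overall        0.5481  2.4085  0.0160  0.0160

top features by |r| with the overall score:
            overall  is_planted_driver
feature_id
F0274         0.838               True
F0279         0.817               True
F0278         0.798               True
F0275         0.783               True
F0273         0.747               True
F0277         0.679               True
F0276         0.670               True
F0104        -0.457              False
...
```

All seven planted drivers rank at the top by |r| with the overall score,
and every response is significant after multiple-testing correction.
The code behind this:

```python
from uvcblink import association, bioassay, chem_features, synthetic, toxpi
import pandas as pd

panel, truth = synthetic.generate_feature_matrix(
    synthetic.PanelConfig(seed=1, series_length=33))
pct = chem_features.percent_total_abundance(
    chem_features.filter_by_abundance(panel, 5000.0))
X = association.build_predictor_matrix(pct, min_pct=1.0)

effect = synthetic.default_planted_effect(panel, truth, noise_cv=0.05)
bio = synthetic.generate_bioassay_plates(
    panel, effect, synthetic.PlateDesign(phenotypes_per_cell_type=2), seed=1)
pods, _ = bioassay.pods_from_plates(bio.plates)
Y = pd.DataFrame({ct: p.scores for ct, p in toxpi.celltype_toxpi(pods).items()})
Y["overall"] = toxpi.overall_toxpi(Y).scores

observed, perm = association.permutation_test(X, Y.loc[X.index], n_perm=1000, seed=1)
print(perm.table)
```

The other narrative scripts in [`examples/`](examples/) walk each stage:
chemistry characterization (`01`), POD derivation (`02`), ToxPi scoring
(`03`), grouping (`04`), and the one-call pipeline (`06`).

## Command line

The whole workflow (or any prefix of it) runs from the shell; synthetic
inputs are generated when no input files are configured:

```bash
uvcblink all --outdir run --seed 7          # everything
uvcblink chem --config my_run.yaml          # chemistry only
uvcblink synth --outdir inputs --seed 3     # just write synthetic inputs
```

Every workflow threshold (abundance filter, ppm/CCS tolerances, predictor
cut, POD departure, λ grid, permutation count, QC correlation) is a named
YAML key with the standard value as default; `manifest.json` in the run
directory records the full configuration, conventions and input hashes.

## Reproducing results

```bash
python -m pytest -q tests/                  # unit + acceptance suites (~2 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script runs the main computations on seeded synthetic
panels — formula recovery, POD recovery error, permutation-test null
calibration, power and driver recovery of the planted signal, clustering
concordance, and one full panel analysis — and writes each quantity with
its sample size as JSON. All randomness derives from `--seed`.

## Layout

```
src/uvcblink/
  formula.py        molecular formulas, DBE, Kendrick mass defect
  matrix.py         FeatureMatrix and anchor-library IO
  synthetic.py      seeded panel + plate generators with ground truth
  chem_features.py  filtering, anchoring, series/formulas, composition
  bioassay.py       normalization, QC, Hill fits, EC10 PODs
  toxpi.py          slice values, cell-type and overall scores
  grouping.py       hierarchical clustering, Newick, concordance
  association.py    ridge, LOOCV tuning, permutation inference
  pipeline.py       orchestration + manifest
  cli.py            click front end
tests/              unit suites + tests/test_acceptance.py
examples/           narrative scripts, one per capability
docs/methods.md     methods note
```
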