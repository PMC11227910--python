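# pnb — phylogenetic neighborhood analysis of seedling survival

`pnb` is a tested, reusable pipeline for neighborhood analyses of seedling
survival in stem-mapped forest dynamics plots. It computes focal-individual
phylogenetic neighborhood indices with permutation-based null models,
density and habitat covariates, and compares binomial mixed models across
phylogenetic index variants, temporal scales, and spatial scales. A
synthetic plot generator with known ground truth stands in for field data.

## What it does

Given a Newick phylogeny of the plot species pool, a stem-mapped adult
census, annual seedling quadrat censuses, and a per-quadrat habitat table,
the pipeline:

1. validates and cross-references all inputs (`pnb.io_core`);
2. computes patristic distances from the tree (`pnb.phylogeny`);
3. builds conspecific density covariates (`s_con`, `a_con`) and
   heterospecific neighbor profiles per focal seedling (`pnb.neighborhood`);
4. computes four phylogenetic indices per focal and neighbor layer —
   total, mean, and minimum patristic distance plus standardized effect
   sizes of the mean and minimum against a 999-draw label-shuffling null
   (`pnb.indices`);
5. derives topography (elevation, convexity, slope) from corner elevations
   and reduces the 13 topographic + soil variables by correlation-matrix
   PCA, keeping canopy openness separate (`pnb.habitat`);
6. fits logit-link Bernoulli mixed models with crossed quadrat and species
   random intercepts by Laplace maximum likelihood — implemented in-package
   and validated against plain logistic regression at the zero-variance
   boundary and against simulation ground truth (`pnb.model`);
7. scans the full factorial of 4 index variants x temporal intervals
   (1/2/3-year) x spatial windows (1/2/4 ha), producing AIC comparison and
   effect-classification tables (`pnb.scan`);
8. simulates complete synthetic datasets — pure-birth tree, Thomas-cluster
   stem maps, latent-factor habitat, dispersal-coupled seedling placement,
   and survival generated from the same standardized covariates the models
   fit — for calibration and parameter-recovery testing (`pnb.synthetic`).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the eight acceptance suites (index oracle
equivalence, exhaustive null enumeration, SES calibration, topography
closed forms, GLMM degenerate-limit oracle, parameter recovery with CI
coverage and type-I error, scan self-consistency, pipeline determinism).
The full suite takes roughly 10 minutes on one CPU; the recovery suites
dominate.

## CLI

```sh
# generate a synthetic plot (adults/seedlings/quadrats/habitat CSVs,
# tree.nwk, truth.json, config.yaml)
pnb simulate --seed 1 --out data/

# per-focal density covariates + phylogenetic indices
pnb indices --data data/ --tree data/tree.nwk --out indices.csv \
    --n-null 999 --seed 1

# one model fit
pnb fit --data data/ --tree data/tree.nwk --indices indices.csv \
    --variant apd --start 2020 --end 2021 --out fit.json

# the full factorial scan -> comparison.csv, effects.csv, run.log
pnb scan --data data/ --tree data/tree.nwk --out scan/ \
    --windows 1ha,2ha,4ha --spans 1,2,3 --variants totpd,avepd,apd,ntpd \
    --seed 1 --n-null 999

# summarize
pnb report --scan-dir scan/
```

`pnb simulate --config cfg.yaml` accepts a YAML file with any `SimConfig`
field (plot extent, species pool sizes, abundance/spatial/habitat model
parameters, survival coefficients `beta`, random-effect SDs).

## Input formats

All inputs are plain CSV (UTF-8, header row, `.` decimal) plus one Newick
tree. `adults.csv`: `tag,species,x,y,dbh` (meters in the plot frame, dbh in
cm, >= 1). `seedlings.csv`: `tag,quadrat_id,species` plus
`status_<year>,height_<year>` per census (`alive`/`dead`/`unrecruited`;
heights in cm, >= 20 at first alive census). `quadrats.csv`:
`quadrat_id,subplot_row,subplot_col[,center_x,center_y],elev_c1..elev_c4`
(subplot corner elevations SW,SE,NE,NW; explicit centers override the
placement rule for relocated quadrats). `habitat.csv`: `quadrat_id`, ten
soil variables (`ph,ec,c,ap,ak,tn,tp,tk,soil_temp,soil_moist`) and `gli`
canopy openness. Species labels must byte-match tree tip labels.
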