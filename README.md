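# psem — piecewise SEM for multi-species camera-trap counts

`psem` infers how a mammalian community is structured — top-down
regulation by predators, bottom-up regulation by prey availability, and
direct landscape effects — from camera-trap occurrence counts. It is
written for ecologists analysing multi-species detection data at a set
of camera stations, each characterised by landscape covariates
(elevation, terrain ruggedness, forest cover, road density).

The method is piecewise structural equation modeling: a hypothesized
causal DAG over species and covariates is fitted by *local estimation* —
one Poisson log-link GLM per species,

    log E[y_v] = b0 + Σ_{u ∈ parents(v)} b_uv · x_u,

with covariates centred/scaled and species predictors entering as raw
counts. Global fit is assessed through the DAG's testable independence
claims (tests of directed separation): each non-adjacent pair should be
conditionally independent given its parents, and the claim p-values
combine into Fisher's C = −2 Σ ln p_i ~ χ²(2k). A complementary χ²
statistic compares the model's equations against saturated counterparts.
The package also implements the stepwise optimization protocol
(whitelist-guarded path additions that must lower C, correlated errors
for unexplained species–species associations, sign-mismatch pruning),
model combination, standardized effect sizes, Nagelkerke pseudo-R², and
a synthetic-data generator for calibration and parameter-recovery
experiments. See `docs/methods.md` for the full statistical account.

## Worked example

Simulate a 140-station survey from the packaged combined model (the
final community DAG with its published coefficients) and run the full
three-model study — optimize the a-priori top-down and bottom-up models,
combine them, and compare fits:

```bash
psem simulate --n 140 --seed 42 --out synth.csv
psem run-study --data synth.csv --outdir study_out
```

which prints

```
             Model          C          C_p  C_DF       chi2       chi2_p  chi2_DF  poor_fit
          combined  57.760923 5.339019e-02    42  36.453973 6.498832e-02       25     False
bottomup_optimized 336.048202 4.728690e-35    74 296.322236 2.676836e-41       39      True
 topdown_optimized 519.217272 4.601260e-68    74 469.726943 3.432094e-74       41      True
```

Read: the combined model's Fisher's C is non-significant (C = 57.8 on
42 df, p = 0.053 > 0.05), so its independence claims — the paths it
*omits* — are consistent with the data, while the pure top-down and
bottom-up models are firmly rejected: on data whose truth contains both
kinds of pathway, neither one-process model can explain the community.
`study_out/` then holds the model-comparison table, the combined model's
per-path coefficient table (estimate, SE, residual df, Wald p,
standardized estimate), per-model goodness-of-fit JSON, and a GraphViz
diagram of the combined DAG (solid = positive, dashed = negative paths).

The same pipeline runs on field data: a CSV with one row per
station×season and columns `station_id, season, elevation, tri, forest,
road_density` plus one count column per species (`lynx, wolf, fox,
wildcat, hare, red_deer, roe_deer, wild_boar`). The library surface
(`read_station_table`, `scale_covariates`, `basis_set`,
`evaluate_model`, `optimize`, `combine`, `run_study`,
`parameter_recovery`, …) exposes every stage individually.

One test refits the packaged combined model against the study's
deposited station table; to run it, place that archive's data as
`data/romania_sem_stations.csv` (it is not distributed here).

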