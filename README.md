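# pfsskit

Quality assessment of protein structure models by comparison of functional-site
predictions, and benchmarking of structure-prediction groups built on top of it.

## The problem and the approach

Standard model-quality metrics (LDDT, the GDT/GDC family, RMSD) measure
distance agreement between a structure model and the experimentally determined
reference structure. `pfsskit` implements a complementary, function-oriented
measure: how faithfully a model reproduces the *functional-site* character of
the reference structure, as seen by a library of SeqFEATURE functional-site
prediction models (e.g. a protein phosphatase 2C aspartate-OD2 site model).
Each SeqFEATURE model emits a raw score for the microenvironment around an
anchor atom; with per-model calibration constants (μ, σ) the raw score becomes
a Z-score and, through the standard normal CDF Φ, a cumulative probability
p = Φ((raw − μ)/σ).

For a reference-side prediction with probability `p_ref` (included only when
its Z-score exceeds the per-model ≥90%-specificity threshold) and the
prediction at the corresponding site of a model with probability `p_model`:

```
difference  d    = |p_ref − p_model|
similarity  SS   = 1 − d
PFSS             = SS / γ
```

where the normalization factor γ is the mean of `p_ref` over the included
reference predictions of that SeqFEATURE model within that structural domain
(so PFSS may slightly exceed 1). Aggregation is unweighted at both upper
levels: per (group, domain), site PFSS values are averaged within each
SeqFEATURE model and the per-model means are averaged to the per-domain gPFSS;
a group's final **gPFSS** is the mean, and its **cumPFSS** the sum, of its
per-domain values over the domains it modeled — cumPFSS rewards both quality
and coverage.

On top of the scores, the benchmarking layer provides group rankings,
Pearson correlation and OLS regression of each standard metric on gPFSS with
leverages and internally studentized residuals (|r| > 3 flags an outlier by
the three-sigma rule), and pairwise Mann–Whitney U comparisons of per-domain
gPFSS arrays among full-coverage groups with a Bonferroni-corrected threshold
α/m.

A seeded synthetic-campaign generator produces every input table (per-model
calibrations, reference hit sites, per-group model scores with controlled
error levels, and standard-metric tables correlated with the injected error),
so the whole pipeline is testable end to end without any real model archive.

## Worked example

A PP2C.6.ASP.OD2 site predicted at Asp 1003 of domain T1169-D4. The reference
probability is 0.9935; a second included reference site at residue 1010 has
probability 0.9515, so γ = (0.9935 + 0.9515)/2 = 0.9725. The first
`Yang_Server` model attempt scores the site 0.0493 lower than the reference.

```
$ pfsskit score --ref-sites reference_sites.tsv --model-sites model_sites.tsv \
    --calibration calibration.tsv --domains domains.tsv --out out
sites read: 2; included: 2; pairs: 1; skipped (no model counterpart): 1
```

`out/gamma.tsv` and `out/pairs.tsv` then contain:

```
sf_model_id     domain_id  gamma
PP2C.6.ASP.OD2  T1169-D4   0.9725

sf_model_id     domain_id  group_name   diff    similarity  pfss
PP2C.6.ASP.OD2  T1169-D4   Yang_Server  0.0493  0.9507      0.9776
```

i.e. PFSS = (1 − 0.0493)/0.9725 = 0.9776: the model reproduces the predicted
phosphatase site almost perfectly. (The residue-1010 reference site
contributes to γ but has no model-side counterpart, so it is logged as
skipped rather than scored.)

A full synthetic benchmark runs the same way:

```
$ pfsskit simulate --out sim --seed 7 --n-groups 8 --n-targets 6 --n-sf-models 8
$ pfsskit report --ref-sites sim/reference_sites.tsv --model-sites sim/model_sites.tsv \
    --calibration sim/calibration.tsv --domains sim/domains.tsv \
    --metrics sim/metrics.tsv --out sim/out
groups assessed: 8; pairs: 510; skipped sites: 19
LDDT: r=0.9964 p=1.169e-07
GDT-TS: r=0.9968 p=8.472e-08
RMS-CA: r=-0.9990 p=2.215e-09
pairwise: 15 comparisons, 10 significant at alpha_corrected=0.01
```

The rankings table (`sim/out/rankings.tsv`) then lists groups by cumPFSS with
gPFSS ± SD, per-metric averages, and domain counts; groups with small injected
error rank highest, and gPFSS correlates strongly with the synthetic LDDT, as
it should when the metric tracks true model error.

## Layout

- `pfsskit.io` — typed TSV readers/writers for sites, calibrations, domains
  (with discontinuous residue ranges) and standard-metric tables
- `pfsskit.calibration` — Z-scoring, Φ-calibration, specificity filter
- `pfsskit.pfss` — difference/similarity scores, γ, PFSS, aggregation
- `pfsskit.pipeline` — campaign orchestration and result-table I/O
- `pfsskit.stats` — rankings, correlations, regression diagnostics,
  Mann–Whitney comparisons with Bonferroni correction
- `pfsskit.synthetic` — seeded synthetic campaign generator
- `pfsskit.cli` — `pfsskit simulate|score|aggregate|rank|correlate|compare|report`

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
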