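# Methods

## Scoring model

Raw functional-site scores are assumed normally distributed per SeqFEATURE
model. The calibration table supplies, per model, the mean μ and standard
deviation σ of raw scores on a large reference corpus and the Z cutoff
`z_threshold` achieving at least 90% specificity. These constants are
*inputs*: the package does not re-derive score distributions or ROC curves.
A raw score becomes z = (raw − μ)/σ and a probability p = Φ(z), computed in
double precision through the error function (`scipy.special.ndtr`);
invariant tests hold Φ(z) + Φ(−z) = 1 to 1e−12.

Reference-side predictions enter an analysis only when z is **strictly**
greater than `z_threshold`; ties at the threshold are excluded. Model-side
predictions at the matched sites are never filtered — the reference side
anchors the site list, and the model is scored at those sites whatever its
probabilities are.

Sites are matched between reference and model on (SeqFEATURE model, residue
number, anchor atom). Residue numbers are author numbering from the
coordinate files; domains are defined by 1-based inclusive, possibly
discontinuous residue ranges and are assumed single-chain, so chain identity
does not participate in matching by default (`require_chain_match=True`
turns it on for multi-chain targets). A reference site with no model-side
counterpart is skipped and counted in the run log; the alternative
`missing_policy="penalize"` scores it as if the model probability were 0.
Skipping is the default because models in a benchmarking campaign normally
cover their domains, and an absent residue usually reflects a trimmed
submission rather than a catastrophically wrong site.

γ is computed per (SeqFEATURE model, domain) as the arithmetic mean of the
included reference probabilities, from the supplied reference-site table
alone. When a key has no included sites it is absent from the γ table and
that model simply contributes no pairs in that domain. Because every included
reference probability is in (0, 1], γ ∈ (0, 1] and PFSS = SS/γ can exceed 1.

The stored difference score is always the absolute value; the signed raw
difference is recoverable as `p_model − p_ref` from the pair table.

Aggregation is strictly "average of averages": site PFSS → per-model mean →
per-domain gPFSS (each model weighted equally regardless of site count) →
group gPFSS (mean over domains) and cumPFSS (sum over domains). Sums use
`math.fsum`; cumPFSS = n_domains × gPFSS holds to 1e−12 by construction.
Multiple submitted attempts per group: the default scores attempt 1 only;
`attempt_policy="best"` keeps, per (group, domain), the attempt with the
highest per-domain gPFSS (ties broken toward the lower attempt number).

## Benchmark statistics

Rankings are dense (tied scores share a rank), descending for cumPFSS/gPFSS
and the LDDT/GDT/GDC family, ascending for RMS metrics, with lexicographic
tie-breaks for determinism. Correlation/regression uses one point per group —
the group's gPFSS against its mean metric value over the chosen domain set —
with no weighting by the number of domains addressed, even though that number
varies considerably between groups. Category filtering (FM, TBM-easy, …)
happens before all statistics, each category giving an independent analysis
set.

Regression diagnostics are an OLS fit (statsmodels) with leverages
h_ii = 1/n + (x_i − x̄)²/Σ(x_j − x̄)² and internally studentized residuals
e_i/(s·√(1 − h_ii)); |residual| > 3 flags an outlier (configurable). The
diagnostics require n ≥ 4 points so the residual standard error has ≥ 2
degrees of freedom; with exactly 3 groups only the correlation is reported,
and below that the metric is skipped with a warning. Note that an internally
studentized residual is bounded by √(n − 2), so no point can be flagged at
the 3-sigma level in samples smaller than n = 12; outlier detection is
meaningful only for reasonably populated categories.

Pairwise Mann–Whitney U comparisons are restricted to groups that addressed
every domain of the chosen set, compared on their aligned per-domain gPFSS
arrays. With k qualifying groups each group takes part in m = k − 1
comparisons, and the Bonferroni-corrected threshold is α/m (0.05/51 ≈ 0.00098
for 52 groups). The exact U null distribution is used for combined samples
≤ 20 without ties; otherwise the tie-corrected normal approximation — the
standard switch-over, verified against exhaustive enumeration for all
combined sizes ≤ 10 in the test suite.

As a finer-grained follow-up to the per-domain comparison,
`pfss.per_model_pfss` pools a group's site PFSS values into one mean per
SeqFEATURE model over all of the group's pairs in the chosen target set; two
groups can then be compared with a Mann–Whitney U test on the per-model
averages of the models they share. This pooling (all pairs of the target
set, one average per model) is this package's chosen interpretation of a
model-level comparison; other poolings (e.g. per model per domain) are
possible.

## Synthetic campaigns

The generator emulates the full data flow rather than sampling PFSS values
directly: per SeqFEATURE model it draws μ ~ U(−20, 80) and σ ~ U(4, 20)
(raw-score units of the same order as real microenvironment scores), sets
`z_threshold` to the 90th percentile of a 2000-sample simulated background,
and draws reference hits from the truncated normal above the threshold by
inverse-CDF sampling (exact and seed-stable). Group error enters on the
**raw-score scale** — model raw score = reference raw score +
N(0, error_scale·σ) — so Z-scoring and Φ-calibration are exercised end to
end. Each group covers a `coverage_fraction` subset of domains. Synthetic
LDDT/GDT-TS (RMS-CA) per (group, domain) are decreasing (increasing)
deterministic functions of the group's realized mean |Δp| plus N(0, 0.01)
noise, giving metric tables correlated with true error as real metric tables
are.

Default dimensions are about a quarter of a full CASP-scale campaign — 26
domains (13 targets × 2), 20 SeqFEATURE models, 30 groups with error scales
log-spaced over [0.02, 2.0], Poisson(5) sites per domain (floored at 1),
category labels drawn with probabilities (0.40, 0.37, 0.12, 0.08, 0.03)
matching a mixed-difficulty target census — chosen to keep a full simulate →
report cycle interactive on one CPU.

What the synthetic data does *not* emulate: 3D coordinates and real
microenvironment feature vectors, correlated errors between neighboring
sites, model-specific failure modes (a real group's error is not homoscedastic
Gaussian on the raw-score scale), chain breaks, and reference sites absent
from models for structural reasons. Passing tests therefore demonstrate the
correctness and sensitivity of the scoring and statistics machinery under a
controlled error model, not the empirical behavior of any particular
structure-prediction method on real targets.

## Numerical and formatting choices

- Tables written by `pfsskit.io` and the pipeline result writers carry full
  shortest-roundtrip float precision, making write→read an identity; the
  report-level tables (rankings/diagnostics/pairwise) are human-facing and
  formatted at 4 decimals, with p-values in 4-significant-digit scientific
  notation.
- The worked example fixes γ = 0.9725 (mean of reference probabilities
  0.9935 and 0.9515), under which (1 − 0.0493)/γ = 0.9776 at 4 decimals.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  spec + seed gives byte-identical output tables.
- Degenerate inputs fail loudly with typed exceptions (empty aggregation,
  non-positive σ or γ, zero-variance correlation, degenerate leverages)
  rather than returning NaN.

## Known limitations

- Quality is assessed only at predicted functional sites, not at every
  residue; domains with no included reference predictions contribute nothing
  and simply drop out of a group's domain set.
- A high-probability functional-site prediction need not correspond to a
  biologically real site; the similarity of predictions remains a valid
  structural-agreement signal regardless, but biological interpretation of
  individual sites requires manual review.
- γ estimated from few reference sites is noisy, and no uncertainty is
  propagated to PFSS or gPFSS.
- The pairwise-comparison campaign requires strict full coverage of the
  domain set; a group missing one domain is excluded rather than compared on
  its subset.
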