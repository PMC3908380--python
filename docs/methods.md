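# Methods

## Data model

An experiment is a set of MS runs. Test runs belong to a *bait group* —
one bait protein purified under one condition, with its biological
replicates; control runs come from a cell line expressing no tagged bait
(or an unrelated tag such as GFP) and are shared globally across all bait
groups. Each (bait, condition) combination is treated as a distinct
purification, so the same bait at two time points forms two bait groups
and conditions are scored independently; `K` counts bait groups within
the experiment being scored. The only measurement is the spectral count
`SC` of each prey in each run; an absent entry means `SC = 0` — spectral
counting does not distinguish "missing" from "not detected". Prey lengths
must be supplied (the package does not infer them from sequence
databases). Bait self-detections are scored but flagged, since a
purification always contains its own bait.

## Scoring

For a pair (bait group *i*, prey *j*) with replicate SC vector of length
`T`, `N` detecting replicates, and `Σf` bait groups detecting the prey:

```
score_ij = NSAF̄_ij · (1 − FDR_ij)^T · W_j · (K/Σf)^(N/T)
```

**NSAF.** Per run, `NSAF_j = (SC_j/L_j) / Σ_k (SC_k/L_k)` over the
detected preys; values sum to 1 exactly. The pair's abundance is the
arithmetic mean over all `T` replicates, counting zero for replicates
without a detection.

**Cross-purification statistics.** `W_j` and the `Z` baseline need one SC
value per purification; replicates are collapsed to their mean SC
(including zeros), the same averaging used everywhere else in the
pipeline. The standard deviation is population-form (divide by `K`) by
default — this keeps `Z` well defined at `K = 2` and makes the per-prey
`Z` values sum exactly to zero — with the sample convention available in
`ScoringConfig`. `W_j = std_j/mean_j` whenever that ratio exceeds
`w_threshold` (default 0, i.e. any positive variation is used; 1
reproduces the original CompPASS convention), and `W_j = 1` otherwise,
including the degenerate all-zero profile.

**Reproducibility exponent.** The uniqueness ratio `K/Σf ≥ 1` is
exponentiated by `R = N/T ∈ (0, 1]`. The default groups the exponent with
the frequency ratio only, `W · (K/Σf)^R`; the alternative reading
`(W · K/Σf)^R` is available as `exponent_mode="joint"` for sensitivity
checks. The baseline weighted-D score keeps its original form
`sqrt(SC · ((K/Σf) · W)^N)`.

**Negative-control FDR.** The pair's replicate SCs are compared to the
prey's SCs across all control runs (both zero-filled) with a one-sided
Wilcoxon–Mann–Whitney test, alternative "bait stochastically greater" —
enrichment over control is what marks a specific interactor, and a
two-sided test would reward control-enriched contaminants. For pooled
sizes up to 12 (the default design is 3 + 6 = 9) the p-value is computed
by exact enumeration of all C(n₁+n₂, n₁) group assignments of the pooled
multiset with mid-ranks, so heavy zero-ties are handled exactly; larger
designs fall back to the normal approximation with tie and continuity
corrections. If all observations are equal, p = 1. The p-value is then
calibrated to a per-pair false discovery rate via the
Sellke–Bayarri–Berger bound `1/(1 + (−e·p·ln p)^{-1})`, clamped to its
supremum 0.5 outside the bound's validity region `p ≥ 1/e`, and p is
floored at 1e-16 before the logarithm. This is a per-pair calibration of
a single p-value, not a set-level multiple-testing procedure, and by
construction `FDR ∈ (0, 0.5]`.

The score is therefore zero iff the pair's mean NSAF is zero, strictly
decreasing in FDR, non-decreasing under uniform scaling of the pair's
SCs, and penalized multiplicatively as more baits detect the prey. Pairs
detected only in controls are never scored (`Σf = 0` for every bait).

## Filters

Filters flag rows, never delete them, and ranks are recomputed over the
survivors; flagging is idempotent and order-independent. The singleton
filter flags pairs whose every replicate SC is 0 or 1 — a single
spectral count per replicate is indistinguishable from noise. This
generalizes the one-SC-in-each-of-three-replicates case to any `T`; the
strict literal rule (all SCs exactly 1) is available as
`singleton_rule="strict_ones"`. The exclusion filter matches prey or bait
identifiers against editable glob-pattern lists organized in categories
(`[heat_shock]`, `[ribosomal]`, …); the package ships an example file,
not a hardcoded gene list, because contaminant membership is
organism- and annotation-dependent.

## Ranking and determinism

Ranks run 1..n over unfiltered rows by descending score, ties broken
lexicographically by (bait group, prey), so output is a pure function of
the input table and configuration; input row order never matters.

## Evaluation protocol

Methods are compared as ranked lists of unordered (bait symbol, prey
symbol) pairs — reciprocal detections of the same interaction collapse —
with condition labels stripped and, where several conditions score the
same pair, the best score kept. Against a reference set (e.g. BioGRID
physical interactions) the package computes top-k overlap curves,
pairwise top-k agreement between methods, full Venn-region counts of
several methods' top-k sets (regions always partition the union), and a
reference-guided score cutoff (default objective: F1 of known-pair
recovery over the scored list, with recall taken over the known pairs
present in the list; precision-at-fixed-recall is the alternative).
Top-k cuts are taken after deterministic tie-breaking so a top-k list is
always exactly k rows. Symbol mapping from prey accessions to gene
symbols happens at evaluation time only, so scoring is identifier-stable.

## Synthetic data

The generator emulates the assumed study design: 6 baits × 3 conditions
× 3 biological replicates plus 6 shared negative controls and 300 preys
by default. Counts are Poisson (negative-binomial overdispersion
optional, default off): planted true edges draw `Poisson(λ_true = 10)`
per replicate thinned by a per-replicate dropout (default 0.2); sticky
binders and named contaminants (`Hsp…`, `RpL…`, 5% of preys each) attach
to each bait with probability 0.7, draw `Poisson(λ_bg = 2)` in the runs
of attached baits, and are carried into each control run with probability
0.3; background preys produce sparse `Poisson(λ_bg)` detections at rate
0.02 per run; bait self-rows draw `Poisson(5·λ_true)`. True edges are
disjoint prey blocks per bait (8 per bait), shared across that bait's
conditions. Everything is a pure function of the configuration including
its seed.

These defaults are chosen to mimic the qualitative structure of
pathway-focused TAP/MS screens — strong, mostly-reproducible true
interactors; low-abundance promiscuous background present in controls —
at a size that scores in seconds. What the generator does *not* emulate:
peptide-level identification and protein inference, correlated
abundances within protein complexes, condition-dependent interaction
dynamics, batch effects between runs, and control runs whose background
composition differs from test runs. Benchmarks on this data therefore
demonstrate that the statistics behave as designed (control
discrimination, reproducibility weighting, frequency penalty), not that
the method achieves any particular accuracy on real screens.

The *noise-free configuration* used for the perfect-separation benchmark
turns off every stochastic noise channel — no dropout, deterministic
control carryover (probability 1), no sporadic background detections —
while keeping the sticky/contaminant structure, so scored negatives still
exist. (Zeroing the background rate entirely would leave no scored
negatives at all, making ranking metrics undefined.) Under it the
composite score ranks every planted edge above every nuisance pair
(AUROC = 1.0); with the default noise levels its AUROC stays above 0.9
and above the NSAF-only and Z baselines.

Benchmark metrics: AUROC is computed by the Mann–Whitney rank identity
with mid-ranks; bait self-rows are excluded; precision is reported at
k = number of planted positives among scored pairs.

## Numerical choices and degenerate inputs

* Exact-enumeration cap at pooled size 12: C(12,6) = 924 assignments,
  exact ties at trivial cost; configurable.
* p-values are floored at 1e-16 before `ln`; the calibration is
  continuous at `p = 1/e`.
* A run with no detections has an empty NSAF mapping (warning, not an
  error); a prey with zero length is rejected at load.
* Scoring refuses experiments without negative controls, and warns when
  a bait group has fewer than three biological replicates — the FDR
  calibration needs controls, and `R = N/T` is only informative with
  `T ≥ 3`.
* Score-table TSVs store floats at 10 significant digits; round-trips
  are exact at that precision.

## Known limitations

* The per-pair FDR is a calibration bound, not an empirical FDR; its
  0.5 ceiling means the score can at most halve per replicate for
  control-like pairs, it cannot zero them — the frequency and weight
  terms carry the rest.
* With very few bait groups (`K = 1`) the frequency and weight terms are
  uninformative and the score reduces to abundance × control evidence.
* The rank-sum test treats replicates as exchangeable; paired or batched
  designs are not modelled.
* Symbol collisions (two accessions mapping to one symbol) are resolved
  by the best score, which slightly favours methods with more scored
  rows in overlap comparisons.
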