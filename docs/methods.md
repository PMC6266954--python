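# Methods

## Model and procedure

`mirotype` characterizes validated miRNA–target pairs in one tissue +
condition cohort in three stages.

**1. Cohort assembly.** Up to three expression matrices (miRNA, gene:
FPKM-like, non-negative; protein: normalized array intensities, possibly
negative) are aligned on a shared sample set. Matching is by identical
sample ids, by barcode prefix (default length 15, i.e. a TCGA barcode
through its sample-type field, with aliquot columns of one group averaged
arithmetically on the FPKM scale), or by an explicit mapping file. Columns
are sorted before aliquot grouping so aggregation is bitwise independent of
input column order. A matched cohort below `min_samples` (default 8) is
refused: permutation p-values and sign estimates below that size are not
meaningful.

**2. Association testing.** For each catalog pair present in the matrices,
two m = 1 global tests are run, oriented along the regulatory arrow: the
gene profile is the response to the miRNA covariate, and (when the cohort
has protein data and the gene has a protein row) the protein profile is the
response to the gene covariate. The statistic is

    c_j = (x_j' r)^2 / (m s^2),   Q = sum_j c_j,

with r the centered (optionally transformed) response, x_j centered and
standardized covariates, and s^2 = r'r/n. For m = 1 this is a monotone
function of the squared Pearson correlation, so the permutation p-value
coincides with the two-sided permutation test of correlation; the group
form (m > 1, `group_target_test`) tests a miRNA against the set of its
targets and decomposes Q into per-target contributions, ranked with the
strongest anti-correlated targets first, anti-correlation being the
signature of genuine targeting.

The null (no covariate associated with the response) is exchangeable in
the response values, so p-values are permutation-based:

* **exhaustive** — all n! rearrangements, used automatically for n ≤ 9;
* **permutation** (default otherwise) — B seeded Monte-Carlo permutations,
  p = (b+1)/(B+1) with b the count of null statistics ≥ the observed one
  (the +1 floor avoids p = 0); B defaults to 10 000 and must be ≥ 999;
* **gamma** (opt-in) — upper tail of a gamma distribution matched to the
  exact first two permutation-null moments of Q. Because the covariate
  columns are centered, A = XX'/(m s^2) is doubly centered and r sums to
  zero, so E[Q] = tr(A)·r'r/(n−1) and E[Q²] reduce to closed forms in
  tr(A), tr(A²), the diagonal of A and the power sums of r, derived by
  enumerating index-coincidence patterns of the quartic form. The formulas
  are verified in the test suite against brute-force enumeration over all
  n! permutations at n = 5–7. Requires n ≥ 4; accuracy is that of a
  two-moment approximation — adequate at cohort scale (a simulated null at
  n = 100 rejects at the nominal 5% within binomial error) but not for
  tiny n, where enumeration is exact anyway.

Numerical choices: the observed statistic used for counting is evaluated
inside the same batched matrix product as the null statistics, so the
identity permutation always counts itself (different BLAS code paths can
disagree by one ulp); null statistics within 1e-9 relative of the observed
value count as ties (≥), since integer-valued data routinely produce
exactly tied rearrangements that last-ulp rounding would otherwise split
arbitrarily. Per-pair permutation seeds are spawned from the run seed via
`SeedSequence(entropy=seed, spawn_key=(pair_index, leg))` over the sorted
catalog, making results independent of catalog file order and reproducible
bit-for-bit.

Transforms: log2(v+1) for FPKM-like assays (FPKM is heavy-tailed;
correlation on the raw scale is dominated by outliers), none for protein.
Complete-case filtering is per pair — rows with an NA in either profile are
dropped and the surviving count is reported as `n_used` — maximizing the
usable n for each pair rather than intersecting NA patterns cohort-wide.
A constant profile, an exactly zero cross-product, or fewer than
`min_samples` complete cases flags the pair `untestable` rather than
dropping it silently.

**3. Classification.** With both legs significant at α (default 0.05,
gate p ≤ α, no multiple-testing correction by default; Benjamini–Hochberg
per test family — miRNA–gene and gene–protein adjusted separately within a
run — is opt-in via `mt_correction="bh"`):

| miRNA–gene sign | gene–protein sign | call |
|---|---|---|
| negative | positive | degradation |
| negative | negative | degradation |
| positive | negative | inhibition |
| positive | positive | no_interaction |

The (negative, negative) row is deliberately read as degradation:
transcript and protein abundances are imperfect proxies for each other, so
an anti-correlated protein leg under a decaying transcript does not
contradict degradation. Without protein data a significant negative
miRNA–gene leg is called degradation and a significant positive one
`no_interaction*` — the star marking that typing was limited by protein
availability. A non-significant required leg yields `no_evidence`; with
`require_both_significant=False` a non-significant protein leg instead
falls back to the protein-absent branch. `no_evidence` and `untestable`
are additions beyond the four biological types so that every catalog pair
receives exactly one call; a sign of exactly zero is a measure-zero event
and is treated as untestable rather than typed arbitrarily.

## Synthetic cohorts

The generator (`synth`) emulates the statistical structure the pipeline
assumes, not any particular dataset: i.i.d. log-normal FPKM marginals
(log2-mean 3, log2-sd 1.5 — right-skewed like real FPKM; the exact values
are immaterial to the tests), planted linear dependencies on the log scale
with slopes chosen so each leg's population correlation magnitude equals
`strength`, miRNA/gene values exponentiated to the FPKM scale (so the
pipeline's log2(v+1) transform approximately recovers the planted
structure), and protein kept on a standardized linear scale. Degradation
pairs get a negative miRNA→gene and positive gene→protein leg; inhibition
pairs the reverse signs; null decoys are fully independent and populate
the catalog so specificity is measurable. Protein rows cover every planted
gene plus a seeded `protein_coverage` fraction of the rest; coverage 0
drops the assay entirely (emulating a cohort with no protein data, e.g.
normal tissue). Each gene is generated from at most one parent miRNA.

Default study conditions for recovery experiments: n = 150 samples,
strength 0.6, 10 planted degradation + 10 planted inhibition + 100 null
decoys, α = 0.05, B = 10 000. What passing these tests shows: the stack
detects moderately strong planted linear signals at realistic cohort sizes
and does not over-type independent pairs. What they do not show: behavior
under real-data features the generator omits — inter-gene covariance,
batch effects, miRNA family cross-talk, dropout-style missingness, or
antibody→gene mapping noise in protein panels.

## Known limitations

* Protein features must already be keyed by gene symbol; no antibody-to-
  gene mapping is attempted (unmapped protein rows are simply never
  matched).
* The test is marginal per pair: no adjustment for clinical covariates and
  no shrinkage across pairs.
* Barcode prefix matching implements plain prefix grouping only, not full
  barcode semantics.
* The gamma approximation matches two moments; far-tail p-values from it
  are approximate and the permutation method remains the reference.
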