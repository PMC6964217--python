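# Methods

`pgnet` analyses curated disease–ncRNA association tables as a
phenotype–genotype network: clinical disease subtypes are phenotype nodes,
the ncRNAs reported for them (miRNA, lncRNA, circRNA) are genotype nodes,
and each literature-supported association is an undirected edge. The
package characterizes these networks four ways — degree-distribution shape,
a universal/specific class contrast, gene-set over-representation of the
classes' validated targets, and tissue-expression clustering of the
miRNAs that appear in sponge (ceRNA) ternary networks — and ships a
synthetic generator that reproduces the statistical structure these
analyses assume, so that every estimator can be validated by parameter
recovery.

## Data model and normalization

Inputs are UTF-8, tab-separated text with `#` comments. On ingestion:

- **miRNA names** are unified by rule: the `hsa-` species prefix is
  stripped and the family token is canonicalized (`MIR-21 → miR-21`,
  `LET-7B → let-7b`), preserving arm suffixes (`-5p`/`-3p`). The rules
  are idempotent and purely lexical; no registry lookup is attempted, so
  genuinely distinct aliases of one gene are not reconciled.
- **Disease labels** are mapped through an explicit merge map onto a
  23-label canonical cardiovascular catalog (e.g. "Acute heart failure"
  and "Chronic heart failure" fold into "Heart failure"; "Others" is the
  catch-all). Unknown labels fail loudly rather than fuzzy-match. The
  curated resource this emulates names only a few of its 23 phenotypes;
  the remaining catalog labels are plausible ICD-10 I05–I79 subtypes and
  can be replaced by a user catalog.
- **Duplicates**: repeated (ncRNA, disease) pairs collapse to one record.
  The biomarker flag is OR-merged (one supporting report suffices);
  conflicting expression directions collapse to `mixed`, a package
  convention for a case the source material leaves unspecified.

Ternary sponge tables keep one triple per row; a multi-gene mRNA cell
("BCL2/HSP60") stays in the triple and is split into individual genes when
network edges are emitted, so the sponge–miRNA pair count is row-faithful
while the miRNA–mRNA edge set is gene-resolved. The packaged ternary table
has 14 lncRNA–miRNA and 3 circRNA–miRNA pairs over 16 distinct miRNAs;
the published clustering analysis mentions 13 miRNAs, a roster that cannot
be reconstructed from the printed table, so the fixture carries all 16.
The packaged tissue-expression matrix is a synthetic stand-in (the source
values are not printed anywhere re-usable) with the described two-block
structure: one miRNA group high in stomach/kidney/liver/spleen/bone, the
other high in myocardium/muscle/colon/thyroid/artery.

## Degree-distribution model

Genotype-side degree counts *distinct diseases* per ncRNA, not supporting
articles. The scale-free hypothesis is the discrete power law

    P(k) = k^(-γ) / ζ(γ, xmin),  k = xmin, xmin+1, …

with ζ the Hurwitz zeta function. `DiscretePowerLaw.fit()` maximizes the
tail log-likelihood Σᵢ[−γ log kᵢ − log ζ(γ, xmin)] by bounded scalar
search on γ ∈ (1.01, 10) (tolerance 1e-9); `xmin` defaults to 1 because
association networks are fitted from k = 1, with an optional KS-minimizing
scan over observed degree values. Goodness of fit is the KS distance
between empirical and model tail CDFs, calibrated by a semi-parametric
surrogate test (resample from the fitted law, refit per surrogate, compare
KS distances); uncertainty in γ comes from a nonparametric percentile
bootstrap of the tail. A log–log least-squares slope of the empirical
P(k) is available for comparison with older regression-based estimates —
it is biased relative to the MLE and never used for inference. Degenerate
inputs refuse to fit: fewer than 3 tail observations, or a tail with no
variation. A fit whose maximum degree is below 3 carries a warning (two
support points barely constrain γ), and the pipeline stage skips such
networks outright — relevant because real lncRNA association networks top
out near k = 5.

Exact inverse-CDF sampling from the discrete law (lookup table for the
bulk, bisection on the zeta survival function for the far tail) serves
both the surrogate test and the synthetic generator. Estimator validation
is by closed loop: at n = 2000 tail samples the median |γ̂ − γ*| over 200
seeds is below 0.1 for γ* ∈ {2.1, 2.5, 2.9} (measured ≈ 0.02).

## Class contrast

miRNAs split at degree 2: *universal* (≥ 2 diseases) vs *specific*
(exactly 1). The biomarker-rate contrast between classes is reported
through three tests side by side — Fisher's exact (two-sided, via the
hypergeometric enumeration definition), chi-square with Yates correction,
and a label-permutation test on the absolute rate difference with the
add-one estimator p = (1 + #exceeding)/(n_perm + 1), default n_perm =
9999. No single test is privileged because the provenance of published
single p-values for this contrast is generally unstated; reconstructing
the obvious 2×2 table from published class sizes and rates (175 at 90.3%,
251 at 59.4%) gives Fisher p ≈ 3.5e-13, orders of magnitude beyond the
commonly quoted 0.005332, so that value is treated as unreproducible and
kept only as a regression fixture. The odds ratio is the sample ad/bc
with a Haldane–Anscombe 0.5 correction when a cell is zero.

Target coverage counts, per class, the distinct genes and the
(miRNA, gene) interactions restricted to class members; the essential
ratio is |class genes ∩ essential catalog| / |class genes| with exact
upper-cased symbol matching (no alias resolution — a documented
limitation relative to curated essential-gene mappings).

## Over-representation analysis

For each gene set, p_raw = P(X ≥ overlap) under the hypergeometric
distribution with the universe as population. The universe defaults to
the union of all collection members, since the universes of proprietary
pathway tools are unknown; a custom universe can be passed. BH ("FDR")
and Bonferroni adjustments come from statsmodels. The per-set enrichment
ratio is overlap/set_size. The default significance threshold is
p_raw < 0.01. The two-query overlap report counts significant sets per
query and their intersection by set name.

## Tissue-expression clustering

Rows (miRNAs) are z-scored (mean 0, sd 1 per row) before any distance is
computed, under both supported distances (1 − Pearson correlation, the
default, and Euclidean); linkage is average by default (complete
available); the row dendrogram is cut at k = 2 by default, matching the
expected two expression regimes. Rows that are constant (undefined
z-score) are held out of the linkage and assigned afterwards to the
nearest cluster centroid. Clustering is fully deterministic given the
matrix and options. On planted two-block matrices the split is recovered
exactly (ARI = 1) at noise sd 0.1 and in ≥ 95% of seeds at sd 0.2.

## Synthetic generator

`SyntheticConfig` defaults are the study conditions of the emulated
resource: 23 phenotypes; 426 miRNA, 99 lncRNA and 24 circRNA entries;
degree exponent 2.09; biomarker rates 0.903 (universal) and 0.594
(specific); per-miRNA validated-target counts Poisson with means 142 and
46 (the reported interaction totals divided by the class sizes:
24937/175 and 11444/251); essential-gene fraction 0.55 (between the
reported per-class ratios 57.8% and 54.1%); a 12000-gene pool; and a
16 × 10 expression matrix with two planted blocks at separation 2.0 and
noise sd 0.1. Degrees are drawn i.i.d. from the discrete power law
truncated at the number of diseases by exact renormalized inverse-CDF
sampling (equivalent to redraw-until-valid, which preserves tail shape
better than capping); each ncRNA's disease set is uniform without
replacement — disease popularity skew (heart failure first in the real
resource) is not modelled; biomarker flags condition on the realized
degree class (association, not causality). Every latent draw lands in a
truth record keyed by the single mandatory seed; identical configs give
byte-identical outputs.

What the generator does **not** emulate: literature/article multiplicity
behind each association, correlated disease co-reporting, miRNA family
structure in names or targets, gene–gene correlation inside gene sets,
and realistic expression dynamic range. Recovery of the generator's
parameters therefore validates the estimators' correctness under the
assumed structure, not their robustness to real curation artifacts.

A separate deterministic fixture constructs an association table whose
partition is exactly 175 universal and 251 specific miRNAs (426 total),
for count-level regression against the emulated resource.

## Pipeline and reproducibility

`pgnet run --config pipeline.yaml` executes
load/simulate → build → fit → contrast → ora → cluster and writes
networks (GraphML), `fit_<class>.json`, `contrast.json`, ORA TSVs,
`clusters.tsv`, a human-readable summary and a manifest recording
parameters and seeds. One root seed is expanded into per-stage seeds via
`numpy.random.SeedSequence.spawn` in a fixed stage order, so a config
fully determines the bundle. Problem sizes used in the validation suite
(e.g. 200 seeds × n = 2000 for exponent recovery, 1000 null simulations
at n_perm = 199 for permutation-test calibration, 100 default-condition
replicates for end-to-end recovery) were chosen as the smallest sizes at
which Monte-Carlo error is comfortably below the tolerances being
asserted.

## Known limitations

- Published exponents for real curated networks (e.g. γ = 2.09/2.66)
  are not reproducible without the underlying database export and a
  statement of the original fitting method; the package validates its
  estimator by parameter recovery instead, and offers the log–log
  regression variant for methodological comparison.
- Proprietary pathway collections cannot be re-run; the ORA engine is
  validated against exhaustive combinatorial enumeration instead.
- Name normalization and gene matching are lexical; no registry
  synchronization.
- The untruncated MLE applied to degree data truncated at 23 diseases is
  mildly upward-biased (≈ +0.1 at the default conditions); fitting a
  truncated law is out of scope.
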