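# pgnet — phenotype–genotype network construction and characterization

`pgnet` is a Python package for analysing curated disease–ncRNA
association tables as a **phenotype–genotype network**: clinical disease
subtypes (e.g. cardiovascular disease subtypes) are phenotype nodes, the
non-coding RNAs reported for them (miRNA, lncRNA, circRNA) are genotype
nodes, and each curated association is an edge. It is aimed at systems
biologists who maintain or consume disease–ncRNA resources and want
reproducible, testable versions of the standard characterization analyses:

- **Scale-free structure.** Fit the discrete power law
  P(k) = k^(−γ)/ζ(γ, xmin) to a degree distribution by maximum
  likelihood, with KS goodness of fit, a semi-parametric surrogate test,
  and bootstrap confidence intervals for γ (scale-free networks typically
  show 2 < γ < 3).
- **Universal vs specific miRNAs.** Partition miRNAs into *universal*
  (associated with ≥ 2 diseases) and *specific* (exactly 1), and contrast
  the classes — biomarker rates (Fisher exact, chi-square and permutation
  tests reported side by side), validated-target coverage, and
  essential-gene ratios.
- **Over-representation analysis.** Hypergeometric enrichment of class
  target sets against GMT collections with BH/Bonferroni adjustment.
- **Ternary sponge networks.** Assemble lncRNA/circRNA–miRNA–mRNA (ceRNA)
  networks from triple tables and export SIF/GraphML for Cytoscape.
- **Tissue-expression clustering.** Deterministic hierarchical clustering
  of miRNA expression profiles (z-scored rows, correlation distance,
  average linkage).
- **Synthetic data.** A generator that reproduces the statistical
  structure of a curated cardiovascular disease–ncRNA resource (23
  phenotypes, power-law degrees, class-dependent biomarker rates and
  target counts), so every estimator is validated by parameter recovery.

## Worked example

```python
from pgnet import (SyntheticConfig, generate, build_bipartite,
                   degree_distribution, DiscretePowerLaw, ClassContrast)

ds = generate(SyntheticConfig(seed=7))          # default study conditions
net = build_bipartite(ds.associations, "miRNA")

dist = degree_distribution(net, "genotype")
fit = DiscretePowerLaw.from_distribution(dist).fit().bootstrap_ci(500, seed=7)
print(fit.summary())

res = ClassContrast(net, targets=ds.targets, essential=ds.essential).fit(
    n_perm=9999, seed=7)
print(res.summary())
```

prints

```
Discrete power-law fit  P(k) ~ k^-gamma
============================================
gamma                2.1687
xmin                      1
n_tail                  426
KS statistic         0.0280
log-likelihood      -586.39
95% CI (boot)    [2.0690, 2.2659]

Universal vs specific miRNA contrast
============================================
universal (k>=2)        156   biomarker rate 0.923
specific  (k=1)         270   biomarker rate 0.630
odds ratio              7.059
p (Fisher exact)     2.49e-12
p (chi2, Yates)      7.31e-11
p (permutation)        0.0001
universal targets   10149 genes,  22487 interactions
specific  targets    7721 genes,  12316 interactions
universal essential-gene ratio 0.551
specific  essential-gene ratio 0.555
```

The fitted exponent γ ≈ 2.17 sits in the scale-free range (the generator
draws degrees at γ = 2.09, truncated at 23 diseases, which biases the
untruncated MLE slightly upward). Of the 426 miRNAs, the 156 universal
ones are flagged as biomarkers far more often than the 270 specific ones
(92% vs 63%), all three tests agree the contrast is significant, and the
universal class covers more target genes and interactions — the pattern
this kind of analysis is designed to surface. Essential-gene ratios
recover the generator's 0.55.

The same stages run from the shell:

```bash
pgnet simulate --seed 7 --out-dir sim/
pgnet fit --associations sim/associations.tsv --boot 1000 --seed 7 --out fit.json
pgnet contrast --associations sim/associations.tsv \
    --targets sim/targets.tsv --essential sim/essential.txt --out contrast.json
pgnet run --config pipeline.yaml        # full bundle with manifest
```

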