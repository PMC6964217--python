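"""Universal/specific miRNA partition and class-contrast statistics.

miRNAs associated with at least two disease types are *universal*; those
associated with exactly one are *specific*.  The contrast between the two
classes is quantified three ways side by side — Fisher's exact test,
chi-square with continuity correction, and a label-permutation test on the
biomarker-rate difference — together with per-class target coverage and
essential-gene ratios.  No single published p-value is claimed: the tests
are reported jointly.

``ClassContrast(...).fit()`` returns a :class:`ClassContrastResults`
carrying the counts, rates, p-values and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import TargetTable
from .network import BipartiteNetwork, degree_distribution


class ContrastError(ValueError):
    """The partition or table cannot support the requested statistic."""


@dataclass(frozen=True)
class ClassPartition:
    """Universal (degree >= 2) vs specific (degree = 1) ncRNA sets."""

    universal: frozenset[str]
    specific: frozenset[str]
    degree_map: dict[str, int]

    def __post_init__(self) -> None:
        if self.universal & self.specific:
            raise ContrastError("universal and specific sets overlap")

    @property
    def n_universal(self) -> int:
        return len(self.universal)

    @property
    def n_specific(self) -> int:
        return len(self.specific)


def partition_by_degree(net: BipartiteNetwork) -> ClassPartition:
    """Partition genotype nodes at the degree-2 threshold."""
    if net.is_empty():
        raise ContrastError("cannot partition an empty network")
    deg = degree_distribution(net, "genotype").degrees
    return ClassPartition(
        universal=frozenset(n for n, k in deg.items() if k >= 2),
        specific=frozenset(n for n, k in deg.items() if k == 1),
        degree_map=deg,
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = class, columns = biomarker yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContrastError("negative cell count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def margins_positive(self) -> bool:
        t = self.as_array()
        return bool(t.sum(0).min() > 0 and t.sum(1).min() > 0)


_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def fisher_exact(table: ContingencyTable2x2,
                 alternative: str = "two_sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (p_value, odds_ratio).  The two-sided p sums hypergeometric
    point probabilities no larger than the observed one.  The odds ratio is
    the sample ad/bc, with a Haldane-Anscombe 0.5 added to every cell when
    any cell is zero.
    """
    if alternative not in _ALTERNATIVES:
        raise ContrastError(f"unknown alternative {alternative!r}")
    if not table.margins_positive:
        raise ContrastError("zero margin in contingency table")
    res = stats.fisher_exact(table.as_array(),
                             alternative=_ALTERNATIVES[alternative])
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(res.pvalue), float(a * d / (b * c))


def chi2_test(table: ContingencyTable2x2) -> float:
    """Chi-square test with Yates continuity correction."""
    if not table.margins_positive:
        raise ContrastError("zero margin in contingency table")
    return float(stats.chi2_contingency(table.as_array(),
                                        correction=True).pvalue)


def permutation_class_test(flags: dict[str, bool], part: ClassPartition,
                           n_perm: int = 9999, seed=1234) -> float:
    """Label-permutation p-value for the biomarker-rate difference.

    Shuffles class labels over nodes and compares |rate_u - rate_s| against
    the observed difference; p = (1 + #exceeding) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ContrastError("n_perm must be >= 1")
    if not part.universal or not part.specific:
        raise ContrastError("both classes must be non-empty")
    uni = np.array([bool(flags[n]) for n in sorted(part.universal)])
    spe = np.array([bool(flags[n]) for n in sorted(part.specific)])
    nu, ns = uni.size, spe.size
    observed = abs(uni.mean() - spe.mean())
    pooled = np.concatenate([uni, spe]).astype(np.float64)
    rng = np.random.default_rng(seed)
    exceed = 0
    # vectorized in blocks to bound memory
    block = max(1, min(n_perm, 10_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.tile(pooled, (b, 1)), axis=1)
        diff = np.abs(perms[:, :nu].mean(1) - perms[:, nu:].mean(1))
        exceed += int((diff >= observed - 1e-12).sum())
        done += b
    return (1 + exceed) / (n_perm + 1)


def target_coverage(part: ClassPartition, targets: TargetTable
                    ) -> dict[str, tuple[int, int]]:
    """Per-class (n_distinct_genes, n_interactions) over the target table."""
    out = {}
    for name, members in (("universal", part.universal),
                          ("specific", part.specific)):
        pairs = targets.pairs_of(members)
        out[name] = (len({g for _, g in pairs}), len(pairs))
    return out


def essential_ratio(class_genes: set[str], essential: set[str]) -> float:
    """Fraction of a class's target genes present in the essential catalog."""
    if not class_genes:
        raise ContrastError("empty gene set")
    return len(class_genes & essential) / len(class_genes)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class ClassContrast:
    """Joint universal-vs-specific contrast over a bipartite network.

    Parameters
    ----------
    net : BipartiteNetwork
        Phenotype-genotype network for the miRNA class.
    targets : TargetTable, optional
        Validated miRNA-target interactions for target coverage.
    essential : set of str, optional
        Essential-gene catalog for per-class essential ratios.
    """

    net: BipartiteNetwork
    targets: TargetTable | None = None
    essential: set[str] | None = None

    def fit(self, n_perm: int = 9999, seed=1234) -> "ClassContrastResults":
        part = partition_by_degree(self.net)
        flags = {nid: bool(self.net.node_attrs.get(nid, {}).get("biomarker",
                                                                False))
                 for nid in self.net.genotype_ids}
        bu = sum(flags[n] for n in part.universal)
        bs = sum(flags[n] for n in part.specific)
        table = ContingencyTable2x2(bu, part.n_universal - bu,
                                    bs, part.n_specific - bs)
        p_f, odds = fisher_exact(table)
        p_c = chi2_test(table)
        p_p = permutation_class_test(flags, part, n_perm=n_perm, seed=seed)

        coverage = essential_by_class = None
        if self.targets is not None:
            coverage = target_coverage(part, self.targets)
            if self.essential is not None:
                essential_by_class = {}
                for name, members in (("universal", part.universal),
                                      ("specific", part.specific)):
                    genes = self.targets.genes_of(members)
                    essential_by_class[name] = (
                        essential_ratio(genes, self.essential) if genes
                        else float("nan"))
        return ClassContrastResults(
            partition=part, table=table,
            biomarker_rate={"universal": bu / part.n_universal,
                            "specific": bs / part.n_specific},
            p_fisher=p_f, p_chi2=p_c, p_perm=p_p, odds_ratio=odds,
            targets_per_class=coverage, essential_ratio=essential_by_class,
        )


@dataclass
class ClassContrastResults:
    """Counts, rates, p-values and coverage for the class contrast."""

    partition: ClassPartition
    table: ContingencyTable2x2
    biomarker_rate: dict[str, float]
    p_fisher: float
    p_chi2: float
    p_perm: float
    odds_ratio: float
    targets_per_class: dict[str, tuple[int, int]] | None = None
    essential_ratio: dict[str, float] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_universal(self) -> int:
        return self.partition.n_universal

    @property
    def n_specific(self) -> int:
        return self.partition.n_specific

    def summary(self) -> str:
        lines = [
            "Universal vs specific miRNA contrast",
            "=" * 44,
            f"universal (k>=2)   {self.n_universal:8d}"
            f"   biomarker rate {self.biomarker_rate['universal']:.3f}",
            f"specific  (k=1)    {self.n_specific:8d}"
            f"   biomarker rate {self.biomarker_rate['specific']:.3f}",
            f"odds ratio         {self.odds_ratio:10.3f}",
            f"p (Fisher exact)   {self.p_fisher:10.3g}",
            f"p (chi2, Yates)    {self.p_chi2:10.3g}",
            f"p (permutation)    {self.p_perm:10.3g}",
        ]
        if self.targets_per_class:
            for name, (ng, ni) in self.targets_per_class.items():
                lines.append(f"{name:9s} targets  {ng:6d} genes, "
                             f"{ni:6d} interactions")
        if self.essential_ratio:
            for name, r in self.essential_ratio.items():
                lines.append(f"{name:9s} essential-gene ratio {r:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_universal": self.n_universal, "n_specific": self.n_specific,
            "biomarker_rate": dict(self.biomarker_rate),
            "table": [[self.table.a, self.table.b],
                      [self.table.c, self.table.d]],
            "p_fisher": self.p_fisher, "p_chi2": self.p_chi2,
            "p_perm": self.p_perm, "odds_ratio": self.odds_ratio,
            "targets_per_class": self.targets_per_class,
            "essential_ratio": self.essential_ratio,
        }
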