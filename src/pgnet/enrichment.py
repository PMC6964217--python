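"""Gene-set over-representation analysis with multiple-testing adjustment.

The statistical skeleton behind pathway/GO enrichment of miRNA target
sets: a one-sided hypergeometric (Fisher upper-tail) p-value per gene set,
Benjamini-Hochberg ("FDR") and Bonferroni adjustment, and a two-query
overlap report of significant sets.  The universe defaults to the union of
all collection members; a custom universe can be supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ORAResult:
    """Over-representation result for one gene set."""

    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_raw: float
    p_bh: float
    p_bonf: float

    @property
    def ratio(self) -> float:
        """Fraction of the set covered by the query (overlap / set_size)."""
        return self.overlap / self.set_size


def _hypergeom_upper(overlap: int, universe: int, set_size: int,
                     query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def ora(query, sets: GeneSetCollection, universe=None) -> list[ORAResult]:
    """Hypergeometric over-representation of a query gene set.

    Query genes outside the universe are dropped with a warning; each
    collection set is intersected with the universe before testing.
    Results are sorted by raw p-value.
    """
    universe = set(universe) if universe is not None else sets.universe()
    if not universe:
        raise EnrichmentError("empty universe")
    query = {g.upper() for g in query}
    dropped = query - universe
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside universe dropped",
                      stacklevel=2)
    query &= universe

    names, raws, rows = [], [], []
    for name, (_, members) in sets.sets.items():
        members = members & universe
        overlap = len(query & members)
        p = _hypergeom_upper(overlap, len(universe), len(members), len(query))
        names.append(name)
        raws.append(p)
        rows.append((name, overlap, len(members)))
    bh = adjust(raws, "bh")
    bonf = adjust(raws, "bonferroni")
    results = [
        ORAResult(set_name=name, overlap=ov, set_size=sz,
                  query_size=len(query), universe_size=len(universe),
                  p_raw=p, p_bh=pb, p_bonf=po)
        for (name, ov, sz), p, pb, po in zip(rows, raws, bh, bonf)
    ]
    results.sort(key=lambda r: (r.p_raw, r.set_name))
    return results


def adjust(pvals, method: str = "bh") -> list[float]:
    """Multiple-testing adjustment: BH step-up or Bonferroni."""
    pvals = list(pvals)
    if any(p < 0 or p > 1 for p in pvals):
        raise EnrichmentError("p-values must lie in [0, 1]")
    if not pvals:
        return []
    key = {"bh": "fdr_bh", "fdr": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in key:
        raise EnrichmentError(f"unknown adjustment method {method!r}")
    return [float(x) for x in
            multipletests(pvals, method=key[method])[1]]


def overlap_report(res_a: list[ORAResult], res_b: list[ORAResult],
                   alpha: float = 0.01) -> tuple[int, int, int]:
    """Counts of significant sets (p_raw < alpha) in each list and shared."""
    sig_a = {r.set_name for r in res_a if r.p_raw < alpha}
    sig_b = {r.set_name for r in res_b if r.p_raw < alpha}
    return len(sig_a), len(sig_b), len(sig_a & sig_b)


def write_ora_tsv(results: list[ORAResult], path) -> None:
    lines = ["set_name\toverlap\tset_size\tquery_size\tuniverse_size"
             "\tp_raw\tp_bh\tp_bonf\tratio"]
    for r in results:
        lines.append(f"{r.set_name}\t{r.overlap}\t{r.set_size}"
                     f"\t{r.query_size}\t{r.universe_size}"
                     f"\t{r.p_raw:.6g}\t{r.p_bh:.6g}\t{r.p_bonf:.6g}"
                     f"\t{r.ratio:.4f}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
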