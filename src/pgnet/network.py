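"""Bipartite phenotype-genotype and ternary sponge network construction.

The bipartite network links clinical disease subtypes (phenotypes) to their
associated ncRNAs (genotypes); the ternary network chains sponge
transcripts (lncRNA/circRNA) through the miRNAs they sequester to the
mRNAs those miRNAs target.  Exports target Cytoscape-compatible formats
(SIF, GraphML) plus a round-trippable edge-list TSV.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .io import AssociationRecord, NCRNA_CLASSES, TernaryTriple, ValidationError


@dataclass
class BipartiteNetwork:
    """Disease and ncRNA node sets with unique undirected association edges."""

    phenotype_nodes: set[str]
    genotype_nodes: set[tuple[str, str]]          # (ncrna_id, ncrna_class)
    edges: set[tuple[str, str]]                   # (disease, ncrna_id)
    node_attrs: dict[str, dict] = field(default_factory=dict)

    @property
    def genotype_ids(self) -> set[str]:
        return {nid for nid, _ in self.genotype_nodes}

    def degree_of(self, ncrna_id: str) -> int:
        return sum(1 for _, nid in self.edges if nid == ncrna_id)

    def is_empty(self) -> bool:
        return not self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for d in self.phenotype_nodes:
            g.add_node(d, kind="phenotype")
        for nid, ncls in self.genotype_nodes:
            attrs = self.node_attrs.get(nid, {})
            g.add_node(nid, kind="genotype", ncrna_class=ncls,
                       biomarker=int(attrs.get("biomarker", False)))
        g.add_edges_from(self.edges)
        return g


@dataclass
class DegreeDistribution:
    """Degree map, histogram and empirical P(k) for one side of the network."""

    degrees: dict[str, int]
    histogram: dict[int, int]
    pk: dict[int, float]

    @property
    def samples(self) -> list[int]:
        """Flat degree sequence (one entry per node)."""
        return sorted(self.degrees.values())

    @classmethod
    def from_degrees(cls, degrees: dict[str, int]) -> "DegreeDistribution":
        hist = Counter(degrees.values())
        n = sum(hist.values())
        return cls(degrees=dict(degrees), histogram=dict(hist),
                   pk={k: c / n for k, c in hist.items()})


@dataclass
class TernaryNetwork:
    """Typed sponge-miRNA-mRNA network assembled from ternary triples."""

    triples: list[TernaryTriple]
    nodes: dict[str, str]                          # id -> {sponge,miRNA,mRNA}
    edges: set[tuple[str, str, str]]               # (src, dst, interaction)

    def pair_counts(self) -> dict[str, int]:
        """Distinct sponge-miRNA pairs per sponge class."""
        pairs = {(t.sponge_class, t.sponge_id, t.mirna_id) for t in self.triples}
        out = Counter(cls for cls, _, _ in pairs)
        return {"lncRNA": out.get("lncRNA", 0), "circRNA": out.get("circRNA", 0)}

    def sponge_degree(self, sponge_id: str) -> int:
        return sum(1 for s, _, kind in self.edges
                   if s == sponge_id and kind == "sponge")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nid, kind in self.nodes.items():
            g.add_node(nid, kind=kind)
        for src, dst, kind in self.edges:
            g.add_edge(src, dst, interaction=kind)
        return g


def build_bipartite(records: list[AssociationRecord],
                    ncrna_class: str = "miRNA",
                    drop_others: bool = False) -> BipartiteNetwork:
    """Build the phenotype-genotype network for one ncRNA class.

    One edge per unique (disease, ncRNA) pair; isolated nodes are absent by
    construction; a node's biomarker attribute is the OR over its records.
    ``drop_others`` excludes the "Others" catch-all phenotype.
    """
    if ncrna_class not in NCRNA_CLASSES:
        raise ValidationError(f"unknown ncRNA class filter {ncrna_class!r}")
    selected = [r for r in records if r.ncrna_class == ncrna_class
                and not (drop_others and r.disease == "Others")]
    if not selected:
        warnings.warn("no records after filtering; returning empty network",
                      stacklevel=2)
        return BipartiteNetwork(set(), set(), set(), {})
    edges = {(r.disease, r.ncrna_id) for r in selected}
    node_attrs: dict[str, dict] = {}
    for r in selected:
        attrs = node_attrs.setdefault(r.ncrna_id, {"biomarker": False})
        attrs["biomarker"] = attrs["biomarker"] or r.biomarker
    return BipartiteNetwork(
        phenotype_nodes={d for d, _ in edges},
        genotype_nodes={(r.ncrna_id, r.ncrna_class) for r in selected},
        edges=edges,
        node_attrs=node_attrs,
    )


def degree_distribution(net: BipartiteNetwork,
                        side: str = "genotype") -> DegreeDistribution:
    """Degree distribution of one side; genotype degrees count distinct diseases."""
    if net.is_empty():
        raise ValidationError("cannot compute degrees of an empty network")
    if side == "genotype":
        deg = Counter(nid for _, nid in net.edges)
    elif side == "phenotype":
        deg = Counter(d for d, _ in net.edges)
    else:
        raise ValidationError(f"unknown side {side!r}")
    return DegreeDistribution.from_degrees(dict(deg))


def build_ternary(triples: list[TernaryTriple],
                  sponge_class: str | None = None) -> TernaryNetwork:
    """Assemble the typed ternary network from validated triples.

    Every triple contributes one sponge-miRNA edge; miRNA-mRNA edges are
    emitted per split mRNA gene (multi-gene cells like "BCL2/HSP60" yield
    one edge per gene); triples with the NA sentinel contribute none.
    """
    if sponge_class is not None:
        triples = [t for t in triples if t.sponge_class == sponge_class]
    nodes: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    for t in triples:
        nodes[t.sponge_id] = "sponge"
        nodes.setdefault(t.mirna_id, "miRNA")
        edges.add((t.sponge_id, t.mirna_id, "sponge"))
        for gene in t.mrna_genes:
            nodes.setdefault(gene, "mRNA")
            edges.add((t.mirna_id, gene, "targets"))
    return TernaryNetwork(triples=list(triples), nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(net: BipartiteNetwork | TernaryNetwork, path,
                   fmt: str = "graphml") -> None:
    """Write a network as SIF, GraphML or an edge-list TSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "sif":
        lines = []
        if isinstance(net, BipartiteNetwork):
            for d, nid in sorted(net.edges):
                lines.append(f"{d}\tassoc\t{nid}")
        else:
            for src, dst, kind in sorted(net.edges):
                lines.append(f"{src}\t{kind}\t{dst}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "edge_tsv":
        lines = ["source\ttarget\tinteraction"]
        if isinstance(net, BipartiteNetwork):
            lines += [f"{d}\t{nid}\tassoc" for d, nid in sorted(net.edges)]
        else:
            lines += [f"{s}\t{t}\t{k}" for s, t, k in sorted(net.edges)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def read_edge_tsv(path) -> set[tuple[str, str, str]]:
    """Re-import an edge-list TSV written by :func:`export_network`."""
    lines = Path(path).read_text().splitlines()
    out = set()
    for line in lines[1:]:
        if line.strip():
            s, t, k = line.split("\t")
            out.add((s, t, k))
    return out
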