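"""Readers, writers and validators for the tabular inputs of the pipeline.

All files are UTF-8, tab-separated, with ``#`` comment lines ignored.  The
module defines the in-memory record types (associations, target tables,
gene-set collections, ternary sponge triples, expression matrices) and the
normalization conventions applied on input:

* miRNA names are unified by rule (species prefix stripped, case
  canonicalized, arm suffixes preserved);
* raw disease labels are mapped through a :class:`DiseaseCatalog` merge map
  (e.g. "Acute heart failure" and "Chronic heart failure" collapse into
  "Heart failure") and unmappable labels fail loudly;
* duplicate (ncRNA, disease) pairs collapse to one record, with the
  biomarker flag OR-merged and conflicting expression directions stored as
  ``mixed``.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NCRNA_CLASSES = frozenset({"miRNA", "lncRNA", "circRNA"})
DIRECTIONS = frozenset({"up", "down", "mixed", "unknown"})

#: sentinel used in ternary tables for "no validated mRNA target reported"
NA_SENTINEL = "NA"

ASSOC_COLUMNS = ["ncrna_id", "ncrna_class", "disease", "biomarker",
                 "direction", "pmid", "sample_note"]
TARGET_COLUMNS = ["mirna_id", "gene", "source"]


class SchemaError(ValueError):
    """A required column or field is missing from an input file."""


class ValidationError(ValueError):
    """Input content violates a contract (unknown label, bad value...)."""


class ParseError(ValueError):
    """A line cannot be parsed; carries the offending line number."""


# ---------------------------------------------------------------------------
# miRNA name normalization
# ---------------------------------------------------------------------------

_MIR_RE = re.compile(r"^(mir|let)[-]?(.*)$", re.IGNORECASE)


def normalize_mirna_name(raw: str) -> str:
    """Unify a miRNA name by rule.

    Strips an ``hsa-`` species prefix, canonicalizes the family token
    ("MIR-21" -> "miR-21", "LET-7B" -> "let-7b") and lower-cases the
    remainder while preserving arm suffixes (-5p/-3p).  Idempotent.
    """
    if not raw or not raw.strip():
        raise ValidationError("empty miRNA name")
    name = raw.strip()
    if name.lower().startswith("hsa-"):
        name = name[4:]
    m = _MIR_RE.match(name)
    if m is None:
        return name
    family = "let" if m.group(1).lower() == "let" else "miR"
    rest = m.group(2).lower()
    return f"{family}-{rest}" if rest else family


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRecord:
    """One curated ncRNA-disease link with its clinical annotations."""

    ncrna_id: str
    ncrna_class: str
    disease: str
    biomarker: bool
    direction: str = "unknown"
    pmid: str = ""
    sample_note: str = ""

    def __post_init__(self) -> None:
        if self.ncrna_class not in NCRNA_CLASSES:
            raise ValidationError(
                f"unknown ncRNA class {self.ncrna_class!r} for {self.ncrna_id!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class DiseaseCatalog:
    """Ordered canonical disease labels plus a raw-label merge map.

    ``merge_map`` sends raw labels (e.g. "Acute heart failure") onto
    canonical catalog members; raw labels already canonical map to
    themselves.  Labels outside the catalog are rejected rather than
    fuzzy-matched.
    """

    labels: tuple[str, ...]
    merge_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate labels in disease catalog")
        bad = [v for v in self.merge_map.values() if v not in set(self.labels)]
        if bad:
            raise ValidationError(f"merge_map targets outside catalog: {bad}")

    def canonical(self, raw: str) -> str:
        raw = raw.strip()
        if raw in self.merge_map:
            return self.merge_map[raw]
        if raw in self.labels:
            return raw
        raise ValidationError(f"disease label not in catalog: {raw!r}")

    @classmethod
    def default(cls) -> "DiseaseCatalog":
        """The shipped 23-disease catalog with the documented merges."""
        return read_disease_catalog(_data_path("disease_catalog.tsv"))


@dataclass
class TargetTable:
    """Validated miRNA -> target-gene interaction pairs."""

    interactions: set[tuple[str, str]]
    source: dict[tuple[str, str], str] = field(default_factory=dict)

    def genes_of(self, mirnas) -> set[str]:
        mirnas = set(mirnas)
        return {g for m, g in self.interactions if m in mirnas}

    def pairs_of(self, mirnas) -> set[tuple[str, str]]:
        mirnas = set(mirnas)
        return {(m, g) for m, g in self.interactions if m in mirnas}


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): name -> (description, member symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def universe(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class TernaryTriple:
    """A sponge(lncRNA|circRNA) - miRNA - mRNA record.

    ``mrna`` keeps the raw table cell ("BCL2/HSP60", or the NA sentinel);
    :attr:`mrna_genes` splits multi-gene cells into the individual symbols.
    """

    sponge_id: str
    sponge_class: str
    mirna_id: str
    mrna: str = NA_SENTINEL
    mechanism: str = "unknown"

    def __post_init__(self) -> None:
        if self.sponge_class not in {"lncRNA", "circRNA"}:
            raise ValidationError(f"bad sponge class {self.sponge_class!r}")
        if not self.mirna_id:
            raise ValidationError("empty miRNA id in ternary triple")
        if self.mechanism not in {"ceRNA_sponge", "direct_target", "unknown"}:
            raise ValidationError(f"bad mechanism {self.mechanism!r}")

    @property
    def has_mrna(self) -> bool:
        return self.mrna != NA_SENTINEL

    @property
    def mrna_genes(self) -> tuple[str, ...]:
        if not self.has_mrna:
            return ()
        return tuple(g.strip() for g in self.mrna.split("/") if g.strip())


@dataclass
class ExpressionMatrix:
    """A miRNA x tissue matrix of non-negative expression levels."""

    row_ids: list[str]
    col_ids: list[str]
    values: "pd.DataFrame"

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError("duplicate row or column ids in expression matrix")
        arr = df.to_numpy(dtype=float)
        import numpy as np
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite values in expression matrix")
        return cls(list(df.index), list(df.columns), df.astype(float))


# ---------------------------------------------------------------------------
# File helpers
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("pgnet") / "data" / name)


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, **kw)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_disease_catalog(path) -> DiseaseCatalog:
    """Read a catalog TSV with columns ``label`` and optional ``merges``.

    ``merges`` is a ';'-separated list of raw labels folded into the row's
    canonical label.
    """
    df = _read_tsv(path)
    _require_columns(df, ["label"], path)
    labels = tuple(df["label"])
    merge_map: dict[str, str] = {}
    if "merges" in df.columns:
        for label, merges in zip(df["label"], df["merges"]):
            for raw in merges.split(";"):
                raw = raw.strip()
                if raw:
                    merge_map[raw] = label
    return DiseaseCatalog(labels=labels, merge_map=merge_map)


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _parse_bool(x: str, path) -> bool:
    s = str(x).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"{path}: bad biomarker flag {x!r}")


def read_associations(path, catalog: DiseaseCatalog | None = None
                      ) -> list[AssociationRecord]:
    """Read, normalize and deduplicate a disease-ncRNA association table.

    Raw disease labels go through the catalog's merge map; duplicate
    (ncrna_id, canonical disease) pairs collapse to a single record whose
    biomarker flag is the OR over duplicates and whose direction is
    ``mixed`` when the duplicates disagree.
    """
    catalog = catalog or DiseaseCatalog.default()
    df = _read_tsv(path)
    _require_columns(df, ASSOC_COLUMNS[:5], path)
    bad_labels = sorted({d for d in df["disease"]
                         if d.strip() not in catalog.merge_map
                         and d.strip() not in catalog.labels})
    if bad_labels:
        raise ValidationError(f"{path}: unmappable disease labels {bad_labels}")

    merged: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        ncrna_class = row.ncrna_class.strip()
        if ncrna_class not in NCRNA_CLASSES:
            raise ValidationError(
                f"{path}: unknown ncRNA class {ncrna_class!r} for {row.ncrna_id!r}")
        ncrna_id = (normalize_mirna_name(row.ncrna_id)
                    if ncrna_class == "miRNA" else row.ncrna_id.strip())
        disease = catalog.canonical(row.disease)
        biomarker = _parse_bool(row.biomarker, path)
        direction = row.direction.strip() or "unknown"
        if direction not in DIRECTIONS:
            raise ValidationError(f"{path}: bad direction {direction!r}")
        key = (ncrna_id, disease)
        if key not in merged:
            order.append(key)
            merged[key] = {
                "ncrna_class": ncrna_class, "biomarker": biomarker,
                "direction": direction,
                "pmid": getattr(row, "pmid", ""),
                "sample_note": getattr(row, "sample_note", ""),
            }
        else:
            rec = merged[key]
            rec["biomarker"] = rec["biomarker"] or biomarker
            if rec["direction"] != direction:
                rec["direction"] = "mixed"
    return [AssociationRecord(ncrna_id=k[0], disease=k[1], **merged[k])
            for k in order]


def write_associations(records, path) -> None:
    rows = [{"ncrna_id": r.ncrna_id, "ncrna_class": r.ncrna_class,
             "disease": r.disease, "biomarker": int(r.biomarker),
             "direction": r.direction, "pmid": r.pmid,
             "sample_note": r.sample_note} for r in records]
    pd.DataFrame(rows, columns=ASSOC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_targets(path) -> TargetTable:
    """Read a miRNA-target interaction TSV (mirna_id, gene, source)."""
    df = _read_tsv(path)
    _require_columns(df, ["mirna_id", "gene"], path)
    interactions: set[tuple[str, str]] = set()
    source: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        gene = row.gene.strip().upper()
        if not gene:
            raise ValidationError(f"{path}: empty gene symbol")
        pair = (normalize_mirna_name(row.mirna_id), gene)
        interactions.add(pair)
        src = getattr(row, "source", "")
        if src:
            source[pair] = src
    return TargetTable(interactions=interactions, source=source)


def write_targets(table: TargetTable, path) -> None:
    rows = sorted(table.interactions)
    pd.DataFrame(
        [{"mirna_id": m, "gene": g, "source": table.source.get((m, g), "")}
         for m, g in rows], columns=TARGET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list (essential-gene export style)."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.upper())
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{ln}: GMT line has fewer than 3 fields")
        name, desc = fields[0], fields[1]
        members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not members:
            raise ParseError(f"{path}:{ln}: gene set {name!r} is empty")
        if name in sets:
            raise ParseError(f"{path}:{ln}: duplicate set name {name!r}")
        sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, desc, *sorted(members)])
        for name, (desc, members) in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ternary_table(path) -> list[TernaryTriple]:
    """Read a sponge-miRNA-mRNA table with lncRNA / circRNA section markers.

    The file interleaves single-token section markers (``lncRNA`` or
    ``circRNA``) with tab-separated data rows (sponge, miRNA, mRNA); each
    data row inherits the sponge class of its enclosing section.  Multi-gene
    mRNA cells stay in one triple; network assembly splits them per gene.
    """
    triples: list[TernaryTriple] = []
    section: str | None = None
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) == 1 and fields[0] in {"lncRNA", "circRNA"}:
            section = fields[0]
            continue
        if section is None:
            raise ParseError(f"{path}:{ln}: data row outside a section marker")
        if len(fields) < 2:
            raise ParseError(f"{path}:{ln}: expected sponge and miRNA columns")
        sponge, mirna = fields[0], normalize_mirna_name(fields[1])
        mrna = fields[2] if len(fields) > 2 and fields[2] else NA_SENTINEL
        mechanism = fields[3] if len(fields) > 3 and fields[3] else "unknown"
        triples.append(TernaryTriple(sponge_id=sponge, sponge_class=section,
                                     mirna_id=mirna, mrna=mrna,
                                     mechanism=mechanism))
    return triples


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a miRNA x tissue expression TSV (first column = miRNA id)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix.from_dataframe(df)


def write_expression_matrix(mat: ExpressionMatrix, path) -> None:
    mat.values.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def load_ternary_fixture() -> list[TernaryTriple]:
    """The published 17-row sponge/miRNA/mRNA table shipped with the package."""
    return read_ternary_table(_data_path("ternary_table.tsv"))


def load_tissue_expression_fixture() -> ExpressionMatrix:
    """Synthetic tissue-expression matrix for the ternary-network miRNAs.

    The published analysis clustered tissue-expression profiles of the
    ternary-network miRNAs; the underlying values are not printed, so this
    fixture is a synthetic stand-in with the reported two-block structure
    (one block high in stomach/kidney/liver/spleen/bone, the other low in
    myocardial/muscle/colon/thyroid tissue).
    """
    return read_expression_matrix(_data_path("synthetic_tissue_expression.tsv"))
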