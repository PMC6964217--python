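"""End-to-end pipeline: load/simulate -> build -> fit -> contrast -> ora -> cluster.

One root seed drives every stochastic stage: stage seeds are spawned from
``numpy.random.SeedSequence(root_seed)`` in a fixed documented order
(simulate, fit, contrast, ora, cluster), so identical configs produce
identical bundles.  Any stage failure aborts with the stage name; outputs
written before the failure keep a ``.partial`` marker in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .cluster import cluster_expression, write_cluster_tsv
from .contrast import ClassContrast
from .enrichment import ora, overlap_report, write_ora_tsv
from .network import (build_bipartite, build_ternary, degree_distribution,
                      export_network)
from .powerlaw import DiscretePowerLaw, FitError
from .simulate import SyntheticConfig, generate

log = logging.getLogger("pgnet")

_STAGES = ("simulate", "fit", "contrast", "ora", "cluster")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths (or a simulate block), stage parameters, output dir."""

    out_dir: Path
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 1234

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(out_dir=Path(raw.get("out_dir", "pgnet_out")),
                   simulate=raw.get("simulate"),
                   inputs=raw.get("inputs", {}),
                   params=raw.get("params", {}),
                   seed=int(raw.get("seed", 1234)))


def _stage_seeds(root: int) -> dict[str, int]:
    children = np.random.SeedSequence(root).spawn(len(_STAGES))
    return {name: int(ss.generate_state(1)[0] % (2 ** 31))
            for name, ss in zip(_STAGES, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    p = config.params
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds,
                      "params": p, "outputs": [], "notices": []}

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    # ------------------------------------------------------------------ data
    stage = "load"
    try:
        if config.simulate is not None:
            sim_cfg = SyntheticConfig(**{**config.simulate,
                                         "seed": config.simulate.get(
                                             "seed", seeds["simulate"])})
            ds = generate(sim_cfg)
            records, targets = ds.associations, ds.targets
            essential, gene_sets = ds.essential, ds.gene_sets
            expression = ds.expression
            emit("truth.json").write_text(json.dumps(
                {k: v for k, v in ds.truth.items()
                 if k not in ("degrees", "biomarker_flags")}, indent=2))
        else:
            catalog = (pio.read_disease_catalog(config.inputs["catalog"])
                       if "catalog" in config.inputs
                       else pio.DiseaseCatalog.default())
            records = (pio.read_associations(config.inputs["associations"],
                                             catalog)
                       if "associations" in config.inputs else [])
            targets = (pio.read_targets(config.inputs["targets"])
                       if "targets" in config.inputs else None)
            essential = (pio.read_gene_list(config.inputs["essential"])
                         if "essential" in config.inputs else None)
            gene_sets = (pio.read_gmt(config.inputs["gmt"])
                         if "gmt" in config.inputs else None)
            expression = (pio.read_expression_matrix(config.inputs["expression"])
                          if "expression" in config.inputs else None)
        triples = (pio.read_ternary_table(config.inputs["ternary"])
                   if "ternary" in config.inputs else None)
    except Exception as e:                                   # noqa: BLE001
        raise PipelineError(stage, e) from e

    summary: list[str] = ["pgnet pipeline summary", "=" * 40]

    # --------------------------------------------------------------- network
    nets = {}
    if records:
        stage = "build"
        try:
            for ncls in ("miRNA", "lncRNA", "circRNA"):
                if any(r.ncrna_class == ncls for r in records):
                    net = build_bipartite(records, ncls)
                    nets[ncls] = net
                    export_network(net, emit(f"network_{ncls}.graphml"),
                                   "graphml")
                    summary.append(
                        f"{ncls}: {len(net.genotype_nodes)} ncRNAs, "
                        f"{len(net.phenotype_nodes)} diseases, "
                        f"{len(net.edges)} associations")
        except Exception as e:                               # noqa: BLE001
            raise PipelineError(stage, e) from e

        stage = "fit"
        try:
            for ncls, net in nets.items():
                dist = degree_distribution(net, "genotype")
                if max(dist.histogram) < 3:
                    msg = (f"{ncls}: max degree < 3, refusing power-law fit "
                           "(exponent would be meaningless)")
                    manifest["notices"].append(msg)
                    summary.append(msg)
                    continue
                try:
                    res = DiscretePowerLaw.from_distribution(
                        dist, xmin=int(p.get("xmin", 1))).fit(
                        p.get("xmin_mode", "fixed"))
                except FitError as fe:
                    manifest["notices"].append(f"{ncls}: {fe}")
                    continue
                res = res.bootstrap_ci(int(p.get("n_boot", 1000)),
                                       seed=seeds["fit"])
                emit(f"fit_{ncls}.json").write_text(
                    json.dumps(res.to_dict(), indent=2))
                summary.append(f"{ncls}: gamma = {res.gamma:.3f} "
                               f"[{res.ci[0]:.3f}, {res.ci[1]:.3f}], "
                               f"KS = {res.ks_stat:.3f}")
        except Exception as e:                               # noqa: BLE001
            raise PipelineError(stage, e) from e

        stage = "contrast"
        try:
            if "miRNA" in nets:
                model = ClassContrast(nets["miRNA"], targets=targets,
                                      essential=essential)
                cres = model.fit(n_perm=int(p.get("n_perm", 9999)),
                                 seed=seeds["contrast"])
                emit("contrast.json").write_text(
                    json.dumps(cres.to_dict(), indent=2))
                summary.append(cres.summary())
        except Exception as e:                               # noqa: BLE001
            raise PipelineError(stage, e) from e

        stage = "ora"
        try:
            if gene_sets is not None and targets is not None \
                    and "miRNA" in nets:
                from .contrast import partition_by_degree
                part = partition_by_degree(nets["miRNA"])
                alpha = float(p.get("alpha", 0.01))
                res_u = ora(targets.genes_of(part.universal), gene_sets)
                res_s = ora(targets.genes_of(part.specific), gene_sets)
                write_ora_tsv(res_u, emit("ora_universal.tsv"))
                write_ora_tsv(res_s, emit("ora_specific.tsv"))
                n_s, n_u, n_sh = overlap_report(res_s, res_u, alpha)
                summary.append(f"enriched sets at p<{alpha}: "
                               f"{n_s} specific, {n_u} universal, "
                               f"{n_sh} shared")
        except Exception as e:                               # noqa: BLE001
            raise PipelineError(stage, e) from e
    else:
        manifest["notices"].append(
            "no association records: bipartite stages skipped")
        summary.append("bipartite stages skipped (no association data)")

    # --------------------------------------------------------------- ternary
    if triples is not None:
        stage = "ternary"
        try:
            tnet = build_ternary(triples)
            export_network(tnet, emit("ternary.graphml"), "graphml")
            counts = tnet.pair_counts()
            summary.append(f"ternary network: {counts['lncRNA']} lncRNA-miRNA"
                           f" and {counts['circRNA']} circRNA-miRNA pairs")
        except Exception as e:                               # noqa: BLE001
            raise PipelineError(stage, e) from e

    # --------------------------------------------------------------- cluster
    if expression is not None:
        stage = "cluster"
        try:
            cres = cluster_expression(expression,
                                      k_rows=int(p.get("k_rows", 2)),
                                      distance=p.get("distance",
                                                     "correlation"),
                                      linkage=p.get("linkage", "average"))
            write_cluster_tsv(expression, cres, emit("clusters.tsv"))
            sizes = np.bincount(list(cres.row_labels.values()))[1:]
            summary.append("expression clusters: "
                           + ", ".join(f"{s} miRNAs" for s in sizes))
        except Exception as e:                               # noqa: BLE001
            raise PipelineError(stage, e) from e

    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    manifest["outputs"].append("summary.txt")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
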