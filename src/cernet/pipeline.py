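"""End-to-end orchestration of the three-step construction.

One configuration drives the whole analysis: per subtype, differential
expression versus the shared normals, the miRNA dys-regulatory network, and
the ceRNA network; across subtypes, hub calling and classification, k-core
decomposition, the power-law degree check, hub sub-networks, gene-set
enrichment and the optional mutation overlay.  A manifest records every
threshold and an input checksum so any run is auditable; given identical
inputs and configuration the result directory is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as cio
from . import __version__
from .cerna import CeRNANetwork, build_cerna
from .diffexpr import call_de, concordance, wilcoxon_de
from .dysreg import DysregNetwork, build_dysreg
from .enrich import enrich
from .topology import (
    classify_hubs,
    hub_subnetwork,
    identify_hubs,
    kcore,
    mutation_overlay,
    powerlaw_check,
    union_subnetwork,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    expression: dict[str, str]  # rna_class -> TSV path (raw values)
    annotation: str
    targets: str
    gmts: dict[str, str] = field(default_factory=dict)  # category -> GMT path
    mutations: dict[str, str] = field(default_factory=dict)  # subtype -> gene list
    subtypes: list[str] | None = None  # default: every non-normal group
    de_fdr: float = 0.05
    min_abs_lfc: float = 1.0
    dysreg_p: float = 0.01
    shared_fdr: float = 0.01
    min_r: float = 0.5
    corr_fdr: float = 0.01
    hub_fraction: float = 0.10
    common_min_subtypes: int = 3
    enrich_fdr: float = 0.05
    pseudocount: float = 1.0
    exact_limit: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr", "shared_fdr", "min_r", "corr_fdr", "enrich_fdr", "dysreg_p"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in (0, 1]")
        if self.min_abs_lfc < 0:
            raise ValueError("min_abs_lfc must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_table(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _graph_edge_table(graph) -> pd.DataFrame:
    rows = []
    for a, b, d in graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append({"geneA": a, "geneB": b, "multiplicity": d.get("multiplicity", 1)})
    table = pd.DataFrame(rows, columns=["geneA", "geneB", "multiplicity"])
    return table.sort_values(["geneA", "geneB"], kind="mergesort").reset_index(drop=True)


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; returns the in-memory results by stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _stage(name):
        logger.info("stage: %s", name)

    # ---- inputs -----------------------------------------------------------
    _stage("io")
    expression = {
        cls: cio.read_expression(path, cls, config.pseudocount)
        for cls, path in sorted(config.expression.items())
    }
    annotation = cio.read_annotation(config.annotation)
    for mat in expression.values():
        annotation.validate_against(mat)
    gene_classes: dict[str, str] = {}
    for cls in ("mRNA", "lncRNA"):
        if cls in expression:
            gene_classes.update({g: cls for g in expression[cls].gene_ids})
    target_map = cio.read_target_map(config.targets, gene_classes)
    subtypes = config.subtypes or annotation.subtypes()
    missing = [s for s in subtypes if s not in annotation.group_names]
    if missing:
        raise ValueError(f"subtypes absent from annotation: {missing}")
    results["expression"] = expression
    results["annotation"] = annotation

    # ---- step 1: differential expression ----------------------------------
    _stage("diffexpr")
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    de_full: dict[str, dict[str, pd.DataFrame]] = {}
    de_called: dict[str, pd.DataFrame] = {}
    for s in subtypes:
        de_full[s] = {}
        called_parts = []
        for cls, mat in expression.items():
            table = wilcoxon_de(
                mat, annotation, s, config.de_fdr, config.min_abs_lfc, config.exact_limit
            )
            de_full[s][cls] = table
            _write_table(table.drop(columns="degenerate"), de_dir / f"{s}.{cls}.tsv")
            called_parts.append(call_de(table, config.de_fdr, config.min_abs_lfc))
        de_called[s] = pd.concat(called_parts, ignore_index=True)
    results["de"] = de_full
    results["de_called"] = de_called

    if len(subtypes) >= 2:
        per_gene, summary = concordance(de_called)
        _write_table(per_gene, out / "concordance_genes.tsv")
        _write_table(summary, out / "concordance.tsv")
        results["concordance"] = summary

    # ---- step 2: miRNA dys-regulatory networks ----------------------------
    _stage("dysreg")
    dysreg_dir = out / "dysreg"
    dysreg_dir.mkdir(exist_ok=True)
    dysreg_nets: dict[str, DysregNetwork] = {}
    for s in subtypes:
        called = de_called[s]
        de_mirnas = set(called.loc[called["class"] == "miRNA", "gene"])
        de_targets = dict(
            zip(
                called.loc[called["class"] != "miRNA", "gene"],
                called.loc[called["class"] != "miRNA", "class"],
            )
        )
        tumor_samples = [
            smp for smp in expression["mRNA"].sample_ids if annotation.groups[smp] == s
        ]
        net = build_dysreg(
            de_mirnas, de_targets, target_map, expression, s, tumor_samples, config.dysreg_p
        )
        dysreg_nets[s] = net
        cio.write_network(net, dysreg_dir / f"{s}.tsv")
    results["dysreg"] = dysreg_nets

    # ---- step 3: ceRNA networks -------------------------------------------
    _stage("cerna")
    cerna_dir = out / "cerna"
    cerna_dir.mkdir(exist_ok=True)
    cerna_nets: dict[str, CeRNANetwork] = {}
    for s in subtypes:
        tumor_samples = [
            smp for smp in expression["mRNA"].sample_ids if annotation.groups[smp] == s
        ]
        net = build_cerna(
            dysreg_nets[s],
            expression,
            tumor_samples,
            config.shared_fdr,
            config.min_r,
            config.corr_fdr,
        )
        cerna_nets[s] = net
        cio.write_network(net, cerna_dir / f"{s}.tsv")
        cio.write_network(net, cerna_dir / f"{s}.sif", format="SIF")
    results["cerna"] = cerna_nets

    # ---- topology -----------------------------------------------------------
    _stage("topology")
    topo_dir = out / "topology"
    topo_dir.mkdir(exist_ok=True)
    hub_sets: dict[str, set] = {}
    hub_rows = []
    kcores = {}
    powerlaw_rows = []
    for s in subtypes:
        graph = cerna_nets[s].graph
        if graph.number_of_nodes() == 0:
            warnings.warn(f"{s}: empty ceRNA network; topology skipped")
            hub_sets[s] = set()
            continue
        hubs = identify_hubs(cerna_nets[s], config.hub_fraction)
        hub_sets[s] = hubs
        degrees = dict(graph.degree())
        hub_rows.extend(
            {"subtype": s, "node": n, "degree": degrees[n]} for n in sorted(hubs)
        )
        kcores[s] = kcore(cerna_nets[s])
        table = kcores[s].to_table()
        table.insert(0, "subtype", s)
        _write_table(table, topo_dir / f"kcore.{s}.tsv")
        try:
            exponent, r2 = powerlaw_check(cerna_nets[s])
        except ValueError:
            exponent, r2 = float("nan"), float("nan")
        powerlaw_rows.append({"subtype": s, "exponent": exponent, "r_squared": r2})
    _write_table(
        pd.DataFrame(hub_rows, columns=["subtype", "node", "degree"]), topo_dir / "hubs.tsv"
    )
    _write_table(
        pd.DataFrame(powerlaw_rows, columns=["subtype", "exponent", "r_squared"]),
        topo_dir / "powerlaw.tsv",
    )
    results["hub_sets"] = hub_sets
    results["kcores"] = kcores

    catalog = None
    populated = {s: h for s, h in hub_sets.items() if h}
    if len(populated) >= 3:
        catalog = classify_hubs(populated, config.common_min_subtypes)
        _write_table(catalog.to_table(), topo_dir / "hub_classes.tsv")
        common_net = union_subnetwork(cerna_nets, catalog.common)
        _write_table(_graph_edge_table(common_net), topo_dir / "subnetwork_common.tsv")
        for s in populated:
            specific = catalog.specific_to(s)
            if specific:
                sub, mirna_edges = hub_subnetwork(
                    cerna_nets[s], specific, dysreg_nets[s], hub_fraction=config.hub_fraction
                )
                _write_table(_graph_edge_table(sub), topo_dir / f"subnetwork_{s}_specific.tsv")
                mir_table = pd.DataFrame(mirna_edges, columns=["mirna", "hub"])
                _write_table(mir_table, topo_dir / f"subnetwork_{s}_specific_mirnas.tsv")
    else:
        warnings.warn("fewer than 3 populated subtype networks; hub classification skipped")
    results["hub_catalog"] = catalog

    # ---- enrichment ---------------------------------------------------------
    if config.gmts and catalog is not None and "mRNA" in expression:
        _stage("enrich")
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        collection = cio.GeneSetCollection()
        for category, path in sorted(config.gmts.items()):
            part = cio.read_gmt(path, category)
            for name, members in part.sets[category].items():
                collection.add(category, name, members)
        universe = set(expression["mRNA"].gene_ids)
        queries = {"common": set(catalog.common) & universe}
        for s in populated:
            queries[f"{s}_specific"] = set(catalog.specific_to(s)) & universe
        enrichments = {}
        for label, query in sorted(queries.items()):
            if not query:
                warnings.warn(f"enrichment query {label!r} empty after restriction to mRNA universe")
                continue
            table = enrich(query, collection, universe, config.enrich_fdr)
            _write_table(table, enr_dir / f"{label}.tsv")
            enrichments[label] = table
        results["enrichment"] = enrichments

    # ---- mutation overlay ---------------------------------------------------
    if config.mutations:
        _stage("mutation_overlay")
        mut_rows = []
        for s in subtypes:
            if s not in config.mutations or s not in kcores:
                continue
            mutated = cio.read_gene_list(config.mutations[s])
            overlay = mutation_overlay(cerna_nets[s], mutated, hub_sets[s], kcores[s])
            if overlay is None:
                continue
            mut_rows.append(
                {
                    "subtype": s,
                    "n_mutated_in_network": overlay.n_mutated_in_network,
                    "degree_p": overlay.degree_p,
                    "hub_enrichment_p": overlay.hub_enrichment_p,
                    "mean_layer_mutated": overlay.mean_layer_mutated,
                    "mean_layer_other": overlay.mean_layer_other,
                }
            )
        _write_table(
            pd.DataFrame(
                mut_rows,
                columns=[
                    "subtype",
                    "n_mutated_in_network",
                    "degree_p",
                    "hub_enrichment_p",
                    "mean_layer_mutated",
                    "mean_layer_other",
                ],
            ),
            out / "mutation_overlay.tsv",
        )
        results["mutation_overlay"] = mut_rows

    # ---- manifest -----------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "subtypes": list(subtypes),
        "inputs": {
            "expression": {cls: _sha256(p) for cls, p in sorted(config.expression.items())},
            "annotation": _sha256(config.annotation),
            "targets": _sha256(config.targets),
            "gmts": {c: _sha256(p) for c, p in sorted(config.gmts.items())},
            "mutations": {s: _sha256(p) for s, p in sorted(config.mutations.items())},
        },
        "summary": {
            "n_de_called": {s: int(len(t)) for s, t in sorted(de_called.items())},
            "dysreg_edges": {s: dysreg_nets[s].graph.number_of_edges() for s in subtypes},
            "cerna_edges": {s: cerna_nets[s].graph.number_of_edges() for s in subtypes},
            "cerna_nodes": {s: cerna_nets[s].graph.number_of_nodes() for s in subtypes},
            "n_hubs": {s: len(hub_sets[s]) for s in subtypes},
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
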