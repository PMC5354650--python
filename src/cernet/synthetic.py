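"""Synthetic multi-subtype cohorts with planted ceRNA structure.

The generator emulates the statistical structure the pipeline assumes:
log2-scale expression with per-gene baselines and Gaussian noise, planted
up/down-regulated genes per subtype, planted miRNA -> target repression
(negative tumor-sample correlation) and planted ceRNA couples — pairs of
targets sharing a fixed number of regulator miRNAs and co-expressed
positively through a shared latent driver.  Ground-truth labels are emitted
alongside so every downstream stage can be scored offline.

Model, per sample s and target gene g (all on the log2 scale):

    x_gs = mu_g + delta_g * [s tumor of a subtype where g is planted DE]
              + beta * S_p(s) * [g endpoint of couple p]
              + c_p(s)        * [g endpoint of couple p]
              + eps_gs,                 eps ~ N(0, noise_sd^2)

where S_p(s) is the baseline-centered summed expression of couple p's
miRNAs, so the repression slope beta < 0 couples each endpoint negatively to
its regulators and — because both endpoints see the same S_p — positively to
its partner.  miRNAs are drawn first; the miRNAs of one couple additionally
share a latent per-sample cluster factor (miRNA genes co-transcribed as a
cluster, e.g. the miR-17-92 family, are strongly co-expressed), which is
what gives each single miRNA -> target edge a detectable correlation even
though every endpoint integrates several miRNAs.  Normal samples carry the
baselines and noise only: no DE shifts, no repression coupling, no drivers.

Couple endpoints and couple-pool miRNAs are planted DE in every subtype
(endpoints down, miRNAs up) on top of the per-class background ``de_fraction``;
their baselines are drawn from the well-expressed range so the non-negativity
floor of the raw scale is essentially never reached.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleAnnotation, TargetMap

__all__ = [
    "SimConfig",
    "Couple",
    "GroundTruth",
    "SimResult",
    "simulate_cohort",
    "write_fixture_bundle",
    "evaluate_de",
    "evaluate_dysreg",
    "evaluate_couples",
]

DEFAULT_SUBTYPES = ("LumA", "LumB", "Her2", "Basal")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings; the defaults define the standard fixture."""

    n_subtypes: int = 2
    n_tumor_per_subtype: int = 50
    n_normal: int = 50
    n_mrna: int = 500
    n_lncrna: int = 100
    n_mirna: int = 100
    de_fraction: float = 0.10  # background planted DE per class per subtype
    de_lfc: float = 1.5  # log2 fold-change magnitude of planted DE
    noise_sd: float = 0.5  # per-gene Gaussian noise, log2 units
    n_couples: int = 30
    mirnas_per_couple: int = 5
    couple_mirna_pool: int = 60  # DE miRNAs the couples draw their regulators from
    couple_lnc_fraction: float = 1 / 3  # couples with one lncRNA endpoint
    repression: float = -0.5  # beta: target slope per unit centered miRNA
    couple_driver_sd: float = 0.5  # shared endpoint driver c_p
    mirna_cluster_sd: float = 0.7  # shared within-couple miRNA factor
    couple_mirna_lfc: float = 2.5  # planted up-shift of couple-pool miRNAs
    decoy_factor: float = 5.0  # decoy target edges per planted edge
    n_decoy_edges: int | None = None  # absolute override of the decoy count
    baseline_range: tuple[float, float] = (3.0, 10.0)
    couple_baseline_range: tuple[float, float] = (12.0, 16.0)
    subtype_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_subtypes": self.n_subtypes,
            "n_tumor_per_subtype": self.n_tumor_per_subtype,
            "n_normal": self.n_normal,
            "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna,
            "n_mirna": self.n_mirna,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.de_fraction < 1:
            raise ValueError("de_fraction must be in (0, 1)")
        if not 0 <= self.couple_lnc_fraction < 1:
            raise ValueError("couple_lnc_fraction must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_couples and self.repression >= 0:
            raise ValueError("repression strength must be negative")
        if self.n_couples < 0 or self.mirnas_per_couple <= 0:
            raise ValueError("couple counts must be non-negative")

    @property
    def subtypes(self) -> list[str]:
        if self.subtype_names is not None:
            names = list(self.subtype_names)
            if len(names) != self.n_subtypes:
                raise ValueError("subtype_names length must equal n_subtypes")
            return names
        if self.n_subtypes <= len(DEFAULT_SUBTYPES):
            return list(DEFAULT_SUBTYPES[: self.n_subtypes])
        return [f"S{i + 1}" for i in range(self.n_subtypes)]

    def validate_feasibility(self) -> None:
        if self.n_couples == 0:
            return
        if self.mirnas_per_couple > self.couple_mirna_pool:
            raise ValueError("mirnas_per_couple exceeds the couple miRNA pool")
        n_bg_mirna = math.floor(self.de_fraction * self.n_mirna)
        if self.couple_mirna_pool + n_bg_mirna > self.n_mirna:
            raise ValueError("couple miRNA pool plus background DE exceeds n_mirna")
        n_lnc_couples = round(self.couple_lnc_fraction * self.n_couples)
        n_mrna_endpoints = 2 * self.n_couples - n_lnc_couples
        if n_mrna_endpoints + math.floor(self.de_fraction * self.n_mrna) > self.n_mrna:
            raise ValueError("not enough mRNA genes for couple endpoints plus background DE")
        if n_lnc_couples + math.floor(self.de_fraction * self.n_lncrna) > self.n_lncrna:
            raise ValueError("not enough lncRNA genes for couple endpoints plus background DE")


@dataclass(frozen=True)
class Couple:
    gene_a: str  # mRNA endpoint
    gene_b: str  # mRNA or lncRNA endpoint
    class_b: str
    mirnas: frozenset

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass
class GroundTruth:
    """Planted structure: DE labels, repression edges, couples, decoys."""

    de: dict[str, dict[str, str]]  # subtype -> gene -> direction
    edges: dict[str, frozenset]  # subtype -> planted (mirna, target) pairs
    couples: list[Couple]
    decoy_edges: frozenset  # (mirna, target) with no expression coupling

    def couple_pairs(self) -> set[tuple[str, str]]:
        return {c.pair for c in self.couples}


@dataclass
class SimResult:
    config: SimConfig
    expression: dict[str, ExpressionMatrix]  # class -> matrix (log2 scale)
    annotation: SampleAnnotation
    target_map: TargetMap
    truth: GroundTruth


def _choose(rng: np.random.Generator, items: Sequence[str], k: int) -> list[str]:
    return list(rng.choice(np.asarray(items, dtype=object), size=k, replace=False))


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate one cohort; identical config (incl. seed) gives identical output."""
    config.validate_feasibility()
    rng = np.random.default_rng(config.seed)
    subtypes = config.subtypes

    mrna_ids = [f"GENE{i:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC{i:04d}" for i in range(config.n_lncrna)]
    mir_ids = [f"MIR{i:04d}" for i in range(config.n_mirna)]
    class_of = {g: "mRNA" for g in mrna_ids}
    class_of.update({g: "lncRNA" for g in lnc_ids})

    # --- planted couples -------------------------------------------------
    couples: list[Couple] = []
    pool: list[str] = []
    if config.n_couples:
        n_lnc_couples = round(config.couple_lnc_fraction * config.n_couples)
        n_mrna_endpoints = 2 * config.n_couples - n_lnc_couples
        mrna_endpoints = _choose(rng, mrna_ids, n_mrna_endpoints)
        lnc_endpoints = _choose(rng, lnc_ids, n_lnc_couples)
        pool = _choose(rng, mir_ids, config.couple_mirna_pool)
        mi = 0
        for i in range(config.n_couples):
            gene_a = mrna_endpoints[mi]
            mi += 1
            if i < n_lnc_couples:
                gene_b, class_b = lnc_endpoints[i], "lncRNA"
            else:
                gene_b, class_b = mrna_endpoints[mi], "mRNA"
                mi += 1
            mirnas = frozenset(_choose(rng, pool, config.mirnas_per_couple))
            couples.append(Couple(gene_a, gene_b, class_b, mirnas))
    endpoint_genes = {c.gene_a for c in couples} | {c.gene_b for c in couples}
    pool_set = set(pool)

    # --- background DE (per subtype, outside the couple machinery) -------
    de: dict[str, dict[str, str]] = {s: {} for s in subtypes}
    for cls_ids, n_cls in ((mrna_ids, config.n_mrna), (lnc_ids, config.n_lncrna), (mir_ids, config.n_mirna)):
        free = [g for g in cls_ids if g not in endpoint_genes and g not in pool_set]
        n_bg = math.floor(config.de_fraction * n_cls)
        for s in subtypes:
            chosen = _choose(rng, free, n_bg)
            signs = rng.choice([-1.0, 1.0], size=n_bg)
            for g, sign in zip(chosen, signs):
                de[s][g] = "up" if sign > 0 else "down"
    for s in subtypes:  # couple machinery is DE in every subtype
        for g in endpoint_genes:
            de[s][g] = "down"
        for m in pool:
            de[s][m] = "up"

    # --- samples ----------------------------------------------------------
    tumor_samples = {s: [f"{s}_T{i:03d}" for i in range(config.n_tumor_per_subtype)] for s in subtypes}
    normal_samples = [f"NORM_N{i:03d}" for i in range(config.n_normal)]
    all_tumor = [smp for s in subtypes for smp in tumor_samples[s]]
    columns = all_tumor + normal_samples
    n_tumor = len(all_tumor)
    n_total = len(columns)
    groups = {smp: s for s in subtypes for smp in tumor_samples[s]}
    groups.update({smp: "normal" for smp in normal_samples})
    tumor_block = {
        s: slice(i * config.n_tumor_per_subtype, (i + 1) * config.n_tumor_per_subtype)
        for i, s in enumerate(subtypes)
    }

    lo, hi = config.baseline_range
    clo, chi = config.couple_baseline_range

    def _baselines(ids: list[str], well_expressed: set) -> np.ndarray:
        mu = rng.uniform(lo, hi, size=len(ids))
        for i, g in enumerate(ids):
            if g in well_expressed:
                mu[i] = rng.uniform(clo, chi)
        return mu

    mu_mir = _baselines(mir_ids, pool_set)
    mu_mrna = _baselines(mrna_ids, endpoint_genes)
    mu_lnc = _baselines(lnc_ids, endpoint_genes)

    def _de_shift(ids: list[str], subtype: str) -> np.ndarray:
        # couple-pool miRNAs carry a stronger planted up-shift (strongly
        # induced miRNA clusters) so the |LFC| >= 1 call is never marginal
        # despite their cluster-driver variance
        shift = np.zeros(len(ids))
        labels = de[subtype]
        for i, g in enumerate(ids):
            if g in pool_set:
                shift[i] = config.couple_mirna_lfc
            elif g in labels:
                shift[i] = config.de_lfc if labels[g] == "up" else -config.de_lfc
        return shift

    # --- miRNA matrix (drawn first) ---------------------------------------
    mir_index = {m: i for i, m in enumerate(mir_ids)}
    Z = mu_mir[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_mirna, n_total))
    for s in subtypes:
        Z[:, tumor_block[s]] += _de_shift(mir_ids, s)[:, None]
    if couples:
        # per-couple cluster factor, tumor samples only
        U = rng.normal(0.0, config.mirna_cluster_sd, size=(len(couples), n_tumor))
        A = np.zeros((config.n_mirna, len(couples)))
        for p, c in enumerate(couples):
            for m in c.mirnas:
                A[mir_index[m], p] = 1.0
        Z[:, :n_tumor] += A @ U

    # --- target matrices ---------------------------------------------------
    X_mrna = mu_mrna[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_mrna, n_total))
    X_lnc = mu_lnc[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_lncrna, n_total))
    for s in subtypes:
        X_mrna[:, tumor_block[s]] += _de_shift(mrna_ids, s)[:, None]
        X_lnc[:, tumor_block[s]] += _de_shift(lnc_ids, s)[:, None]
    if couples:
        C = rng.normal(0.0, config.couple_driver_sd, size=(len(couples), n_tumor))
        Z_centered = Z[:, :n_tumor] - mu_mir[:, None]
        mrna_index = {g: i for i, g in enumerate(mrna_ids)}
        lnc_index = {g: i for i, g in enumerate(lnc_ids)}
        for p, c in enumerate(couples):
            rows = [mir_index[m] for m in sorted(c.mirnas)]
            S = Z_centered[rows].sum(axis=0)
            effect = config.repression * S + C[p]
            for gene in (c.gene_a, c.gene_b):
                if gene in mrna_index:
                    X_mrna[mrna_index[gene], :n_tumor] += effect
                else:
                    X_lnc[lnc_index[gene], :n_tumor] += effect

    # raw-scale expression is non-negative, so the log2 scale floors at 0
    Z = np.maximum(Z, 0.0)
    X_mrna = np.maximum(X_mrna, 0.0)
    X_lnc = np.maximum(X_lnc, 0.0)

    expression = {
        "mRNA": ExpressionMatrix("mRNA", pd.DataFrame(X_mrna, index=mrna_ids, columns=columns)),
        "lncRNA": ExpressionMatrix("lncRNA", pd.DataFrame(X_lnc, index=lnc_ids, columns=columns)),
        "miRNA": ExpressionMatrix("miRNA", pd.DataFrame(Z, index=mir_ids, columns=columns)),
    }

    # --- target map: planted edges + decoys --------------------------------
    planted_edges = {
        (m, g) for c in couples for m in c.mirnas for g in (c.gene_a, c.gene_b)
    }
    n_decoys = (
        config.n_decoy_edges
        if config.n_decoy_edges is not None
        else int(round(config.decoy_factor * len(planted_edges)))
    )
    de_union_mirnas = sorted({g for s in subtypes for g in de[s] if g.startswith("MIR")})
    de_union_targets = sorted({g for s in subtypes for g in de[s] if not g.startswith("MIR")})
    decoys: set[tuple[str, str]] = set()
    if n_decoys:
        if not de_union_mirnas or not de_union_targets:
            raise ValueError("cannot place decoy edges without DE miRNAs and DE targets")
        max_pairs = len(de_union_mirnas) * len(de_union_targets) - len(planted_edges)
        if n_decoys > max_pairs:
            raise ValueError(f"requested {n_decoys} decoy edges but only {max_pairs} pairs available")
        while len(decoys) < n_decoys:
            m = de_union_mirnas[rng.integers(len(de_union_mirnas))]
            g = de_union_targets[rng.integers(len(de_union_targets))]
            if (m, g) not in planted_edges:
                decoys.add((m, g))
    triples = frozenset(
        (m, g, class_of[g]) for m, g in planted_edges | decoys
    )
    target_map = TargetMap(triples)

    truth = GroundTruth(
        de=de,
        edges={s: frozenset(planted_edges) for s in subtypes},
        couples=couples,
        decoy_edges=frozenset(decoys),
    )
    return SimResult(config, expression, SampleAnnotation(groups), target_map, truth)


def write_fixture_bundle(
    result: SimResult, directory: str | Path, overwrite: bool = False, pseudocount: float = 1.0
) -> dict[str, Path]:
    """Write a cohort to disk in the formats the io module reads.

    Expression goes out on the raw scale (``2**x - pseudocount``) so that
    ``read_expression`` recovers the simulated log2 matrices; ground truth is
    written as TSVs.  Re-running with the same seed is byte-identical.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty (use overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    name_of = {"mRNA": "mrna", "lncRNA": "lncrna", "miRNA": "mirna"}
    for cls, mat in result.expression.items():
        raw = np.maximum(np.exp2(mat.data.to_numpy()) - pseudocount, 0.0)
        frame = pd.DataFrame(raw, index=mat.data.index, columns=mat.data.columns)
        path = directory / f"{name_of[cls]}.tsv"
        frame.to_csv(path, sep="\t", float_format="%.6f")
        paths[cls] = path

    ann_path = directory / "annotation.tsv"
    with open(ann_path, "w") as fh:
        for smp in result.expression["mRNA"].sample_ids:
            fh.write(f"{smp}\t{result.annotation.groups[smp]}\n")
    paths["annotation"] = ann_path

    tgt_path = directory / "targets.tsv"
    with open(tgt_path, "w") as fh:
        for m, g, cls in sorted(result.target_map.triples):
            fh.write(f"{m}\t{g}\t{cls}\n")
    paths["targets"] = tgt_path

    de_path = directory / "truth_de.tsv"
    with open(de_path, "w") as fh:
        fh.write("subtype\tgene\tdirection\n")
        for s in sorted(result.truth.de):
            for g in sorted(result.truth.de[s]):
                fh.write(f"{s}\t{g}\t{result.truth.de[s][g]}\n")
    paths["truth_de"] = de_path

    edge_path = directory / "truth_edges.tsv"
    with open(edge_path, "w") as fh:
        fh.write("subtype\tmirna\ttarget\n")
        for s in sorted(result.truth.edges):
            for m, g in sorted(result.truth.edges[s]):
                fh.write(f"{s}\t{m}\t{g}\n")
    paths["truth_edges"] = edge_path

    couple_path = directory / "truth_couples.tsv"
    with open(couple_path, "w") as fh:
        fh.write("geneA\tgeneB\tclassB\tmirnas\n")
        for c in sorted(result.truth.couples, key=lambda c: c.pair):
            fh.write(f"{c.gene_a}\t{c.gene_b}\t{c.class_b}\t{','.join(sorted(c.mirnas))}\n")
    paths["truth_couples"] = couple_path

    cfg_path = directory / "sim_config.json"
    cfg = asdict(result.config)
    cfg["subtype_names"] = result.config.subtypes
    with open(cfg_path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["config"] = cfg_path
    return paths


# --- ground-truth scoring helpers -----------------------------------------


def evaluate_de(
    called: Mapping[str, pd.DataFrame], truth: GroundTruth, all_genes: set
) -> dict[str, float]:
    """Sensitivity over planted DE (direction-matched) and false-call rate
    among non-planted genes, averaged over subtypes."""
    sens, fcr = [], []
    for s, labels in truth.de.items():
        table = called[s]
        calls = dict(zip(table["gene"], table["direction"]))
        hit = sum(1 for g, d in labels.items() if calls.get(g) == d)
        sens.append(hit / len(labels))
        non_planted = all_genes - set(labels)
        false = sum(1 for g in calls if g not in labels)
        fcr.append(false / len(non_planted) if non_planted else 0.0)
    return {"sensitivity": float(np.mean(sens)), "false_call_rate": float(np.mean(fcr))}


def evaluate_dysreg(networks: Mapping[str, object], truth: GroundTruth) -> float:
    """Mean recall of planted miRNA -> target edges across subtype networks."""
    recalls = []
    for s, planted in truth.edges.items():
        net = networks[s]
        recovered = sum(1 for m, g in planted if net.graph.has_edge(m, g))
        recalls.append(recovered / len(planted) if planted else float("nan"))
    return float(np.mean(recalls))


def evaluate_couples(networks: Mapping[str, object], truth: GroundTruth) -> dict[str, float]:
    """Mean sensitivity and precision of planted couple recovery.

    Sensitivity: fraction of planted couples present as edges of the subtype
    ceRNA network.  Precision: fraction of called edges that are planted
    couples.  Both averaged over subtypes.
    """
    pairs = truth.couple_pairs()
    sens, prec = [], []
    for s in truth.de:
        net = networks[s]
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        hit = len(pairs & edges)
        sens.append(hit / len(pairs) if pairs else float("nan"))
        prec.append(hit / len(edges) if edges else float("nan"))
    return {"sensitivity": float(np.mean(sens)), "precision": float(np.mean(prec))}
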