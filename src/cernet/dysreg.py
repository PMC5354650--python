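"""miRNA dys-regulatory networks.

For one subtype, a bipartite directed network miRNA -> target is built from
(i) the sequence-predicted target map, restricted to (ii) miRNAs and targets
that are both differentially expressed in that subtype, keeping (iii) only
pairs whose expression across the subtype's tumor samples is negatively
correlated (Pearson r < 0, two-sided p < 0.01 by default, uncorrected by
design — the raw threshold is what defines the network).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pearson_with_p
from .io import ExpressionMatrix, TargetMap

logger = logging.getLogger(__name__)

__all__ = ["DysregNetwork", "pearson_test", "build_dysreg"]


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-transform p-value."""
    return pearson_with_p(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


@dataclass
class DysregNetwork:
    """Bipartite miRNA -> target graph for one subtype.

    Nodes carry ``kind`` ("miRNA" or "target") and targets a ``rna_class``;
    edges carry the Pearson ``r`` and raw ``p`` computed on the subtype's
    tumor samples.
    """

    subtype: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    sif_relation: str = "represses"

    @property
    def mirnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "miRNA"}

    @property
    def targets(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "target"}

    def regulators_of(self, target: str) -> set[str]:
        return set(self.graph.predecessors(target)) if target in self.graph else set()

    def target_class(self, target: str) -> str | None:
        return self.graph.nodes[target].get("rna_class") if target in self.graph else None

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": m,
                "target": t,
                "target_class": self.graph.nodes[t].get("rna_class"),
                "r": d["r"],
                "p": d["p"],
            }
            for m, t, d in self.graph.edges(data=True)
        ]
        table = pd.DataFrame(rows, columns=["mirna", "target", "target_class", "r", "p"])
        return table.sort_values(["mirna", "target"], kind="mergesort").reset_index(drop=True)


def _stack_expression(
    expr: Mapping[str, ExpressionMatrix], genes: list[str], samples: list[str]
) -> pd.DataFrame:
    """Rows for ``genes`` pulled from the per-class matrices, aligned on ``samples``."""
    pieces = []
    for mat in expr.values():
        present = [g for g in genes if g in mat.data.index]
        if present:
            pieces.append(mat.data.loc[present, samples])
    if not pieces:
        return pd.DataFrame(columns=samples)
    stacked = pd.concat(pieces, axis=0)
    return stacked[~stacked.index.duplicated(keep="first")]


def build_dysreg(
    de_mirnas: set,
    de_targets: Mapping[str, str],
    targets: TargetMap,
    expr: Mapping[str, ExpressionMatrix],
    subtype: str,
    tumor_samples: list[str],
    p_max: float = 0.01,
) -> DysregNetwork:
    """Assemble the subtype dys-regulatory network.

    ``de_targets`` maps DE target gene id to its RNA class; ``expr`` maps RNA
    class to its (full-cohort) expression matrix — correlations are computed
    on ``tumor_samples`` only.  An edge (m, g) is retained iff the pair is
    sequence-predicted, both endpoints are DE in this subtype, and the
    tumor-sample Pearson correlation is negative with raw p < ``p_max``.
    Zero-variance genes are skipped and logged; isolated nodes are dropped.
    """
    net = DysregNetwork(subtype)
    if not de_mirnas or not de_targets:
        warnings.warn(f"{subtype}: empty DE set; dys-regulatory network is empty")
        return net

    candidate = [
        (m, t, cls)
        for m, t, cls in targets.triples
        if m in de_mirnas and t in de_targets
    ]
    if not candidate:
        return net

    n = len(tumor_samples)
    if n < 3:
        raise ValueError("need at least 3 tumor samples for correlation")

    mirna_expr = expr["miRNA"].data
    tgt_genes = sorted({t for _, t, _ in candidate})
    tgt_mat = _stack_expression(
        {k: v for k, v in expr.items() if k != "miRNA"}, tgt_genes, tumor_samples
    )

    # standardize rows once; r = z_m . z_t / n
    def _standardize(frame: pd.DataFrame) -> tuple[pd.DataFrame, set]:
        arr = frame.to_numpy(dtype=float)
        mean = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, keepdims=True)
        flat = set(frame.index[(sd[:, 0] == 0.0)])
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (arr - mean) / sd
        return pd.DataFrame(z, index=frame.index, columns=frame.columns), flat

    mirnas_used = sorted({m for m, _, _ in candidate if m in mirna_expr.index})
    mir_z, mir_flat = _standardize(mirna_expr.loc[mirnas_used, tumor_samples])
    tgt_z, tgt_flat = _standardize(tgt_mat)
    skipped = 0
    df = n - 2

    for m, t, cls in sorted(candidate):
        if m not in mir_z.index or t not in tgt_z.index:
            skipped += 1
            continue
        if m in mir_flat or t in tgt_flat:
            skipped += 1
            continue
        r = float(mir_z.loc[m].to_numpy() @ tgt_z.loc[t].to_numpy()) / n
        r = max(-1.0, min(1.0, r))
        if r >= 0:
            continue
        if abs(r) == 1.0:
            p = 0.0
        else:
            tstat = r * np.sqrt(df / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(tstat), df))
        if p >= p_max:
            continue
        cls = cls if cls is not None else de_targets.get(t)
        net.graph.add_node(m, kind="miRNA")
        net.graph.add_node(t, kind="target", rna_class=cls)
        net.graph.add_edge(m, t, r=r, p=p)
    if skipped:
        logger.info(
            "%s: skipped %d candidate pairs (missing expression or zero variance)", subtype, skipped
        )
    return net
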