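"""Subtype ceRNA networks from the shared-miRNA hypergeometric test.

Two targets of a subtype's dys-regulatory network are called competing
endogenous RNAs when (1) they share significantly more regulator miRNAs than
expected by chance — an upper-tail hypergeometric test over the network's
miRNA universe, Bonferroni corrected over all candidate pairs — and (2)
their expression across the subtype's tumor samples is positively correlated
with r >= 0.5 and a Bonferroni-corrected correlation p below threshold.
Edges of the assembled undirected network all carry weight 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import hypergeom_upper_tail
from .dysreg import DysregNetwork, _stack_expression
from .io import ExpressionMatrix

__all__ = ["SharedMiRNATest", "CeRNANetwork", "hypergeom_shared", "candidate_pairs", "build_cerna"]


def hypergeom_shared(M: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for the shared-miRNA count of a target pair.

    ``M`` is the miRNA universe (miRNA nodes of the subtype dys-regulatory
    network), ``K`` and ``n`` the regulator counts of the two targets, ``x``
    the observed shared count.
    """
    return hypergeom_upper_tail(M, K, n, x)


@dataclass(frozen=True)
class SharedMiRNATest:
    gene_a: str
    gene_b: str
    M: int
    K: int
    n: int
    x: int
    p_raw: float
    p_adj: float
    shared: frozenset


@dataclass
class CeRNANetwork:
    """Undirected target-target graph for one subtype; all edge weights 1."""

    subtype: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    sif_relation: str = "cerna"

    def to_edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, d in self.graph.edges(data=True):
            a, b = sorted((a, b))
            rows.append(
                {
                    "geneA": a,
                    "geneB": b,
                    "classA": self.graph.nodes[a].get("rna_class"),
                    "classB": self.graph.nodes[b].get("rna_class"),
                    "n_shared": d["n_shared"],
                    "shared_fdr": d["shared_fdr"],
                    "r": d["r"],
                    "corr_fdr": d["corr_fdr"],
                }
            )
        table = pd.DataFrame(
            rows,
            columns=["geneA", "geneB", "classA", "classB", "n_shared", "shared_fdr", "r", "corr_fdr"],
        )
        return table.sort_values(["geneA", "geneB"], kind="mergesort").reset_index(drop=True)


def candidate_pairs(net: DysregNetwork) -> list[tuple[str, str]]:
    """All unordered target pairs of the network sharing >= 1 regulator miRNA.

    Pairs span RNA classes (mRNA-mRNA, mRNA-lncRNA, lncRNA-lncRNA alike).
    """
    pairs = set()
    for m in net.mirnas:
        regulated = sorted(net.graph.successors(m))
        for a, b in combinations(regulated, 2):
            pairs.add((a, b))
    return sorted(pairs)


def build_cerna(
    net: DysregNetwork,
    expr: Mapping[str, ExpressionMatrix],
    tumor_samples: list[str],
    shared_fdr: float = 0.01,
    min_r: float = 0.5,
    corr_fdr: float = 0.01,
) -> CeRNANetwork:
    """Call ceRNA edges among the dys-regulatory network's targets.

    Both Bonferroni corrections use m = the number of candidate pairs tested
    in this subtype, applied independently to the sharing test and the
    correlation test.  The correlation uses the subtype's tumor samples.
    Isolated nodes are dropped from the assembled network.
    """
    out = CeRNANetwork(net.subtype)
    pairs = candidate_pairs(net)
    if not pairs:
        warnings.warn(f"{net.subtype}: no candidate target pairs; ceRNA network is empty")
        return out

    m_tests = len(pairs)
    M = len(net.mirnas)
    regulators = {t: net.regulators_of(t) for t in net.targets}

    genes = sorted(net.targets)
    tgt_mat = _stack_expression(
        {k: v for k, v in expr.items() if k != "miRNA"}, genes, tumor_samples
    )
    arr = tgt_mat.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    zindex = {g: i for i, g in enumerate(tgt_mat.index)}
    flat = {g for g, i in zindex.items() if sd[i, 0] == 0.0}
    n_samp = len(tumor_samples)
    dof = n_samp - 2

    for a, b in pairs:
        if a not in zindex or b not in zindex or a in flat or b in flat:
            continue
        shared = regulators[a] & regulators[b]
        x = len(shared)
        p_shared = hypergeom_shared(M, len(regulators[a]), len(regulators[b]), x)
        p_shared_adj = min(1.0, p_shared * m_tests)
        if p_shared_adj >= shared_fdr:
            continue
        r = float(z[zindex[a]] @ z[zindex[b]]) / n_samp
        r = max(-1.0, min(1.0, r))
        if r < min_r:
            continue
        if abs(r) == 1.0:
            p_corr = 0.0
        else:
            tstat = r * np.sqrt(dof / (1.0 - r * r))
            p_corr = float(2.0 * stats.t.sf(abs(tstat), dof))
        p_corr_adj = min(1.0, p_corr * m_tests)
        if p_corr_adj >= corr_fdr:
            continue
        out.graph.add_node(a, rna_class=net.target_class(a))
        out.graph.add_node(b, rna_class=net.target_class(b))
        out.graph.add_edge(
            a,
            b,
            weight=1,
            shared=frozenset(shared),
            n_shared=x,
            shared_p=p_shared,
            shared_fdr=p_shared_adj,
            r=r,
            corr_p=p_corr,
            corr_fdr=p_corr_adj,
        )
    return out
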