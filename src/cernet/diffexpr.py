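"""Per-subtype differential expression by Wilcoxon rank-sum versus normals.

Each subtype's tumor samples are compared with the shared normal cohort,
gene by gene, with a two-sided rank-sum test.  P-values are Bonferroni
adjusted within the RNA class (reported under the column name ``fdr``, the
label conventionally used for the thresholded quantity in this literature)
and significance requires both ``fdr < 0.05`` and ``|log2 fold change| >= 1``
by default.  The log2 fold change is the difference of group means on the
already-log2 matrix.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = ["wilcoxon_de", "call_de", "concordance"]

DE_COLUMNS = ["gene", "class", "subtype", "W", "p", "fdr", "lfc", "direction", "degenerate"]


def _asymptotic_ranksum(tumor: np.ndarray, normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected normal-approximation rank-sum over gene rows.

    No continuity correction, matching the scalar kernel.  Returns
    (rank-sum W of the tumor group, two-sided p) per gene.
    """
    n1 = tumor.shape[1]
    n2 = normal.shape[1]
    pooled = np.concatenate([tumor, normal], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    u = w - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction: sum of (t^3 - t) over tie groups, per gene
    sorted_vals = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(sorted_vals[i], return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var <= 0, 1.0, np.minimum(p, 1.0))
    return w, p


def wilcoxon_de(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    subtype: str,
    fdr: float = 0.05,
    min_abs_lfc: float = 1.0,
    exact_limit: int = 10,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per gene: ``subtype`` vs normals.

    Exact enumeration is used for a gene when both groups have at most
    ``exact_limit`` samples and its pooled values are tie-free; otherwise the
    tie-corrected normal approximation.  Genes with zero variance in both
    groups get ``p = 1`` by convention and are flagged ``degenerate``.
    Bonferroni adjustment spans all genes of the matrix (one RNA class).
    """
    tumor_samples = [s for s in ann.samples_in(subtype) if s in expr.data.columns]
    normal_samples = [s for s in ann.samples_in(ann.normal_label) if s in expr.data.columns]
    if subtype not in ann.group_names:
        raise ValueError(f"subtype {subtype!r} absent from annotation")
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise ValueError(
            f"need >=2 samples per group; got {len(tumor_samples)} {subtype} and "
            f"{len(normal_samples)} {ann.normal_label}"
        )

    tumor = expr.data.loc[:, tumor_samples].to_numpy()
    normal = expr.data.loc[:, normal_samples].to_numpy()
    n_genes = tumor.shape[0]
    lfc = tumor.mean(axis=1) - normal.mean(axis=1)

    use_exact = len(tumor_samples) <= exact_limit and len(normal_samples) <= exact_limit
    w = np.empty(n_genes)
    p = np.empty(n_genes)
    degenerate = np.zeros(n_genes, dtype=bool)
    if use_exact:
        for i in range(n_genes):
            res = rank_sum_test(tumor[i], normal[i], "two-sided", exact_limit)
            w[i], p[i] = res.statistic, res.pvalue
            degenerate[i] = res.method == "degenerate"
    else:
        w, p = _asymptotic_ranksum(tumor, normal)
        pooled = np.concatenate([tumor, normal], axis=1)
        degenerate = np.all(pooled == pooled[:, :1], axis=1)
        p = np.where(degenerate, 1.0, p)
    if degenerate.any():
        logger.info("%d genes with zero variance in both groups (p=1 by convention)", int(degenerate.sum()))

    adj = np.minimum(1.0, p * n_genes)
    significant = (adj < fdr) & (np.abs(lfc) >= min_abs_lfc)
    direction = np.where(significant, np.where(lfc > 0, "up", "down"), "NS")

    return pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "class": expr.rna_class,
            "subtype": subtype,
            "W": w,
            "p": p,
            "fdr": adj,
            "lfc": lfc,
            "direction": direction,
            "degenerate": degenerate,
        }
    )


def call_de(results: pd.DataFrame, fdr: float = 0.05, min_abs_lfc: float = 1.0) -> pd.DataFrame:
    """Filter to significant genes: adjusted p < ``fdr`` and |LFC| >= ``min_abs_lfc``.

    Direction is (re)assigned from the LFC sign, so ``call_de`` can be run at
    thresholds other than the ones used in :func:`wilcoxon_de`.
    """
    keep = (results["fdr"] < fdr) & (results["lfc"].abs() >= min_abs_lfc)
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["lfc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def concordance(de_sets: Mapping[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-subtype sharing and direction concordance of DE calls.

    ``de_sets`` maps subtype name to its called DE table.  Returns a per-gene
    table (gene, k = number of subtypes where DE, concordant flag) and a
    summary of concordant/discordant percentages per k >= 2.  A change is
    concordant when its direction is identical in every subtype where the
    gene is DE; genes DE in a single subtype are reported with k = 1 but
    excluded from the percentages.
    """
    if len(de_sets) < 2:
        raise ValueError("concordance needs DE calls for at least 2 subtypes")
    directions: dict[str, dict[str, str]] = {}
    for subtype, table in de_sets.items():
        for gene, direction in zip(table["gene"], table["direction"]):
            directions.setdefault(gene, {})[subtype] = direction
    rows = []
    for gene in sorted(directions):
        per_subtype = directions[gene]
        k = len(per_subtype)
        concordant = len(set(per_subtype.values())) == 1
        rows.append({"gene": gene, "k": k, "concordant": concordant if k >= 2 else pd.NA})
    per_gene = pd.DataFrame(rows, columns=["gene", "k", "concordant"])

    summary_rows = []
    for k, group in per_gene[per_gene["k"] >= 2].groupby("k"):
        n = len(group)
        n_conc = int(group["concordant"].sum())
        summary_rows.append(
            {
                "k": int(k),
                "n_genes": n,
                "pct_concordant": 100.0 * n_conc / n,
                "pct_discordant": 100.0 * (n - n_conc) / n,
            }
        )
    summary = pd.DataFrame(summary_rows, columns=["k", "n_genes", "pct_concordant", "pct_discordant"])
    return per_gene, summary
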