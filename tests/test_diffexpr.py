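from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from cernet._stats import rank_sum_test
from cernet.diffexpr import call_de, concordance, wilcoxon_de
from cernet.io import ExpressionMatrix, SampleAnnotation
from cernet.synthetic import SimConfig, simulate_cohort


def _cohort(tumor_rows, normal_rows, genes):
    """Expression + annotation for a one-subtype toy cohort."""
    n_t = len(tumor_rows[0])
    n_n = len(normal_rows[0])
    cols = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
    data = [list(t) + list(n) for t, n in zip(tumor_rows, normal_rows)]
    mat = ExpressionMatrix("mRNA", pd.DataFrame(data, index=genes, columns=cols))
    groups = {f"t{i}": "LumA" for i in range(n_t)}
    groups.update({f"n{i}": "normal" for i in range(n_n)})
    return mat, SampleAnnotation(groups)


def permutation_pvalue(x, y):
    """Exhaustive two-sided rank-sum p over all group assignments (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    hits = sum(
        1
        for idx in combinations(range(n), n1)
        if abs(ranks[list(idx)].sum() - mu) >= abs(w_obs - mu) - 1e-9
    )
    return hits / comb(n, n1)


class TestWilcoxonDE:
    def test_identical_groups(self):
        mat, ann = _cohort([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]], ["g"])
        res = wilcoxon_de(mat, ann, "LumA")
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "lfc"] == 0.0
        assert res.loc[0, "direction"] == "NS"

    def test_exact_mode_complete_separation(self):
        # tumor (5,6,7,8) vs normal (1,2,3,4): two-sided exact p = 2/70
        mat, ann = _cohort([[5.0, 6.0, 7.0, 8.0]], [[1.0, 2.0, 3.0, 4.0]], ["g"])
        res = wilcoxon_de(mat, ann, "LumA")
        assert res.loc[0, "p"] == pytest.approx(2 / 70)
        assert res.loc[0, "W"] == 26  # ranks 5+6+7+8

    def test_lfc_is_mean_difference_of_log2(self):
        mat, ann = _cohort([[4.0, 4.0, 4.0]], [[3.0, 3.0, 3.0]], ["g"])
        res = wilcoxon_de(mat, ann, "LumA")
        assert res.loc[0, "lfc"] == pytest.approx(1.0)

    def test_degenerate_gene_flagged(self):
        mat, ann = _cohort([[2.0, 2.0, 2.0]], [[2.0, 2.0, 2.0]], ["g"])
        res = wilcoxon_de(mat, ann, "LumA")
        assert res.loc[0, "p"] == 1.0 and bool(res.loc[0, "degenerate"])

    def test_missing_subtype_errors(self):
        mat, ann = _cohort([[1.0, 2.0]], [[1.0, 2.0]], ["g"])
        with pytest.raises(ValueError, match="absent"):
            wilcoxon_de(mat, ann, "Basal")

    def test_bonferroni_spans_all_genes(self):
        mat, ann = _cohort(
            [[5.0, 6.0, 7.0, 8.0]] * 3, [[1.0, 2.0, 3.0, 4.0]] * 3, ["g1", "g2", "g3"]
        )
        res = wilcoxon_de(mat, ann, "LumA")
        assert np.allclose(res["fdr"], np.minimum(1.0, res["p"] * 3))

    def test_exact_matches_permutation_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n1, n2 = rng.integers(2, 7, size=2)
            x, y = rng.normal(size=int(n1)), rng.normal(size=int(n2))
            res = rank_sum_test(x, y, "two-sided")
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(permutation_pvalue(x, y), abs=1e-12)

    def test_vectorized_asymptotic_matches_scipy(self):
        from scipy import stats

        from cernet.diffexpr import _asymptotic_ranksum

        rng = np.random.default_rng(17)
        tumor = np.round(rng.normal(size=(15, 20)), 1)  # rounding induces ties
        normal = np.round(rng.normal(size=(15, 18)), 1)
        w, p = _asymptotic_ranksum(tumor, normal)
        for i in range(15):
            ref = stats.mannwhitneyu(
                tumor[i], normal[i], method="asymptotic", use_continuity=False
            )
            assert w[i] == pytest.approx(float(ref.statistic) + 20 * 21 / 2)
            assert p[i] == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_invariant_under_monotone_relabeling(self):
        rng = np.random.default_rng(5)
        tumor = rng.normal(1.0, 1.0, size=(4, 30))
        normal = rng.normal(0.0, 1.0, size=(4, 25))
        genes = [f"g{i}" for i in range(4)]
        mat, ann = _cohort(tumor, normal, genes)
        base = wilcoxon_de(mat, ann, "LumA")
        # strictly increasing transform of every value
        mono = ExpressionMatrix("mRNA", np.exp(mat.data / 4.0))
        res = wilcoxon_de(mono, ann, "LumA")
        assert np.allclose(res["p"], base["p"])
        assert np.allclose(res["W"], base["W"])


class TestCallDE:
    @pytest.mark.parametrize(
        "fdr,lfc,included,direction",
        [
            (0.04, 0.9, False, None),
            (0.04, -1.2, True, "down"),
            (0.06, 3.0, False, None),
            (0.01, 1.0, True, "up"),  # |LFC| >= 1 is inclusive
        ],
    )
    def test_threshold_rule(self, fdr, lfc, included, direction):
        table = pd.DataFrame(
            {
                "gene": ["g"],
                "class": ["mRNA"],
                "subtype": ["LumA"],
                "W": [0.0],
                "p": [fdr / 10],
                "fdr": [fdr],
                "lfc": [lfc],
                "direction": ["NS"],
                "degenerate": [False],
            }
        )
        called = call_de(table)
        assert (len(called) == 1) == included
        if included:
            assert called.loc[0, "direction"] == direction

    def test_noiseless_recovery_is_exact(self):
        """With vanishing noise the pipeline calls exactly the planted DE genes."""
        cfg = SimConfig(
            n_subtypes=2,
            n_tumor_per_subtype=10,
            n_normal=10,
            n_mrna=60,
            n_lncrna=20,
            n_mirna=20,
            noise_sd=1e-9,
            n_couples=0,
            seed=3,
        )
        sim = simulate_cohort(cfg)
        for s in cfg.subtypes:
            planted = sim.truth.de[s]
            for cls, mat in sim.expression.items():
                called = call_de(wilcoxon_de(mat, sim.annotation, s))
                expected = {g: d for g, d in planted.items() if g in mat.data.index}
                assert dict(zip(called["gene"], called["direction"])) == expected

    def test_noiseless_lfc_equals_planted(self):
        cfg = SimConfig(
            n_subtypes=2,
            n_tumor_per_subtype=5,
            n_normal=5,
            n_mrna=40,
            n_lncrna=10,
            n_mirna=10,
            noise_sd=1e-9,
            de_lfc=1.0,
            n_couples=0,
            seed=4,
        )
        sim = simulate_cohort(cfg)
        s = cfg.subtypes[0]
        res = wilcoxon_de(sim.expression["mRNA"], sim.annotation, s)
        planted = sim.truth.de[s]
        lfc = dict(zip(res["gene"], res["lfc"]))
        for gene, direction in planted.items():
            if gene in lfc:
                assert lfc[gene] == pytest.approx(1.0 if direction == "up" else -1.0, abs=1e-6)


class TestConcordance:
    def _tables(self, layout):
        # layout: gene -> {subtype: direction}
        out = {}
        for s in {s for dirs in layout.values() for s in dirs}:
            rows = [
                {"gene": g, "direction": dirs[s]} for g, dirs in layout.items() if s in dirs
            ]
            out[s] = pd.DataFrame(rows, columns=["gene", "direction"])
        return out

    def test_sharing_and_flags(self):
        tables = self._tables(
            {
                "gA": {"s1": "up", "s2": "up", "s3": "up"},
                "gB": {"s1": "up", "s2": "up", "s3": "down"},
                "gC": {"s1": "down"},
            }
        )
        per_gene, summary = concordance(tables)
        row = per_gene.set_index("gene")
        assert row.loc["gA", "k"] == 3 and bool(row.loc["gA", "concordant"])
        assert row.loc["gB", "k"] == 3 and not bool(row.loc["gB", "concordant"])
        assert row.loc["gC", "k"] == 1
        k3 = summary.set_index("k").loc[3]
        assert k3["pct_concordant"] == pytest.approx(50.0)
        assert 1 not in summary["k"].tolist(), "singleton genes excluded from percentages"

    def test_needs_two_subtypes(self):
        with pytest.raises(ValueError):
            concordance({"s1": pd.DataFrame({"gene": [], "direction": []})})
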