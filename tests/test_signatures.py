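"""Module scoring, cell-cycle assignment, proportion statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecaxis

from conftest import make_ann, make_norm


class TestModuleScore:
    def test_self_controlled_set_scores_zero(self, small_pre):
        genes = list(small_pre.norm.gene_ids[:40])
        score = ecaxis.module_score(small_pre.norm, genes,
                                    control_genes=genes)
        np.testing.assert_array_equal(score, 0.0)

    def test_duplicate_genes_collapse(self, small_pre):
        genes = list(small_pre.norm.gene_ids[10:30])
        s1 = ecaxis.module_score(small_pre.norm, genes, seed=3)
        s2 = ecaxis.module_score(small_pre.norm, genes + genes[:7], seed=3)
        np.testing.assert_allclose(s1, s2)

    def test_deterministic_given_seed(self, small_pre):
        genes = list(small_pre.norm.gene_ids[5:45])
        s1 = ecaxis.module_score(small_pre.norm, genes, seed=11)
        s2 = ecaxis.module_score(small_pre.norm, genes, seed=11)
        np.testing.assert_array_equal(s1, s2)

    def test_absent_set_error(self, small_pre):
        with pytest.raises(ValueError, match="absent"):
            ecaxis.module_score(small_pre.norm, ["no_such_gene"])

    def test_random_sets_score_near_zero(self, null_run):
        """Random gene sets on null data (no planted condition effects)
        score near zero on average: the binned controls are unbiased."""
        matrix, _, _, norm = null_run
        rng = np.random.default_rng(0)
        main = [g for g in norm.gene_ids
                if not g.startswith(("mt-", "TdTomato"))]
        means = []
        for draw in range(20):
            genes = rng.choice(main, size=50, replace=False)
            means.append(ecaxis.module_score(norm, list(genes),
                                             seed=draw).mean())
        # unbiased: the Monte-Carlo average over draws is near zero, and
        # single draws stay within the spread set by within-bin variation
        assert abs(np.mean(means)) < 0.05
        assert np.abs(means).max() < 0.3

    def test_planted_up_module_scores_higher_in_case(self, small_pre,
                                                     small_sim):
        """A module of planted up-regulated genes scores higher in the
        case condition."""
        _, _, truth = small_sim
        gt = truth.gene_truth
        up = gt.loc[(gt["effect_class"] == "global")
                    & (gt["effect_delta"] > 0), "gene"]
        score = ecaxis.module_score(small_pre.norm, list(up), seed=0)
        cond = small_pre.ann.set_index("cell_id").loc[
            small_pre.norm.cell_ids, "condition"].to_numpy()
        p = stats.mannwhitneyu(score[cond == "PAH"],
                               score[cond == "Control"],
                               alternative="greater").pvalue
        assert p < 0.01


class TestCellCycle:
    def test_phase_rule(self):
        # build cells with controlled S / G2M expression
        genes = [f"s{i}" for i in range(5)] + [f"m{i}" for i in range(5)] + \
            [f"f{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        vals = rng.uniform(1.0, 1.2, (50, 3))
        vals[:10, 0] = 0.0           # cell 0: no cycling expression -> G1
        vals[:5, 1] += 2.0           # cell 1: S genes high
        vals[5:10, 2] += 2.0         # cell 2: G2M genes high
        norm = make_norm(vals, genes=genes)
        cc = ecaxis.assign_cell_cycle(norm, genes[:5], genes[5:10], seed=0)
        assert cc["cc_phase"][0] == "G1"
        assert cc["cc_phase"][1] == "S"
        assert cc["cc_phase"][2] == "G2M"

    def test_empty_set_error(self, small_pre):
        with pytest.raises(ValueError):
            ecaxis.assign_cell_cycle(small_pre.norm, [], ["Cdk1"])

    def test_proliferating_population_most_cycling(self, small_pre,
                                                   small_truth_ann):
        """The planted proliferating population has the largest non-G1
        fraction."""
        cc = ecaxis.assign_cell_cycle(small_pre.norm, ecaxis.S_GENES,
                                      ecaxis.G2M_GENES, seed=0)
        merged = cc.merge(small_truth_ann[["cell_id", "population"]],
                          on="cell_id")
        frac = (merged.assign(cycling=merged["cc_phase"] != "G1")
                .groupby("population")["cycling"].mean())
        assert frac.idxmax() == "Proliferating"

    def test_percentages_sum_to_100(self, small_pre, small_truth_ann):
        cc = ecaxis.assign_cell_cycle(small_pre.norm, ecaxis.S_GENES,
                                      ecaxis.G2M_GENES, seed=0)
        pct, _ = ecaxis.phase_percentages(cc, small_truth_ann)
        totals = pct[["G1", "S", "G2M"]].sum(axis=1)
        np.testing.assert_allclose(totals, 100.0, atol=1e-9)


def proportion_ann(ctrl_props, case_props, n=200):
    cells, samples, conds, pops = [], [], [], []
    for j, (cond, props) in enumerate(
            (("Control", ctrl_props), ("PAH", case_props))):
        for si, p in enumerate(props):
            s = f"{cond}{si + 1}"
            k = int(round(p * n))
            for i in range(n):
                cells.append(f"{s}_c{i}")
                samples.append(s)
                conds.append(cond)
                pops.append("CapillaryB" if i < k else "CapillaryA")
    return make_ann(cells, samples, conds, populations=pops)


class TestProportionTest:
    def test_identical_groups_p_one(self):
        ann = proportion_ann([0.10, 0.10, 0.10], [0.10, 0.10, 0.10])
        out = ecaxis.proportion_test(ann, "CapillaryB")
        assert out["p_value"] == 1.0

    def test_matches_independent_t_computation(self):
        ann = proportion_ann([0.10, 0.12, 0.11], [0.20, 0.22, 0.21])
        out = ecaxis.proportion_test(ann, "CapillaryB")
        ref = stats.ttest_ind(np.log10([0.10, 0.12, 0.11]),
                              np.log10([0.20, 0.22, 0.21]), equal_var=True)
        assert out["t_stat"] == pytest.approx(ref.statistic, abs=1e-10)
        assert out["p_value"] == pytest.approx(ref.pvalue, abs=1e-10)
        assert out["p_value"] < 0.001
        assert out["df"] == 4

    def test_sample_size_invariance(self):
        a = ecaxis.proportion_test(
            proportion_ann([0.10, 0.12, 0.11], [0.20, 0.22, 0.21], n=200),
            "CapillaryB")
        b = ecaxis.proportion_test(
            proportion_ann([0.10, 0.12, 0.11], [0.20, 0.22, 0.21], n=400),
            "CapillaryB")
        assert a["t_stat"] == pytest.approx(b["t_stat"], abs=1e-12)

    def test_symmetric_under_condition_swap(self):
        ann = proportion_ann([0.10, 0.12, 0.11], [0.20, 0.22, 0.21])
        a = ecaxis.proportion_test(ann, "CapillaryB",
                                   conditions=("Control", "PAH"))
        b = ecaxis.proportion_test(ann, "CapillaryB",
                                   conditions=("PAH", "Control"))
        assert a["p_value"] == pytest.approx(b["p_value"], abs=1e-12)
        assert a["t_stat"] == pytest.approx(-b["t_stat"], abs=1e-12)

    def test_single_sample_condition_error(self):
        ann = proportion_ann([0.1], [0.2, 0.2])
        with pytest.raises(ValueError, match="fewer than 2"):
            ecaxis.proportion_test(ann, "CapillaryB")
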