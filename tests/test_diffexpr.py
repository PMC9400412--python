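"""Rank-sum test, pooled and consensus DE, specificity, ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, rankdata

import ecaxis
from ecaxis.diffexpr import _ranksum_rows

from conftest import make_ann, make_norm


def brute_force_p(x, y):
    """Independent enumeration oracle: two-sided permutation p for U."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return hits / total


class TestWilcoxon:
    def test_fully_separated_groups(self):
        u, p = ecaxis.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_p_one(self):
        _, p = ecaxis.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            ecaxis.wilcoxon_rank_sum([], [1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1,
                    max_size=5),
           st.lists(st.floats(-5, 5, allow_nan=False), min_size=1,
                    max_size=5))
    def test_swap_antisymmetry(self, x, y):
        ux, px = ecaxis.wilcoxon_rank_sum(x, y)
        uy, py = ecaxis.wilcoxon_rank_sum(y, x)
        assert px == pytest.approx(py, abs=1e-12)
        assert ux + uy == pytest.approx(len(x) * len(y), abs=1e-9)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.poisson(3, rng.integers(8, 40))
            y = rng.poisson(4, rng.integers(8, 40))
            _, p = ecaxis.wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
            assert p == pytest.approx(ref, rel=1e-10)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2.0, size=(30, 25)).astype(float)
        u, p = _ranksum_rows(X, 10)
        for i in range(30):
            ui, pi = ecaxis.wilcoxon_rank_sum(X[i, :10], X[i, 10:])
            assert u[i] == pytest.approx(ui, abs=1e-9)
            assert p[i] == pytest.approx(pi, rel=1e-10)


def two_condition_norm(gene_rows, n_per_sample=30, seed=0):
    """Three control + three case samples with per-gene value generators.

    gene_rows: dict gene -> callable(sample_name, rng, n) -> values.
    """
    rng = np.random.default_rng(seed)
    samples = ["Control1", "Control2", "Control3", "PAH1", "PAH2", "PAH3"]
    cells, sample_ids, conds = [], [], []
    for s in samples:
        for i in range(n_per_sample):
            cells.append(f"{s}_c{i}")
            sample_ids.append(s)
            conds.append("PAH" if s.startswith("PAH") else "Control")
    vals = np.zeros((len(gene_rows), len(cells)))
    for gi, (g, gen) in enumerate(gene_rows.items()):
        col = 0
        for s in samples:
            vals[gi, col:col + n_per_sample] = gen(s, rng, n_per_sample)
            col += n_per_sample
    norm = make_norm(vals, genes=list(gene_rows), cells=cells)
    ann = make_ann(cells, sample_ids, conds, populations="CapillaryA")
    return norm, ann


def up_in(samples_up, hi=2.5, lo=0.5):
    def gen(s, rng, n):
        base = hi if s in samples_up else lo
        return rng.uniform(base, base + 0.5, n)
    return gen


class TestDEPopulation:
    def test_logfc_formula(self):
        # case expm1-mean 3, control expm1-mean 1 -> ln(4/2) = ln 2
        norm, ann = two_condition_norm({
            "g_target": lambda s, rng, n: np.full(
                n, np.log1p(3.0) if s.startswith("PAH") else np.log1p(1.0)),
            "g_flat": lambda s, rng, n: rng.uniform(1, 2, n),
        })
        tab = ecaxis.de_population(norm, ann, "CapillaryA", return_all=True)
        row = tab[tab["gene"] == "g_target"].iloc[0]
        assert row["log_fc"] == pytest.approx(math.log(2), rel=1e-9)
        assert row["direction"] == "up"

    def test_identical_values_not_tested(self):
        norm, ann = two_condition_norm({
            "g_same": lambda s, rng, n: np.full(n, 1.5),
            "g_up": up_in(["PAH1", "PAH2", "PAH3"]),
        })
        tab = ecaxis.de_population(norm, ann, "CapillaryA", return_all=True)
        assert "g_same" not in set(tab["gene"])
        assert "g_up" in set(tab["gene"])

    def test_min_pct_gate(self):
        def rare(s, rng, n):
            v = np.zeros(n)
            v[0] = 3.0 if s.startswith("PAH") else 0.0
            return v
        norm, ann = two_condition_norm({"g_rare": rare,
                                        "g_up": up_in(["PAH1", "PAH2",
                                                       "PAH3"])})
        tab = ecaxis.de_population(norm, ann, "CapillaryA", min_pct=0.1,
                                   return_all=True)
        assert "g_rare" not in set(tab["gene"])

    def test_absent_population_error(self):
        norm, ann = two_condition_norm({"g": up_in([])})
        with pytest.raises(ValueError, match="Lymphatic"):
            ecaxis.de_population(norm, ann, "Lymphatic")


class TestConsensusDE:
    CASE = ["PAH1", "PAH2", "PAH3"]
    CTRL = ["Control1", "Control2", "Control3"]

    def _norm(self):
        return two_condition_norm({
            "g_all9": up_in(["PAH1", "PAH2", "PAH3"]),
            "g_8of9": up_in(["PAH1", "PAH3"]),  # PAH2 looks like Control
            "g_null": up_in([]),
        })

    def test_all_pairs_up_is_consensus(self):
        norm, ann = self._norm()
        res = ecaxis.consensus_de(norm, ann, "CapillaryA", self.CASE,
                                  self.CTRL)
        assert "g_all9" in res.consensus_genes()
        assert "g_null" not in res.consensus_genes()

    def test_failing_one_pair_breaks_consensus(self):
        norm, ann = self._norm()
        res = ecaxis.consensus_de(norm, ann, "CapillaryA", self.CASE,
                                  self.CTRL)
        assert "g_8of9" not in res.consensus_genes()
        # but the pooled analysis may still report it
        pooled = ecaxis.de_population(norm, ann, "CapillaryA")
        assert "g_8of9" in set(pooled["gene"])

    def test_relaxed_majority_rule(self):
        norm, ann = self._norm()
        res = ecaxis.consensus_de(norm, ann, "CapillaryA", self.CASE,
                                  self.CTRL, min_frac_pairs=0.6)
        assert "g_8of9" in res.consensus_genes()

    def test_consensus_subset_of_pairwise_union(self):
        norm, ann = self._norm()
        res = ecaxis.consensus_de(norm, ann, "CapillaryA", self.CASE,
                                  self.CTRL)
        union = set()
        for cs in self.CASE:
            for ct in self.CTRL:
                t = ecaxis.de_population(norm, ann, "CapillaryA",
                                         case_samples=[cs],
                                         control_samples=[ct])
                union |= set(t["gene"])
        assert set(res.consensus_genes()) <= union

    def test_alpha_monotonicity(self):
        norm, ann = self._norm()
        loose = ecaxis.consensus_de(norm, ann, "CapillaryA", self.CASE,
                                    self.CTRL, alpha=0.05)
        strict = ecaxis.consensus_de(norm, ann, "CapillaryA", self.CASE,
                                     self.CTRL, alpha=1e-6)
        assert set(strict.consensus_genes()) <= set(loose.consensus_genes())

    def test_empty_pair_vetoes_consensus(self):
        norm, ann = self._norm()
        ann.loc[ann["sample_id"] == "PAH2", "qc_pass"] = False
        res = ecaxis.consensus_de(norm, ann, "CapillaryA", self.CASE,
                                  self.CTRL)
        assert res.consensus_genes() == []


class TestSpecificResponse:
    def _setup(self):
        pops = ["Artery", "CapillaryA", "CapillaryB"]
        cells, sample_ids, conds, pop_col = [], [], [], []
        for s, cond in (("Control1", "Control"), ("Control2", "Control"),
                        ("PAH1", "PAH"), ("PAH2", "PAH")):
            for p in pops:
                for i in range(10):
                    cells.append(f"{s}_{p}_{i}")
                    sample_ids.append(s)
                    conds.append(cond)
                    pop_col.append(p)
        rng = np.random.default_rng(0)
        pop_arr = np.array(pop_col)
        cond_arr = np.array(conds)
        genes = [f"spec{i}" for i in range(3)] + [f"glob{i}" for i in range(3)]
        vals = rng.uniform(0.5, 0.7, (6, len(cells)))
        for gi in range(3):  # up only in CapillaryB under PAH
            sel = (pop_arr == "CapillaryB") & (cond_arr == "PAH")
            vals[gi, sel] += 1.0
        for gi in range(3, 6):  # up everywhere under PAH
            vals[gi, cond_arr == "PAH"] += 1.0
        norm = make_norm(vals, genes=genes, cells=cells)
        ann = make_ann(cells, sample_ids, conds, populations=pop_col)
        return norm, ann, genes

    def test_target_specific_cluster_selected(self):
        norm, ann, genes = self._setup()
        sel = ecaxis.specific_response(genes, norm, ann, "CapillaryB",
                                       n_gene_clusters=2)
        assert set(sel) == {"spec0", "spec1", "spec2"}

    def test_uniform_response_not_selected(self):
        norm, ann, genes = self._setup()
        sel = ecaxis.specific_response(genes[3:] + genes[:1], norm, ann,
                                       "CapillaryB", n_gene_clusters=2)
        assert not set(sel) & {"glob0", "glob1", "glob2"}

    def test_needs_two_genes(self):
        norm, ann, genes = self._setup()
        with pytest.raises(ValueError):
            ecaxis.specific_response(genes[:1], norm, ann, "CapillaryB")


class TestEnrichORA:
    def test_closed_form_extreme(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"hit": universe[:5]}
        out = ecaxis.enrich_ora(universe[:5], universe, sets)
        expect = 1.0 / math.comb(20, 5)
        assert out["p_value"][0] == pytest.approx(expect, rel=1e-10)

    def test_disjoint_list_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = ecaxis.enrich_ora(universe[10:15], universe,
                                {"s": universe[:5]})
        assert out["p_value"][0] == 1.0

    def test_set_equals_universe_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = ecaxis.enrich_ora(universe[:3], universe, {"s": universe})
        assert out["p_value"][0] == pytest.approx(1.0)

    def test_relabelling_invariance(self):
        universe = [f"g{i}" for i in range(30)]
        lut = {g: f"x_{g}" for g in universe}
        sets = {"s": universe[:8]}
        p1 = ecaxis.enrich_ora(universe[:6], universe, sets)["p_value"][0]
        p2 = ecaxis.enrich_ora([lut[g] for g in universe[:6]],
                               [lut[g] for g in universe],
                               {"s": [lut[g] for g in sets["s"]]})["p_value"][0]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_list_outside_universe_error(self):
        with pytest.raises(ValueError):
            ecaxis.enrich_ora(["zzz"], ["g1"], {"s": ["g1"]})

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            ecaxis.enrich_ora([], [], {"s": ["g1"]})
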