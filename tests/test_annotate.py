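"""Clustering, reference typing, marker labelling, EndMT assessment."""

import numpy as np
import pandas as pd
import pytest

import ecaxis
from ecaxis.qc_norm import ReducedMatrix

from conftest import make_ann, make_norm


def blob_reduced(seed=0, n=200, d=5, sep=20.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, d))
    b = rng.normal(0, 1, (n, d))
    b[:, 0] += sep
    scores = np.vstack([a, b])
    cells = np.array([f"c{i}" for i in range(2 * n)], dtype=object)
    return ReducedMatrix(scores, np.zeros((d, 1)), np.array(["g"]), cells,
                         np.ones(d))


class TestClusterCells:
    def test_two_separated_blobs_give_two_clusters(self):
        red = blob_reduced()
        labels = ecaxis.cluster_cells(red, k_neighbors=15, seed=0)
        assert labels.max() == 1
        # each blob is one cluster
        assert len(set(labels[:200])) == 1
        assert len(set(labels[200:])) == 1

    def test_deterministic_given_seed(self):
        red = blob_reduced(seed=3)
        l1 = ecaxis.cluster_cells(red, 15, 0.8, seed=42)
        l2 = ecaxis.cluster_cells(red, 15, 0.8, seed=42)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_cells_error(self):
        red = blob_reduced(n=5)
        with pytest.raises(ValueError):
            ecaxis.cluster_cells(red, k_neighbors=50)


class TestReferenceAnnotation:
    def _refs(self):
        genes = np.array([f"g{i}" for i in range(30)], dtype=object)
        rng = np.random.default_rng(0)
        profiles = rng.uniform(0, 3, (3, 30))
        return ecaxis.ReferenceProfiles(genes, np.array(["A", "B", "C"],
                                        dtype=object), profiles)

    def test_self_match(self):
        refs = self._refs()
        norm = make_norm(refs.profiles.T, genes=list(refs.gene_ids),
                         cells=["cA", "cB", "cC"])
        labels = ecaxis.annotate_cells_by_reference(norm, refs)
        assert list(labels) == ["A", "B", "C"]

    def test_all_zero_cell_unassigned(self):
        refs = self._refs()
        vals = np.zeros((30, 1))
        norm = make_norm(vals, genes=list(refs.gene_ids))
        assert ecaxis.annotate_cells_by_reference(norm, refs)[0] == \
            "Unassigned"

    def test_monotone_transform_invariance(self):
        """Spearman typing depends only on ranks: any strictly increasing
        transform of a cell's profile leaves its label unchanged."""
        refs = self._refs()
        rng = np.random.default_rng(5)
        cell = rng.uniform(0, 3, 30)
        norm1 = make_norm(cell[:, None], genes=list(refs.gene_ids))
        norm2 = make_norm(np.exp(2 * cell[:, None]) - 0.9,
                          genes=list(refs.gene_ids))
        l1 = ecaxis.annotate_cells_by_reference(norm1, refs)
        l2 = ecaxis.annotate_cells_by_reference(norm2, refs)
        assert list(l1) == list(l2)

    def test_contaminant_recall_on_synthetic(self, small_sim, small_pre,
                                             small_truth_ann):
        """References built from an independently seeded simulation label
        planted contaminants as non-endothelial."""
        ref_params = ecaxis.SimulationParams(
            n_genes=700, cells_per_sample=250, n_global_de=60,
            n_popspecific_de=20, n_sectional_de=6, n_zonation_arterial=30,
            n_zonation_venous=30, n_zonation_junction=10,
            n_program_genes=15, seed=99)
        rm, rann, rtruth = ecaxis.simulate_experiment(ref_params)
        rnorm = ecaxis.normalize(rm)
        refs = ecaxis.build_reference_profiles(
            rnorm, rtruth.cell_truth["true_population"].to_numpy())
        labels = ecaxis.annotate_cells_by_reference(small_pre.norm, refs)
        truth = small_sim[2].cell_truth.set_index("cell_id")
        cont = truth.loc[small_pre.norm.cell_ids, "is_contaminant"].to_numpy()
        non_ec = ~np.isin(labels, list(ecaxis.EC_POPULATIONS))
        assert non_ec[cont].mean() >= 0.9


class TestLabelPopulations:
    def _panel(self):
        return ecaxis.MarkerPanel(
            markers={"CapillaryB": [("Car4", "up")],
                     "Artery": [("Cxcl12", "up")],
                     "Immune": [("Tyrobp", "up")]},
            pan_ec=["Cdh5"])

    def test_single_marker_cluster(self):
        genes = ["Car4", "Cxcl12", "Tyrobp", "Cdh5"]
        # cluster 0 expresses only Car4; cluster 1 only Cxcl12
        vals = np.array([[3, 3, 0, 0], [0, 0, 3, 3],
                         [0, 0, 0, 0], [2, 2, 2, 2]], dtype=float)
        norm = make_norm(vals, genes=genes)
        clusters = np.array([0, 0, 1, 1])
        assignment, per_cell = ecaxis.label_populations(
            clusters, norm, self._panel(),
            reporter_counts=np.array([5, 5, 5, 5]))
        assert assignment[0] == "CapillaryB"
        assert assignment[1] == "Artery"

    def test_tyrobp_zero_reporter_cluster_is_immune(self):
        genes = ["Car4", "Cxcl12", "Tyrobp", "Cdh5"]
        vals = np.array([[3, 3, 0, 0], [0, 0, 0, 0],
                         [0, 0, 4, 4], [2, 2, 0, 0]], dtype=float)
        norm = make_norm(vals, genes=genes)
        clusters = np.array([0, 0, 1, 1])
        assignment, _ = ecaxis.label_populations(
            clusters, norm, self._panel(),
            reporter_counts=np.array([8, 7, 0, 0]))
        assert assignment[1] == "Immune"

    def test_permutation_invariant_to_cluster_numbering(self):
        genes = ["Car4", "Cxcl12", "Tyrobp", "Cdh5"]
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 3, (4, 12))
        norm = make_norm(vals, genes=genes)
        clusters = np.repeat([0, 1, 2], 4)
        rep = rng.integers(0, 10, 12)
        a1, _ = ecaxis.label_populations(clusters, norm, self._panel(), rep)
        perm = {0: 2, 1: 0, 2: 1}
        clusters2 = np.array([perm[c] for c in clusters])
        a2, _ = ecaxis.label_populations(clusters2, norm, self._panel(), rep)
        for old, new in perm.items():
            assert a1[old] == a2[new]

    def test_empty_panel_error(self):
        norm = make_norm(np.ones((2, 4)))
        with pytest.raises(ValueError, match="empty"):
            ecaxis.label_populations(np.zeros(4, int), norm,
                                     ecaxis.MarkerPanel(markers={}))


class TestAssessEndMT:
    def _setup(self, acta2_row):
        genes = ["Acta2", "Col1a1", "Cdh5", "Pecam1"]
        vals = np.array([acta2_row, [0, 0, 0, 0],
                         [2, 2, 2, 2], [2, 2, 2, 2]], dtype=float)
        norm = make_norm(vals, genes=genes)
        ann = make_ann([f"c{i}" for i in range(4)],
                       ["s1", "s1", "s2", "s2"],
                       ["Control", "Control", "PAH", "PAH"],
                       reporter=[5, 5, 5, 5])
        return norm, ann

    def test_zero_case(self):
        norm, ann = self._setup([0, 0, 0, 0])
        out = ecaxis.assess_endmt(norm, ann)
        acta = out[out["gene"] == "Acta2"]
        assert (acta["fraction"] == 0).all()

    def test_saturation_case(self):
        norm, ann = self._setup([1, 1, 1, 1])
        out = ecaxis.assess_endmt(norm, ann)
        acta = out[out["gene"] == "Acta2"]
        assert (acta["fraction"] == 1).all()

    def test_no_reporter_positive_error(self):
        norm, ann = self._setup([0, 0, 0, 0])
        ann["reporter_count"] = 0
        with pytest.raises(ValueError, match="reporter"):
            ecaxis.assess_endmt(norm, ann)

    def test_synthetic_endothelium_below_one_percent(self, small_pre):
        """With no planted mesenchymal transition, under 1% of
        reporter-positive cells express the smooth-muscle gene."""
        ann = small_pre.ann[small_pre.ann["qc_pass"]]
        out = ecaxis.assess_endmt(small_pre.norm, ann)
        acta = out[out["gene"] == "Acta2"]
        pooled = acta["n_expressing"].sum() / acta["n_reporter_pos"].sum()
        assert pooled < 0.01
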