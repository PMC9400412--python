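"""Cell typing: graph clustering, reference correlation, marker panels, EndMT.

Clustering is shared-nearest-neighbor (Jaccard-weighted) community detection
in PCA space.  Reference-based typing is a single-pass Spearman argmax
against mean expression profiles of labelled populations -- a deliberately
simple surrogate for iterative reference classifiers; its acceptance surface
is recovery of known synthetic truth, not replication of any tool's
internals.  Population labels come from a canonical marker panel scored per
cluster; clusters that look more immune/mesenchymal than endothelial and
carry no lineage-reporter UMIs are called contaminants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .core_io import NormalizedMatrix, logger
from .cellcycle_genes import CELL_CYCLE_GENES
from .qc_norm import ReducedMatrix
from .synthetic import MARKER_GENES, PAN_EC_GENES


@dataclass
class MarkerPanel:
    """population -> [(gene symbol, direction)] plus a pan-EC gene list."""

    markers: dict = field(default_factory=dict)
    pan_ec: list = field(default_factory=list)

    @classmethod
    def default(cls) -> "MarkerPanel":
        markers = {pop: [(g, "up") for g in genes]
                   for pop, genes in MARKER_GENES.items()}
        markers["Proliferating"] = [(g, "up") for g in CELL_CYCLE_GENES]
        return cls(markers=markers, pan_ec=list(PAN_EC_GENES))

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "MarkerPanel":
        """Build from a TSV-backed table (population, gene, direction)."""
        markers: dict = {}
        pan = []
        for _, row in df.iterrows():
            direction = row.get("direction", "up") or "up"
            if row["population"] == "panEC":
                pan.append(row["gene"])
            else:
                markers.setdefault(row["population"], []).append(
                    (row["gene"], direction))
        return cls(markers=markers, pan_ec=pan)

    def to_table(self) -> pd.DataFrame:
        rows = [(pop, g, d) for pop, gs in self.markers.items()
                for g, d in gs]
        rows += [("panEC", g, "up") for g in self.pan_ec]
        return pd.DataFrame(rows, columns=["population", "gene", "direction"])


@dataclass
class ReferenceProfiles:
    """label -> mean log-normalized expression over a shared gene union."""

    gene_ids: np.ndarray
    labels: np.ndarray
    profiles: np.ndarray  # (n_labels, n_genes)

    def __post_init__(self) -> None:
        if len(np.unique(self.labels)) != len(self.labels):
            raise ValueError("reference labels must be unique")
        if not np.all(np.isfinite(self.profiles)):
            raise ValueError("reference profiles must be finite")


def build_reference_profiles(norm: NormalizedMatrix,
                             labels: np.ndarray | pd.Series,
                             genes: np.ndarray | None = None
                             ) -> ReferenceProfiles:
    """Mean expression per label over ``genes`` (default: all genes)."""
    labels = np.asarray(labels, dtype=object)
    if genes is None:
        genes = norm.gene_ids
    gidx = norm.gene_index()
    rows = np.array([gidx[g] for g in genes], dtype=int)
    uniq = np.array(sorted(set(labels)), dtype=object)
    profiles = np.zeros((len(uniq), len(rows)))
    for i, lab in enumerate(uniq):
        cols = np.where(labels == lab)[0]
        profiles[i] = np.asarray(
            norm.values[rows][:, cols].mean(axis=1)).ravel()
    return ReferenceProfiles(np.asarray(genes, dtype=object), uniq, profiles)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _snn_graph(scores: np.ndarray, k_neighbors: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(scores)
    knn = nn.kneighbors_graph(scores, mode="connectivity")  # includes self? no
    # include the cell itself in its neighbor set, as is conventional
    knn = knn.tolil()
    knn.setdiag(1)
    knn = knn.tocsr()
    shared = knn @ knn.T  # counts of shared neighbors
    shared = shared.tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    k = k_neighbors + 1
    jac = s / (2 * k - s)
    keep = jac > 0
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_cells(reduced: ReducedMatrix, k_neighbors: int = 20,
                  resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Leiden community detection on the SNN graph.

    Returns integer labels ordered by decreasing cluster size; deterministic
    given the seed.
    """
    n = reduced.scores.shape[0]
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if n <= k_neighbors:
        raise ValueError(f"{n} cells but k_neighbors={k_neighbors}")
    graph = _snn_graph(reduced.scores, k_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[x] for x in raw], dtype=int)
    logger.info("cluster_cells: %d cells -> %d clusters (k=%d, res=%.2f, "
                "seed=%d)", n, labels.max() + 1, k_neighbors, resolution, seed)
    return labels


# ---------------------------------------------------------------------------
# Reference-correlation typing
# ---------------------------------------------------------------------------


def annotate_cells_by_reference(norm: NormalizedMatrix,
                                refs: ReferenceProfiles) -> np.ndarray:
    """Per-cell Spearman-correlation argmax over reference profiles.

    Cells with zero variance over the gene union are labelled "Unassigned";
    ties break by label lexicographic order (labels are stored sorted).
    """
    if len(refs.labels) < 2:
        raise ValueError("need at least two reference labels")
    gidx = norm.gene_index()
    rows = np.array([gidx[g] for g in refs.gene_ids if g in gidx], dtype=int)
    present = np.array([g in gidx for g in refs.gene_ids])
    if rows.size == 0:
        raise ValueError("reference gene union absent from matrix")
    if not present.all():
        logger.warning("annotate_cells_by_reference: %d reference genes "
                       "absent from matrix", int((~present).sum()))
    X = np.asarray(norm.values[rows].todense()).T  # cells x genes
    R = np.asarray(refs.profiles[:, present])      # labels x genes

    cell_ranks = rankdata(X, axis=1)
    ref_ranks = rankdata(R, axis=1)
    cr = cell_ranks - cell_ranks.mean(axis=1, keepdims=True)
    rr = ref_ranks - ref_ranks.mean(axis=1, keepdims=True)
    cnorm = np.linalg.norm(cr, axis=1)
    rnorm = np.linalg.norm(rr, axis=1)
    degenerate = cnorm == 0
    cnorm[degenerate] = 1.0
    corr = (cr @ rr.T) / np.outer(cnorm, np.where(rnorm == 0, 1.0, rnorm))
    best = np.argmax(corr, axis=1)  # argmax takes first (lexicographic) tie
    labels = refs.labels[best].astype(object)
    labels[degenerate] = "Unassigned"
    return labels


# ---------------------------------------------------------------------------
# Marker-panel population labelling
# ---------------------------------------------------------------------------


def label_populations(clusters: np.ndarray, norm: NormalizedMatrix,
                      panel: MarkerPanel,
                      reporter_counts: np.ndarray | None = None
                      ) -> tuple[dict, np.ndarray]:
    """Assign a population to every cluster from marker scores.

    Marker score of a population for a cluster = mean (direction-signed)
    z-scored cluster-mean expression of its panel genes.  A cluster whose
    pan-EC score is below its Immune or Mesenchymal score and whose median
    reporter count is zero is called a contaminant (labelled Immune or
    Mesenchymal, whichever scores higher).

    Returns (cluster -> population map, per-cell population labels).
    """
    if not panel.markers:
        raise ValueError("empty marker panel")
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    gidx = norm.gene_index()
    panel_genes = sorted({g for gs in panel.markers.values() for g, _ in gs}
                         | set(panel.pan_ec))
    missing = [g for g in panel_genes if g not in gidx]
    if missing:
        logger.warning("marker panel genes absent from matrix: %s",
                       missing[:10])
    panel_genes = [g for g in panel_genes if g in gidx]
    rows = np.array([gidx[g] for g in panel_genes], dtype=int)
    means = np.zeros((len(uniq), len(rows)))
    for i, c in enumerate(uniq):
        cols = np.where(clusters == c)[0]
        means[i] = np.asarray(norm.values[rows][:, cols].mean(axis=1)).ravel()
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1) if len(uniq) > 1 else np.ones(len(rows))
    sd = np.where(sd > 0, sd, 1.0)
    z = (means - mu) / sd
    col_of = {g: j for j, g in enumerate(panel_genes)}

    def score(cluster_i: int, genes: list) -> float:
        vals = [z[cluster_i, col_of[g]] * (1.0 if d == "up" else -1.0)
                for g, d in genes if g in col_of]
        return float(np.mean(vals)) if vals else -np.inf

    assignment: dict = {}
    for i, c in enumerate(uniq):
        scores = {pop: score(i, genes)
                  for pop, genes in panel.markers.items()}
        pan_score = score(i, [(g, "up") for g in panel.pan_ec]) \
            if panel.pan_ec else np.inf
        best = max(sorted(scores), key=lambda p: scores[p])
        contaminant_scores = {p: scores[p] for p in ("Immune", "Mesenchymal")
                              if p in scores}
        if contaminant_scores and reporter_counts is not None:
            med_rep = float(np.median(
                np.asarray(reporter_counts)[clusters == c]))
            worst = max(sorted(contaminant_scores),
                        key=lambda p: contaminant_scores[p])
            if pan_score < contaminant_scores[worst] and med_rep == 0:
                best = worst
        assignment[int(c)] = best
    per_cell = np.array([assignment[int(c)] for c in clusters], dtype=object)
    logger.info("label_populations: %d clusters -> %s", len(uniq),
                {c: p for c, p in sorted(assignment.items())})
    return assignment, per_cell


# ---------------------------------------------------------------------------
# EndMT assessment
# ---------------------------------------------------------------------------


def assess_endmt(norm: NormalizedMatrix, ann: pd.DataFrame,
                 mesenchymal_genes: tuple = ("Acta2", "Col1a1"),
                 reporter_min: int = 1,
                 ec_marker_genes: tuple = tuple(PAN_EC_GENES)) -> pd.DataFrame:
    """Fraction of reporter-positive cells expressing each mesenchymal gene.

    Per sample and mesenchymal gene: the fraction of reporter-positive cells
    (reporter_count >= reporter_min) with a nonzero count for the gene, plus
    the mean pan-EC marker expression of the positive and negative subsets.
    """
    if reporter_min < 1:
        raise ValueError("reporter_min must be >= 1")
    gidx = norm.gene_index()
    # align the annotation with the matrix's cell order
    aligned = ann.set_index("cell_id").reindex(norm.cell_ids)
    if aligned["sample_id"].isna().any():
        aligned = aligned.dropna(subset=["sample_id"])
    pos_by_cell = {c: i for i, c in enumerate(norm.cell_ids)}
    pos_mask = aligned["reporter_count"].to_numpy() >= reporter_min
    if not pos_mask.any():
        raise ValueError("no reporter-positive cells")
    ec_rows = np.array([gidx[g] for g in ec_marker_genes if g in gidx],
                       dtype=int)
    ec_mean = (np.asarray(norm.values[ec_rows].mean(axis=0)).ravel()
               if ec_rows.size else np.zeros(norm.n_cells))
    records = []
    for sample, cells in aligned.groupby("sample_id").groups.items():
        cols = np.array([pos_by_cell[c] for c in cells], dtype=int)
        cols = cols[aligned.loc[cells, "reporter_count"].to_numpy()
                    >= reporter_min]
        for gene in mesenchymal_genes:
            if gene not in gidx:
                logger.warning("assess_endmt: gene %r absent", gene)
                continue
            vals = np.asarray(
                norm.values[gidx[gene]][:, cols].todense()).ravel()
            expressing = vals > 0
            records.append({
                "sample_id": sample,
                "gene": gene,
                "n_reporter_pos": len(cols),
                "n_expressing": int(expressing.sum()),
                "fraction": float(expressing.mean()) if len(cols) else 0.0,
                "ec_marker_mean_pos": float(ec_mean[cols[expressing]].mean())
                if expressing.any() else np.nan,
                "ec_marker_mean_neg": float(ec_mean[cols[~expressing]].mean())
                if (~expressing).any() else np.nan,
            })
    return pd.DataFrame(records)
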