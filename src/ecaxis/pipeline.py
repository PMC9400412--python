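"""End-to-end orchestration of the analysis stages.

Chains QC -> normalization -> HVG/PCA -> clustering -> population labelling
-> axis ordering with one configuration object, so the command-line
interface, tests and scripted analyses share a single code path.  Every
stage stays callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import MarkerPanel, cluster_cells, label_populations
from .core_io import (
    ExpressionMatrix,
    NormalizedMatrix,
    PipelineConfig,
    VASCULAR_POPULATIONS,
    logger,
)
from .qc_norm import (
    QCMetrics,
    ReducedMatrix,
    compute_qc,
    filter_cells,
    normalize,
    select_hvg_and_reduce,
)
from .zonation import AxisOrdering, fit_principal_curve


@dataclass
class PreprocessResult:
    metrics: QCMetrics
    ann: pd.DataFrame           # qc_pass filled; all input cells retained
    norm: NormalizedMatrix      # surviving cells only
    reduced: ReducedMatrix


def preprocess(matrix: ExpressionMatrix, ann: pd.DataFrame,
               cfg: PipelineConfig | None = None) -> PreprocessResult:
    """QC, filter, normalize and reduce; annotation rows are kept for all
    cells with ``qc_pass`` updated in place."""
    cfg = cfg or PipelineConfig()
    ann = ann.copy()
    metrics = compute_qc(matrix, cfg.mito_prefix,
                         sample_ids=ann["sample_id"].to_numpy(),
                         reporter_gene=cfg.reporter_gene)
    keep = filter_cells(metrics, cfg.nmads)
    rep = metrics.table.set_index("cell_id")["reporter_count"]
    ann["reporter_count"] = rep.loc[ann["cell_id"]].to_numpy()
    ann["qc_pass"] = ann["cell_id"].isin(keep)
    surv = matrix.subset_cells(keep)
    norm = normalize(surv, cfg.scale_constant)
    sample_of = ann.set_index("cell_id")["sample_id"]
    reduced = select_hvg_and_reduce(
        norm, cfg.n_hvg, cfg.n_components, cfg.seed,
        sample_ids=sample_of.loc[norm.cell_ids].to_numpy(),
        n_bins=cfg.n_mean_bins)
    return PreprocessResult(metrics, ann, norm, reduced)


def annotate_populations(pre: PreprocessResult,
                         cfg: PipelineConfig | None = None,
                         panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Cluster surviving cells and label populations from the marker panel.

    Returns the annotation table with cluster_id and population filled for
    QC-passing cells."""
    cfg = cfg or PipelineConfig()
    panel = panel or MarkerPanel.default()
    clusters = cluster_cells(pre.reduced, cfg.k_neighbors, cfg.resolution,
                             cfg.seed)
    rep = pre.ann.set_index("cell_id").loc[pre.norm.cell_ids,
                                           "reporter_count"].to_numpy()
    _, per_cell = label_populations(clusters, pre.norm, panel,
                                    reporter_counts=rep)
    ann = pre.ann.set_index("cell_id")
    ann.loc[pre.norm.cell_ids, "cluster_id"] = clusters
    ann.loc[pre.norm.cell_ids, "population"] = per_cell
    return ann.reset_index()


def fit_axis(pre: PreprocessResult, ann: pd.DataFrame,
             cfg: PipelineConfig | None = None) -> AxisOrdering:
    """Order Artery/CapillaryA/Vein cells along the arteriovenous axis and
    write their positions into ``ann.axis_position``."""
    cfg = cfg or PipelineConfig()
    pops = ann.set_index("cell_id").loc[pre.norm.cell_ids, "population"]
    mask = pops.isin(VASCULAR_POPULATIONS).to_numpy()
    if mask.sum() < 3:
        raise ValueError("too few vascular cells for axis fitting")
    cells = pre.norm.cell_ids[mask]
    reduced = pre.reduced.subset_cells(cells)
    anchor = pre.norm.subset_cells(cells).gene_values(cfg.anchor_gene)
    ordering = fit_principal_curve(
        reduced, pops.to_numpy()[mask], anchor, cfg.anchor_gene,
        cfg.curve_tol, cfg.curve_max_iter)
    ann = ann.set_index("cell_id")
    ann.loc[ordering.cell_ids, "axis_position"] = ordering.lam
    ann.reset_index(inplace=True)
    logger.info("fit_axis: %d cells ordered", len(ordering.cell_ids))
    return ordering
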