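"""Cell QC, log-normalization, HVG selection, scaling and PCA.

QC follows the outlier convention of the standard single-cell QC toolkits:
cells more than ``nmads`` median-absolute-deviations (with the 1.4826 normal
consistency constant) below the per-sample median of log1p(library size) or
log1p(genes detected), or above it for mitochondrial fraction, are flagged.

Batch handling is deliberately simple: each highly-variable gene is centered
per sample after z-scaling, which removes per-sample location shifts from
the reduced space.  Differential expression never uses these corrected
values (see the diffexpr module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .core_io import ExpressionMatrix, NormalizedMatrix, logger

MAD_CONSTANT = 1.4826  # normal-consistency scaling, as in the cited toolkit


@dataclass
class QCMetrics:
    """Per-cell QC metrics plus outlier verdict flags."""

    table: pd.DataFrame  # cell_id, sample_id, library_size, n_genes_detected,
    #                      mito_fraction, reporter_count,
    #                      low_library, low_genes, high_mito

    @property
    def fail_mask(self) -> np.ndarray:
        t = self.table
        return (t["low_library"] | t["low_genes"] | t["high_mito"]).to_numpy()


def compute_qc(matrix: ExpressionMatrix, mito_prefix: str = "mt-",
               sample_ids: pd.Series | np.ndarray | None = None,
               reporter_gene: str = "TdTomato") -> QCMetrics:
    """Compute per-cell library size, detected genes, mito fraction, reporter.

    No cells are removed here; verdict flags are filled by
    :func:`filter_cells`.
    """
    if not mito_prefix:
        raise ValueError("mito_prefix must be non-empty")
    counts = matrix.counts.tocsc()
    lib = np.asarray(counts.sum(axis=0)).ravel()
    ngenes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_rows = np.array([g.startswith(mito_prefix) for g in matrix.gene_ids])
    if not mito_rows.any():
        logger.warning("no gene matches mito prefix %r; mito_fraction = 0",
                       mito_prefix)
        mito = np.zeros_like(lib, dtype=float)
    else:
        mito = np.asarray(counts[mito_rows].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
    gidx = matrix.gene_index()
    reporter = (
        np.asarray(counts[gidx[reporter_gene]].todense()).ravel().astype(int)
        if reporter_gene in gidx
        else np.zeros(matrix.n_cells, dtype=int)
    )
    table = pd.DataFrame({
        "cell_id": matrix.cell_ids,
        "sample_id": (np.asarray(sample_ids, dtype=object)
                      if sample_ids is not None
                      else np.repeat("all", matrix.n_cells)),
        "library_size": lib,
        "n_genes_detected": ngenes,
        "mito_fraction": mito_frac,
        "reporter_count": reporter,
    })
    for col in ("low_library", "low_genes", "high_mito"):
        table[col] = False
    logger.info("compute_qc: %d cells, median library %.0f, "
                "median mito fraction %.3f",
                matrix.n_cells, np.median(lib), np.median(mito_frac))
    return QCMetrics(table)


def _mad_outlier(values: np.ndarray, nmads: float, side: str) -> np.ndarray:
    med = np.median(values)
    mad = MAD_CONSTANT * np.median(np.abs(values - med))
    if side == "lower":
        return (med - values) > nmads * mad
    return (values - med) > nmads * mad


def filter_cells(metrics: QCMetrics, nmads: float = 3.0) -> np.ndarray:
    """Flag per-sample MAD outliers; return the surviving cell ids.

    The rule is iterated to a fixed point (medians and MADs re-estimated on
    the survivors until no further cell is flagged), which makes filtering
    idempotent.  A zero MAD (identical cells) flags nothing: the comparison
    is strict.  Mutates the verdict flags in ``metrics.table``.
    """
    if nmads <= 0:
        raise ValueError("nmads must be positive")
    t = metrics.table
    for col in ("low_library", "low_genes", "high_mito"):
        t[col] = False
    loglib = np.log1p(t["library_size"].to_numpy(float))
    loggenes = np.log1p(t["n_genes_detected"].to_numpy(float))
    mito = t["mito_fraction"].to_numpy(float)
    samples = t["sample_id"].to_numpy()
    fail = np.zeros(len(t), dtype=bool)
    flags = {k: np.zeros(len(t), dtype=bool)
             for k in ("low_library", "low_genes", "high_mito")}
    for _ in range(100):
        new = False
        for s in pd.unique(samples):
            live = (samples == s) & ~fail
            if not live.any():
                continue
            for key, vals, side in (("low_library", loglib, "lower"),
                                    ("low_genes", loggenes, "lower"),
                                    ("high_mito", mito, "upper")):
                out = _mad_outlier(vals[live], nmads, side)
                if out.any():
                    idx = np.where(live)[0][out]
                    flags[key][idx] = True
                    fail[idx] = True
                    new = True
        if not new:
            break
    for k, v in flags.items():
        t[k] = v
    keep = ~fail
    if not keep.any():
        raise ValueError("QC removed every cell; thresholds look misconfigured")
    logger.info("filter_cells: %d of %d cells pass (nmads=%.1f)",
                int(keep.sum()), len(keep), nmads)
    return t.loc[keep, "cell_id"].to_numpy(dtype=object)


def normalize(matrix: ExpressionMatrix,
              scale_constant: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize and log-transform.

    value = ln(1 + count * scale_constant / library_size).
    """
    lib = matrix.library_sizes()
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero library size for cell(s) {matrix.cell_ids[zero[:5]]}")
    scaled = matrix.counts.tocsc().astype(float)
    scaled = scaled.multiply(sp.csr_matrix(scale_constant / lib)).tocsr()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(scaled, matrix.gene_ids, matrix.cell_ids,
                            lib / scale_constant, scale_constant)


@dataclass
class ReducedMatrix:
    """Cell x component scores with loadings and the HVG identifiers used."""

    scores: np.ndarray      # (n_cells, n_components)
    loadings: np.ndarray    # (n_components, n_hvg)
    hvg_ids: np.ndarray
    cell_ids: np.ndarray
    explained_variance: np.ndarray

    def subset_cells(self, cell_ids) -> "ReducedMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return ReducedMatrix(self.scores[idx], self.loadings, self.hvg_ids,
                             self.cell_ids[idx], self.explained_variance)


def highly_variable_genes(norm: NormalizedMatrix, n_hvg: int = 2000,
                          n_bins: int = 20) -> np.ndarray:
    """Top genes by within-mean-bin z-score of log dispersion.

    Dispersion is variance/mean of expm1(values); constant or unexpressed
    genes are excluded.  Ties break by gene id (lexicographic) for
    determinism.
    """
    vals = norm.values.copy()
    vals.data = np.expm1(vals.data)
    n = norm.n_cells
    mean = np.asarray(vals.sum(axis=1)).ravel() / n
    sq = vals.copy()
    sq.data = sq.data ** 2
    var = np.asarray(sq.sum(axis=1)).ravel() / n - mean ** 2
    var = np.maximum(var * n / max(n - 1, 1), 0.0)
    expressed = (mean > 0) & (var > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(expressed, var / np.maximum(mean, 1e-300), np.nan)
    logdisp = np.log(np.where(disp > 0, disp, np.nan))

    order = pd.DataFrame({
        "gene": norm.gene_ids,
        "mean": mean,
        "logdisp": logdisp,
        "expressed": expressed,
    })
    usable = order[order["expressed"]].copy()
    if len(usable) == 0:
        raise ValueError("no expressed genes")
    n_hvg_eff = min(n_hvg, len(usable))
    if n_hvg_eff < n_hvg:
        logger.warning("only %d expressed genes for n_hvg=%d; using all",
                       len(usable), n_hvg)
    usable["bin"] = pd.qcut(usable["mean"].rank(method="first"),
                            q=min(n_bins, len(usable)), labels=False)
    z = usable.groupby("bin")["logdisp"].transform(
        lambda x: (x - x.mean()) / (x.std(ddof=1) if len(x) > 1 and
                                    x.std(ddof=1) > 0 else 1.0))
    usable["z"] = z.fillna(0.0)
    usable = usable.sort_values(["z", "gene"], ascending=[False, True])
    return usable["gene"].to_numpy(dtype=object)[:n_hvg_eff]


def select_hvg_and_reduce(norm: NormalizedMatrix, n_hvg: int = 2000,
                          n_components: int = 30, seed: int = 0,
                          sample_ids: np.ndarray | None = None,
                          n_bins: int = 20) -> ReducedMatrix:
    """HVG selection, per-gene z-scaling (clipped at +/-10), optional
    per-sample centering (the batch correction), then PCA."""
    hvg = highly_variable_genes(norm, n_hvg, n_bins)
    gidx = norm.gene_index()
    rows = np.array([gidx[g] for g in hvg], dtype=int)
    X = np.asarray(norm.values[rows].todense(), dtype=np.float64).T  # cells x hvg
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -10.0, 10.0)
    if sample_ids is not None:
        sample_ids = np.asarray(sample_ids)
        for s in pd.unique(sample_ids):
            mask = sample_ids == s
            X[mask] -= X[mask].mean(axis=0)
    n_components = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="randomized",
              random_state=seed)
    scores = pca.fit_transform(X)
    # deterministic sign convention: largest-|loading| entry positive
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    logger.info("select_hvg_and_reduce: %d HVGs, %d components, seed=%d",
                len(hvg), n_components, seed)
    return ReducedMatrix(scores, pca.components_, hvg, norm.cell_ids.copy(),
                         pca.explained_variance_)
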