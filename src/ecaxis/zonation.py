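"""Arteriovenous axis ordering and zonation-resolved differential expression.

Cells of the Artery -> CapillaryA -> Vein continuum are ordered by a
Hastie-Stuetzle principal curve in PCA space, initialized on the piecewise
linear path through the three population centroids: iterate {project cells
onto the curve -> smooth each coordinate against arc length with a cubic
smoothing spline (penalty by generalized cross-validation) ->
re-parameterize by cumulative chord length} until the mean per-cell shift in
normalized position falls below tolerance.  Positions lambda are min-max
normalized to [0, 1] and oriented so the anchor marker (an arterial gene by
default) is high at lambda = 0.

The axis is then cut into equal-width sections and the replicate-consensus
DE procedure is run per section, yielding a gene x section log-fold-change
profile of position-dependent condition effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import gaussian_kde

from .core_io import NormalizedMatrix, VASCULAR_POPULATIONS, logger
from .diffexpr import ConsensusDEResult, consensus_de
from .qc_norm import ReducedMatrix


@dataclass
class AxisOrdering:
    """Per-cell arc-length position on the fitted arteriovenous curve."""

    cell_ids: np.ndarray
    lam: np.ndarray             # normalized position in [0, 1]
    curve: np.ndarray           # ordered control points in component space
    orientation_anchor: str
    iterations: int
    final_shift: float
    converged: bool

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "lambda": self.lam})


def _project_to_polyline(X: np.ndarray, pts: np.ndarray):
    """Project points onto a polyline; returns (arc_length, distance)."""
    seg = np.diff(pts, axis=0)                     # (K, d)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 0
    seg, starts, seg_len = seg[keep], pts[:-1][keep], seg_len[keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d2 = np.full(X.shape[0], np.inf)
    best_s = np.zeros(X.shape[0])
    for k in range(len(seg)):
        diff = X - starts[k]
        t = np.clip(diff @ seg[k] / (seg_len[k] ** 2), 0.0, 1.0)
        proj = starts[k] + t[:, None] * seg[k]
        d2 = ((X - proj) ** 2).sum(axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_s[closer] = cum[k] + t[closer] * seg_len[k]
    return best_s, np.sqrt(best_d2)


def _smooth_curve(s: np.ndarray, X: np.ndarray, n_grid: int) -> np.ndarray:
    """Smooth each coordinate against arc length; evaluate on a grid.

    Projected positions are first averaged within equal-count arc-length
    bins (a scatterplot smoother pre-step); a cubic smoothing spline with
    GCV-chosen penalty runs through the bin means.  Falls back to linear
    interpolation when the spline problem is degenerate.
    """
    order = np.argsort(s, kind="stable")
    s_sorted, X_sorted = s[order], X[order]
    n_bins = min(n_grid, max(4, len(s) // 20))
    edges = np.linspace(0, len(s), n_bins + 1).astype(int)
    sm = np.array([s_sorted[a:b].mean() for a, b in zip(edges, edges[1:])
                   if b > a])
    Xm = np.vstack([X_sorted[a:b].mean(axis=0)
                    for a, b in zip(edges, edges[1:]) if b > a])
    xu, inv = np.unique(sm, return_inverse=True)
    grid = np.linspace(s.min(), s.max(), n_grid)
    new = np.empty((n_grid, X.shape[1]))
    inside = np.clip(grid, xu[0], xu[-1])
    for j in range(X.shape[1]):
        y_avg = np.bincount(inv, weights=Xm[:, j]) / np.bincount(inv)
        if len(xu) >= 10:
            try:
                spl = make_smoothing_spline(xu, y_avg)  # GCV-chosen penalty
                y = spl(inside)
                # linear extension beyond the bin-mean range: cubic
                # extrapolation is unstable at the ends
                d = spl.derivative()
                lo = grid < xu[0]
                hi = grid > xu[-1]
                y[lo] = spl(xu[0]) + (grid[lo] - xu[0]) * d(xu[0])
                y[hi] = spl(xu[-1]) + (grid[hi] - xu[-1]) * d(xu[-1])
                new[:, j] = y
                continue
            except Exception:  # degenerate abscissa; use the bin means
                pass
        new[:, j] = np.interp(grid, xu, y_avg)
    return new


def _normalize(s: np.ndarray) -> np.ndarray:
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise ValueError("degenerate curve: all positions identical")
    return (s - lo) / (hi - lo)


def fit_principal_curve(reduced: ReducedMatrix, populations: np.ndarray,
                        anchor_values: np.ndarray,
                        anchor_gene: str = "Cxcl12",
                        tol: float = 1e-3, max_iter: int = 50,
                        n_grid: int = 100) -> AxisOrdering:
    """Fit the arteriovenous principal curve and return per-cell positions.

    ``populations`` and ``anchor_values`` (the anchor gene's expression) are
    aligned with ``reduced.cell_ids``.  Returns the last iterate with a
    warning when the mean shift has not fallen below ``tol`` by
    ``max_iter``.
    """
    populations = np.asarray(populations, dtype=object)
    present = [p for p in VASCULAR_POPULATIONS if (populations == p).any()]
    if len(present) < 3:
        raise ValueError(
            f"need cells from all of {VASCULAR_POPULATIONS}, have {present}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    X = np.asarray(reduced.scores, dtype=float)
    centroids = np.vstack([
        X[populations == p].mean(axis=0) for p in VASCULAR_POPULATIONS])
    # extend the end segments so cells beyond the terminal centroids do not
    # clamp onto the endpoints
    d0 = centroids[0] - centroids[1]
    d0 /= np.linalg.norm(d0)
    ext0 = max(float(((X - centroids[0]) @ d0).max()), 0.0)
    d2 = centroids[2] - centroids[1]
    d2 /= np.linalg.norm(d2)
    ext2 = max(float(((X - centroids[2]) @ d2).max()), 0.0)
    path = np.vstack([centroids[0] + ext0 * d0, centroids,
                      centroids[2] + ext2 * d2])
    # subdivide so the first projection has resolution
    curve = np.vstack([
        np.linspace(path[i], path[i + 1], n_grid // 4, endpoint=False)
        for i in range(len(path) - 1)
    ] + [path[-1:]])

    s, _ = _project_to_polyline(X, curve)
    lam = _normalize(s)
    iterations = 0
    shift = np.inf
    best_shift = np.inf
    stall = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        curve = _smooth_curve(s, X, n_grid)
        s, _ = _project_to_polyline(X, curve)
        new_lam = _normalize(s)
        # positions may flip globally between iterates; compare up to flip
        shift = min(np.mean(np.abs(new_lam - lam)),
                    np.mean(np.abs((1 - new_lam) - lam)))
        lam = new_lam
        if shift < tol:
            converged = True
            break
        # stall detection: the iteration oscillates around a fixed point
        # with amplitude above tol -- stop rather than cycle to max_iter
        if shift < 0.9 * best_shift:
            best_shift = shift
            stall = 0
        else:
            stall += 1
            if stall >= 3:
                break
    if not converged:
        logger.warning("fit_principal_curve: stopped after %d iterations "
                       "without reaching tol (mean shift %.2e)", iterations,
                       shift)

    low = anchor_values[lam < 0.2]
    high = anchor_values[lam > 0.8]
    if low.size and high.size and low.mean() < high.mean():
        lam = 1.0 - lam
        curve = curve[::-1].copy()
    logger.info("fit_principal_curve: %d cells, %d iterations, shift %.2e",
                len(lam), iterations, shift)
    return AxisOrdering(reduced.cell_ids.copy(), lam, curve, anchor_gene,
                        iterations, float(shift), converged)


def axis_density(ordering: AxisOrdering, ann: pd.DataFrame,
                 bandwidth="silverman", n_grid: int = 512) -> pd.DataFrame:
    """Per-condition Gaussian kernel density of lambda, reflected at 0 and 1.

    Each returned curve integrates to 1 over [0, 1] (trapezoid rule).
    """
    lam = pd.Series(ordering.lam, index=ordering.cell_ids)
    cond = ann.set_index("cell_id").loc[ordering.cell_ids, "condition"]
    if np.ptp(ordering.lam) == 0:
        raise ValueError("degenerate positions: all lambda equal")
    grid = np.linspace(0.0, 1.0, n_grid)
    out = {"lambda": grid}
    for c in pd.unique(cond):
        vals = lam[cond.to_numpy() == c].to_numpy()
        if len(vals) < 10:
            raise ValueError(f"condition {c!r} has fewer than 10 cells")
        kde = gaussian_kde(vals, bw_method=bandwidth)
        dens = kde(grid) + kde(-grid) + kde(2.0 - grid)  # boundary reflection
        dens /= np.trapezoid(dens, grid)
        out[c] = dens
    return pd.DataFrame(out)


def assign_sections(lam: np.ndarray, n_sections: int = 10,
                    equal_count: bool = False) -> np.ndarray:
    """1-based section index per cell; equal-width bins on [0, 1] by default."""
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    lam = np.asarray(lam, dtype=float)
    if equal_count:
        edges = np.quantile(lam, np.linspace(0, 1, n_sections + 1))
        edges[0], edges[-1] = 0.0, 1.0
    else:
        edges = np.linspace(0.0, 1.0, n_sections + 1)
    idx = np.digitize(lam, edges[1:-1], right=False) + 1
    return idx


@dataclass
class SectionDEProfile:
    """Gene x section consensus log-fold-change profile."""

    logfc: pd.DataFrame       # genes x sections; 0 where not consensus
    consensus: pd.DataFrame   # bool, same shape
    tested: pd.Series         # bool per section
    n_degs: pd.Series         # consensus DEG count per section
    results: dict             # section -> ConsensusDEResult

    def peak_section(self, gene: str) -> int | None:
        """Section (1-based) of the largest |consensus logFC|; None if the
        gene never reaches consensus."""
        row = self.logfc.loc[gene].to_numpy(dtype=float)
        if not np.any(row != 0):
            return None
        return int(np.nanargmax(np.abs(row)) + 1)


def sectioned_consensus_de(norm: NormalizedMatrix, ann: pd.DataFrame,
                           ordering: AxisOrdering,
                           case_samples: list, control_samples: list,
                           n_sections: int = 10, min_cells: int = 20,
                           logfc_threshold: float = 0.25,
                           min_pct: float = 0.1, alpha: float = 0.05,
                           adjust: str = "bonferroni",
                           equal_count: bool = False) -> SectionDEProfile:
    """Replicate-consensus DE within each arteriovenous section.

    A section is untested (reported missing, not zero) when any sample
    contributes fewer than ``min_cells`` cells to it.
    """
    sections = assign_sections(ordering.lam, n_sections, equal_count)
    sec_of = pd.Series(sections, index=ordering.cell_ids)
    on_axis = ann["cell_id"].isin(sec_of.index).to_numpy()
    cell_section = np.zeros(len(ann), dtype=int)
    cell_section[on_axis] = sec_of.loc[
        ann.loc[on_axis, "cell_id"]].to_numpy()

    samples = list(case_samples) + list(control_samples)
    genes = pd.Index(norm.gene_ids, name="gene")
    cols = [f"section_{i}" for i in range(1, n_sections + 1)]
    logfc = pd.DataFrame(0.0, index=genes, columns=cols)
    consensus = pd.DataFrame(False, index=genes, columns=cols)
    tested = pd.Series(False, index=cols)
    n_degs = pd.Series(0, index=cols)
    results: dict[int, ConsensusDEResult] = {}
    for i in range(1, n_sections + 1):
        mask = cell_section == i
        per_sample = ann.loc[mask & ann["qc_pass"].to_numpy(), "sample_id"] \
            .value_counts()
        short = [s for s in samples if per_sample.get(s, 0) < min_cells]
        col = f"section_{i}"
        if short:
            logger.info("section %d untested: <%d cells in sample(s) %s",
                        i, min_cells, short)
            logfc[col] = np.nan
            continue
        res = consensus_de(norm, ann, None, case_samples, control_samples,
                           logfc_threshold, min_pct, alpha, adjust,
                           cell_mask=mask)
        results[i] = res
        tested[col] = True
        consensus[col] = res.consensus.to_numpy()
        vals = np.where(res.consensus.to_numpy(),
                        res.consensus_logfc.to_numpy(), 0.0)
        logfc[col] = vals
        n_degs[col] = int(res.consensus.sum())
    logger.info("sectioned_consensus_de: %d/%d sections tested, DEGs per "
                "section %s", int(tested.sum()), n_sections,
                n_degs.to_dict())
    return SectionDEProfile(logfc, consensus, tested, n_degs, results)
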