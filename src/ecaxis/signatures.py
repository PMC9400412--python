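"""Gene-module signature scores, cell-cycle phases, proportion statistics.

Module scores follow the binned-control construction standard in single-cell
analysis: genes are ranked by mean expression and cut into ``n_bins``
equal-size bins; for each set gene, ``n_ctrl`` control genes are sampled
without replacement from its bin, and the score is the per-cell mean of the
set genes minus the mean of the pooled controls.  The score of a set whose
control pool is forced equal to the set itself is exactly zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import NormalizedMatrix, logger


def module_score(norm: NormalizedMatrix, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0,
                 control_genes=None) -> np.ndarray:
    """Per-cell signature score of a gene set against expression-matched
    controls.

    ``control_genes`` overrides control sampling with an explicit pool
    (used e.g. for self-control identity checks).  Deterministic given the
    seed; duplicate set genes are collapsed.
    """
    gidx = norm.gene_index()
    genes = sorted({g for g in gene_set})
    present = [g for g in genes if g in gidx]
    missing = [g for g in genes if g not in gidx]
    if not present:
        raise ValueError(f"gene set entirely absent from matrix: {missing}")
    if missing:
        logger.warning("module_score: %d set genes absent: %s",
                       len(missing), missing[:10])
    rows = np.array([gidx[g] for g in present], dtype=int)
    set_mean = np.asarray(norm.values[rows].mean(axis=0)).ravel()

    if control_genes is not None:
        ctrl_rows = np.array([gidx[g] for g in sorted(set(control_genes))
                              if g in gidx], dtype=int)
    else:
        rng = np.random.default_rng(seed)
        gene_mean = np.asarray(norm.values.mean(axis=1)).ravel()
        order = np.argsort(gene_mean, kind="stable")
        n_bins_eff = min(n_bins, norm.n_genes)
        bins = np.array_split(order, n_bins_eff)
        bin_of = np.empty(norm.n_genes, dtype=int)
        for b, members in enumerate(bins):
            bin_of[members] = b
        ctrl: set[int] = set()
        for r in rows:
            pool = bins[bin_of[r]]
            take = min(n_ctrl, len(pool))
            ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl_rows = np.array(sorted(ctrl), dtype=int)
    ctrl_mean = np.asarray(norm.values[ctrl_rows].mean(axis=0)).ravel()
    return set_mean - ctrl_mean


def assign_cell_cycle(norm: NormalizedMatrix, s_genes, g2m_genes,
                      seed: int = 0, n_bins: int = 24,
                      n_ctrl: int = 100) -> pd.DataFrame:
    """Assign per-cell cycle phase from S and G2M module scores.

    Phase is G1 when both scores are <= 0, otherwise the argmax phase.
    """
    if not list(s_genes) or not list(g2m_genes):
        raise ValueError("both phase gene sets must be non-empty")
    s_score = module_score(norm, s_genes, n_bins, n_ctrl, seed)
    g2m_score = module_score(norm, g2m_genes, n_bins, n_ctrl, seed + 1)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0), "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame({
        "cell_id": norm.cell_ids,
        "s_score": s_score,
        "g2m_score": g2m_score,
        "cc_phase": phase,
    })


def phase_percentages(cc: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-sample phase percentages plus a per-phase condition t-test."""
    merged = cc.merge(ann[["cell_id", "sample_id", "condition"]], on="cell_id")
    counts = (merged.groupby(["sample_id", "condition", "cc_phase"])
              .size().unstack(fill_value=0))
    for ph in ("G1", "S", "G2M"):
        if ph not in counts:
            counts[ph] = 0
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct = pct.reset_index()
    rows = []
    for ph in ("G1", "S", "G2M"):
        a = pct.loc[pct["condition"] == "Control", ph].to_numpy(float)
        b = pct.loc[pct["condition"] == "PAH", ph].to_numpy(float)
        if len(a) >= 2 and len(b) >= 2:
            t, p = _pooled_t(a, b)
        else:
            t, p = np.nan, np.nan
        rows.append({"cc_phase": ph, "t_stat": t, "p_value": p})
    return pct, pd.DataFrame(rows)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Student's two-sample t with pooled variance; zero-variance guard."""
    na, nb = len(a), len(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            logger.info("zero-variance t-test with equal means; p = 1")
            return 0.0, 1.0
        logger.warning("zero-variance t-test with unequal means; p = 0")
        return math_inf_sign(a.mean() - b.mean()), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(min(1.0, p))


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


def proportion_test(ann: pd.DataFrame, population: str,
                    conditions: tuple = ("Control", "PAH"),
                    ec_only: bool = True) -> dict:
    """Unpaired t-test on log10 per-sample population proportions.

    Proportions are computed among QC-passing cells (endothelial populations
    only when ``ec_only``); a sample without the population gets the floor
    1/(cells+1), with a warning."""
    from .core_io import EC_POPULATIONS

    t = ann[ann["qc_pass"]]
    if ec_only:
        t = t[t["population"].isin(EC_POPULATIONS)]
    props: dict[str, list] = {c: [] for c in conditions}
    samples: dict[str, list] = {c: [] for c in conditions}
    for (sample, cond), sub in t.groupby(["sample_id", "condition"]):
        if cond not in props:
            continue
        n = len(sub)
        k = int((sub["population"] == population).sum())
        if k == 0:
            logger.warning("proportion_test: population %r absent from "
                           "sample %s; using floor 1/(n+1)", population,
                           sample)
            prop = 1.0 / (n + 1)
        else:
            prop = k / n
        props[cond].append(prop)
        samples[cond].append(sample)
    for cond in conditions:
        if len(props[cond]) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
    a = np.log10(props[conditions[0]])
    b = np.log10(props[conditions[1]])
    t_stat, p = _pooled_t(np.asarray(a), np.asarray(b))
    return {
        "population": population,
        "proportions": {c: dict(zip(samples[c], props[c]))
                        for c in conditions},
        "t_stat": t_stat,
        "p_value": p,
        "df": len(a) + len(b) - 2,
    }
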