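"""Differential expression: pooled, replicate-consensus, specificity, ORA.

The test statistic is the two-sample Wilcoxon rank-sum (Mann-Whitney U) on
midranks, with tie-corrected normal approximation and continuity correction;
small tie-free problems (n1+n2 <= 12) use exact enumeration of the
permutation distribution.  Fold changes are natural-log ratios of
expm1-means with a pseudocount of 1:

    log_fc = ln[(mean(expm1 case) + 1) / (mean(expm1 control) + 1)]

so a threshold of 0.25 means what it does in the standard single-cell
toolkits.  Per-test multiplicity adjustment is Bonferroni over tested genes
(config-switchable to BH); BH is used for over-representation analysis.

The "stringent" consensus analysis runs the pooled test for every
(case sample x control sample) pair and calls a gene only if every pair is
individually significant, above the fold-change gate, and consistent in
sign -- the guard against replicate-driven artifacts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom, norm as normal, rankdata
from statsmodels.stats.multitest import multipletests

from .core_io import NormalizedMatrix, logger

__all__ = [
    "wilcoxon_rank_sum",
    "de_population",
    "consensus_de",
    "ConsensusDEResult",
    "specific_response",
    "enrich_ora",
]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumeration of all C(n1+n2, n1) labelings."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    mu = n1 * n2 / 2.0
    d_obs = abs(u_obs - mu)
    count = 0
    total = 0
    base = n1 * (n1 + 1) / 2.0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - base
        count += abs(u - mu) >= d_obs - 1e-12
        total += 1
    return count / total


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample rank-sum test; returns (U for x, two-sided p).

    Exact enumeration when n1+n2 <= 12 and the pooled sample is tie-free;
    otherwise tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if n1 + n2 <= 12 and tie_free:
        return float(u), float(_exact_p(x, y, u))
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float(((t ** 3) - t).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    mu = n1 * n2 / 2.0
    d = u - mu
    z = (d - math.copysign(0.5, d)) / math.sqrt(var) if d != 0 else 0.0
    p = min(1.0, 2.0 * normal.sf(abs(z)))
    return float(u), float(p)


def _ranksum_rows(X: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum test: X is (genes, cells) with case cells first."""
    G, n = X.shape
    n2 = n - n1
    R = rankdata(X, axis=1)
    u = R[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    S = np.sort(X, axis=1)
    new = np.ones((G, n), dtype=bool)
    new[:, 1:] = S[:, 1:] != S[:, :-1]
    gid = np.cumsum(new, axis=1) - 1
    flat = (np.arange(G)[:, None] * n + gid).ravel()
    t = np.bincount(flat, minlength=G * n).reshape(G, n).astype(float)
    tie_term = (t ** 3 - t).sum(axis=1)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    d = u - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d - np.sign(d) * 0.5) / np.sqrt(var)
    z[d == 0] = 0.0
    p = np.where(var > 0, np.minimum(1.0, 2.0 * normal.sf(np.abs(z))), 1.0)
    return u, p


def _ranksum_blocked(X: np.ndarray, n1: int, block: int = 256):
    us, ps = [], []
    for start in range(0, X.shape[0], block):
        u, p = _ranksum_rows(X[start:start + block], n1)
        us.append(u)
        ps.append(p)
    if not us:
        return np.zeros(0), np.zeros(0)
    return np.concatenate(us), np.concatenate(ps)


# ---------------------------------------------------------------------------
# Pooled per-population DE
# ---------------------------------------------------------------------------


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if p.size == 0:
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment {method!r}")


def _group_stats(values: sp.spmatrix, cols: np.ndarray):
    sub = values[:, cols]
    pct = np.asarray((sub > 0).sum(axis=1)).ravel() / max(len(cols), 1)
    e = sub.copy()
    e.data = np.expm1(e.data)
    mean = np.asarray(e.sum(axis=1)).ravel() / max(len(cols), 1)
    return pct, mean


def _de_table(values: sp.spmatrix, gene_ids: np.ndarray,
              case_cols: np.ndarray, ctrl_cols: np.ndarray,
              logfc_threshold: float, min_pct: float, alpha: float,
              adjust: str) -> pd.DataFrame:
    """Full tested-gene table for one case/control comparison."""
    pct_case, m_case = _group_stats(values, case_cols)
    pct_ctrl, m_ctrl = _group_stats(values, ctrl_cols)
    logfc = np.log((m_case + 1.0) / (m_ctrl + 1.0))
    tested = ((np.maximum(pct_case, pct_ctrl) >= min_pct)
              & (np.abs(logfc) >= logfc_threshold))
    rows = np.where(tested)[0]
    table = pd.DataFrame({
        "gene": gene_ids[rows],
        "log_fc": logfc[rows],
        "pct_case": pct_case[rows],
        "pct_control": pct_ctrl[rows],
    })
    if rows.size:
        cols = np.concatenate([case_cols, ctrl_cols])
        X = np.asarray(values[rows][:, cols].todense(), dtype=float)
        _, p = _ranksum_blocked(X, len(case_cols))
        table["p_value"] = p
        table["p_adj"] = _adjust(p, adjust)
    else:
        table["p_value"] = np.zeros(0)
        table["p_adj"] = np.zeros(0)
    table["direction"] = np.where(table["log_fc"] > 0, "up", "down")
    table["significant"] = table["p_adj"] < alpha
    return table


def _align_annotation(norm: NormalizedMatrix, ann: pd.DataFrame,
                      cell_mask=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Reindex the annotation (and an optional per-cell mask) to the
    normalized matrix's cell order.  The mask may be a boolean Series
    indexed by cell_id or an array aligned with ``ann`` rows."""
    indexed = ann.set_index("cell_id")
    missing = [c for c in norm.cell_ids[:5] if c not in indexed.index]
    if missing:
        raise ValueError(f"annotation lacks cells {missing}")
    aligned = indexed.reindex(norm.cell_ids)
    if aligned["sample_id"].isna().any():
        raise ValueError("annotation lacks some matrix cells")
    if cell_mask is None:
        mask = np.ones(norm.n_cells, dtype=bool)
    elif isinstance(cell_mask, pd.Series):
        mask = cell_mask.reindex(norm.cell_ids).fillna(False).to_numpy(bool)
    else:
        cell_mask = np.asarray(cell_mask)
        if len(cell_mask) == len(ann):
            mask = pd.Series(cell_mask, index=ann["cell_id"]).reindex(
                norm.cell_ids).fillna(False).to_numpy(bool)
        elif len(cell_mask) == norm.n_cells:
            mask = cell_mask.astype(bool)
        else:
            raise ValueError("cell_mask length matches neither annotation "
                             "nor matrix")
    return aligned, mask


def _condition_cols(ann: pd.DataFrame, population: str | None,
                    samples: list | None, condition: str,
                    mask: np.ndarray) -> np.ndarray:
    """Column indices (into the aligned matrix) for one comparison group."""
    sel = ann["qc_pass"].to_numpy(bool).copy()
    if population is not None:
        pops = ann["population"].to_numpy()
        if population not in pops:
            raise ValueError(f"population {population!r} absent from annotation")
        sel &= pops == population
    if samples is not None:
        sel &= ann["sample_id"].isin(samples).to_numpy()
    else:
        sel &= (ann["condition"] == condition).to_numpy()
    sel &= mask
    return np.where(sel)[0]


def de_population(norm: NormalizedMatrix, ann: pd.DataFrame,
                  population: str | None,
                  logfc_threshold: float = 0.25, min_pct: float = 0.1,
                  alpha: float = 0.05, adjust: str = "bonferroni",
                  case_samples: list | None = None,
                  control_samples: list | None = None,
                  cell_mask: np.ndarray | None = None,
                  return_all: bool = False) -> pd.DataFrame:
    """Pooled case-vs-control DE within one population.

    Genes are tested when detected in >= ``min_pct`` of either group and
    |log_fc| >= ``logfc_threshold``; Bonferroni correction is over tested
    genes.  Returns the significant records (or the full tested table when
    ``return_all``)."""
    if logfc_threshold < 0:
        raise ValueError("logfc_threshold must be >= 0")
    ann, mask = _align_annotation(norm, ann, cell_mask)
    case_cols = _condition_cols(ann, population, case_samples, "PAH", mask)
    ctrl_cols = _condition_cols(ann, population, control_samples, "Control",
                                mask)
    if case_cols.size == 0 or ctrl_cols.size == 0:
        raise ValueError("empty case or control group")
    values = norm.values.tocsc()
    table = _de_table(values, norm.gene_ids, case_cols, ctrl_cols,
                      logfc_threshold, min_pct, alpha, adjust)
    table.insert(1, "population", population if population else "all")
    logger.info(
        "de_population(%s): %d vs %d cells, %d tested, %d significant",
        population, case_cols.size, ctrl_cols.size, len(table),
        int(table["significant"].sum()),
    )
    return table if return_all else table[table["significant"]].reset_index(
        drop=True)


# ---------------------------------------------------------------------------
# Replicate-consensus ("stringent") DE
# ---------------------------------------------------------------------------


@dataclass
class ConsensusDEResult:
    """Per-pair fold changes / adjusted p-values and the consensus verdict."""

    population: str
    pair_logfc: pd.DataFrame   # genes x pairs
    pair_padj: pd.DataFrame    # genes x pairs (NaN where not tested)
    consensus: pd.Series       # bool per gene
    consensus_logfc: pd.Series  # median pair log_fc (all genes)
    n_pairs: int

    def consensus_genes(self) -> list:
        return list(self.consensus.index[self.consensus])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.consensus.index,
            "population": self.population,
            "consensus": self.consensus.to_numpy(),
            "consensus_logfc": self.consensus_logfc.to_numpy(),
            "n_pairs_passing": self.n_pairs_passing().to_numpy(),
        })

    def n_pairs_passing(self) -> pd.Series:
        ok = self.pair_padj.notna() & (self.pair_padj < 1.0)
        return ok.sum(axis=1)


def consensus_de(norm: NormalizedMatrix, ann: pd.DataFrame,
                 population: str | None,
                 case_samples: list, control_samples: list,
                 logfc_threshold: float = 0.25, min_pct: float = 0.1,
                 alpha: float = 0.05, adjust: str = "bonferroni",
                 min_frac_pairs: float = 1.0,
                 cell_mask: np.ndarray | None = None) -> ConsensusDEResult:
    """Run DE for every case x control sample pair and intersect.

    consensus(gene) <=> the gene is tested and significant with
    |log_fc| >= threshold and a consistent sign in at least
    ``min_frac_pairs`` of the pairs (default: all of them).
    """
    if not case_samples or not control_samples:
        raise ValueError("need at least one case and one control sample")
    ann, mask = _align_annotation(norm, ann, cell_mask)
    values = norm.values.tocsc()
    genes = pd.Index(norm.gene_ids, name="gene")
    pair_logfc, pair_padj, pair_pass, pair_sign = {}, {}, {}, {}
    untestable = False
    for cs in case_samples:
        case_cols = _condition_cols(ann, population, [cs], "PAH", mask)
        for ct in control_samples:
            ctrl_cols = _condition_cols(ann, population, [ct], "Control",
                                        mask)
            key = f"{cs}|{ct}"
            if case_cols.size == 0 or ctrl_cols.size == 0:
                logger.warning("consensus_de(%s): pair %s has an empty "
                               "group; marked untestable", population, key)
                untestable = True
                pair_logfc[key] = pd.Series(np.nan, index=genes)
                pair_padj[key] = pd.Series(np.nan, index=genes)
                pair_pass[key] = pd.Series(False, index=genes)
                pair_sign[key] = pd.Series(0.0, index=genes)
                continue
            tab = _de_table(values, norm.gene_ids, case_cols, ctrl_cols,
                            logfc_threshold, min_pct, alpha, adjust)
            # full per-gene logfc (including untested genes) for the profile
            _, m_case = _group_stats(values, case_cols)
            _, m_ctrl = _group_stats(values, ctrl_cols)
            full_lfc = pd.Series(np.log((m_case + 1) / (m_ctrl + 1)),
                                 index=genes)
            padj = pd.Series(np.nan, index=genes)
            padj.loc[tab["gene"].to_numpy()] = tab["p_adj"].to_numpy()
            ok = pd.Series(False, index=genes)
            ok.loc[tab.loc[tab["significant"], "gene"].to_numpy()] = True
            pair_logfc[key] = full_lfc
            pair_padj[key] = padj
            pair_pass[key] = ok
            pair_sign[key] = np.sign(full_lfc)
    lfc = pd.DataFrame(pair_logfc)
    padj = pd.DataFrame(pair_padj)
    passed = pd.DataFrame(pair_pass)
    signs = pd.DataFrame(pair_sign)
    n_pairs = lfc.shape[1]
    need = max(1, int(np.ceil(min_frac_pairs * n_pairs)))
    n_pass = passed.sum(axis=1)
    # direction must agree across the passing pairs
    n_up = (passed & (signs > 0)).sum(axis=1)
    n_down = (passed & (signs < 0)).sum(axis=1)
    consistent = (n_up == n_pass) | (n_down == n_pass)
    # an untestable pair contributes passed=False everywhere, so with the
    # default all-pairs rule it vetoes every gene
    if min_frac_pairs >= 1.0:
        consensus = passed.all(axis=1) & consistent
    else:
        consensus = (n_pass >= need) & consistent
    result = ConsensusDEResult(
        population=population if population else "all",
        pair_logfc=lfc,
        pair_padj=padj,
        consensus=consensus,
        consensus_logfc=lfc.median(axis=1),
        n_pairs=n_pairs,
    )
    logger.info("consensus_de(%s): %d pairs, %d consensus genes",
                population, n_pairs, int(consensus.sum()))
    return result


# ---------------------------------------------------------------------------
# Subpopulation specificity
# ---------------------------------------------------------------------------


def specific_response(de_genes: list, norm: NormalizedMatrix,
                      ann: pd.DataFrame, target_population: str,
                      n_gene_clusters: int = 4,
                      specificity_ratio: float = 2.0,
                      populations: list | None = None) -> list:
    """Select DEGs whose condition response is specific to one population.

    Builds the gene x (population x condition) mean-expression matrix,
    z-scores per gene, clusters genes (average linkage, correlation
    distance) into ``n_gene_clusters`` groups, and returns the genes of
    clusters whose mean |Delta(PAH - Control)| in the target population is at
    least ``specificity_ratio`` times the largest mean |Delta| in any other
    population."""
    if len(de_genes) < 2:
        raise ValueError("need at least two DEGs to cluster")
    gidx = norm.gene_index()
    rows = np.array([gidx[g] for g in de_genes], dtype=int)
    ann, _ = _align_annotation(norm, ann)
    if populations is None:
        populations = [p for p in pd.unique(ann["population"])
                       if p not in ("Immune", "Mesenchymal", "Unassigned")]
    qc = ann["qc_pass"].to_numpy(bool)
    cols = {}
    for pop in populations:
        for cond in ("Control", "PAH"):
            sel = np.where(qc & (ann["population"] == pop).to_numpy()
                           & (ann["condition"] == cond).to_numpy())[0]
            if sel.size:
                cols[(pop, cond)] = sel
    pops_used = sorted({p for p, _ in cols})
    mat = np.zeros((len(rows), len(cols)))
    keys = list(cols)
    values = norm.values.tocsc()
    for j, key in enumerate(keys):
        mat[:, j] = np.asarray(
            values[rows][:, cols[key]].mean(axis=1)).ravel()
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    d = pdist(z, metric="correlation")
    d = np.nan_to_num(d, nan=2.0)
    link = linkage(d, method="average")
    # deepen the cut until n_gene_clusters clusters with >= 2 members
    # exist: singleton outliers must not consume the requested clusters
    t = n_gene_clusters
    while True:
        labels = fcluster(link, t=t, criterion="maxclust")
        sizes = np.bincount(labels)
        if (sizes >= 2).sum() >= n_gene_clusters or t >= len(de_genes):
            break
        t += 1

    # per-population condition response, raw scale
    delta = {}
    for pop in pops_used:
        if (pop, "PAH") in cols and (pop, "Control") in cols:
            delta[pop] = (mat[:, keys.index((pop, "PAH"))]
                          - mat[:, keys.index((pop, "Control"))])
    if target_population not in delta:
        raise ValueError(f"target population {target_population!r} missing a "
                         "condition")
    selected: list = []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        if len(members) < 2:  # outlier singletons are never selected
            continue
        target = float(np.abs(np.mean(delta[target_population][members])))
        others = [float(np.abs(np.mean(delta[p][members])))
                  for p in delta if p != target_population]
        if others and target >= specificity_ratio * max(others):
            selected.extend(np.asarray(de_genes, dtype=object)[members])
    logger.info("specific_response(%s): %d of %d DEGs selected",
                target_population, len(selected), len(de_genes))
    return selected


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------


def enrich_ora(gene_list, universe, gene_sets: dict) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH correction.

    p = P(X >= k) with population |universe|, successes |set & universe|,
    draws |gene_list|.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list)
    stray = gene_list - universe
    if stray:
        raise ValueError(f"gene_list not contained in universe: "
                         f"{sorted(stray)[:5]}")
    M, N = len(universe), len(gene_list)
    records = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        k = len(in_universe & gene_list)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        records.append({"set": name, "overlap": k, "set_size": K,
                        "p_value": min(1.0, p)})
    df = pd.DataFrame(records)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
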