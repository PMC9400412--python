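"""Synthetic UMI-count experiment generator (Gamma-Poisson).

Emulates a 3 Control + 3 PAH lineage-reporter single-cell experiment on lung
endothelium: seven endothelial populations plus two low-reporter contaminant
populations, an arteriovenous latent coordinate lambda driving marker
gradients, planted condition effects (global, population-specific,
section-localized, optionally replicate-inconsistent), per-sample batch
multipliers, damaged high-mitochondrial cells, and an appended lineage
reporter gene.  Counts are negative binomial (Gamma-Poisson) around a
per-cell library-size budget:

    y_gc ~ NB(mean = L_c * m_gc / sum_g m_gc, size)
    m_gc = mu_g * pop_boost * exp(beta_g f(lambda_c))
               * exp(delta_g * w * 1[case & affected]) * exp(eps_gs)

Ground truth sufficient to score recovery (populations, lambda, effect genes
and sizes, batch factors) is returned alongside the matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cellcycle_genes import CELL_CYCLE_GENES
from .core_io import (
    EC_POPULATIONS,
    ExpressionMatrix,
    logger,
    new_annotation,
    write_mtx_bundle,
    write_table,
)

LN = math.log

#: Latent arteriovenous coordinate ranges per population; the overlaps make
#: the three axis clusters adjacent, as in the real vasculature.
LAMBDA_RANGES = {
    "Artery": (0.0, 0.30),
    "CapillaryA": (0.25, 0.75),
    "CapillaryB": (0.30, 0.70),
    "Vein": (0.70, 1.0),
}

#: Canonical marker symbols planted into the matrix.  Direction is always
#: "up" in the owning population.
MARKER_GENES = {
    "Artery": ["Cxcl12", "Mgp"],
    "Vein": ["Vwf", "Prss23", "Vcam1"],
    "CapillaryA": ["Nrp1", "Sema3c"],
    "CapillaryB": ["Car4"],
    "Lymphatic": ["Ccl21a", "Prox1"],
    "SftpPlus": ["Sftpa1", "Sftpb", "Sftpc", "Sftpd"],
    "Immune": ["Tyrobp", "Ptprc", "Cd52"],
    "Mesenchymal": ["Gsn", "Col1a1", "Acta2"],
}
PAN_EC_GENES = ["Cdh5", "Pecam1"]
REPORTER_GENE = "TdTomato"

#: Mesenchymal genes kept near-silent in endothelium (no planted EndMT):
#: expected UMIs per endothelial cell at the median library size.
_SILENT_IN_EC = {"Acta2": 0.005, "Col1a1": 0.005}

_VASCULAR = ("Artery", "CapillaryA", "CapillaryB", "Vein")

EFFECT_CLASSES = ("none", "global", "population_specific",
                  "section_localized", "inconsistent")


@dataclass
class SimulationParams:
    """Stated world of the generator; defaults are the documented conditions."""

    n_genes: int = 2000
    cells_per_sample: int = 2000
    n_control: int = 3
    n_case: int = 3
    proportions: dict = field(default_factory=lambda: {
        "CapillaryA": 0.60, "CapillaryB": 0.12, "Artery": 0.08, "Vein": 0.08,
        "Lymphatic": 0.04, "Proliferating": 0.03, "SftpPlus": 0.004,
        "Immune": 0.03, "Mesenchymal": 0.016,
    })
    n_global_de: int = 150
    n_popspecific_de: int = 40
    popspecific_target: str = "CapillaryB"
    n_sectional_de: int = 10
    sectional_center: float = 0.45
    sectional_width: float = 0.08
    n_inconsistent_de: int = 0
    effect_min: float = LN(1.5)
    effect_max: float = LN(3.0)
    batch_sd: float = 0.1
    library_log_mean: float = LN(5000.0)
    library_log_sd: float = 0.3
    nb_size: float = 10.0
    mito_fraction: float = 0.05
    n_mito_genes: int = 10
    damaged_fraction: float = 0.02
    damaged_mito_range: tuple = (0.25, 0.60)
    reporter_mean_ec: float = 20.0
    reporter_mean_contaminant: float = 0.05
    marker_boost: float = 12.0
    n_program_genes: int = 30
    program_boost_range: tuple = (LN(2.0), LN(5.0))
    n_zonation_arterial: int = 70
    n_zonation_venous: int = 70
    n_zonation_junction: int = 25
    zonation_amp_min: float = LN(3.0)
    zonation_amp_max: float = LN(8.0)
    cc_boost: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"population proportions sum to {total}, not 1")
        for name in ("n_genes", "cells_per_sample", "n_control", "n_case",
                     "n_global_de", "n_popspecific_de", "n_sectional_de",
                     "n_inconsistent_de", "n_mito_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("population proportions must be >= 0")

    @classmethod
    def null(cls, **overrides) -> "SimulationParams":
        """A true null world: no condition effects, no batch variation."""
        base = dict(n_global_de=0, n_popspecific_de=0, n_sectional_de=0,
                    n_inconsistent_de=0, batch_sd=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    """Planted ground truth tables for recovery scoring."""

    cell_truth: pd.DataFrame   # per-cell population, lambda, flags
    gene_truth: pd.DataFrame   # per-gene roles, zonation and effect params
    batch_factors: pd.DataFrame  # gene x sample log multipliers eps_gs
    params: SimulationParams

    def effect_genes(self, effect_class: str) -> list:
        sub = self.gene_truth[self.gene_truth["effect_class"] == effect_class]
        return list(sub["gene"])


def _logistic(x: np.ndarray, center: float, width: float, rising: bool) -> np.ndarray:
    z = (x - center) / width
    return 1.0 / (1.0 + np.exp(z if not rising else -z))


def zonation_weight(kind: str, lam: np.ndarray, center: float,
                    width: float) -> np.ndarray:
    """Unit-amplitude zonation profile f(lambda) in [0, 1]; NaN lambda -> 0."""
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    ok = np.isfinite(lam)
    if kind == "arterial-logistic":
        out[ok] = _logistic(lam[ok], center, width, rising=False)
    elif kind == "venous-logistic":
        out[ok] = _logistic(lam[ok], center, width, rising=True)
    elif kind == "junction-gaussian":
        out[ok] = np.exp(-((lam[ok] - center) ** 2) / (2.0 * width ** 2))
    elif kind == "flat":
        pass
    else:
        raise ValueError(f"unknown zonation profile {kind!r}")
    return out


def _build_gene_truth(params: SimulationParams, rng: np.random.Generator):
    """Assign names, baselines, population boosts, zonation and effects."""
    pops = list(params.proportions)
    named: list[tuple[str, str | None]] = []  # (symbol, marker population)
    for pop, genes in MARKER_GENES.items():
        named += [(g, pop) for g in genes]
    named += [(g, "panEC") for g in PAN_EC_GENES]
    named += [(g, "Proliferating") for g in CELL_CYCLE_GENES]
    n_named = len(named)
    n_zon = (params.n_zonation_arterial + params.n_zonation_venous
             + params.n_zonation_junction)
    n_eff = (params.n_global_de + params.n_popspecific_de
             + params.n_sectional_de + params.n_inconsistent_de)
    n_prog = params.n_program_genes * len(params.proportions)
    if params.n_genes < n_named + n_zon + n_prog + 2 * n_eff + 10:
        raise ValueError(
            f"n_genes={params.n_genes} too small for {n_named} named, "
            f"{n_zon} zonation, {n_prog} program and {n_eff} effect genes"
        )

    symbols = [s for s, _ in named]
    symbols += [f"gene{i + 1:04d}" for i in range(params.n_genes - n_named)]
    genes = pd.DataFrame({"gene": symbols})
    genes["marker_population"] = [p for _, p in named] + [None] * (
        params.n_genes - n_named)

    # Baselines: generic lognormal(0, 1); markers planted high so they rank
    # at the top of their population's expression profile.
    mu = rng.lognormal(0.0, 1.0, size=params.n_genes)
    is_cc = genes["marker_population"].values == "Proliferating"
    for i, (sym, pop) in enumerate(named):
        if sym in _SILENT_IN_EC:
            mu[i] = _SILENT_IN_EC[sym]
        elif pop == "Proliferating":
            mu[i] = rng.lognormal(0.0, 0.7)
        else:
            mu[i] = math.exp(1.3) * rng.lognormal(0.0, 0.1)
    # near-silent genes are calibrated to an expected count per cell at the
    # median library size, independent of n_genes
    for i, (sym, _pop) in enumerate(named):
        if sym in _SILENT_IN_EC:
            mu[i] = _SILENT_IN_EC[sym] * mu.sum() / math.exp(
                params.library_log_mean)
    genes["baseline_mean"] = mu

    # Population boost matrix (log scale).
    log_boost = np.zeros((params.n_genes, len(pops)))
    pop_idx = {p: j for j, p in enumerate(pops)}
    for i, (sym, pop) in enumerate(named):
        if pop == "panEC":
            for q in pops:
                if q not in EC_POPULATIONS:
                    log_boost[i, pop_idx[q]] = LN(0.02)
        elif pop == "Proliferating":
            log_boost[i, pop_idx[pop]] = LN(params.cc_boost)
        elif sym in _SILENT_IN_EC:
            # low baseline everywhere, strongly induced in the owning
            # (mesenchymal) population only
            log_boost[i, pop_idx[pop]] = LN(3000.0)
        else:
            for q in pops:
                if q == pop:
                    log_boost[i, pop_idx[q]] = LN(params.marker_boost)
                elif pop in _VASCULAR and q in _VASCULAR:
                    log_boost[i, pop_idx[q]] = 0.0  # gradient via zonation
                else:
                    log_boost[i, pop_idx[q]] = LN(0.05)

    # Zonation profiles: vascular markers carry the canonical gradients,
    # anonymous generic genes fill in the continuum.
    genes["zonation_type"] = "flat"
    genes["zonation_amplitude"] = 0.0
    genes["zonation_center"] = np.nan
    genes["zonation_width"] = np.nan
    sym_row = {s: i for i, s in enumerate(symbols)}

    def set_zon(i, kind, amp, center, width):
        genes.loc[i, ["zonation_type", "zonation_amplitude",
                      "zonation_center", "zonation_width"]] = (
            kind, amp, center, width)

    for s in MARKER_GENES["Artery"]:
        set_zon(sym_row[s], "arterial-logistic", LN(3.0), 0.35, 0.05)
    for s in MARKER_GENES["Vein"]:
        set_zon(sym_row[s], "venous-logistic", LN(3.0), 0.65, 0.05)
    for s in MARKER_GENES["CapillaryA"]:
        set_zon(sym_row[s], "junction-gaussian", LN(2.0), 0.50, 0.25)

    # Per-population expression programs: each population is enriched for a
    # block of anonymous genes beyond its canonical markers, as real cell
    # types are -- this is what makes the populations clusterable at all.
    generic = np.arange(n_named, params.n_genes)
    n_prog_total = params.n_program_genes * len(pops)
    prog_pool = rng.choice(generic, size=n_prog_total, replace=False)
    genes["program_population"] = None
    for j, pop in enumerate(pops):
        block = prog_pool[j * params.n_program_genes:
                          (j + 1) * params.n_program_genes]
        boosts = rng.uniform(*params.program_boost_range, size=len(block))
        log_boost[block, pop_idx[pop]] += boosts
        genes.loc[block, "program_population"] = pop

    generic = np.setdiff1d(generic, prog_pool)
    zon_pool = rng.choice(generic, size=n_zon, replace=False)
    cursor = 0
    for kind, count in (
        ("arterial-logistic", params.n_zonation_arterial),
        ("venous-logistic", params.n_zonation_venous),
        ("junction-gaussian", params.n_zonation_junction),
    ):
        for i in zon_pool[cursor:cursor + count]:
            amp = rng.uniform(params.zonation_amp_min, params.zonation_amp_max)
            if kind == "arterial-logistic":
                center, width = rng.uniform(0.20, 0.50), 0.05
            elif kind == "venous-logistic":
                center, width = rng.uniform(0.50, 0.80), 0.05
            else:
                center, width = rng.uniform(0.30, 0.70), rng.uniform(0.05, 0.15)
            set_zon(int(i), kind, amp, center, width)
        cursor += count

    # Condition effects: planted on the more-abundant half of the remaining
    # generic genes -- a 0.25 fold-change gate is only observable for genes
    # expressed at the simulated depth.
    genes["effect_class"] = "none"
    genes["effect_delta"] = 0.0
    genes["affected_samples"] = ""
    free = np.setdiff1d(generic, zon_pool)
    eligible = free[mu[free] >= np.median(mu[free])]
    if len(eligible) < n_eff:
        raise ValueError("not enough abundant generic genes for the "
                         "requested effect counts")
    eff_pool = rng.choice(eligible, size=n_eff, replace=False)
    # Section-localized effects go on the best-expressed picks: the planted
    # phenomenon (a localized up-regulation peak) concerns well-expressed
    # genes, and localization of a near-silent gene is not measurable.
    by_abundance = eff_pool[np.argsort(-mu[eff_pool], kind="stable")]
    sect_pick = by_abundance[:params.n_sectional_de]
    rest = rng.permutation(np.setdiff1d(eff_pool, sect_pick))
    head = params.n_global_de + params.n_popspecific_de
    eff_pool = np.concatenate([rest[:head], sect_pick, rest[head:]])
    c = 0

    def take(n):
        nonlocal c
        out = eff_pool[c:c + n]
        c += n
        return out

    glob = take(params.n_global_de)
    for j, i in enumerate(glob):
        if j == 0:
            delta = LN(2.0)  # sentinel: exactly 2-fold, up
        else:
            sign = 1.0 if j % 2 == 1 else -1.0
            delta = sign * rng.uniform(params.effect_min, params.effect_max)
        genes.loc[i, ["effect_class", "effect_delta"]] = ("global", delta)
    for i in take(params.n_popspecific_de):
        genes.loc[i, ["effect_class", "effect_delta"]] = (
            "population_specific",
            rng.uniform(params.effect_min, params.effect_max),
        )
    for i in take(params.n_sectional_de):
        genes.loc[i, ["effect_class", "effect_delta"]] = (
            "section_localized", LN(2.0))
        genes.loc[i, ["zonation_center", "zonation_width"]] = (
            params.sectional_center, params.sectional_width)
    for i in take(params.n_inconsistent_de):
        genes.loc[i, ["effect_class", "effect_delta"]] = (
            "inconsistent", rng.uniform(LN(2.0), params.effect_max))

    return genes, log_boost, pops, is_cc


def simulate_experiment(params: SimulationParams | None = None):
    """Generate (ExpressionMatrix, annotation table, SyntheticTruth).

    Deterministic given ``params.seed``.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    genes, log_boost, pops, _ = _build_gene_truth(params, rng)
    n_genes = params.n_genes
    props = np.array([params.proportions[p] for p in pops])
    pop_of = {j: p for j, p in enumerate(pops)}

    samples = [f"Control{i + 1}" for i in range(params.n_control)] + [
        f"PAH{i + 1}" for i in range(params.n_case)]
    conditions = ["Control"] * params.n_control + ["PAH"] * params.n_case
    case_samples = samples[params.n_control:]
    inconsistent_affected = [case_samples[i] for i in range(len(case_samples))
                             if i % 2 == 0]  # e.g. PAH1 and PAH3 of 3
    genes.loc[genes["effect_class"] == "inconsistent", "affected_samples"] = (
        ";".join(inconsistent_affected))
    genes.loc[genes["effect_class"].isin(
        ("global", "population_specific", "section_localized")),
        "affected_samples"] = ";".join(case_samples)

    eps = rng.normal(0.0, params.batch_sd, size=(n_genes, len(samples))) \
        if params.batch_sd > 0 else np.zeros((n_genes, len(samples)))

    # Precompute zonation row data.
    zrows = genes.index[genes["zonation_type"] != "flat"].to_numpy()
    ztype = genes["zonation_type"].to_numpy()
    zamp = genes["zonation_amplitude"].to_numpy()
    zcen = genes["zonation_center"].to_numpy()
    zwid = genes["zonation_width"].to_numpy()
    mu = genes["baseline_mean"].to_numpy()
    eclass = genes["effect_class"].to_numpy()
    edelta = genes["effect_delta"].to_numpy()
    glob_rows = np.where(eclass == "global")[0]
    pspec_rows = np.where(eclass == "population_specific")[0]
    sect_rows = np.where(eclass == "section_localized")[0]
    incon_rows = np.where(eclass == "inconsistent")[0]

    mito_w = rng.dirichlet(np.ones(params.n_mito_genes)) \
        if params.n_mito_genes else np.zeros(0)

    blocks, cells_meta = [], []
    for s_idx, (sample, condition) in enumerate(zip(samples, conditions)):
        n = params.cells_per_sample
        pop_j = rng.choice(len(pops), size=n, p=props)
        pop_names = np.array([pop_of[j] for j in pop_j], dtype=object)
        lam = np.full(n, np.nan)
        for p, (lo, hi) in LAMBDA_RANGES.items():
            mask = pop_names == p
            lam[mask] = rng.uniform(lo, hi, size=mask.sum())
        damaged = rng.random(n) < params.damaged_fraction
        is_ec = np.isin(pop_names, EC_POPULATIONS)

        logm = np.log(mu)[:, None] + log_boost[:, pop_j] + eps[:, s_idx][:, None]
        for i in zrows:
            logm[i] += zamp[i] * zonation_weight(ztype[i], lam, zcen[i], zwid[i])
        if condition == "PAH":
            logm[glob_rows] += edelta[glob_rows][:, None]
            tmask = pop_names == params.popspecific_target
            if tmask.any():
                logm[np.ix_(pspec_rows, np.where(tmask)[0])] += \
                    edelta[pspec_rows][:, None]
            if len(sect_rows):
                w = zonation_weight("junction-gaussian", lam,
                                    params.sectional_center,
                                    params.sectional_width)
                logm[sect_rows] += edelta[sect_rows][:, None] * w[None, :]
            if len(incon_rows) and sample in inconsistent_affected:
                logm[incon_rows] += edelta[incon_rows][:, None]

        m = np.exp(logm)
        rel = m / m.sum(axis=0, keepdims=True)
        lib = rng.lognormal(params.library_log_mean, params.library_log_sd, n)
        mito_share = np.where(
            damaged,
            rng.uniform(*params.damaged_mito_range, size=n),
            params.mito_fraction,
        )
        rep_mean = np.where(is_ec, params.reporter_mean_ec,
                            params.reporter_mean_contaminant)
        main_budget = np.maximum(lib * (1.0 - mito_share) - rep_mean, 1.0)
        mean = np.vstack([
            rel * main_budget[None, :],
            rep_mean[None, :],
            mito_w[:, None] * (lib * mito_share)[None, :],
        ])
        size = params.nb_size
        p_nb = size / (size + mean)
        counts = rng.negative_binomial(size, p_nb)
        blocks.append(sp.csr_matrix(counts))
        cells_meta.append(pd.DataFrame({
            "cell_id": [f"{sample}_c{i + 1:05d}" for i in range(n)],
            "sample_id": sample,
            "condition": condition,
            "true_population": pop_names,
            "true_axis_position": lam,
            "is_contaminant": ~is_ec,
            "is_damaged": damaged,
            "target_library": lib,
            "mito_share": mito_share,
        }))

    counts = sp.hstack(blocks, format="csr")
    cell_truth = pd.concat(cells_meta, ignore_index=True)
    gene_ids = np.array(
        list(genes["gene"])
        + [REPORTER_GENE]
        + [f"mt-{i + 1}" for i in range(params.n_mito_genes)],
        dtype=object,
    )
    matrix = ExpressionMatrix(counts, gene_ids,
                              cell_truth["cell_id"].to_numpy(dtype=object))
    reporter = np.asarray(counts[params.n_genes].todense()).ravel().astype(int)
    ann = new_annotation(cell_truth["cell_id"], cell_truth["sample_id"],
                         cell_truth["condition"], reporter)
    batch = pd.DataFrame(eps, columns=samples)
    batch.insert(0, "gene", genes["gene"].to_numpy())
    truth = SyntheticTruth(cell_truth, genes.copy(), batch, params)
    logger.info(
        "simulate_experiment: seed=%d %d genes x %d cells, %d samples, "
        "%d planted effect genes",
        params.seed, matrix.n_genes, matrix.n_cells, len(samples),
        int((genes["effect_class"] != "none").sum()),
    )
    return matrix, ann, truth


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> dict:
    """Write per-cell / per-gene / batch truth tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cell_truth": write_table(truth.cell_truth, outdir / "cell_truth.tsv"),
        "gene_truth": write_table(truth.gene_truth, outdir / "gene_truth.tsv"),
        "batch_factors": write_table(truth.batch_factors,
                                     outdir / "batch_factors.tsv"),
    }
    return paths


def read_truth(outdir: str | Path,
               params: SimulationParams | None = None) -> SyntheticTruth:
    outdir = Path(outdir)
    cell = pd.read_csv(outdir / "cell_truth.tsv", sep="\t")
    gene = pd.read_csv(outdir / "gene_truth.tsv", sep="\t",
                       keep_default_na=True)
    gene["affected_samples"] = gene["affected_samples"].fillna("")
    gene["marker_population"] = gene["marker_population"].where(
        gene["marker_population"].notna(), None)
    batch = pd.read_csv(outdir / "batch_factors.tsv", sep="\t")
    return SyntheticTruth(cell, gene, batch, params or SimulationParams())


def write_experiment(matrix: ExpressionMatrix, ann: pd.DataFrame,
                     truth: SyntheticTruth, outdir: str | Path) -> dict:
    """Write the full MTX bundle, metadata and truth tables."""
    outdir = Path(outdir)
    paths = write_mtx_bundle(matrix, outdir)
    paths["metadata"] = write_table(
        ann[["cell_id", "sample_id", "condition"]], outdir / "metadata.tsv")
    paths.update(write_truth(truth, outdir))
    return paths
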