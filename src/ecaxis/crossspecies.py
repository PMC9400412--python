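"""Cross-species DEG mapping and overlap statistics.

Gene identity across species defaults to case-normalized symbol equality
(mouse ``Cd74`` <-> human ``CD74``); an explicit two-column ortholog TSV
overrides it.  Overlap fractions use all reference DEGs in the denominator
by default (unmapped genes are reported, never silently dropped), matching
the convention of quoting "x% of the up-regulated genes".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import logger


@dataclass
class OrthologMap:
    """Symbol pairs (species A -> species B); optionally one-to-one."""

    pairs: pd.DataFrame  # columns: source, target
    one_to_one: bool = True

    def __post_init__(self) -> None:
        self.pairs = self.pairs[["source", "target"]].dropna()
        if self.one_to_one:
            for col in ("source", "target"):
                dup = self.pairs[col][self.pairs[col].duplicated()]
                if len(dup):
                    raise ValueError(
                        f"duplicate {col} symbols in one-to-one map: "
                        f"{sorted(set(dup))[:5]}")

    @classmethod
    def from_table(cls, df: pd.DataFrame, one_to_one: bool = True):
        cols = list(df.columns[:2])
        out = df.rename(columns={cols[0]: "source", cols[1]: "target"})
        return cls(out, one_to_one)

    @classmethod
    def case_normalized(cls, genes) -> "OrthologMap":
        """The default symbol-capitalization map (e.g. Cd74 -> CD74)."""
        src = sorted(set(genes))
        return cls(pd.DataFrame({"source": src,
                                 "target": [g.upper() for g in src]}))

    def lookup(self) -> dict:
        return dict(zip(self.pairs["source"], self.pairs["target"]))


def map_orthologs(genes, ortholog_map: OrthologMap) -> tuple[list, list]:
    """Translate symbols; returns (mapped targets, unmapped sources)."""
    table = ortholog_map.lookup()
    mapped, unmapped = [], []
    for g in genes:
        if g in table:
            mapped.append(table[g])
        else:
            unmapped.append(g)
    if unmapped:
        logger.info("map_orthologs: %d of %d genes unmapped", len(unmapped),
                    len(genes))
    return mapped, unmapped


@dataclass
class OverlapReport:
    """Per-direction sharing statistics plus k-way intersections."""

    per_direction: pd.DataFrame  # direction, n_reference, n_shared_any, fraction_shared
    shared_any: dict             # direction -> sorted gene list
    full_intersection: dict      # direction -> genes shared with EVERY table
    per_table: dict              # (direction, table) -> sorted shared genes

    def fraction(self, direction: str) -> float:
        row = self.per_direction.set_index("direction")
        return float(row.loc[direction, "fraction_shared"])


def _significant(table: pd.DataFrame, use_adjusted: bool,
                 alpha: float) -> pd.DataFrame:
    col = "p_adj" if use_adjusted else "p_value"
    if col not in table.columns:
        raise ValueError(f"table lacks required column {col!r}")
    return table[table[col] < alpha]


def overlap_deg_sets(reference_de: pd.DataFrame, other_tables: dict,
                     ortholog_maps: dict | None = None,
                     direction_aware: bool = True,
                     use_adjusted: dict | None = None,
                     alpha: float = 0.05) -> OverlapReport:
    """Overlap a reference DEG table with named external DEG tables.

    A reference gene counts as shared-any when at least one other table
    contains its ortholog as significant (per that table's significance
    mode: adjusted or raw p) with, if ``direction_aware``, the same
    direction.  Each table needs columns gene, direction and p_value or
    p_adj.
    """
    if "direction" not in reference_de.columns:
        raise ValueError("reference table lacks a direction column")
    use_adjusted = use_adjusted or {}
    ortholog_maps = ortholog_maps or {}
    rows, shared_any, full_inter, per_table = [], {}, {}, {}
    for direction in ("up", "down"):
        ref = reference_de[reference_de["direction"] == direction]
        ref_genes = list(dict.fromkeys(ref["gene"]))
        hits: dict[str, set] = {}
        for name in sorted(other_tables):
            table = other_tables[name]
            if "direction" not in table.columns:
                raise ValueError(f"table {name!r} lacks a direction column")
            sig = _significant(table, use_adjusted.get(name, True), alpha)
            if direction_aware:
                sig = sig[sig["direction"] == direction]
            omap = ortholog_maps.get(
                name, OrthologMap.case_normalized(ref_genes))
            lut = omap.lookup()
            present = set(sig["gene"])
            hits[name] = {g for g in ref_genes if lut.get(g) in present}
            per_table[(direction, name)] = sorted(hits[name])
        union = set().union(*hits.values()) if hits else set()
        inter = set.intersection(*hits.values()) if hits else set()
        shared_any[direction] = sorted(union)
        full_inter[direction] = sorted(inter)
        n_ref = len(ref_genes)
        rows.append({
            "direction": direction,
            "n_reference": n_ref,
            "n_shared_any": len(union),
            "fraction_shared": len(union) / n_ref if n_ref else np.nan,
        })
    report = OverlapReport(pd.DataFrame(rows), shared_any, full_inter,
                           per_table)
    logger.info("overlap_deg_sets: %s",
                report.per_direction.to_dict("records"))
    return report


def overlap_with_external(sc_de: pd.DataFrame, external: pd.DataFrame,
                          fc_threshold: float = 1.5,
                          alpha: float = 0.05) -> dict:
    """Validate single-cell DEGs against an external (bulk) DE table.

    The single-cell set is first restricted to |fold change| >=
    ``fc_threshold`` on the linear scale (log_fc is natural log
    internally); a gene is validated when the external table carries it as
    significant with the same direction.  Returns the validated fraction
    and gene lists; ``evaluable`` is False when the filtered set is empty.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    for col in ("gene", "fold_change", "significant"):
        if col not in external.columns:
            raise ValueError(f"external table lacks column {col!r}")
    ln_thr = np.log(fc_threshold)
    sc = sc_de[np.abs(sc_de["log_fc"]) >= ln_thr]
    if len(sc) == 0:
        return {"evaluable": False, "fraction_validated": np.nan,
                "n_candidates": 0, "validated_genes": []}
    ext = external[external["significant"].astype(bool)]
    ext_dir = {g: ("up" if fc > 1 else "down")
               for g, fc in zip(ext["gene"], ext["fold_change"])}
    validated = [g for g, d in zip(sc["gene"], sc["direction"])
                 if ext_dir.get(g) == d]
    return {
        "evaluable": True,
        "fraction_validated": len(validated) / len(sc),
        "n_candidates": int(len(sc)),
        "validated_genes": sorted(validated),
    }
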