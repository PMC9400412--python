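"""Data model, standard-format I/O, configuration and logging.

The in-memory containers are deliberately thin: a sparse genes x cells count
matrix with identifier arrays (:class:`ExpressionMatrix`), its log-normalized
counterpart (:class:`NormalizedMatrix`), and a per-cell annotation table kept
as a plain :class:`pandas.DataFrame` with a fixed column contract
(:data:`ANNOTATION_COLUMNS`).

External formats follow the 10x dialect: MatrixMarket ``.mtx`` (1-based on
disk, 0-based in memory) plus one-identifier-per-line ``genes.tsv`` /
``barcodes.tsv`` side files, gzip-transparent.  Tabular results are written
as tab-separated UTF-8 with a header; reals survive a round-trip to 12
significant digits.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("ecaxis")

#: Populations used throughout; "Unassigned" is the fallback label.
POPULATIONS = (
    "Artery",
    "Vein",
    "CapillaryA",
    "CapillaryB",
    "Lymphatic",
    "Proliferating",
    "SftpPlus",
    "Immune",
    "Mesenchymal",
    "Unassigned",
)

#: Endothelial (lineage) populations; the remainder are contaminants.
EC_POPULATIONS = (
    "Artery",
    "Vein",
    "CapillaryA",
    "CapillaryB",
    "Lymphatic",
    "Proliferating",
    "SftpPlus",
)

#: Populations ordered along the arteriovenous axis.
VASCULAR_POPULATIONS = ("Artery", "CapillaryA", "Vein")

CONDITIONS = ("Control", "PAH")

#: Column contract for the per-cell annotation table.
ANNOTATION_COLUMNS = (
    "cell_id",
    "sample_id",
    "condition",
    "reporter_count",
    "qc_pass",
    "cluster_id",
    "population",
    "cc_phase",
    "axis_position",
)


class FormatError(ValueError):
    """Raised when an on-disk input violates its declared format."""


def configure_logging(level: str = "INFO") -> None:
    """Attach a stream handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise FormatError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Raw UMI counts, genes x cells, with unique string identifiers."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene identifiers for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell identifiers for {n_cells} matrix columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise FormatError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, cell_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = _positions(self.cell_ids, cell_ids, "cell")
        return ExpressionMatrix(
            self.counts[:, idx], self.gene_ids, self.cell_ids[idx]
        )

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, same shape and identifiers as its source.

    values[g, c] = ln(1 + count[g, c] * scale_constant / library_size[c]).
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    size_factors: np.ndarray
    scale_constant: float = 1e4

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, cell_ids: Iterable[str]) -> "NormalizedMatrix":
        idx = _positions(self.cell_ids, cell_ids, "cell")
        return NormalizedMatrix(
            self.values[:, idx],
            self.gene_ids,
            self.cell_ids[idx],
            self.size_factors[idx],
            self.scale_constant,
        )

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense per-cell vector for one gene symbol."""
        idx = self.gene_index()
        if gene not in idx:
            raise KeyError(f"gene {gene!r} not in matrix")
        return np.asarray(self.values[idx[gene]].todense()).ravel()


def _positions(universe: np.ndarray, wanted: Iterable[str], what: str) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(universe)}
    try:
        return np.array([lookup[w] for w in wanted], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"unknown {what} identifier {exc.args[0]!r}") from exc


def new_annotation(
    cell_ids: Iterable[str],
    sample_ids: Iterable[str],
    conditions: Iterable[str],
    reporter_counts: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Build a fresh annotation table with the full column contract."""
    df = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "sample_id": list(sample_ids),
            "condition": list(conditions),
        }
    )
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    per_sample = df.groupby("sample_id")["condition"].nunique()
    if (per_sample > 1).any():
        raise ValueError("condition must be constant within a sample")
    df["reporter_count"] = (
        0 if reporter_counts is None else np.asarray(list(reporter_counts), dtype=int)
    )
    df["qc_pass"] = True
    df["cluster_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["population"] = "Unassigned"
    df["cc_phase"] = pd.array([pd.NA] * len(df), dtype="string")
    df["axis_position"] = np.nan
    return df[list(ANNOTATION_COLUMNS)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _read_id_file(path: Path) -> list[str]:
    """Read a 10x identifier side file; uses the symbol column when present."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            out.append(parts[1] if len(parts) >= 2 else parts[0])
    return out


def read_mtx_bundle(
    matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> ExpressionMatrix:
    """Read a MatrixMarket matrix with gene/barcode side files.

    The MTX file is 1-based coordinate format (genes as rows); duplicate
    coordinates are summed per the MatrixMarket convention.  Identifier files
    must match the matrix dimensions exactly.
    """
    matrix_path = Path(matrix_path)
    for p in (matrix_path, Path(genes_path), Path(barcodes_path)):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    with _open_text(matrix_path) as fh:
        try:
            coo = scipy.io.mmread(fh)
        except Exception as exc:
            raise FormatError(f"invalid MatrixMarket file {matrix_path}: {exc}") from exc
    coo = sp.coo_matrix(coo)
    if coo.data.size and np.any(coo.data != np.floor(coo.data)):
        raise FormatError(f"non-integer entries in {matrix_path}")
    genes = _read_id_file(Path(genes_path))
    barcodes = _read_id_file(Path(barcodes_path))
    if len(genes) != coo.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(genes)} identifiers for {coo.shape[0]} matrix rows"
        )
    if len(barcodes) != coo.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} identifiers for "
            f"{coo.shape[1]} matrix columns"
        )
    mat = ExpressionMatrix(coo.tocsr(), np.array(genes, dtype=object),
                           np.array(barcodes, dtype=object))
    logger.info(
        "read_mtx_bundle: %d genes x %d cells, %d stored entries",
        mat.n_genes, mat.n_cells, mat.counts.nnz,
    )
    return mat


def write_mtx_bundle(matrix: ExpressionMatrix, outdir: str | Path,
                     prefix: str = "") -> dict:
    """Write the matrix as matrix.mtx + genes.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "genes": outdir / f"{prefix}genes.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), matrix.counts.tocoo(), field="integer")
    paths["genes"].write_text(
        "".join(f"{g}\t{g}\n" for g in matrix.gene_ids), encoding="utf-8"
    )
    paths["barcodes"].write_text(
        "".join(f"{b}\n" for b in matrix.cell_ids), encoding="utf-8"
    )
    return paths


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as tab-separated UTF-8 with header.

    Reals are rendered with 12 significant digits so a write -> read -> write
    cycle is byte-identical.
    """
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.12g",
                   encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cell metadata TSV (cell_id, sample_id, condition)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    missing = {"cell_id", "sample_id", "condition"} - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    return df


def read_gmt(path: str | Path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with _open_text(Path(path)) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    if not sets:
        raise FormatError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# (field name, default, min, max) -- closed bounds; None = unbounded.
_NUMERIC_RANGES = {
    "scale_constant": (1e-12, None),
    "nmads": (1e-12, None),
    "n_hvg": (1, None),
    "n_components": (1, None),
    "n_mean_bins": (2, None),
    "k_neighbors": (2, None),
    "resolution": (1e-12, None),
    "logfc_threshold": (0.0, None),
    "min_pct": (0.0, 1.0),
    "alpha": (1e-300, 1.0),
    "consensus_min_frac": (1e-12, 1.0),
    "n_gene_clusters": (2, None),
    "specificity_ratio": (0.0, None),
    "score_bins": (2, None),
    "score_ctrl": (1, None),
    "n_sections": (2, None),
    "min_cells_per_section": (1, None),
    "curve_tol": (1e-300, None),
    "curve_max_iter": (1, None),
    "fc_threshold": (1.0, None),
    "reporter_min": (1, None),
    "seed": (0, None),
}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the documented defaults."""

    # qc_norm
    scale_constant: float = 1e4
    mito_prefix: str = "mt-"
    nmads: float = 3.0
    n_hvg: int = 2000
    n_components: int = 30
    n_mean_bins: int = 20
    # annotate
    reporter_gene: str = "TdTomato"
    reporter_min: int = 1
    k_neighbors: int = 20
    resolution: float = 0.8
    marker_panel_path: str | None = None
    # diffexpr
    logfc_threshold: float = 0.25
    min_pct: float = 0.1
    alpha: float = 0.05
    consensus_min_frac: float = 1.0
    n_gene_clusters: int = 4
    specificity_ratio: float = 2.0
    adjust_method: str = "bonferroni"
    # signatures
    score_bins: int = 24
    score_ctrl: int = 100
    gene_set_paths: tuple = ()
    # zonation
    n_sections: int = 10
    min_cells_per_section: int = 20
    equal_count_sections: bool = False
    anchor_gene: str = "Cxcl12"
    curve_tol: float = 1e-3
    curve_max_iter: int = 50
    # crossspecies
    fc_threshold: float = 1.5
    mapped_denominator: bool = False
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad = []
        for name, (lo, hi) in _NUMERIC_RANGES.items():
            val = getattr(self, name)
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                bad.append(f"{name}={val!r} (not numeric)")
                continue
            if not math.isfinite(float(val)):
                bad.append(f"{name}={val!r} (not finite)")
            elif (lo is not None and val < lo) or (hi is not None and val > hi):
                bad.append(f"{name}={val!r} (outside [{lo}, {hi}])")
        if self.adjust_method not in ("bonferroni", "bh"):
            bad.append(f"adjust_method={self.adjust_method!r}")
        if bad:
            raise ValueError("invalid configuration: " + "; ".join(bad))

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                        encoding="utf-8")
        return path


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; unspecified fields take defaults, unknown keys fail."""
    data = {}
    if path is not None:
        raw = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config {path} is not a mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "gene_set_paths" in data and data["gene_set_paths"] is not None:
        data["gene_set_paths"] = tuple(data["gene_set_paths"])
    return PipelineConfig(**data)
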