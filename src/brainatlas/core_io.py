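"""Domain containers and on-disk formats shared by every pipeline stage.

The pipeline moves four kinds of objects around: a spatially resolved
cell-by-gene table (:class:`CellTable`), a reference single-cell dataset
with a two-level taxonomy (:class:`ReferenceDataset`), a binary barcode
codebook (:class:`Codebook`) and a multi-subunit ligand-receptor database
(:class:`LRDatabase`).  All tables are UTF-8 CSV with a header row; sparse
count matrices use MatrixMarket coordinate format with 1-based indices.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("brainatlas")

__all__ = [
    "CellTable",
    "ReferenceDataset",
    "Codebook",
    "CodebookEntry",
    "LRDatabase",
    "LRPair",
    "AnalysisConfig",
    "FormatError",
    "read_cell_table",
    "write_cell_table",
    "read_codebook",
    "write_codebook",
    "read_lr_database",
    "write_lr_database",
]

# metadata columns required on every cell table
_META_REQUIRED = ("cell_id", "section_id", "x", "y", "z_planes", "volume")
_META_OPTIONAL = (
    "subclass_label",
    "cluster_label",
    "subclass_confidence",
    "cluster_confidence",
    "ccfx",
    "ccfy",
    "ccfz",
    "region_label",
    "neurotransmitter_labels",
)


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected dialect."""


@dataclass
class CellTable:
    """Per-cell coordinates, imaged volume, panel counts and labels.

    ``counts`` holds raw integer counts over ``genes``; ``normalized`` is
    filled in by the preprocessing stage (volume-corrected, mean-rescaled
    real counts) and ``imputed`` by the integration stage (full gene
    universe).  ``meta`` is indexed by ``cell_id`` and carries coordinates
    in micrometres, the imaged volume in cubic micrometres, and any label
    columns attached so far.
    """

    genes: list[str]
    counts: np.ndarray  # (n_cells, n_genes)
    meta: pd.DataFrame  # indexed by cell_id
    normalized: np.ndarray | None = None
    imputed: np.ndarray | None = None
    imputed_genes: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.genes):
            raise ValueError("counts shape must be (n_cells, n_genes)")
        if self.counts.shape[0] != len(self.meta):
            raise ValueError("counts and metadata disagree on cell number")
        if not self.meta.index.is_unique:
            raise FormatError("duplicate cell_id")
        if len(self.meta) and not (self.meta["volume"] > 0).all():
            raise ValueError("volume must be positive")
        for col in ("x", "y"):
            if len(self.meta) and not np.isfinite(self.meta[col]).all():
                raise ValueError(f"non-finite coordinate in column {col}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def cell_ids(self) -> pd.Index:
        return self.meta.index

    def expression(self) -> np.ndarray:
        """Normalized counts if available, raw counts otherwise."""
        return self.normalized if self.normalized is not None else self.counts

    def subset(self, mask: np.ndarray) -> "CellTable":
        """Row subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CellTable(
            genes=self.genes,
            counts=self.counts[idx],
            meta=self.meta.iloc[idx].copy(),
            normalized=None if self.normalized is None else self.normalized[idx],
            imputed=None if self.imputed is None else self.imputed[idx],
            imputed_genes=self.imputed_genes,
        )

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene not in panel: {gene}") from None


@dataclass
class ReferenceDataset:
    """Reference single-cell counts with subclass and cluster labels.

    Clusters nest within subclasses: each cluster label maps to exactly
    one subclass label.  ``partition_label`` is filled by the integration
    stage when subclasses are grouped into integration partitions.
    """

    genes: list[str]
    counts: np.ndarray
    cell_ids: list[str]
    subclass_labels: np.ndarray
    cluster_labels: np.ndarray
    partition_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.subclass_labels = np.asarray(self.subclass_labels, dtype=object)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        # each cluster must map to exactly one subclass
        mapping: dict[object, object] = {}
        for cl, sc in zip(self.cluster_labels, self.subclass_labels):
            if mapping.setdefault(cl, sc) != sc:
                raise ValueError(f"cluster {cl!r} spans multiple subclasses")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def cluster_to_subclass(self) -> dict:
        return {
            cl: sc for cl, sc in zip(self.cluster_labels, self.subclass_labels)
        }


@dataclass(frozen=True)
class CodebookEntry:
    name: str
    barcode: tuple[int, ...]
    is_blank: bool = False

    @property
    def weight(self) -> int:
        return int(sum(self.barcode))


@dataclass
class Codebook:
    """Gene-to-binary-barcode map with fixed barcode length."""

    entries: list[CodebookEntry]
    n_bits: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if len(e.barcode) != self.n_bits:
                raise FormatError(
                    f"barcode length {len(e.barcode)} != n_bits {self.n_bits}"
                )
        codes = [e.barcode for e in self.entries]
        if len(set(codes)) != len(codes):
            raise FormatError("duplicate barcodes")

    def __len__(self) -> int:
        return len(self.entries)

    def barcode_matrix(self) -> np.ndarray:
        return np.array([e.barcode for e in self.entries], dtype=np.uint8)


@dataclass(frozen=True)
class LRPair:
    pair_id: str
    pathway: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise FormatError(f"empty subunit list in pair {self.pair_id}")


@dataclass
class LRDatabase:
    pairs: list[LRPair]

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate pair_id")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with the defaults used throughout.

    Radii are micrometres, volumes cubic micrometres.
    """

    # preprocessing
    volume_thresholds: dict = field(
        default_factory=lambda: {3: (50.0, 1500.0), 5: (80.0, 2500.0), 6: (100.0, 3000.0)}
    )
    target_mean_counts: float = 250.0
    count_quantile: float = 0.01
    doublet_cutoff: float = 0.25
    neurotransmitter_threshold: int = 2
    # integration
    pca_dims: int = 100
    cca_dims: int = 100
    knn_graph_k: int = 15
    anchor_k: int = 5
    transfer_k: int = 100
    impute_k: int = 30
    downsample: int = 100_000
    subclass_gate: float = 0.8
    cluster_gate: float = 0.5
    # spatial modules
    composition_k: int = 50
    leiden_resolution: float = 1.0
    # gradients
    purity_k: int = 50
    # interactions
    r_proximal_strict: float = 15.0
    r_proximal_relaxed: float = 30.0
    r_randomization: float = 100.0
    n_rounds: int = 1000
    alpha: float = 0.05
    min_observed_pairs: int = 20
    lr_min_fold: float = 2.0
    lr_max_p: float = 0.01
    lr_min_frac_positive: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.r_proximal_strict, self.r_proximal_relaxed, self.r_randomization):
            if r <= 0:
                raise ValueError("radii must be positive")
        for p in (self.alpha, self.lr_max_p, self.count_quantile, self.subclass_gate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "volume_thresholds" in data:
            data["volume_thresholds"] = {
                int(k): tuple(v) for k, v in data["volume_thresholds"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["volume_thresholds"] = {
            int(k): list(v) for k, v in data["volume_thresholds"].items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(matrix_path: Path) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Read cells x genes matrix from dense CSV or MTX triplet.

    MTX input expects sidecar files ``<stem>.rows.txt`` (cell ids) and
    ``<stem>.cols.txt`` (gene names) next to the ``.mtx`` file.
    Returns (matrix, gene names, cell ids or None for dense CSV without
    an id column).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path).toarray()
        rows_path = matrix_path.with_suffix(".rows.txt")
        cols_path = matrix_path.with_suffix(".cols.txt")
        if not rows_path.exists() or not cols_path.exists():
            raise FormatError(f"missing sidecar name files for {matrix_path}")
        cell_ids = rows_path.read_text().split()
        genes = cols_path.read_text().split()
        if mat.shape != (len(cell_ids), len(genes)):
            raise FormatError("matrix shape disagrees with sidecar name files")
        return mat, genes, cell_ids
    df = pd.read_csv(matrix_path, index_col=0)
    return df.to_numpy(), list(df.columns), [str(i) for i in df.index]


def read_cell_table(matrix_path: str | Path, metadata_path: str | Path) -> CellTable:
    """Read and join a count matrix with its cell metadata.

    The metadata CSV must be keyed by ``cell_id``; cells present in only
    one of the two files are rejected rather than silently dropped.
    """
    mat, genes, cell_ids = _read_matrix(Path(matrix_path))
    meta = pd.read_csv(metadata_path, dtype={"cell_id": str})
    for col in _META_REQUIRED:
        if col not in meta.columns:
            raise FormatError(f"missing column: {col}")
    if meta["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id in metadata")
    meta = meta.set_index("cell_id")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(mat.shape[0])]
    if set(cell_ids) != set(meta.index):
        raise FormatError("cell ids differ between matrix and metadata")
    meta = meta.loc[cell_ids]
    if "neurotransmitter_labels" in meta.columns:
        meta["neurotransmitter_labels"] = meta["neurotransmitter_labels"].map(
            lambda v: frozenset() if pd.isna(v) or v == "" else frozenset(str(v).split(";"))
        )
    counts = np.asarray(mat, dtype=float)
    if np.allclose(counts, np.round(counts)):
        counts = np.round(counts).astype(np.int64)
    logger.info("read_cell_table: %d cells x %d genes", counts.shape[0], counts.shape[1])
    return CellTable(genes=genes, counts=counts, meta=meta)


def write_cell_table(
    table: CellTable,
    matrix_path: str | Path,
    metadata_path: str | Path,
    sparse: bool = False,
) -> None:
    """Write a cell table back to disk in a form ``read_cell_table`` accepts."""
    matrix_path = Path(matrix_path)
    if sparse or matrix_path.suffix == ".mtx":
        sp = scipy.sparse.coo_matrix(table.counts)
        scipy.io.mmwrite(str(matrix_path), sp, field="integer")
        matrix_path.with_suffix(".rows.txt").write_text(
            "\n".join(str(c) for c in table.cell_ids) + ("\n" if len(table.meta) else "")
        )
        matrix_path.with_suffix(".cols.txt").write_text("\n".join(table.genes) + "\n")
    else:
        df = pd.DataFrame(table.counts, index=table.cell_ids, columns=table.genes)
        df.index.name = "cell_id"
        df.to_csv(matrix_path)
    meta = table.meta.copy()
    if "neurotransmitter_labels" in meta.columns:
        meta["neurotransmitter_labels"] = meta["neurotransmitter_labels"].map(
            lambda v: ";".join(sorted(v)) if isinstance(v, (set, frozenset)) else v
        )
    meta.index.name = "cell_id"
    meta.to_csv(metadata_path)


def read_codebook(path: str | Path) -> Codebook:
    """Read a ``name,barcode`` CSV codebook; blanks are named ``Blank-<k>``."""
    df = pd.read_csv(path, dtype=str)
    for col in ("name", "barcode"):
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    entries = []
    n_bits = None
    for _, row in df.iterrows():
        bc = str(row["barcode"])
        if set(bc) - {"0", "1"}:
            raise FormatError(f"non-binary barcode for {row['name']}: {bc}")
        if n_bits is None:
            n_bits = len(bc)
        elif len(bc) != n_bits:
            raise FormatError(
                f"barcode length mismatch for {row['name']}: {len(bc)} != {n_bits}"
            )
        name = str(row["name"])
        entries.append(
            CodebookEntry(
                name=name,
                barcode=tuple(int(c) for c in bc),
                is_blank=name.startswith("Blank-"),
            )
        )
    if n_bits is None:
        raise FormatError("empty codebook")
    return Codebook(entries=entries, n_bits=n_bits)


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    rows = [
        {"name": e.name, "barcode": "".join(str(b) for b in e.barcode)}
        for e in codebook.entries
    ]
    pd.DataFrame(rows, columns=["name", "barcode"]).to_csv(path, index=False)


def read_lr_database(path: str | Path) -> LRDatabase:
    """Read a ligand-receptor pair table with ``;``-separated subunit lists."""
    df = pd.read_csv(path, dtype=str)
    for col in ("pair_id", "pathway", "ligand_subunits", "receptor_subunits"):
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    pairs = []
    for _, row in df.iterrows():
        lig = tuple(g for g in str(row["ligand_subunits"]).split(";") if g)
        rec = tuple(g for g in str(row["receptor_subunits"]).split(";") if g)
        pairs.append(
            LRPair(
                pair_id=str(row["pair_id"]),
                pathway=str(row["pathway"]),
                ligand_subunits=lig,
                receptor_subunits=rec,
            )
        )
    return LRDatabase(pairs=pairs)


def write_lr_database(db: LRDatabase, path: str | Path) -> None:
    rows = [
        {
            "pair_id": p.pair_id,
            "pathway": p.pathway,
            "ligand_subunits": ";".join(p.ligand_subunits),
            "receptor_subunits": ";".join(p.receptor_subunits),
        }
        for p in db.pairs
    ]
    pd.DataFrame(
        rows, columns=["pair_id", "pathway", "ligand_subunits", "receptor_subunits"]
    ).to_csv(path, index=False)
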