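"""Cell-table QC, count normalization and neurotransmitter assignment.

The QC pipeline runs volume filter -> volume normalization -> mean
rescaling -> total-count quantile filter -> doublet hook.  Each step only
removes cells or rescales counts, never reorders genes.  All threshold
comparisons are strict; boundary values survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import CellTable

logger = logging.getLogger("brainatlas")

__all__ = [
    "VolumeThresholds",
    "NeurotransmitterRules",
    "filter_by_volume",
    "normalize_counts",
    "filter_count_quantiles",
    "assign_neurotransmitters",
    "doublet_hook",
    "run_qc",
]


@dataclass(frozen=True)
class VolumeThresholds:
    """Acceptable imaged-volume windows (um^3) keyed by z-plane count.

    Very small volumes are segmentation artifacts; very large ones are
    unseparated z-overlapping cells.  The window widens with the number
    of imaged z-planes because more planes capture more soma.
    """

    by_z_planes: dict = field(
        default_factory=lambda: {
            3: (50.0, 1500.0),
            5: (80.0, 2500.0),
            6: (100.0, 3000.0),
        }
    )

    def __post_init__(self) -> None:
        for z, (lo, hi) in self.by_z_planes.items():
            if lo >= hi:
                raise ValueError(f"volume window for z={z} must be ordered")


@dataclass(frozen=True)
class NeurotransmitterRules:
    """Marker transporter genes per neurotransmitter group.

    A cell carries a group if any of that group's markers reaches
    ``threshold`` raw counts; groups may overlap (e.g. cells co-expressing
    glutamate and GABA transporters carry both labels).
    """

    markers: dict = field(
        default_factory=lambda: {
            "Glut": ("Slc17a7", "Slc17a6", "Slc17a8"),
            "Gaba": ("Slc32a1",),
            "Sero": ("Slc6a4",),
            "Dopa": ("Slc6a3",),
            "Choli": ("Slc18a3",),
            "Glycine": ("Slc6a5",),
            "Nora": ("Slc6a2",),
            "Hist": ("Hdc",),
        }
    )
    threshold: int = 2

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


def filter_by_volume(
    cells: CellTable, thresholds: VolumeThresholds = VolumeThresholds()
) -> CellTable:
    """Remove cells with volume strictly outside their z-plane window."""
    z_values = cells.meta["z_planes"].to_numpy()
    unknown = set(np.unique(z_values)) - set(thresholds.by_z_planes)
    if unknown:
        raise ValueError(f"no volume thresholds for z_planes values {sorted(unknown)}")
    vol = cells.meta["volume"].to_numpy()
    keep = np.ones(cells.n_cells, dtype=bool)
    for z, (lo, hi) in thresholds.by_z_planes.items():
        at_z = z_values == z
        keep &= ~(at_z & ((vol < lo) | (vol > hi)))
    logger.info("filter_by_volume: removed %d / %d cells", (~keep).sum(), cells.n_cells)
    return cells.subset(keep)


def normalize_counts(cells: CellTable, target_mean: float = 250.0) -> CellTable:
    """Divide counts by imaged volume, then rescale globally so the mean
    per-cell total equals ``target_mean``.  Output lands in ``normalized``;
    raw integer counts are preserved."""
    if cells.n_cells == 0:
        raise ValueError("cannot normalize an empty table")
    vol = cells.meta["volume"].to_numpy()[:, None]
    per_volume = cells.counts / vol
    mean_total = per_volume.sum(axis=1).mean()
    if mean_total == 0:
        raise ValueError("all counts are zero")
    out = cells.subset(np.arange(cells.n_cells))
    out.normalized = per_volume * (target_mean / mean_total)
    return out


def filter_count_quantiles(cells: CellTable, q: float = 0.01) -> CellTable:
    """Remove cells whose total (normalized) counts fall strictly below the
    q-quantile or above the (1-q)-quantile (linear-interpolation quantiles)."""
    if not 0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    totals = cells.expression().sum(axis=1)
    lo, hi = np.quantile(totals, [q, 1 - q])
    keep = ~((totals < lo) | (totals > hi))
    logger.info(
        "filter_count_quantiles: removed %d / %d cells", (~keep).sum(), cells.n_cells
    )
    return cells.subset(keep)


def assign_neurotransmitters(
    cells: CellTable, rules: NeurotransmitterRules = NeurotransmitterRules()
) -> CellTable:
    """Attach neurotransmitter labels from raw marker counts.

    Raw (pre-normalization) integer counts are compared against the
    threshold because it is a copy-number rule.  Marker genes absent from
    the panel skip their group with a warning.
    """
    out = cells.subset(np.arange(cells.n_cells))
    labels = [set() for _ in range(cells.n_cells)]
    for group, markers in rules.markers.items():
        present = [g for g in markers if g in cells.genes]
        if not present:
            logger.warning(
                "assign_neurotransmitters: no markers of group %s in panel", group
            )
            continue
        cols = [cells.gene_index(g) for g in present]
        hit = (cells.counts[:, cols] >= rules.threshold).any(axis=1)
        for i in np.flatnonzero(hit):
            labels[i].add(group)
    out.meta = out.meta.copy()
    out.meta["neurotransmitter_labels"] = [frozenset(s) for s in labels]
    return out


def doublet_hook(
    cells: CellTable, scores: dict | None = None, cutoff: float = 0.25
) -> CellTable:
    """Remove cells whose externally computed doublet score exceeds the
    cutoff (strict).  Without scores this is the identity: doublet scoring
    itself is delegated to the caller."""
    if scores is None:
        return cells
    s = np.array([scores.get(cid, 0.0) for cid in cells.cell_ids])
    keep = ~(s > cutoff)
    logger.info("doublet_hook: removed %d / %d cells", (~keep).sum(), cells.n_cells)
    return cells.subset(keep)


def run_qc(
    cells: CellTable,
    thresholds: VolumeThresholds = VolumeThresholds(),
    target_mean: float = 250.0,
    q: float = 0.01,
    doublet_scores: dict | None = None,
    doublet_cutoff: float = 0.25,
) -> CellTable:
    """Full QC pipeline in canonical order."""
    cells = filter_by_volume(cells, thresholds)
    cells = normalize_counts(cells, target_mean)
    cells = filter_count_quantiles(cells, q)
    cells = doublet_hook(cells, doublet_scores, doublet_cutoff)
    return cells
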