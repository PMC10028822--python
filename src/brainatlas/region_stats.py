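"""Region-level composition summaries.

Enrichment scores compare a cell type's prevalence inside a region to
its prevalence across the whole dataset, either as fractions of cells
(volume-free, the default) or as densities per region volume.  Local
complexity counts distinct neuronal subclasses among each neuron's 50
nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core_io import CellTable

__all__ = [
    "EnrichmentMatrix",
    "enrichment_scores",
    "local_complexity",
    "split_by_ccfx",
    "composition_fractions",
]


@dataclass
class EnrichmentMatrix:
    """Cell types x regions fold-change matrix.

    In fraction mode the score of type t in region r is
    (n_tr / n_.r) / (n_t. / n_..); in density mode the per-volume
    analogue.  In fraction mode the type-frequency-weighted column
    average of scores equals 1.
    """

    scores: pd.DataFrame  # rows: types, columns: regions
    mode: str  # "fraction" | "density"
    empty_regions: list

    def __post_init__(self) -> None:
        if (self.scores.to_numpy() < 0).any():
            raise ValueError("enrichment scores must be non-negative")


def enrichment_scores(
    types: np.ndarray,
    regions: np.ndarray,
    mode: str = "fraction",
    region_volume: dict | None = None,
) -> EnrichmentMatrix:
    """Fold change of each type's fraction (or density) per region."""
    if mode not in ("fraction", "density"):
        raise ValueError("mode must be 'fraction' or 'density'")
    if mode == "density" and region_volume is None:
        raise ValueError("density mode requires region volumes")
    types = np.asarray(types, dtype=object)
    regions = np.asarray(regions, dtype=object)
    counts = pd.crosstab(pd.Series(types, name="type"), pd.Series(regions, name="region"))
    if mode == "density":
        missing = set(counts.columns) - set(region_volume)
        if missing:
            raise ValueError(f"regions without volume: {sorted(missing)}")
        vols = np.array([region_volume[r] for r in counts.columns], dtype=float)
        dens = counts.to_numpy() / vols[None, :]
        overall = counts.sum(axis=1).to_numpy() / vols.sum()
        scores = dens / overall[:, None]
    else:
        col_tot = counts.sum(axis=0).to_numpy().astype(float)
        frac_in = np.divide(
            counts.to_numpy(),
            col_tot[None, :],
            out=np.zeros(counts.shape),
            where=col_tot[None, :] > 0,
        )
        overall = counts.sum(axis=1).to_numpy() / counts.to_numpy().sum()
        scores = frac_in / overall[:, None]
    empty = [c for c, t in zip(counts.columns, counts.sum(axis=0)) if t == 0]
    return EnrichmentMatrix(
        scores=pd.DataFrame(scores, index=counts.index, columns=counts.columns),
        mode=mode,
        empty_regions=empty,
    )


def local_complexity(
    cells: CellTable, subclass_of: dict | None = None, k: int = 50
) -> pd.Series:
    """Distinct neuronal subclasses among each neuron's k nearest neighbors.

    Searches are per section, Euclidean, ties broken by index.  Sections
    with k or fewer neurons are flagged (NaN) rather than scored.
    ``subclass_of`` optionally overrides the ``subclass_label`` column.
    """
    if subclass_of is None:
        labels = cells.meta["subclass_label"].to_numpy(dtype=object)
    else:
        labels = np.array([subclass_of[c] for c in cells.cell_ids], dtype=object)
    out = pd.Series(np.nan, index=cells.cell_ids, name="local_complexity")
    for section, idx in cells.meta.groupby("section_id").indices.items():
        if len(idx) <= k:
            continue
        pts = cells.meta.iloc[idx][["x", "y"]].to_numpy()
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, nbrs = nn.kneighbors(pts)
        sec_labels = labels[idx]
        vals = [len(set(sec_labels[row[1:]])) for row in nbrs]
        out.iloc[idx] = vals
    return out


def split_by_ccfx(cells: CellTable, region: str) -> pd.Series:
    """Split one region into anterior/posterior halves along ccfx.

    The cut is the midpoint of the region's ccfx range; cells strictly
    below go anterior, at or above go posterior.  Other regions keep
    their label.
    """
    if "ccfx" not in cells.meta.columns:
        raise ValueError("ccfx coordinates required")
    labels = cells.meta["region_label"].astype(object).copy()
    mask = labels == region
    if not mask.any():
        return labels
    ccfx = cells.meta.loc[mask, "ccfx"]
    cut = (ccfx.min() + ccfx.max()) / 2
    labels[mask] = np.where(ccfx < cut, f"{region}-anterior", f"{region}-posterior")
    return labels


def composition_fractions(labels: np.ndarray, group_by: np.ndarray) -> pd.DataFrame:
    """Per-group cell-type fractions (each group sums to 1); empty groups
    are dropped."""
    df = pd.crosstab(
        pd.Series(np.asarray(group_by, dtype=object), name="group"),
        pd.Series(np.asarray(labels, dtype=object), name="type"),
    )
    df = df[df.sum(axis=1) > 0]
    return df.div(df.sum(axis=1), axis=0)
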