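"""Synthetic reference and spatial datasets with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: region-structured homogeneous Poisson point patterns, per-cluster
negative-binomial expression, linear spatial expression gradients,
pairwise spatial attraction between cell types (a Thomas-like parent/
daughter process), and ligand-receptor upregulation in proximal cell
pairs.  Every dataset comes with a :class:`PlantedTruth` sidecar so each
pipeline stage can be scored against what was actually planted.

Counts follow a negative binomial parameterized by (mean m, dispersion r)
with variance m + m^2/r; ``r = inf`` recovers Poisson.  Before any QC
normalization, per-cell counts scale with the imaged volume, so the
volume-normalization step of preprocessing is exercised nontrivially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import CellTable, LRDatabase, LRPair, ReferenceDataset

__all__ = [
    "RegionSpec",
    "ClusterSpec",
    "SubclassSpec",
    "GradientSpec",
    "AttractionSpec",
    "LREffectSpec",
    "SimulationSpec",
    "PlantedTruth",
    "simulate_reference",
    "simulate_section",
    "simulate_measured",
    "default_specs",
]


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned rectangle with per-subclass intensity (cells per mm^2)."""

    name: str
    x0: float
    y0: float
    x1: float
    y1: float
    intensity: dict  # subclass name -> cells / mm^2

    @property
    def area_mm2(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0) / 1e6

    def overlaps(self, other: "RegionSpec") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    profile: tuple  # mean expression per gene over the full universe


@dataclass(frozen=True)
class SubclassSpec:
    name: str
    clusters: tuple  # ClusterSpec, >= 1
    dispersion: float = 5.0  # NB dispersion; inf -> Poisson
    is_neuron: bool = True
    category: str = "neuronal"  # neuronal | astrocyte | other


@dataclass(frozen=True)
class GradientSpec:
    """Linear shift of cluster means for a gene set along a spatial axis."""

    subclass: str
    genes: tuple
    axis: str  # "x" or "y"
    slope: float  # counts per um, applied as profile + slope * (coord - min)


@dataclass(frozen=True)
class AttractionSpec:
    """Each type-A cell spawns a type-B daughter nearby with given probability."""

    type_a: str
    type_b: str
    radius: float  # um
    attach_prob: float


@dataclass(frozen=True)
class LREffectSpec:
    """Fold upregulation of ligand genes in type-A cells and receptor genes
    in type-B cells when the two lie within ``radius`` of each other."""

    pair_id: str
    type_a: str
    type_b: str
    fold: float
    radius: float  # um


@dataclass
class SimulationSpec:
    genes: list
    panel: list
    regions: list
    subclasses: list
    gradient_specs: list = field(default_factory=list)
    attraction_specs: list = field(default_factory=list)
    lr_effect_specs: list = field(default_factory=list)
    lr_database: LRDatabase | None = None
    volume_mean: float = 300.0  # um^3
    volume_sigma: float = 0.25  # lognormal sigma of volume
    z_planes: int = 5

    def __post_init__(self) -> None:
        universe = set(self.genes)
        if not set(self.panel) <= universe:
            raise ValueError("panel must be a subset of the gene universe")
        for r in self.regions:
            if any(v < 0 for v in r.intensity.values()):
                raise ValueError(f"negative intensity in region {r.name}")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"regions {a.name} and {b.name} overlap")
        for e in self.lr_effect_specs:
            if e.fold < 1:
                raise ValueError("lr_effect fold must be >= 1")
        for sc in self.subclasses:
            for cl in sc.clusters:
                if len(cl.profile) != len(self.genes):
                    raise ValueError(
                        f"profile length mismatch for cluster {cl.name}"
                    )

    def subclass(self, name: str) -> SubclassSpec:
        for sc in self.subclasses:
            if sc.name == name:
                return sc
        raise KeyError(name)


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a simulated dataset."""

    subclass: list
    cluster: list
    region: list
    interacting_pairs: list  # [(type_a, type_b)]
    lr_upregulated: list  # [(pair_id, type_a, type_b)]
    gradient_axes: dict  # subclass -> axis

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "subclass": list(self.subclass),
                    "cluster": list(self.cluster),
                    "region": list(self.region),
                    "interacting_pairs": [list(p) for p in self.interacting_pairs],
                    "lr_upregulated": [list(p) for p in self.lr_upregulated],
                    "gradient_axes": self.gradient_axes,
                },
                indent=1,
            )
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + mean^2/dispersion (elementwise)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not np.any(pos):
        return out
    if np.isinf(dispersion):
        out[pos] = rng.poisson(mean[pos])
    else:
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_reference(
    spec: SimulationSpec, n_per_cluster: int, seed: int
) -> ReferenceDataset:
    """Draw a reference single-cell dataset: NB counts around each cluster
    profile over the full gene universe, with subclass/cluster labels."""
    if n_per_cluster < 2:
        raise ValueError("n_per_cluster must be >= 2")
    rng = np.random.default_rng(seed)
    blocks, subclass_labels, cluster_labels = [], [], []
    for sc in spec.subclasses:
        for cl in sc.clusters:
            mean = np.tile(np.asarray(cl.profile, dtype=float), (n_per_cluster, 1))
            blocks.append(_nb_draw(rng, mean, sc.dispersion))
            subclass_labels += [sc.name] * n_per_cluster
            cluster_labels += [cl.name] * n_per_cluster
    counts = np.vstack(blocks)
    cell_ids = [f"ref_{i}" for i in range(counts.shape[0])]
    return ReferenceDataset(
        genes=list(spec.genes),
        counts=counts,
        cell_ids=cell_ids,
        subclass_labels=np.array(subclass_labels, dtype=object),
        cluster_labels=np.array(cluster_labels, dtype=object),
    )


def _bbox(regions) -> tuple[float, float, float, float]:
    return (
        min(r.x0 for r in regions),
        min(r.y0 for r in regions),
        max(r.x1 for r in regions),
        max(r.y1 for r in regions),
    )


def simulate_section(
    spec: SimulationSpec, seed: int, section_id: str = "sec0"
) -> tuple[CellTable, PlantedTruth]:
    """Simulate one imaged section.

    Parent cells are homogeneous Poisson within each region at the stated
    per-subclass intensity.  Attraction specs then spawn type-B daughters
    uniformly within ``radius`` of each type-A parent with probability
    ``attach_prob``.  Expression is drawn per cell from its cluster
    profile (with gradient shifts and ligand-receptor proximity effects
    applied to the mean), scaled by the cell's sampled volume, and
    restricted to the measurement panel.
    """
    rng = np.random.default_rng(seed)
    xs, ys, subclass, cluster, region = [], [], [], [], []

    for reg in spec.regions:
        for sc_name, lam in reg.intensity.items():
            n = rng.poisson(lam * reg.area_mm2)
            if n == 0:
                continue
            sc = spec.subclass(sc_name)
            xs.append(rng.uniform(reg.x0, reg.x1, n))
            ys.append(rng.uniform(reg.y0, reg.y1, n))
            subclass += [sc_name] * n
            ks = rng.integers(0, len(sc.clusters), n)
            cluster += [sc.clusters[k].name for k in ks]
            region += [reg.name] * n

    xs = np.concatenate(xs) if xs else np.empty(0)
    ys = np.concatenate(ys) if ys else np.empty(0)
    x0, y0, x1, y1 = _bbox(spec.regions)

    # attractive daughters: Thomas-like parent/daughter process
    for att in spec.attraction_specs:
        if att.attach_prob <= 0:
            continue
        parents = [i for i, s in enumerate(subclass) if s == att.type_a]
        sc_b = spec.subclass(att.type_b)
        new_x, new_y = [], []
        for i in parents:
            if rng.uniform() >= att.attach_prob:
                continue
            rad = att.radius * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            new_x.append(np.clip(xs[i] + rad * np.cos(ang), x0, x1))
            new_y.append(np.clip(ys[i] + rad * np.sin(ang), y0, y1))
        if new_x:
            xs = np.concatenate([xs, new_x])
            ys = np.concatenate([ys, new_y])
            for nx, ny in zip(new_x, new_y):
                subclass.append(att.type_b)
                k = rng.integers(0, len(sc_b.clusters))
                cluster.append(sc_b.clusters[k].name)
                reg_name = next(
                    (
                        r.name
                        for r in spec.regions
                        if r.x0 <= nx <= r.x1 and r.y0 <= ny <= r.y1
                    ),
                    spec.regions[0].name,
                )
                region.append(reg_name)

    n_cells = len(subclass)
    genes = list(spec.genes)
    profile_of = {
        cl.name: np.asarray(cl.profile, dtype=float)
        for sc in spec.subclasses
        for cl in sc.clusters
    }
    dispersion_of = {sc.name: sc.dispersion for sc in spec.subclasses}
    means = np.vstack([profile_of[c] for c in cluster]) if n_cells else np.empty((0, len(genes)))

    gi = {g: j for j, g in enumerate(genes)}
    for gr in spec.gradient_specs:
        coord = xs if gr.axis == "x" else ys
        shift = gr.slope * (coord - coord.min()) if n_cells else coord
        rows = np.array([s == gr.subclass for s in subclass])
        cols = [gi[g] for g in gr.genes]
        for j in cols:
            means[rows, j] = np.maximum(means[rows, j] + shift[rows], 0.0)

    # ligand-receptor proximity effects on the expression means
    if spec.lr_effect_specs:
        if spec.lr_database is None:
            raise ValueError("lr_effect_specs require an lr_database")
        pair_of = {p.pair_id: p for p in spec.lr_database.pairs}
        pts = np.column_stack([xs, ys])
        tree = cKDTree(pts) if n_cells else None
        sub_arr = np.array(subclass, dtype=object)
        for eff in spec.lr_effect_specs:
            pair = pair_of[eff.pair_id]
            a_idx = np.flatnonzero(sub_arr == eff.type_a)
            b_idx = np.flatnonzero(sub_arr == eff.type_b)
            if len(a_idx) == 0 or len(b_idx) == 0:
                continue
            tree_b = cKDTree(pts[b_idx])
            tree_a = cKDTree(pts[a_idx])
            a_hit = a_idx[
                [len(nb) > 0 for nb in tree_b.query_ball_point(pts[a_idx], eff.radius)]
            ]
            b_hit = b_idx[
                [len(nb) > 0 for nb in tree_a.query_ball_point(pts[b_idx], eff.radius)]
            ]
            for g in pair.ligand_subunits:
                means[a_hit, gi[g]] *= eff.fold
            for g in pair.receptor_subunits:
                means[b_hit, gi[g]] *= eff.fold

    volumes = spec.volume_mean * rng.lognormal(
        -0.5 * spec.volume_sigma**2, spec.volume_sigma, n_cells
    )
    means *= (volumes / spec.volume_mean)[:, None]

    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    for i in range(n_cells):
        counts[i] = _nb_draw(rng, means[i], dispersion_of[_sub_of(subclass, i)])

    panel_idx = [gi[g] for g in spec.panel]
    meta = pd.DataFrame(
        {
            "section_id": section_id,
            "x": xs,
            "y": ys,
            "z_planes": spec.z_planes,
            "volume": volumes,
            "subclass_label": subclass,
            "cluster_label": cluster,
            "subclass_confidence": 1.0,
            "cluster_confidence": 1.0,
            "region_label": region,
        },
        index=pd.Index([f"{section_id}_c{i}" for i in range(n_cells)], name="cell_id"),
    )
    table = CellTable(genes=list(spec.panel), counts=counts[:, panel_idx], meta=meta)
    truth = PlantedTruth(
        subclass=list(subclass),
        cluster=list(cluster),
        region=list(region),
        interacting_pairs=[
            (a.type_a, a.type_b) for a in spec.attraction_specs if a.attach_prob > 0
        ],
        lr_upregulated=[
            (e.pair_id, e.type_a, e.type_b) for e in spec.lr_effect_specs
        ],
        gradient_axes={g.subclass: g.axis for g in spec.gradient_specs},
    )
    return table, truth


def _sub_of(subclass: list, i: int) -> str:
    return subclass[i]


def simulate_measured(
    spec: SimulationSpec, n_per_cluster: int, seed: int
) -> tuple[CellTable, PlantedTruth]:
    """Draw a measured (panel-restricted) dataset without spatial structure.

    Convenience for exercising integration: counts come from the same
    cluster profiles as :func:`simulate_reference`, restricted to the
    panel and scaled by a sampled per-cell volume; positions are uniform
    in a unit box and carry no signal.
    """
    rng = np.random.default_rng(seed)
    gi = {g: j for j, g in enumerate(spec.genes)}
    panel_idx = [gi[g] for g in spec.panel]
    blocks, subclass, cluster = [], [], []
    vols = []
    for sc in spec.subclasses:
        for cl in sc.clusters:
            v = spec.volume_mean * rng.lognormal(
                -0.5 * spec.volume_sigma**2, spec.volume_sigma, n_per_cluster
            )
            mean = np.asarray(cl.profile, dtype=float)[None, :] * (
                v / spec.volume_mean
            )[:, None]
            blocks.append(_nb_draw(rng, mean, sc.dispersion))
            subclass += [sc.name] * n_per_cluster
            cluster += [cl.name] * n_per_cluster
            vols.append(v)
    counts = np.vstack(blocks)[:, panel_idx]
    n = counts.shape[0]
    meta = pd.DataFrame(
        {
            "section_id": "meas0",
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "z_planes": spec.z_planes,
            "volume": np.concatenate(vols),
        },
        index=pd.Index([f"meas_c{i}" for i in range(n)], name="cell_id"),
    )
    table = CellTable(genes=list(spec.panel), counts=counts, meta=meta)
    truth = PlantedTruth(
        subclass=subclass,
        cluster=cluster,
        region=["box"] * n,
        interacting_pairs=[],
        lr_upregulated=[],
        gradient_axes={},
    )
    return table, truth


# ---------------------------------------------------------------------------
# named fixtures used throughout the test and acceptance suites


def _marker_profiles(
    n_genes: int,
    n_subclasses: int,
    n_clusters_per_subclass: int,
    base: float = 0.5,
    subclass_level: float = 8.0,
    cluster_level: float = 6.0,
    markers_per_subclass: int = 6,
    markers_per_cluster: int = 3,
) -> tuple[list, list]:
    """Block-marker cluster profiles: each subclass owns a block of elevated
    genes, each cluster a smaller sub-block on top."""
    genes = [f"g{j:03d}" for j in range(n_genes)]
    subclasses = []
    pos = 0
    for s in range(n_subclasses):
        sub_block = range(pos, pos + markers_per_subclass)
        pos += markers_per_subclass
        clusters = []
        for c in range(n_clusters_per_subclass):
            profile = np.full(n_genes, base)
            profile[list(sub_block)] = subclass_level
            cl_block = range(pos + c * markers_per_cluster, pos + (c + 1) * markers_per_cluster)
            profile[list(cl_block)] = cluster_level
            clusters.append(
                ClusterSpec(name=f"S{s}_C{c}", profile=tuple(profile))
            )
        pos += n_clusters_per_subclass * markers_per_cluster
        subclasses.append(
            SubclassSpec(name=f"S{s}", clusters=tuple(clusters), dispersion=5.0)
        )
    return genes, subclasses


def _two_type_spec(
    attach_prob: float,
    radius: float = 10.0,
    intensity_a: float = 200.0,
    intensity_b: float = 200.0,
    side: float = 1000.0,
) -> SimulationSpec:
    genes, subclasses = _marker_profiles(30, 2, 1, markers_per_subclass=8, markers_per_cluster=4)
    region = RegionSpec(
        "sq", 0.0, 0.0, side, side, {"S0": intensity_a, "S1": intensity_b}
    )
    att = [AttractionSpec("S0", "S1", radius, attach_prob)] if attach_prob > 0 else []
    return SimulationSpec(
        genes=genes,
        panel=genes,
        regions=[region],
        subclasses=subclasses,
        attraction_specs=att,
    )


def default_specs() -> dict:
    """Named simulation fixtures used by the acceptance suite.

    csr          two types at complete spatial randomness (no interaction)
    attraction   planted S0-S1 attraction (radius 10 um, attach prob 0.5)
    two_region   two rectangles with disjoint dominant subclasses
    gradient     one subclass with a planted linear expression gradient
                 along x next to one with well-separated discrete clusters
    lr_effect    attraction fixture plus a 3-fold ligand-receptor
                 upregulation in proximal S0-S1 pairs
    integration  10 subclasses x 3 clusters, 150-gene universe, 100-gene
                 panel, for label transfer and imputation
    """
    specs = {}
    specs["csr"] = _two_type_spec(0.0)
    specs["attraction"] = _two_type_spec(0.5, radius=10.0)

    # two regions, disjoint dominant subclasses, light shared background
    genes, subclasses = _marker_profiles(40, 5, 1, markers_per_subclass=6, markers_per_cluster=2)
    top = RegionSpec(
        "west", 0.0, 0.0, 1000.0, 1000.0, {"S0": 1200.0, "S1": 1200.0, "S4": 100.0}
    )
    bottom = RegionSpec(
        "east", 1000.0, 0.0, 2000.0, 1000.0, {"S2": 1200.0, "S3": 1200.0, "S4": 100.0}
    )
    specs["two_region"] = SimulationSpec(
        genes=genes, panel=genes, regions=[top, bottom], subclasses=subclasses
    )

    # gradient subclass (3 overlapping clusters along x, planted gradient)
    # beside a subclass with cleanly separated clusters
    n_genes = 60
    genes = [f"g{j:03d}" for j in range(n_genes)]
    grad_genes = tuple(genes[0:16])

    def _profile(blocks: dict, base: float = 5.0) -> tuple:
        p = np.full(n_genes, base)
        for j, v in blocks.items():
            p[j] = v
        return tuple(p)

    grad_clusters = tuple(
        ClusterSpec(f"G_C{c}", _profile({j: 1.0 for j in range(0, 16)}))
        for c in range(3)
    )
    sep_clusters = tuple(
        ClusterSpec(
            f"D_C{c}",
            _profile({j: 12.0 for j in range(20 + 8 * c, 28 + 8 * c)}),
        )
        for c in range(3)
    )
    grad_sub = SubclassSpec("Grad", grad_clusters, dispersion=20.0)
    sep_sub = SubclassSpec("Discrete", sep_clusters, dispersion=20.0)
    region = RegionSpec(
        "sq", 0.0, 0.0, 1000.0, 1000.0, {"Grad": 600.0, "Discrete": 600.0}
    )
    specs["gradient"] = SimulationSpec(
        genes=genes,
        panel=genes,
        regions=[region],
        subclasses=[grad_sub, sep_sub],
        gradient_specs=[GradientSpec("Grad", grad_genes, "x", slope=0.01)],
    )

    # ligand-receptor effect on top of the planted attraction; kept sparse
    # so that cells proximal to one partner are rarely proximal to others
    # (non-proximal pairs must remain a clean control group)
    lr_spec = _two_type_spec(
        0.25, radius=10.0, intensity_a=25.0, intensity_b=25.0, side=2500.0
    )
    lrdb = LRDatabase(
        pairs=[
            LRPair("L1", "Wnt", ("g020",), ("g021", "g022")),
            LRPair("L2", "Bmp", ("g023",), ("g024",)),
            LRPair("L3", "Fgf", ("g025", "g026"), ("g027",)),
        ]
    )
    lr_spec.lr_database = lrdb
    lr_spec.lr_effect_specs = [LREffectSpec("L1", "S0", "S1", fold=3.0, radius=30.0)]
    # ensure LR genes have a workable baseline expression
    new_subclasses = []
    for sc in lr_spec.subclasses:
        new_clusters = []
        for cl in sc.clusters:
            p = np.asarray(cl.profile)
            p[20:28] = 1.0
            new_clusters.append(ClusterSpec(cl.name, tuple(p)))
        new_subclasses.append(
            SubclassSpec(sc.name, tuple(new_clusters), sc.dispersion, sc.is_neuron, sc.category)
        )
    lr_spec.subclasses = new_subclasses
    specs["lr_effect"] = lr_spec

    # integration fixture: 10 subclasses x 3 clusters over 150 genes,
    # 100-gene panel (the withheld 50 genes exercise imputation)
    genes, subclasses = _marker_profiles(
        150, 10, 3, markers_per_subclass=6, markers_per_cluster=3
    )
    panel = [g for j, g in enumerate(genes) if j % 3 != 2][:100]
    region = RegionSpec("sq", 0.0, 0.0, 1000.0, 1000.0, {})
    specs["integration"] = SimulationSpec(
        genes=genes, panel=panel, regions=[region], subclasses=subclasses
    )
    return specs
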