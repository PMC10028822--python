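import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainatlas import synthetic
from brainatlas.core_io import CellTable, LRDatabase, LRPair
from brainatlas.interactions import (
    ProximityParams,
    count_proximal,
    eligible_types,
    lr_score,
    lr_test,
    randomization_null,
    upregulated_genes,
)
from brainatlas.interactions import test_interactions as interaction_test
from brainatlas.region_stats import enrichment_scores


def _brute_force_count(xy_a, xy_b, r, same_set=False):
    n = 0
    for i, p in enumerate(xy_a):
        js = range(i + 1, len(xy_b)) if same_set else range(len(xy_b))
        for j in js:
            if np.linalg.norm(p - xy_b[j]) < r:
                n += 1
    return n


class TestCountProximal:
    def test_two_cells_within_radius(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[10.0, 0.0]])
        assert count_proximal(a, b, 15.0) == 1

    def test_distance_exactly_r_excluded(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[15.0, 0.0]])
        assert count_proximal(a, b, 15.0) == 0

    def test_matches_brute_force_cross(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 300, (100, 2))
        b = rng.uniform(0, 300, (100, 2))
        assert count_proximal(a, b, 25.0) == _brute_force_count(a, b, 25.0)

    def test_matches_brute_force_same_set(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 300, (120, 2))
        assert count_proximal(a, a, 25.0, same_set=True) == _brute_force_count(
            a, a, 25.0, same_set=True
        )

    def test_sections_never_mix(self):
        a = np.array([[0.0, 0.0], [0.0, 0.0]])
        b = np.array([[1.0, 0.0], [1.0, 0.0]])
        n = count_proximal(
            a,
            b,
            15.0,
            section_a=np.array(["s1", "s2"]),
            section_b=np.array(["s1", "s2"]),
        )
        assert n == 2  # one pair per section, no cross-section pairs

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_grid_counter_equals_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 200, (40, 2))
        b = rng.uniform(0, 200, (40, 2))
        assert count_proximal(a, b, 30.0) == _brute_force_count(a, b, 30.0)


class TestRandomizationNull:
    def test_displacement_bounded(self):
        rng = np.random.default_rng(2)
        from brainatlas.interactions import _displace

        xy = rng.uniform(0, 500, (200, 2))
        moved = _displace(np.random.default_rng(0), xy, 100.0)
        assert np.all(np.linalg.norm(moved - xy, axis=1) <= 100.0)

    def test_counts_preserved_per_type(self):
        rng = np.random.default_rng(3)
        xy_a = rng.uniform(0, 500, (50, 2))
        xy_b = rng.uniform(0, 500, (70, 2))
        params = ProximityParams(n_rounds=5, seed=0)
        mu, sd, samples = randomization_null(xy_a, xy_b, params)
        assert len(samples) == 5
        assert sd >= 1e-9

    def test_csr_observed_within_null(self, specs):
        """Complete spatial randomness: the observed proximal-pair count
        sits within 4 sigma of the randomization null."""
        tbl, _ = synthetic.simulate_section(specs["csr"], seed=5)
        sub = tbl.meta["subclass_label"].to_numpy()
        xy = tbl.meta[["x", "y"]].to_numpy()
        params = ProximityParams(n_rounds=200, seed=0)
        mu, sd, _ = randomization_null(xy[sub == "S0"], xy[sub == "S1"], params)
        obs = count_proximal(xy[sub == "S0"], xy[sub == "S1"], params.r_proximal)
        assert abs(obs - mu) <= 4 * sd


class TestTestInteractions:
    def _table(self, xy, labels):
        n = len(xy)
        meta = pd.DataFrame(
            {
                "section_id": "s",
                "x": xy[:, 0],
                "y": xy[:, 1],
                "z_planes": 3,
                "volume": 100.0,
                "subclass_label": labels,
            },
            index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
        )
        return CellTable(genes=["g"], counts=np.ones((n, 1), int), meta=meta)

    def test_low_observed_count_never_called(self):
        """Ten tightly attached pairs have a tiny p-value but fall below
        the 20-pair observation floor."""
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 2000, (10, 2))
        b = a + rng.normal(0, 1.0, (10, 2))
        xy = np.vstack([a, b])
        labels = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        df = interaction_test(
            self._table(xy, labels),
            ["A", "B"],
            ProximityParams(n_rounds=100, seed=0),
        )
        row = df[(df.type_a == "A") & (df.type_b == "B")].iloc[0]
        assert row["observed"] == 10
        assert not row["called"]

    def test_planted_attraction_called(self, specs):
        tbl, _ = synthetic.simulate_section(specs["attraction"], seed=3)
        df = interaction_test(
            tbl, ["S0", "S1"], ProximityParams(n_rounds=200, seed=0)
        )
        row = df[(df.type_a == "S0") & (df.type_b == "S1")].iloc[0]
        assert row["called"] and row["fold"] > 1.5

    def test_observed_at_null_mean_p_half(self):
        from scipy.stats import norm

        assert norm.sf(10.0, 10.0, 2.0) == pytest.approx(0.5)

    def test_symmetry_under_relabeling(self, specs):
        tbl, _ = synthetic.simulate_section(specs["attraction"], seed=4)
        params = ProximityParams(n_rounds=100, seed=0)
        df1 = interaction_test(tbl, ["S0", "S1"], params)
        sub = tbl.meta["subclass_label"].map({"S0": "S1", "S1": "S0"})
        tbl2 = tbl.subset(np.arange(tbl.n_cells))
        tbl2.meta = tbl2.meta.copy()
        tbl2.meta["subclass_label"] = sub
        df2 = interaction_test(tbl2, ["S0", "S1"], params)
        obs1 = df1[(df1.type_a == "S0") & (df1.type_b == "S1")]["observed"].iloc[0]
        obs2 = df2[(df2.type_a == "S0") & (df2.type_b == "S1")]["observed"].iloc[0]
        assert obs1 == obs2


class TestLRScore:
    def test_zero_expression_zero_score(self):
        assert lr_score([0.0], [0.0, 0.0])[0] == 0.0

    def test_single_subunit_formula(self):
        assert lr_score([2.0], [3.0])[0] == pytest.approx(np.log(7.0))

    def test_multi_subunit_product(self):
        # ligand subunits (2, 3), receptor (1): S = ln(1 + 6 * 1)
        assert lr_score([[2.0, 3.0]], [[1.0]])[0] == pytest.approx(np.log(7.0))

    def test_literal_variant_cross_terms(self):
        # (prod L)^|q| * (prod R)^|p| with L=(2,), R=(3,4): 2^2 * 12^1 = 48
        s = lr_score([[2.0]], [[3.0, 4.0]], literal=True)[0]
        assert s == pytest.approx(np.log(49.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lig=st.lists(st.floats(0, 50), min_size=1, max_size=3),
        rec=st.lists(st.floats(0, 50), min_size=1, max_size=3),
    )
    def test_score_non_negative(self, lig, rec):
        assert lr_score([lig], [rec])[0] >= 0.0


class TestLRTest:
    def test_identical_expression_no_hits(self):
        rng = np.random.default_rng(7)
        n = 60
        xy = rng.uniform(0, 500, (2 * n, 2))
        meta = pd.DataFrame(
            {
                "section_id": "s",
                "x": xy[:, 0],
                "y": xy[:, 1],
                "z_planes": 3,
                "volume": 100.0,
            },
            index=pd.Index([f"c{i}" for i in range(2 * n)], name="cell_id"),
        )
        counts = np.full((2 * n, 3), 4)
        cells = CellTable(genes=["L", "R1", "R2"], counts=counts, meta=meta)
        a = cells.subset(np.arange(n))
        b = cells.subset(np.arange(n, 2 * n))
        db = LRDatabase(pairs=[LRPair("P", "w", ("L",), ("R1", "R2"))])
        out = lr_test(a, b, db, r_proximal=30.0, seed=0)
        assert not out["significant"].any()

    def test_planted_effect_recovered(self, specs):
        spec = specs["lr_effect"]
        tbl, truth = synthetic.simulate_section(spec, seed=1)
        a = tbl.subset((tbl.meta["subclass_label"] == "S0").to_numpy())
        b = tbl.subset((tbl.meta["subclass_label"] == "S1").to_numpy())
        out = lr_test(a, b, spec.lr_database, r_proximal=30.0, seed=1)
        out = out.set_index("pair_id")
        assert bool(out.loc["L1", "significant"])
        assert not out.loc[["L2", "L3"], "significant"].any()

    def test_sparse_positive_fraction_blocks_significance(self):
        """A pair scoring positive in under 40% of proximal pairs is not
        significant however large the fold."""
        rng = np.random.default_rng(8)
        n = 40
        xy = np.column_stack([np.arange(2 * n) * 5.0, np.zeros(2 * n)])
        meta = pd.DataFrame(
            {
                "section_id": "s",
                "x": xy[:, 0],
                "y": xy[:, 1],
                "z_planes": 3,
                "volume": 100.0,
            },
            index=pd.Index([f"c{i}" for i in range(2 * n)], name="cell_id"),
        )
        counts = np.zeros((2 * n, 2), int)
        hot = rng.choice(2 * n, size=(2 * n) // 5, replace=False)
        counts[hot] = 50
        cells = CellTable(genes=["L", "R"], counts=counts, meta=meta)
        a = cells.subset(np.arange(0, 2 * n, 2))
        b = cells.subset(np.arange(1, 2 * n, 2))
        db = LRDatabase(pairs=[LRPair("P", "w", ("L",), ("R",))])
        out = lr_test(a, b, db, r_proximal=30.0, seed=0)
        if len(out) and out["frac_positive_proximal"].iloc[0] < 0.4:
            assert not out["significant"].iloc[0]


class TestUpregulatedGenes:
    def test_no_partner_cells_empty(self, specs):
        tbl, _ = synthetic.simulate_section(specs["csr"], seed=0)
        a = tbl.subset((tbl.meta["subclass_label"] == "S0").to_numpy())
        far = a.subset(np.arange(min(5, a.n_cells)))
        far.meta = far.meta.copy()
        far.meta["x"] = far.meta["x"] + 1e6
        out = upregulated_genes(a, far, r_proximal=30.0)
        assert len(out) == 0

    def test_planted_upregulation_detected(self):
        rng = np.random.default_rng(9)
        n = 300
        xy_a = rng.uniform(0, 2000, (n, 2))
        xy_b = xy_a[: n // 3] + rng.normal(0, 3.0, (n // 3, 2))
        near = np.zeros(n, bool)
        near[: n // 3] = True
        counts_a = rng.poisson(2.0, (n, 4))
        counts_a[near, 0] = rng.poisson(8.0, near.sum())  # 4-fold in proximal
        meta_a = pd.DataFrame(
            {
                "section_id": "s",
                "x": xy_a[:, 0],
                "y": xy_a[:, 1],
                "z_planes": 3,
                "volume": 100.0,
            },
            index=pd.Index([f"a{i}" for i in range(n)], name="cell_id"),
        )
        a = CellTable(genes=["up", "g1", "g2", "g3"], counts=counts_a, meta=meta_a)
        meta_b = pd.DataFrame(
            {
                "section_id": "s",
                "x": xy_b[:, 0],
                "y": xy_b[:, 1],
                "z_planes": 3,
                "volume": 100.0,
            },
            index=pd.Index([f"b{i}" for i in range(len(xy_b))], name="cell_id"),
        )
        b = CellTable(
            genes=["up", "g1", "g2", "g3"],
            counts=rng.poisson(2.0, (len(xy_b), 4)),
            meta=meta_b,
        )
        out = upregulated_genes(a, b, r_proximal=15.0, hvgs=["up", "g1", "g2", "g3"])
        assert "up" in set(out["gene"])
        assert set(out["gene"]) <= {"up"}

    def test_modest_fold_excluded(self):
        """Fold 1.5 with a tiny p-value still fails the 2-fold criterion."""
        rng = np.random.default_rng(10)
        n = 2000
        xy_a = np.column_stack([np.arange(n) * 100.0, np.zeros(n)])
        xy_b = xy_a[: n // 2] + 1.0
        counts = np.zeros((n, 1))
        counts[: n // 2, 0] = rng.poisson(300.0, n // 2)  # fold 1.5
        counts[n // 2 :, 0] = rng.poisson(200.0, n // 2)
        meta_a = pd.DataFrame(
            {
                "section_id": "s",
                "x": xy_a[:, 0],
                "y": xy_a[:, 1],
                "z_planes": 3,
                "volume": 100.0,
            },
            index=pd.Index([f"a{i}" for i in range(n)], name="cell_id"),
        )
        a = CellTable(genes=["g"], counts=counts.astype(int), meta=meta_a)
        meta_b = meta_a.iloc[: n // 2].copy()
        meta_b.index = pd.Index([f"b{i}" for i in range(n // 2)], name="cell_id")
        meta_b["x"] = xy_b[:, 0]
        b = CellTable(genes=["g"], counts=np.ones((n // 2, 1), int), meta=meta_b)
        out = upregulated_genes(a, b, r_proximal=15.0, hvgs=["g"])
        assert len(out) == 0


class TestEligibleTypes:
    def _cells(self, labels, region, conf=0.9):
        n = len(labels)
        meta = pd.DataFrame(
            {
                "section_id": "s",
                "x": 0.0,
                "y": 0.0,
                "z_planes": 3,
                "volume": 100.0,
                "subclass_label": labels,
                "subclass_confidence": conf,
                "region_label": region,
            },
            index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
        )
        return CellTable(genes=["g"], counts=np.ones((n, 1), int), meta=meta)

    def test_neuronal_threshold_depends_on_region(self):
        labels = np.array(["N"] * 30 + ["M"] * 70, dtype=object)
        regions = np.array(["easy"] * 50 + ["hard"] * 50, dtype=object)
        cells = self._cells(labels, regions)
        enr = enrichment_scores(labels, regions)
        cat = {"N": "neuronal", "M": "neuronal"}
        # N is enriched ~1.2x in easy; craft a type with score 3 via counts
        labels2 = np.array(["N"] * 75 + ["M"] * 225, dtype=object)
        regions2 = np.array(
            ["easy"] * 60 + ["hard"] * 15 + ["easy"] * 40 + ["hard"] * 185,
            dtype=object,
        )
        cells2 = self._cells(labels2, regions2)
        enr2 = enrichment_scores(labels2, regions2)
        score = enr2.scores.loc["N", "easy"]
        assert 2.0 <= score < 6.0
        types_easy, _ = eligible_types(
            cells2, "easy", enr2, cat, high_threshold_regions=set()
        )
        assert "N" in types_easy
        types_hard, _ = eligible_types(
            cells2, "easy", enr2, cat, high_threshold_regions={"easy"}
        )
        assert "N" not in types_hard

    def test_other_cells_need_51(self):
        labels = np.array(["X"] * 51 + ["N"] * 49, dtype=object)
        regions = np.array(["r"] * 100, dtype=object)
        cells = self._cells(labels, regions)
        enr = enrichment_scores(labels, regions)
        types, _ = eligible_types(
            cells, "r", enr, {"X": "other", "N": "other"}
        )
        assert types == ["X"]

    def test_low_confidence_cells_dropped(self):
        labels = np.array(["X"] * 60, dtype=object)
        regions = np.array(["r"] * 60, dtype=object)
        cells = self._cells(labels, regions, conf=0.5)
        enr = enrichment_scores(labels, regions)
        types, gated = eligible_types(cells, "r", enr, {"X": "other"})
        assert gated.n_cells == 0 and types == []

    def test_astrocytes_at_threshold_one(self):
        labels = np.array(["Astro"] * 50 + ["N"] * 50, dtype=object)
        regions = np.array(["r"] * 100, dtype=object)
        cells = self._cells(labels, regions)
        enr = enrichment_scores(labels, regions)
        types, _ = eligible_types(
            cells, "r", enr, {"Astro": "astrocyte", "N": "neuronal"}
        )
        assert "Astro" in types


class TestParams:
    def test_invalid_radius_order_rejected(self):
        with pytest.raises(ValueError):
            ProximityParams(r_proximal=150.0, r_randomization=100.0)

    def test_min_rounds(self):
        with pytest.raises(ValueError):
            ProximityParams(n_rounds=1)


class TestCallPipeline:
    def test_planted_pair_called_once_and_csr_quiet(self, specs):
        """The merged strict/relaxed call set contains the planted pair
        exactly once; the CSR fixture yields no calls."""
        from brainatlas.interactions import call_pipeline

        params = ProximityParams(n_rounds=200, seed=0)
        tbl, truth = synthetic.simulate_section(specs["attraction"], seed=2)
        result = call_pipeline(
            tbl, {"sq": ["S0", "S1"]}, lrdb=None, params=params
        )
        calls = result["calls"]
        planted = calls[(calls.type_a == "S0") & (calls.type_b == "S1")]
        assert len(planted) == 1  # deduplicated across the two modes
        assert planted["mode"].iloc[0] == "strict15"

        tbl_csr, _ = synthetic.simulate_section(specs["csr"], seed=2)
        result_csr = call_pipeline(
            tbl_csr, {"sq": ["S0", "S1"]}, lrdb=None, params=params
        )
        assert len(result_csr["calls"]) == 0

    def test_relaxed_call_requires_lr_hit(self, specs):
        """With the ligand-receptor database supplied, the planted pair is
        called and its relaxed-mode evidence includes the planted LR pair."""
        from brainatlas.interactions import call_pipeline

        spec = specs["lr_effect"]
        tbl, _ = synthetic.simulate_section(spec, seed=1)
        result = call_pipeline(
            tbl,
            {"sq": ["S0", "S1"]},
            lrdb=spec.lr_database,
            params=ProximityParams(n_rounds=200, seed=1),
        )
        calls = result["calls"]
        assert {("S0", "S1")} <= {
            (a, b) for a, b in zip(calls.type_a, calls.type_b)
        }
        lr = result["lr_hits"]
        if len(lr):
            sig = lr[lr["significant"]]
            assert set(sig["pair_id"]) <= {"L1"}
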