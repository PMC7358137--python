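import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from simap import plates, synthetic
from simap.errors import LayoutError, SchemaError
from simap.plates import (PlateGeometry, build_layout_mi1, build_layout_mi2,
                          pair_differences, quantify_plate_image,
                          read_spot_table, write_spot_table)


def _sentinels(n):
    return [f"yd{i:02d}" for i in range(n)]


class TestMi1Layout:
    def test_full_plate_replicate_accounting(self):
        layouts = build_layout_mi1(_sentinels(44), "leu9", ["varA"])
        (lay,) = layouts
        frame = lay.to_frame()
        occupied = frame[frame["role"] != "empty"]
        assert len(occupied) == 44 * 2 * 16 + 2 * 64 == 1536
        per = occupied.groupby(["strain_id", "query_id"]).size()
        assert set(per[per.index.get_level_values(0) != "leu9"]) == {16}
        assert set(per["leu9"]) == {64}

    def test_pairing_adjacent_and_injective(self):
        (lay,) = build_layout_mi1(_sentinels(30), "leu9", ["varA"])
        lay.validate()
        for (r, c), (pr, pc) in lay.pairing.items():
            assert max(abs(r - pr), abs(c - pc)) == 1
        assert len(set(lay.pairing.values())) == len(lay.pairing)

    def test_one_plate_per_variant(self):
        layouts = build_layout_mi1(_sentinels(10), "leu9", ["a", "b", "c"])
        assert [l.plate_id for l in layouts] == ["mi1_a", "mi1_b", "mi1_c"]

    @pytest.mark.parametrize("n_strains, variants", [
        (45, ["a"]),          # 46 strains with the neutral control
        (10, []),             # no query
        (10, list("abcdef")),  # 6 variant queries
    ])
    def test_capacity_errors(self, n_strains, variants):
        with pytest.raises(LayoutError):
            build_layout_mi1(_sentinels(n_strains), "leu9", variants)


class TestMi2Layout:
    def test_pair_and_replicate_counts(self):
        lay = build_layout_mi2(_sentinels(8), [f"v{i}" for i in range(7)])
        assert len(lay.pairing) == 768
        frame = lay.to_frame()
        queries = frame[frame["role"].isin(["variant", "vector_control"])]
        assert queries.groupby("query_id").size().eq(96).all()
        assert queries.groupby(["query_id", "strain_id"]).size().eq(12).all()

    def test_pairing_injective_and_adjacent(self):
        lay = build_layout_mi2(_sentinels(8), [f"v{i}" for i in range(7)])
        lay.validate()
        assert len(set(lay.pairing.values())) == len(lay.pairing)

    @pytest.mark.parametrize("n_sent, n_var", [(7, 7), (9, 7), (8, 9), (8, 6)])
    def test_wrong_cardinality_errors(self, n_sent, n_var):
        with pytest.raises(LayoutError):
            build_layout_mi2(_sentinels(n_sent), [f"v{i}" for i in range(n_var)])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_random_id_sets_always_valid(self, seed):
        rng = np.random.default_rng(seed)
        sent = [f"s{rng.integers(1e6)}_{i}" for i in range(8)]
        var = [f"v{rng.integers(1e6)}_{i}" for i in range(7)]
        lay = build_layout_mi2(sent, var)
        lay.validate()
        assert len(lay.positions) == lay.rows * lay.cols == 1536


class TestSpotTableIO:
    def test_round_trip_identity(self, tmp_path):
        table = pd.DataFrame({"plate_id": "p", "row": [0, 0, 1], "col": [0, 1, 0],
                              "area_px": [10.5, 0.0, 3.25]})
        write_spot_table(table, tmp_path / "t.tsv")
        back = read_spot_table(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back, table)

    def test_duplicate_position_cites_line(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("plate_id\trow\tcol\tarea_px\np\t0\t0\t1\np\t0\t0\t2\n")
        with pytest.raises(SchemaError, match=r"line.*3"):
            read_spot_table(path)

    @pytest.mark.parametrize("body", [
        "plate_id\trow\tcol\np\t0\t0\n",              # missing column
        "plate_id\trow\tcol\tarea_px\np\t0\t0\tNaN\n",  # non-finite area
        "plate_id\trow\tcol\tarea_px\np\t0\t0\t-4\n",   # negative area
    ])
    def test_malformed_tables_rejected(self, tmp_path, body):
        path = tmp_path / "bad.tsv"
        path.write_text(body)
        with pytest.raises(SchemaError):
            read_spot_table(path)


class TestQuantifyImage:
    # pitch sized so colonies fill a sizeable fraction of each grid cell,
    # as on a real pinned plate — the per-cell percentile threshold needs
    # both background and colony pixels inside the window
    GEOM = PlateGeometry(width=64, height=64, origin_x=8, origin_y=8,
                         pitch=16, rows=4, cols=4)

    def test_black_image_all_zero(self):
        table = quantify_plate_image(np.zeros((64, 64), dtype=np.uint8), self.GEOM)
        assert (table["area_px"] == 0).all()

    def test_single_disk_area_recovered(self):
        spots = pd.DataFrame({"plate_id": "p", "row": [1], "col": [2], "area_px": [81.0]})
        img = synthetic.render_plate_image(spots, self.GEOM)
        table = quantify_plate_image(img, self.GEOM).set_index(["row", "col"])
        assert abs(table.loc[(1, 2), "area_px"] - 81) <= 2
        assert table.drop(index=(1, 2))["area_px"].eq(0).all()

    def test_render_quantify_round_trip(self):
        rng = np.random.default_rng(5)
        areas = rng.uniform(40, 110, 16)
        spots = pd.DataFrame({"plate_id": "p",
                              "row": np.repeat(np.arange(4), 4),
                              "col": np.tile(np.arange(4), 4),
                              "area_px": areas})
        img = synthetic.render_plate_image(spots, self.GEOM)
        table = quantify_plate_image(img, self.GEOM, plate_id="p")
        merged = spots.merge(table, on=["plate_id", "row", "col"], suffixes=("", "_q"))
        rel = (merged["area_px_q"] - merged["area_px"]).abs() / merged["area_px"]
        assert rel.max() <= 0.02

    def test_plate_brightness_factor_propagates(self):
        """Two plates rendered with areas scaled 1.3x differ by ~1.3x per spot."""
        rng = np.random.default_rng(6)
        areas = rng.uniform(60, 110, 16)
        base = pd.DataFrame({"plate_id": "p", "row": np.repeat(np.arange(4), 4),
                             "col": np.tile(np.arange(4), 4), "area_px": areas})
        biased = base.assign(area_px=areas * 1.3)
        q1 = quantify_plate_image(synthetic.render_plate_image(base, self.GEOM), self.GEOM)
        q2 = quantify_plate_image(synthetic.render_plate_image(biased, self.GEOM), self.GEOM)
        ratio = q2["area_px"] / q1["area_px"]
        assert np.allclose(ratio, 1.3, rtol=0.05)

    def test_png_round_trip(self, tmp_path):
        spots = pd.DataFrame({"plate_id": "p", "row": [0], "col": [1],
                              "area_px": [60.0]})
        img = synthetic.render_plate_image(spots, self.GEOM)
        plates.write_plate_image(img, tmp_path / "plate.png")
        back = plates.read_plate_image(tmp_path / "plate.png")
        assert np.array_equal(back, img)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(LayoutError):
            quantify_plate_image(np.zeros((50, 50), dtype=np.uint8), self.GEOM)

    def test_overlapping_spots_rejected(self):
        tight = PlateGeometry(width=40, height=40, origin_x=5, origin_y=5,
                              pitch=10, rows=2, cols=2)
        spots = pd.DataFrame({"plate_id": "p", "row": [0], "col": [0],
                              "area_px": [400.0]})
        with pytest.raises(LayoutError):
            synthetic.render_plate_image(spots, tight)


class TestPairDifferences:
    def _toy(self):
        lay = plates.PlateLayout(plate_id="p", rows=2, cols=4)
        for c in range(0, 4, 2):
            lay.positions[(0, c)] = plates.Position("s", "wt", "wt_control")
            lay.positions[(0, c + 1)] = plates.Position("s", "varA", "variant")
            lay.pairing[(0, c + 1)] = (0, c)
        lay.validate()
        return lay

    def test_simple_difference(self):
        lay = self._toy()
        table = pd.DataFrame({"plate_id": "p", "row": 0, "col": range(4),
                              "area_px": [100.0, 120.0, 80.0, 80.0]})
        diffs = pair_differences(table, lay)
        assert list(diffs["diff"]) == [20.0, 0.0]

    def test_missing_position_listed(self):
        lay = self._toy()
        table = pd.DataFrame({"plate_id": "p", "row": 0, "col": [0, 1, 2],
                              "area_px": [1.0, 2.0, 3.0]})
        with pytest.raises(SchemaError, match=r"\(0, 3\)"):
            pair_differences(table, lay)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_loop(self, seed):
        """Vectorized pairing equals an independent per-pair loop."""
        lay = build_layout_mi2([f"s{i}" for i in range(8)],
                               [f"v{i}" for i in range(7)])
        rng = np.random.default_rng(seed)
        recs = [(lay.plate_id, r, c, float(rng.uniform(0, 300)))
                for r in range(lay.rows) for c in range(lay.cols)]
        table = pd.DataFrame(recs, columns=plates.SPOT_COLUMNS)
        diffs = pair_differences(table, lay)
        areas = {(r, c): a for _, r, c, a in recs}
        for rec in diffs.sample(50, random_state=0).itertuples(index=False):
            expected = areas[(rec.row, rec.col)] - areas[lay.pairing[(rec.row, rec.col)]]
            assert rec.diff == pytest.approx(expected, abs=1e-12)
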