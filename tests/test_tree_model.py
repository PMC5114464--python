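import math

import numpy as np
import pytest

from corowave.synthetic_data import SyntheticConfig, generate_tree
from corowave.tree_model import (
    BifurcationRecord,
    TreeValidationError,
    VascularTree,
    VesselSegment,
    assign_transmural_layer,
    assign_weibel_generations,
    extract_bifurcations,
    load_tree,
    save_tree,
    transmural_layer,
)


def _write(tmp_path, text, name="tree.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadSave:
    def test_minimal_three_row_table(self, tmp_path):
        p = _write(
            tmp_path,
            "id,parent,radius_mm,length_mm\n"
            "r,,1.0,10.0\n"
            "a,r,0.8,8.0\n"
            "b,r,0.6,6.0\n",
        )
        tree = load_tree(p)
        assert len(tree) == 3
        records, _ = extract_bifurcations(tree)
        assert len(records) == 1

    def test_round_trip_identity(self, tmp_path, minimal_tree):
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        save_tree(minimal_tree, p1)
        save_tree(load_tree(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_round_trip_preserves_fields(self, tmp_path):
        tree = VascularTree(
            [
                VesselSegment("r", None, 1.2345678901234567, 10.0,
                              territory="LAD", transmural_depth=0.25,
                              extra={"note": "x"}),
                VesselSegment("a", "r", 0.8, 8.0, territory="LAD",
                              transmural_depth=0.5, extra={"note": "y"}),
                VesselSegment("b", "r", 0.6, 6.0, territory="LCx",
                              transmural_depth=0.75, extra={"note": ""}),
            ]
        )
        p = tmp_path / "t.csv"
        save_tree(tree, p)
        back = load_tree(p)
        for seg in tree:
            other = back.segment(seg.id)
            assert other.parent_id == seg.parent_id
            assert other.radius == seg.radius  # full precision
            assert other.length == seg.length
            assert other.territory == seg.territory
            assert other.transmural_depth == seg.transmural_depth
            assert other.extra == seg.extra

    def test_generated_fixture_round_trip(self, tmp_path, small_tree):
        p = tmp_path / "gen.csv"
        save_tree(small_tree, p)
        back = load_tree(p)  # re-validation happens on construction
        assert len(back) == len(small_tree) <= 500
        assert len(back) > 490

    def test_minimal_tree_writes_three_rows(self, tmp_path, minimal_tree):
        p = tmp_path / "t.csv"
        save_tree(minimal_tree, p)
        lines = [l for l in p.read_text().splitlines() if l]
        assert len(lines) == 4  # header + 3 data rows

    def test_missing_column(self, tmp_path):
        p = _write(tmp_path, "id,parent,radius_mm\nr,,1.0\n")
        with pytest.raises(ValueError, match="length_mm"):
            load_tree(p)

    def test_nonpositive_radius_names_row(self, tmp_path):
        p = _write(
            tmp_path,
            "id,parent,radius_mm,length_mm\nr,,1.0,10.0\nbad,r,-0.5,5.0\n",
        )
        with pytest.raises(TreeValidationError, match="bad"):
            load_tree(p)

    def test_multiple_roots(self, tmp_path):
        p = _write(
            tmp_path,
            "id,parent,radius_mm,length_mm\na,,1.0,1.0\nb,,1.0,1.0\n",
        )
        with pytest.raises(TreeValidationError, match="multiple roots"):
            load_tree(p)

    def test_cycle_detected(self, tmp_path):
        p = _write(
            tmp_path,
            "id,parent,radius_mm,length_mm\n"
            "r,,1.0,1.0\na,b,0.5,1.0\nb,a,0.5,1.0\n",
        )
        with pytest.raises(TreeValidationError, match="unreachable"):
            load_tree(p)

    def test_unresolved_parent(self, tmp_path):
        p = _write(
            tmp_path,
            "id,parent,radius_mm,length_mm\nr,,1.0,1.0\na,ghost,0.5,1.0\n",
        )
        with pytest.raises(TreeValidationError, match="ghost"):
            load_tree(p)

    def test_unknown_edge_convention(self, tmp_path):
        p = _write(tmp_path, "id,parent,radius_mm,length_mm\nr,,1,1\n")
        with pytest.raises(ValueError, match="edge convention"):
            load_tree(p, edge_convention="pairs")


class TestExtractBifurcations:
    def test_sigma_gamma_arithmetic(self, minimal_tree):
        records, _ = extract_bifurcations(minimal_tree)
        (rec,) = records
        assert rec.sigma == pytest.approx(1.2, abs=1e-12)
        assert rec.gamma == pytest.approx(0.5, abs=1e-12)
        assert rec.d1_id == "a" and rec.d2_id == "b"
        assert rec.r_m == minimal_tree.segment("m").radius

    def test_trifurcation_excluded(self):
        segs = [VesselSegment("m", None, 1.0, 1.0)] + [
            VesselSegment(f"c{i}", "m", 0.5, 1.0) for i in range(3)
        ]
        records, census = extract_bifurcations(VascularTree(segs))
        assert records == []
        assert census["counts"]["n_furcation"] == 1

    def test_equal_daughters_gamma_one(self):
        segs = [
            VesselSegment("m", None, 1.0, 1.0),
            VesselSegment("y", "m", 0.7, 1.0),
            VesselSegment("x", "m", 0.7, 1.0),
        ]
        records, _ = extract_bifurcations(VascularTree(segs))
        (rec,) = records
        assert rec.gamma == 1.0
        assert rec.d1_id == "x"  # id order breaks the tie

    def test_census_fractions_sum_to_one(self, small_tree):
        _, census = extract_bifurcations(small_tree)
        assert sum(census["fractions"].values()) == pytest.approx(1.0)

    def test_record_invariants(self, small_tree):
        records, _ = extract_bifurcations(small_tree)
        assert records
        for rec in records:
            assert rec.sigma * rec.A_m == pytest.approx(
                rec.A_d1 + rec.A_d2, rel=1e-14
            )
            assert 0.0 < rec.gamma <= 1.0
            assert rec.A_d1 >= rec.A_d2


class TestWeibelGenerations:
    def test_root_daughters_are_generation_one(self, minimal_tree):
        assign_weibel_generations(minimal_tree)
        assert minimal_tree.segment("m").weibel_generation == 0
        assert minimal_tree.segment("a").weibel_generation == 1
        assert minimal_tree.segment("b").weibel_generation == 1

    def test_unary_chain_does_not_increment(self):
        tree = VascularTree(
            [
                VesselSegment("r", None, 1.0, 1.0),
                VesselSegment("u", "r", 0.9, 1.0),  # pass-through
                VesselSegment("a", "u", 0.7, 1.0),
                VesselSegment("b", "u", 0.7, 1.0),
                VesselSegment("c", "a", 0.5, 1.0),
                VesselSegment("d", "a", 0.5, 1.0),
            ]
        )
        assign_weibel_generations(tree)
        assert tree.segment("u").weibel_generation == 0
        assert tree.segment("a").weibel_generation == 1
        assert tree.segment("c").weibel_generation == 2

    def test_balanced_depth_four_tree(self):
        segs = [VesselSegment("n", None, 5.0, 1.0)]
        frontier = ["n"]
        for level in range(4):
            nxt = []
            for p in frontier:
                for side in "LR":
                    cid = p + side
                    segs.append(
                        VesselSegment(cid, p, 5.0 * 0.7 ** (level + 1), 1.0)
                    )
                    nxt.append(cid)
            frontier = nxt
        tree = VascularTree(segs)
        assign_weibel_generations(tree)
        assert max(s.weibel_generation for s in tree) == 4

    def test_non_decreasing_along_paths(self, small_tree):
        tree = small_tree.copy()
        assign_weibel_generations(tree)
        for seg in tree:
            if seg.parent_id is not None:
                parent = tree.segment(seg.parent_id)
                assert seg.weibel_generation >= parent.weibel_generation

    def test_record_numbering_starts_at_one(self, small_tree):
        tree = small_tree.copy()
        assign_weibel_generations(tree)
        records, _ = extract_bifurcations(tree)
        assert min(r.weibel_generation for r in records) == 1


class TestTransmuralLayer:
    @pytest.mark.parametrize(
        "depth,expected", [(0.0, 1), (0.34, 2), (1.0, 3), (0.999, 3), (1 / 3, 2)]
    )
    def test_layer_arithmetic(self, depth, expected):
        assert transmural_layer(depth, 3) == expected

    def test_missing_depth_fails(self, minimal_tree):
        with pytest.raises(ValueError, match="transmural_depth"):
            assign_transmural_layer(minimal_tree)

    def test_tree_level_assignment(self):
        tree = generate_tree(
            SyntheticConfig(root_radius=1.0, r_min=0.2, seed=1, max_segments=50)
        )
        layers = assign_transmural_layer(tree, n_layers=3)
        assert set(layers) == {s.id for s in tree}
        assert set(layers.values()) <= {1, 2, 3}


def test_bifurcation_record_validates_nothing_silly():
    rec = BifurcationRecord(
        mother_id="m", d1_id="a", d2_id="b",
        A_m=2.5, A_d1=2.0, A_d2=1.0, sigma=1.2, gamma=0.5, r_m=0.89,
    )
    assert rec.gamma <= 1.0


def test_duplicate_ids_rejected():
    with pytest.raises(TreeValidationError, match="duplicate"):
        VascularTree(
            [
                VesselSegment("r", None, 1.0, 1.0),
                VesselSegment("r", None, 1.0, 1.0),
            ]
        )
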