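"""Tree generator, analytic ground truth, rasterization, cohort draws."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import retmorph as rm
from retmorph.synthetic import (
    GroupSpec,
    Segment,
    TreeSpec,
    _spec_strahler,
    ground_truth_morphometry,
)


class TestGenerateTreeSpec:
    def test_depth_one_is_a_single_unbranched_segment(self, disc):
        spec = rm.generate_tree_spec(1, disc=disc, seed=0)
        assert len(spec.segments) == 1
        assert spec.junctions == []

    def test_constant_laws_propagate_to_every_junction(self, disc):
        spec = rm.generate_tree_spec(
            3,
            angle_law=("constant", 60.0),
            diameter_ratio_law=("constant", (0.8, 0.6)),
            disc=disc,
            seed=1,
        )
        gt = ground_truth_morphometry(spec)
        assert len(gt.junctions) >= 1
        # planned 60° split, Pythagorean ratios: (0.8² + 0.6²)/1² = 1
        assert np.allclose(gt.junctions["angle"], 60.0, atol=1e-6)
        assert np.allclose(gt.junctions["coefficient"], 1.0, atol=1e-9)

    def test_same_seed_gives_byte_identical_spec(self, disc):
        a = rm.generate_tree_spec(4, disc=disc, seed=7)
        b = rm.generate_tree_spec(4, disc=disc, seed=7)
        assert json.dumps(a.to_json()) == json.dumps(b.to_json())

    def test_root_on_disc_edge_growing_outward(self, disc):
        spec = rm.generate_tree_spec(3, disc=disc, seed=5)
        r = math.hypot(spec.root_point[0] - disc.center[0],
                       spec.root_point[1] - disc.center[1])
        assert r == pytest.approx(disc.radius, abs=1e-6)
        # every segment end is farther from the center than the root
        for seg in spec.segments:
            assert math.hypot(*(seg.end - np.asarray(disc.center))) > disc.radius

    def test_daughter_diameters_never_exceed_parent(self, disc):
        spec = rm.generate_tree_spec(5, disc=disc, seed=11, base_length=55.0)
        by_id = {s.id: s for s in spec.segments}
        for s in spec.segments:
            if s.parent is not None:
                assert s.diameter <= by_id[s.parent].diameter
        spec.validate()  # acyclicity, emanation, angle range

    def test_invalid_law_bounds_raise(self, disc):
        with pytest.raises(ValueError):
            rm.generate_tree_spec(3, angle_law=("uniform", 90.0, 20.0), disc=disc, seed=0)
        with pytest.raises(ValueError):
            rm.generate_tree_spec(0, disc=disc, seed=0)
        with pytest.raises(ValueError):
            rm.generate_tree_spec(3, angle_law=("constant", 5.0), disc=disc, seed=0)

    def test_json_round_trip(self, disc):
        spec = rm.generate_tree_spec(3, disc=disc, seed=2)
        back = TreeSpec.from_json(json.loads(json.dumps(spec.to_json())))
        assert json.dumps(back.to_json()) == json.dumps(spec.to_json())


class TestGroundTruth:
    def test_single_segment_has_empty_table_and_flagged_ma(self, disc):
        spec = rm.generate_tree_spec(1, disc=disc, seed=0)
        gt = ground_truth_morphometry(spec)
        assert len(gt.junctions) == 0
        assert "main_angle_undefined" in gt.flags

    def test_symmetric_bifurcation_classified_by_equal_orders(self, disc):
        spec = rm.generate_tree_spec(
            2, diameter_ratio_law=("constant", (0.8, 0.8)), disc=disc, seed=0,
            asymmetry=0.0,
        )
        gt = ground_truth_morphometry(spec)
        assert set(gt.junctions["class"]) == {"bifurcation"}

    @pytest.mark.parametrize("seed", range(10))
    def test_classes_match_brute_force_strahler_recursion(self, disc, seed, strahler_oracle):
        spec = rm.generate_tree_spec(4, disc=disc, seed=seed)
        children = {}
        roots = []
        for s in spec.segments:
            if s.parent is None:
                roots.append(s.id)
            else:
                children.setdefault(s.parent, []).append(s.id)
        oracle = strahler_oracle(children, roots)
        assert _spec_strahler(spec) == oracle
        gt = ground_truth_morphometry(spec)
        for _, row in gt.junctions.iterrows():
            o1, o2 = row["daughter_orders"]
            expect = "bifurcation" if o1 == o2 else "branching"
            assert row["class"] == expect


class TestRender:
    def test_single_stroke_area_matches_analytic_stadium(self):
        disc = rm.DiscGeometry((10.0, 10.0), 10.0)
        # centerline off the pixel lattice: an integer-row horizontal stroke
        # would put every boundary pixel center exactly on the stadium edge
        seg = Segment(0, None, (60.5, 30.0), (0.0, 1.0), 40.0, 6.0)
        spec = TreeSpec("artery", (60.5, 30.0), (0.0, 1.0), [seg], [], disc)
        mask = rm.render_tree(spec, 120, 120)
        area = int(mask.grid.sum())
        expect = 40 * 6 + math.pi * 3**2
        assert abs(area - expect) <= 0.10 * expect

    def test_empty_spec_renders_all_background(self):
        disc = rm.DiscGeometry((10.0, 10.0), 10.0)
        spec = TreeSpec("vein", (0.0, 0.0), (0.0, 1.0), [], [], disc)
        assert not rm.render_tree(spec, 64, 64).grid.any()

    def test_out_of_canvas_segment_is_reported(self, disc):
        spec = rm.generate_tree_spec(3, disc=disc, seed=0)
        with pytest.raises(ValueError, match="out of canvas"):
            rm.render_tree(spec, 64, 64)

    def test_rendered_stroke_remeasures_at_its_drawn_width(self):
        disc = rm.DiscGeometry((10.0, 10.0), 10.0)
        seg = Segment(0, None, (40.0, 20.0), (0.35, 0.9368), 110.0, 9.0)
        spec = TreeSpec("artery", (40.0, 20.0), (0.35, 0.9368), [seg], [], disc)
        mask = rm.render_tree(spec, 200, 200)
        g = rm.build_graph(rm.skeletonize(mask))
        g = rm.estimate_diameters(mask, g)
        edge = max(g.edges.values(), key=lambda e: e.length)
        assert 8.0 <= edge.mean_diameter <= 10.0


class TestSimulateCohort:
    def _spec(self, sd, n, seed=0):
        means = {m: 80.0 for m in rm.METRICS}
        sds = {m: sd for m in rm.METRICS}
        return rm.CohortSpec([GroupSpec("normal", n, means, sds)], seed=seed)

    def test_zero_sd_is_degenerate_at_the_mean(self):
        df = rm.simulate_cohort(self._spec(0.0, 5))
        assert (df[list(rm.METRICS)] == 80.0).all().all()
        assert len(df) == 5

    def test_large_sample_mean_near_population_mean(self):
        df = rm.simulate_cohort(self._spec(5.0, 10_000, seed=42))
        assert abs(df["MA"].mean() - 80.0) < 0.2

    def test_same_seed_same_csv_bytes(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            df = rm.simulate_cohort(rm.reference_cohort_spec("vein", "derived", seed=9))
            p = tmp_path / f"{run}.csv"
            df.to_csv(p, index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_reference_cohort_matches_published_group_sizes(self):
        df = rm.simulate_cohort(rm.reference_cohort_spec("vein", "derived", seed=0))
        counts = df["group"].value_counts().to_dict()
        assert counts == rm.REFERENCE_GROUP_SIZES

    def test_duplicate_group_labels_rejected(self):
        g = GroupSpec("low", 3, {m: 1.0 for m in rm.METRICS}, {m: 0.0 for m in rm.METRICS})
        with pytest.raises(ValueError):
            rm.CohortSpec([g, g])

    def test_ci_derived_sd_inverts_the_interval(self):
        # SD -> CI -> SD round trip at n = 100
        sd = rm.ci_derived_sd(80 - 1.96 * 2.5 / 10, 80 + 1.96 * 2.5 / 10, 100)
        assert sd == pytest.approx(2.5, rel=1e-9)


def test_ground_truth_annulus_flags_match_module_rule(disc):
    spec = rm.generate_tree_spec(4, disc=disc, seed=13)
    gt = ground_truth_morphometry(spec)
    for _, row in gt.junctions.iterrows():
        assert row["in_annulus"] == rm.in_annulus(
            (row["node_row"], row["node_col"]), disc
        )
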