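"""Ray-cast visual fields: coverage, occlusion, field containment."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from shoalsight.vision import (
    VisionConfig,
    body_models,
    cast_field,
    collective_coverage,
    occlusion_index,
    stimulus_visible_any,
)

BL = np.array([27.0])


def _lone_fish(arena, field="full", config=None, pos=(0.0, 0.0), heading=0.0):
    cfg = config or VisionConfig()
    return cast_field(np.asarray(pos, dtype=float), heading, 27.0, [], arena, cfg,
                      field=field, fish_id=0)


class TestCastField:
    def test_lone_fish_360_sees_whole_arena(self, arena):
        cfg = VisionConfig(full_field_deg=360.0, n_rays=1440)
        res = _lone_fish(arena, config=cfg)
        assert res.coverage_fraction == pytest.approx(1.0, abs=0.01)
        assert res.blocked_ray_fraction == 0.0

    def test_neighbour_on_sight_line_hides_stimulus(self, arena):
        stim = np.array([400.0, 0.0])
        blocker = body_models(np.array([[200.0, 0.0]]), np.array([np.pi / 2]),
                              BL, VisionConfig(), fish_ids=[1])
        res = cast_field(np.zeros(2), 0.0, 27.0, blocker, arena, VisionConfig(),
                         field="binocular", stimulus=stim, fish_id=0)
        assert res.stimulus_visible is False
        clear = cast_field(np.zeros(2), 0.0, 27.0, [], arena, VisionConfig(),
                           field="binocular", stimulus=stim, fish_id=0)
        assert clear.stimulus_visible is True

    def test_binocular_region_inside_full_region(self, arena, rng):
        for _ in range(5):
            pos = rng.uniform([-400, -200], [400, 200], size=(4, 2))
            ang = rng.uniform(0, 2 * np.pi, 4)
            bodies = body_models(pos, ang, np.full(4, 27.0), VisionConfig(),
                                 fish_ids=list(range(4)))
            b = cast_field(pos[0], ang[0], 27.0, bodies, arena, VisionConfig(),
                           field="binocular", fish_id=0)
            f = cast_field(pos[0], ang[0], 27.0, bodies, arena, VisionConfig(),
                           field="full", fish_id=0)
            assert b.coverage_fraction <= f.coverage_fraction + 1e-9
            pb, pf = Polygon(b.visible_polygon), Polygon(f.visible_polygon)
            # sampled containment: binocular points lie in the full field
            pts = rng.uniform([-650, -350], [650, 350], size=(300, 2))
            for p in pts:
                if pb.contains(Point(*p)):
                    assert pf.buffer(2.0).contains(Point(*p))

    def test_occluder_never_enlarges_the_region(self, arena, rng):
        pos0 = np.zeros(2)
        base = cast_field(pos0, 0.3, 27.0, [], arena, VisionConfig(),
                          field="full", fish_id=0)
        area = Polygon(base.visible_polygon).area
        others = []
        for k in range(4):
            others += body_models(rng.uniform([-200, -100], [300, 100], (1, 2)),
                                  rng.uniform(0, np.pi, 1), BL, VisionConfig(),
                                  fish_ids=[k + 1])
            res = cast_field(pos0, 0.3, 27.0, others, arena, VisionConfig(),
                             field="full", fish_id=0)
            new_area = Polygon(res.visible_polygon).area
            assert new_area <= area + 1e-6
            area = new_area

    def test_rigid_motion_invariance_under_arena_symmetry(self, arena, rng):
        """The stadium is symmetric under point reflection: mapping the whole
        scene through the centre leaves coverage unchanged to ray tolerance."""
        pos = rng.uniform([-300, -150], [300, 150], size=(5, 2))
        ang = rng.uniform(0, 2 * np.pi, 5)
        bl = np.full(5, 27.0)
        cfg = VisionConfig()
        bodies = body_models(pos, ang, bl, cfg, fish_ids=list(range(5)))
        a = cast_field(pos[0], ang[0], 27.0, bodies, arena, cfg, field="full",
                       fish_id=0).coverage_fraction
        bodies_r = body_models(-pos, ang + np.pi, bl, cfg, fish_ids=list(range(5)))
        b = cast_field(-pos[0], ang[0] + np.pi, 27.0, bodies_r, arena, cfg,
                       field="full", fish_id=0).coverage_fraction
        assert b == pytest.approx(a, abs=0.01)


class TestOcclusionIndex:
    def test_isolated_fish_zero(self, arena):
        assert occlusion_index(np.zeros(2), 0.0, 27.0, [], arena, VisionConfig(),
                               fish_id=0) == 0.0

    def test_ringed_fish_near_one(self, arena):
        """A tight ring of touching neighbour bodies blocks nearly all rays."""
        cfg = VisionConfig(full_field_deg=360.0)
        r = 30.0
        centres, angs = [], []
        for k in range(12):
            a = 2 * np.pi * k / 12
            centres.append([r * np.cos(a), r * np.sin(a)])
            angs.append(a + np.pi / 2)  # tangential: bodies form a wall
        bodies = body_models(np.array(centres), np.array(angs), np.full(12, 27.0),
                             cfg, fish_ids=list(range(1, 13)))
        v = occlusion_index(np.zeros(2), 0.0, 27.0, bodies, arena, cfg, fish_id=0)
        assert v >= 0.9

    def test_monotone_in_neighbours(self, arena, rng):
        cfg = VisionConfig()
        bodies = []
        prev = 0.0
        for k in range(5):
            bodies += body_models(rng.uniform([-150, -80], [150, 80], (1, 2)),
                                  rng.uniform(0, np.pi, 1), BL, cfg, fish_ids=[k + 1])
            v = occlusion_index(np.zeros(2), 0.0, 27.0, bodies, arena, cfg, fish_id=0)
            assert v >= prev - 1e-12
            prev = v


class TestStimulusVisibleAny:
    def test_group_facing_away_binocular_blind(self, arena):
        stim = np.array([600.0, 0.0])
        pos = np.stack([np.linspace(-200, -100, 4), np.zeros(4)], axis=1)
        ang = np.full(4, np.pi)  # all facing -x, stimulus at +x
        seen, seers = stimulus_visible_any(pos, ang, np.full(4, 27.0), stim, arena,
                                           VisionConfig(), field="binocular")
        assert not seen and seers == set()

    def test_facing_fish_sees(self, arena):
        stim = np.array([600.0, 0.0])
        pos = np.array([[0.0, 0.0], [0.0, 60.0]])
        ang = np.array([0.0, np.pi])
        seen, seers = stimulus_visible_any(pos, ang, np.full(2, 27.0), stim, arena,
                                           VisionConfig(), field="binocular",
                                           fish_ids=[1, 2])
        assert seen and seers == {1}

    def test_consistent_with_cast_field(self, arena, rng):
        cfg = VisionConfig()
        for _ in range(25):
            pos = rng.uniform([-400, -200], [400, 200], size=(8, 2))
            ang = rng.uniform(0, 2 * np.pi, 8)
            bl = np.full(8, 27.0)
            stim = np.asarray(arena.ports[0].position)
            _, seers = stimulus_visible_any(pos, ang, bl, stim, arena, cfg,
                                            field="full")
            bodies = body_models(pos, ang, bl, cfg, fish_ids=list(range(8)))
            per_fish = {
                i
                for i in range(8)
                if cast_field(pos[i], ang[i], bl[i], bodies, arena, cfg,
                              field="full", stimulus=stim, fish_id=i).stimulus_visible
            }
            assert seers == per_fish


class TestCollectiveCoverage:
    def test_single_fish_equals_own_coverage(self, arena):
        pos = np.array([[50.0, 20.0], [900.0, 900.0]])  # second fish far outside range
        cfg = VisionConfig(max_range_mm=200.0)
        own = cast_field(pos[0], 1.0, 27.0, [], arena, cfg, field="binocular",
                         fish_id=0).coverage_fraction
        both = collective_coverage(pos[:1], np.array([1.0]), BL, arena, cfg,
                                   field="binocular")
        assert both == pytest.approx(own, rel=1e-6)

    def test_disjoint_fields_add(self, arena):
        cfg = VisionConfig(max_range_mm=100.0)
        pos = np.array([[-400.0, 0.0], [400.0, 0.0]])
        ang = np.array([np.pi / 2, -np.pi / 2])
        bl = np.full(2, 27.0)
        singles = [
            cast_field(pos[i], ang[i], bl[i], [], arena, cfg, field="binocular",
                       fish_id=i).coverage_fraction
            for i in range(2)
        ]
        union = collective_coverage(pos, ang, bl, arena, cfg, field="binocular")
        assert union == pytest.approx(sum(singles), rel=1e-3)


class TestGridClassification:
    def test_per_point_visibility_matches_polygon(self, arena, rng):
        """Point-wise visibility (angle + segment occlusion) agrees with the
        ray-cast polygon on >= 98% of grid points."""
        from shapely.geometry import Point, Polygon as ShPolygon

        from shoalsight.vision import _eye_point, _point_visible

        cfg = VisionConfig()
        pos = np.array([0.0, 0.0]) + rng.normal(scale=100, size=(8, 2))
        theta = rng.uniform(0, 2 * np.pi, 8)
        bl = np.full(8, 27.0)
        bodies = body_models(pos, theta, bl, cfg, fish_ids=list(range(8)))
        res = cast_field(pos[0], theta[0], bl[0], bodies, arena, cfg,
                         field="full", fish_id=0)
        poly = ShPolygon(res.visible_polygon)
        eye = _eye_point(pos[0], theta[0], bl[0], cfg, arena)
        half = cfg.field_half_angle("full")
        xs = np.linspace(-650, 650, 80)
        ys = np.linspace(-350, 350, 44)
        agree = total = 0
        for x in xs:
            for y in ys:
                p = np.array([x, y])
                if not arena.contains(p):
                    continue
                total += 1
                by_oracle = _point_visible(eye, theta[0], half, p, bodies,
                                           arena.diagonal_mm, 0)
                by_polygon = poly.contains(Point(x, y))
                agree += by_oracle == by_polygon
        assert agree / total >= 0.98


class TestFieldAngleRobustness:
    @pytest.mark.parametrize("half_angle", [10.0, 15.0, 20.0])
    def test_coverage_order_effect_across_binocular_angles(self, arena, half_angle):
        """Disordered groups out-cover polarized ones for any plausible
        binocular half-angle, not just the 15-degree default."""
        from shoalsight.simulate import SimConfig, simulate_shoal
        from shoalsight.vision import collective_coverage

        cfg = VisionConfig(binocular_half_angle_deg=half_angle)

        def mean_cov(w_align, seed0):
            vals = []
            for k in range(20):
                traj, theta = simulate_shoal(SimConfig(seed=seed0 + k, w_align=w_align),
                                             n_frames=300)
                vals.append(collective_coverage(traj.positions[:, 298], theta[:, 298],
                                                traj.body_length_mm, arena, cfg,
                                                "binocular"))
            return np.mean(vals)

        assert mean_cov(-0.5, 81_000) > mean_cov(3.0, 82_000)
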