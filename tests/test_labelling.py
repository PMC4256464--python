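import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from goldstereo.annotations import Compartment, Profile
from goldstereo.labelling import (
    AssignmentParams,
    assign_particles,
    distance_to_profile,
    labelling_density,
    pool_counts,
)
from goldstereo.scene import LabellingModel, SceneParams, make_scene, place_gold

from ._oracles import brute_force_distance
from .conftest import random_polylines


class TestDistanceToProfile:
    def test_perpendicular_foot(self):
        seg = np.array([[-10.0, 0.0], [10.0, 0.0]])
        assert distance_to_profile((0.0, 5.0), seg) == pytest.approx(5.0)

    def test_beyond_segment_end_uses_endpoint(self):
        seg = np.array([[-10.0, 0.0], [10.0, 0.0]])
        assert distance_to_profile((20.0, 0.0), seg) == pytest.approx(10.0)

    def test_single_point_polyline_rejected(self):
        with pytest.raises(ValueError):
            distance_to_profile((0.0, 0.0), np.array([[1.0, 1.0]]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            poly = random_polylines(rng, int(rng.integers(1, 15)), extent=500.0)
            point = rng.uniform(-100.0, 600.0, size=2)
            mine = distance_to_profile(point, poly)
            ref = brute_force_distance(point, poly)
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-9)


def _profile(comp, y):
    return Profile(comp, np.array([[0.0, y], [100.0, y]]))


class TestAssignParticles:
    def test_within_threshold_assigned(self):
        res = assign_particles(
            np.array([[50.0, 5.0]]), [_profile(Compartment.PLASMA_MEMBRANE, 0.0)]
        )
        assert res.counts[Compartment.PLASMA_MEMBRANE] == 1
        assert res.unassigned == 0

    def test_outside_threshold_unassigned(self):
        res = assign_particles(
            np.array([[50.0, 40.0]]), [_profile(Compartment.PLASMA_MEMBRANE, 0.0)]
        )
        assert res.counts[Compartment.PLASMA_MEMBRANE] == 0
        assert res.unassigned == 1

    def test_boundary_is_strict(self):
        res = assign_particles(
            np.array([[50.0, 15.0]]), [_profile(Compartment.PLASMA_MEMBRANE, 0.0)]
        )
        assert res.unassigned == 1

    def test_exact_tie_goes_to_lexicographic_first(self):
        # equidistant (10 nm) between endo_membrane and mitosome profiles
        profiles = [
            _profile(Compartment.MITOSOME, 0.0),
            _profile(Compartment.ENDO_MEMBRANE, 20.0),
        ]
        res = assign_particles(np.array([[50.0, 10.0]]), profiles)
        assert res.counts[Compartment.ENDO_MEMBRANE] == 1
        assert res.counts[Compartment.MITOSOME] == 0

    def test_nearest_wins_when_within_both(self):
        profiles = [
            _profile(Compartment.MITOSOME, 0.0),
            _profile(Compartment.ENDO_MEMBRANE, 20.0),
        ]
        res = assign_particles(np.array([[50.0, 12.0]]), profiles)
        assert res.counts[Compartment.ENDO_MEMBRANE] == 1

    def test_empty_inputs(self):
        res = assign_particles(np.empty((0, 2)), [])
        assert res.total == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(5.0, 60.0))
    def test_conservation_and_threshold_monotonicity(self, seed, threshold):
        """assigned + unassigned == total, and a larger threshold never
        loses particles from any compartment."""
        rng = np.random.default_rng(seed)
        scene = make_scene(SceneParams(seed=seed % 1000))
        particles = rng.uniform(0.0, 3000.0, size=(60, 2))
        base = assign_particles(
            particles, scene.profiles, AssignmentParams(assoc_dist_nm=threshold)
        )
        assert base.total == 60
        wider = assign_particles(
            particles, scene.profiles, AssignmentParams(assoc_dist_nm=threshold + 20)
        )
        for c in base.counts:
            assert wider.counts[c] >= base.counts[c]

    def test_recovery_of_true_origins(self):
        """With jitter << threshold and no background, nearly all specific
        gold is recovered into its true compartment."""
        model = LabellingModel(background_intensity=0.0, jitter_sd_nm=2.0)
        hits = total = 0
        for seed in range(20):
            scene = make_scene(SceneParams(seed=seed))
            gold = place_gold(scene, model, "native", seed=seed + 1000)
            res = assign_particles(gold.points, scene.profiles)
            hits += int((res.labels == gold.origins).sum())
            total += len(gold.points)
        assert total > 500
        assert hits / total >= 0.99


class TestLabellingDensity:
    def test_basic_arithmetic(self):
        out = labelling_density(
            {Compartment.PLASMA_MEMBRANE: 20}, {Compartment.PLASMA_MEMBRANE: 4000.0}
        )
        assert out[Compartment.PLASMA_MEMBRANE].density_per_um == pytest.approx(5.0)

    def test_zero_count_zero_density(self):
        out = labelling_density(
            {Compartment.MITOSOME: 0}, {Compartment.MITOSOME: 4000.0}
        )
        assert out[Compartment.MITOSOME].density_per_um == 0.0

    def test_zero_length_density_undefined_not_zero(self):
        out = labelling_density({Compartment.MITOSOME: 3}, {Compartment.MITOSOME: 0.0})
        assert out[Compartment.MITOSOME].density_per_um is None

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            labelling_density(
                {Compartment.MITOSOME: -1}, {Compartment.MITOSOME: 10.0}
            )

    def test_pooling_is_ratio_of_sums(self):
        c = Compartment.PLASMA_MEMBRANE
        N, L = pool_counts([({c: 10}, {c: 1000.0}), ({c: 0}, {c: 3000.0})])
        pooled = labelling_density(N, L)[c].density_per_um
        assert pooled == pytest.approx(2.5)  # 10 gold / 4 um, not mean of ratios
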