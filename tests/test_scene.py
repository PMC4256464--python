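import dataclasses
import math

import numpy as np
import pytest

from goldstereo.annotations import Compartment
from goldstereo.scene import (
    LabellingModel,
    SceneParams,
    StudyGroundTruth,
    make_scene,
    place_gold,
    simulate_study,
)


class TestSceneParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cell_radius_nm": -1.0},
            {"field_size_nm": 0.0},
            {"mito_axis_range_nm": (300.0, 50.0)},
            {"endo_len_range_nm": (-10.0, 100.0)},
            {"n_mitosomes": -1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneParams(**kwargs)


class TestMakeScene:
    def test_no_mitosomes_gives_zero_true_length(self):
        scene = make_scene(SceneParams(n_mitosomes=0, seed=3))
        assert scene.true_length_nm[Compartment.MITOSOME] == 0.0

    def test_degenerate_axis_range_gives_circle_circumference(self):
        scene = make_scene(
            SceneParams(n_mitosomes=1, mito_axis_range_nm=(300.0, 300.0), seed=3)
        )
        # a 300 nm circle: circumference pi*300, short of the exact value
        # only by polyline discretisation
        L = scene.true_length_nm[Compartment.MITOSOME]
        assert L == pytest.approx(math.pi * 300.0, rel=5e-3)
        assert L < math.pi * 300.0  # inscribed polygon is strictly shorter

    def test_true_length_matches_analytic_polyline_sum(self, default_scene):
        for comp, total in default_scene.true_length_nm.items():
            manual = sum(
                p.length_nm for p in default_scene.profiles if p.compartment == comp
            )
            assert total == pytest.approx(manual, abs=1e-9)

    def test_determinism_and_seed_sensitivity(self):
        params = SceneParams(seed=42)
        a, b = make_scene(params), make_scene(params)
        for pa, pb in zip(a.profiles, b.profiles):
            np.testing.assert_array_equal(pa.points, pb.points)
        c = make_scene(SceneParams(seed=43))
        assert not np.array_equal(a.profiles[0].points, c.profiles[0].points)

    def test_expected_profile_inventory(self, default_scene):
        by_comp = {}
        for p in default_scene.profiles:
            by_comp.setdefault(p.compartment, []).append(p)
        assert len(by_comp[Compartment.PLASMA_MEMBRANE]) == 1
        assert len(by_comp[Compartment.NUCLEAR_ENVELOPE]) == 1
        assert len(by_comp[Compartment.ENDO_MEMBRANE]) == 4
        assert len(by_comp[Compartment.MITOSOME]) == 4
        assert all(p.closed for p in by_comp[Compartment.MITOSOME])
        assert not any(p.closed for p in by_comp[Compartment.ENDO_MEMBRANE])


class TestPlaceGold:
    def test_zero_rates_give_empty_particle_list(self, default_scene):
        model = LabellingModel(
            specific_density={c: 0.0 for c in Compartment if c != Compartment.NONE},
            background_intensity=0.0,
        )
        gold = place_gold(default_scene, model, "native", seed=1)
        assert gold.points.shape == (0, 2)

    def test_unknown_condition_rejected(self, default_scene):
        with pytest.raises(ValueError, match="condition"):
            place_gold(default_scene, LabellingModel(), "blocked", seed=1)

    def test_specific_counts_match_poisson_expectation(self, default_scene):
        """Mean specific count over many seeds ~ lambda * true length, and
        the index of dispersion is Poisson-like."""
        lam = 5.0
        model = LabellingModel(
            specific_density={Compartment.PLASMA_MEMBRANE: lam},
            background_intensity=0.0,
        )
        L_um = default_scene.true_length_nm[Compartment.PLASMA_MEMBRANE] / 1000.0
        expected = lam * L_um
        counts = np.array(
            [
                len(place_gold(default_scene, model, "native", seed=s).points)
                for s in range(2000)
            ]
        )
        se = math.sqrt(expected / len(counts))
        assert counts.mean() == pytest.approx(expected, abs=3 * se)
        dispersion = counts.var(ddof=1) / counts.mean()
        assert 0.8 < dispersion < 1.2

    def test_complete_inhibition_leaves_only_background(self, default_scene):
        model = LabellingModel(inhibition_efficiency=1.0)
        area_um2 = (default_scene.params.field_size_nm / 1000.0) ** 2
        expected = model.background_intensity * area_um2
        counts = []
        for s in range(2000):
            gold = place_gold(default_scene, model, "inhibited", seed=s)
            assert set(gold.origins) <= {"background"}
            counts.append(len(gold.points))
        se = math.sqrt(expected / len(counts))
        assert np.mean(counts) == pytest.approx(expected, abs=3 * se)

    def test_expected_count_nonincreasing_in_inhibition(self, default_scene):
        means = []
        for rho in (0.0, 0.5, 1.0):
            model = LabellingModel(inhibition_efficiency=rho)
            means.append(
                np.mean(
                    [
                        len(place_gold(default_scene, model, "inhibited", s).points)
                        for s in range(300)
                    ]
                )
            )
        assert means[0] >= means[1] >= means[2]


class TestSimulateStudy:
    def test_annotation_count(self, small_study):
        annotations, _ = small_study
        assert len(annotations) == 2 * 3 * 2  # experiments x micrographs x conditions

    def test_default_protocol_scale(self):
        annotations, truth = simulate_study(
            SceneParams(n_mitosomes=0, n_endo_tubules=0),
            LabellingModel(background_intensity=0.0),
            seed=9,
        )
        assert len(annotations) == 3 * 18 * 2
        assert truth.n_experiments == 3
        assert truth.micrographs_per_condition == 18

    def test_ground_truth_roundtrip(self, small_study, tmp_path):
        _, truth = small_study
        truth.write_json(tmp_path / "gt.json")
        back = StudyGroundTruth.read_json(tmp_path / "gt.json")
        assert back.scene_params == truth.scene_params
        assert back.model == truth.model
        assert back.true_length_nm == truth.true_length_nm
        assert back.seed == truth.seed

    def test_identical_seeds_identical_output(self):
        kwargs = dict(
            scene_params=SceneParams(),
            model=LabellingModel(),
            n_experiments=1,
            micrographs_per_condition=2,
            seed=77,
        )
        a, _ = simulate_study(**kwargs)
        b, _ = simulate_study(**kwargs)
        for x, y in zip(a, b):
            assert x.to_dict() == y.to_dict()
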