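import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pharmnet.chemio_features import FeaturePoint, FeaturePointSet
from pharmnet.errors import ConfigError, DomainError, ModelError, OrientationError
from pharmnet.pharmacophore import (
    ActivityClass,
    FilterConfig,
    MatchConfig,
    ModelFeature,
    PharmacophoreModel,
    classify_activity,
    compound_matches,
    evaluate_model,
    match,
    match_rmsd,
    screen_library,
)
from pharmnet.synthetic_data import (
    SyntheticLibrarySpec,
    generate_matching_library,
    generate_random_feature_sets,
)

from _oracles import brute_force_match, superpose_rmsd_oracle
from conftest import make_record


def triangle_model(d12, d13, d23, types=("HYD_ARO", "HYD", "HBA"), radii=(1.0, 1.0, 1.0)):
    return PharmacophoreModel(
        features=tuple(
            ModelFeature(f"F{i+1}", t, r) for i, (t, r) in enumerate(zip(types, radii))
        ),
        distances=((0.0, d12, d13), (d12, 0.0, d23), (d13, d23, 0.0)),
    )


def feature_set(coords, types, name="probe"):
    return FeaturePointSet(
        name, 0, [FeaturePoint(t, tuple(x), ()) for t, x in zip(types, coords)]
    )


class TestEmbedModel:
    def test_igf1r_model_distances_reproduced(self, igf1r_model, model_coords):
        d = np.linalg.norm(model_coords[:, None] - model_coords[None, :], axis=-1)
        np.testing.assert_allclose(d, igf1r_model.distance_matrix(), atol=1e-9, rtol=0)

    def test_canonical_placement(self, model_coords):
        np.testing.assert_allclose(model_coords[0], 0.0, atol=1e-12)
        assert model_coords[1][1] == 0.0 and model_coords[1][2] == 0.0
        assert model_coords[1][0] > 0
        assert model_coords[2][1] >= 0 and model_coords[2][2] == 0.0

    def test_equilateral_closed_form(self):
        coords = triangle_model(1.0, 1.0, 1.0).embed()
        expected = np.array([[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]])
        np.testing.assert_allclose(coords, expected, atol=1e-12)

    def test_triangle_inequality_violation_is_infeasible(self):
        with pytest.raises(ModelError):
            triangle_model(1.0, 1.0, 3.0).embed()

    def test_model_invariants_enforced(self):
        with pytest.raises(ModelError):
            PharmacophoreModel(
                features=(ModelFeature("F1", "HBA", 1.0),), distances=((0.0,),)
            )
        with pytest.raises(ModelError):
            triangle_model(-1.0, 1.0, 1.0)
        with pytest.raises(ModelError):
            ModelFeature("F1", "HBA", 0.0)

    def test_packaged_model_radii(self, igf1r_model):
        assert [f.radius for f in igf1r_model.features] == [1.4, 0.8, 0.9]
        assert [f.feature_type for f in igf1r_model.features] == ["HYD_ARO", "HYD", "HBA"]


class TestMatch:
    def test_identity_placement_matches_exactly(self, igf1r_model, model_coords):
        fs = feature_set(model_coords, [f.feature_type for f in igf1r_model.features])
        res = match(fs, igf1r_model)
        assert res.matched
        assert res.max_pair_deviation == pytest.approx(0.0, abs=1e-12)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_empty_point_set_no_match(self, igf1r_model):
        res = match(FeaturePointSet("empty", 0, []), igf1r_model)
        assert not res.matched
        assert res.assignment is None

    def test_type_incompatibility_blocks_match(self, igf1r_model, model_coords):
        fs = feature_set(model_coords, ["HBD", "HBD", "HBD"])
        assert not match(fs, igf1r_model).matched

    def test_hyd_slot_accepts_aromatic_point(self, igf1r_model, model_coords):
        types = ["HYD_ARO", "HYD_ARO", "HBA"]  # aromatic point in the HYD slot
        fs = feature_set(model_coords, types)
        assert match(fs, igf1r_model).matched
        strict = MatchConfig(hyd_accepts_aromatic=False)
        assert not match(fs, igf1r_model, strict).matched

    def test_hyd_aro_slot_rejects_plain_hyd(self, igf1r_model, model_coords):
        fs = feature_set(model_coords, ["HYD", "HYD", "HBA"])
        assert not match(fs, igf1r_model).matched

    @pytest.mark.parametrize("seed", range(25))
    def test_matcher_equals_brute_force_on_random_8_point_sets(self, igf1r_model, seed):
        fs = generate_random_feature_sets(1, 8, seed)[0]
        got = match(fs, igf1r_model)
        want_matched, want_assign, want_maxdev = brute_force_match(fs, igf1r_model)
        assert got.matched == want_matched
        if want_matched:
            assert got.assignment == want_assign
            assert got.max_pair_deviation == pytest.approx(want_maxdev, abs=1e-12)

    def test_jitter_monotonicity_along_fixed_ray(self, igf1r_model, model_coords):
        rng = np.random.default_rng(7)
        direction = rng.normal(size=model_coords.shape)
        direction /= np.linalg.norm(direction)
        types = [f.feature_type for f in igf1r_model.features]
        seen_false = False
        for amplitude in np.linspace(0.0, 12.0, 60):
            fs = feature_set(model_coords + amplitude * direction, types)
            matched = match(fs, igf1r_model).matched
            if seen_false:
                assert not matched
            seen_false = seen_false or not matched
        assert seen_false  # the ray must eventually leave the tolerance band


class TestMatchRmsd:
    def test_congruent_triple_is_zero(self, model_coords, rng):
        rot = Rotation.random(random_state=rng)
        moved = rot.apply(model_coords) + rng.uniform(-5, 5, 3)
        assert match_rmsd(moved, model_coords) == pytest.approx(0.0, abs=1e-9)

    def test_displaced_point_matches_oracle(self, model_coords):
        probe = model_coords.copy()
        probe[2] += np.array([0.3, 0.0, 0.0])
        got = match_rmsd(probe, model_coords)
        want = superpose_rmsd_oracle(probe, model_coords)
        assert got == pytest.approx(want, abs=1e-9)
        assert got > 0

    def test_reflection_not_allowed(self, model_coords):
        reflected = model_coords * np.array([1.0, -1.0, 1.0])
        got = match_rmsd(reflected, model_coords)
        want = superpose_rmsd_oracle(reflected, model_coords)
        assert got == pytest.approx(want, abs=1e-9)

    def test_random_clouds_match_oracle(self, rng):
        for _ in range(20):
            P = rng.uniform(-5, 5, size=(5, 3))
            Q = rng.uniform(-5, 5, size=(5, 3))
            assert match_rmsd(P, Q) == pytest.approx(superpose_rmsd_oracle(P, Q), abs=1e-8)

    def test_fewer_than_three_points_is_error(self):
        with pytest.raises(OrientationError):
            match_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "ic50,expected",
        [
            (0.04, ActivityClass.MOST_ACTIVE),
            (0.5, ActivityClass.MOST_ACTIVE),
            (0.500001, ActivityClass.MODERATELY_ACTIVE),
            (20.0, ActivityClass.MODERATELY_ACTIVE),
            (60.0, ActivityClass.LESS_ACTIVE),
            (60.1, ActivityClass.INACTIVE),
            (200.0, ActivityClass.INACTIVE),
        ],
    )
    def test_thresholds(self, ic50, expected):
        assert classify_activity(ic50) is expected

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_is_domain_error(self, bad):
        with pytest.raises(DomainError):
            classify_activity(bad)


class TestEvaluateModel:
    def test_perfect_library_gives_accuracy_one(self, igf1r_model):
        spec = SyntheticLibrarySpec(n_positive=21, n_negative=2, jitter_sigma=0.2,
                                    decoy_points_range=(0, 3), seed=42)
        library = generate_matching_library(spec, igf1r_model)
        # independent per-compound check before trusting the report
        for fs, label in library:
            assert brute_force_match(fs, igf1r_model)[0] == (label == "active")
        report = evaluate_model(igf1r_model, library)
        assert (report.tp, report.tn, report.fp, report.fn) == (21, 2, 0, 0)
        assert report.accuracy == 1.0

    def test_infinite_tolerance_degenerates(self, igf1r_model):
        spec = SyntheticLibrarySpec(n_positive=5, n_negative=5, seed=3)
        library = generate_matching_library(spec, igf1r_model)
        loose = PharmacophoreModel(
            features=tuple(
                ModelFeature(f.label, f.feature_type, 1e6) for f in igf1r_model.features
            ),
            distances=igf1r_model.distances,
        )
        report = evaluate_model(loose, library)
        assert report.sensitivity == 1.0
        assert report.specificity == 0.0

    def test_counts_partition_labels(self, igf1r_model):
        spec = SyntheticLibrarySpec(n_positive=4, n_negative=3, seed=11)
        library = generate_matching_library(spec, igf1r_model)
        report = evaluate_model(igf1r_model, library)
        assert report.tp + report.fn == 4
        assert report.tn + report.fp == 3

    def test_empty_library_is_error(self, igf1r_model):
        with pytest.raises(DomainError):
            evaluate_model(igf1r_model, [])

    def test_undefined_rates_are_none_not_zero(self):
        from pharmnet.pharmacophore import EvaluationReport

        rep = EvaluationReport(tp=0, fp=0, tn=3, fn=0)
        assert rep.sensitivity is None
        assert rep.specificity == 1.0


# a permissive model that common drug-like aromatics can satisfy
PERMISSIVE = PharmacophoreModel(
    features=(
        ModelFeature("F1", "HYD_ARO", 4.0),
        ModelFeature("F2", "HYD", 4.0),
        ModelFeature("F3", "HBA", 4.0),
    ),
    distances=((0.0, 4.0, 5.0), (4.0, 0.0, 6.0), (5.0, 6.0, 0.0)),
)

HBD5_POLYOL = "OCC(O)C(O)C(O)CO"  # xylitol: 5 donors, 5 acceptors

POLYOL_MODEL = PharmacophoreModel(
    features=(
        ModelFeature("F1", "HBD", 5.0),
        ModelFeature("F2", "HBA", 5.0),
        ModelFeature("F3", "HBA", 5.0),
    ),
    distances=((0.0, 3.0, 4.0), (3.0, 0.0, 3.0), (4.0, 3.0, 0.0)),
)


class TestScreenLibrary:
    def test_ethanol_cannot_match_three_features(self, igf1r_model):
        report = screen_library([make_record("CCO", "ethanol")], igf1r_model)
        assert report.stage_survivors["pharmacophore"] == 0
        assert report.hits == []

    def test_hbd_boundary_strict_vs_inclusive(self):
        rec = make_record(HBD5_POLYOL, "xylitol")
        assert compound_matches(rec, POLYOL_MODEL)
        report = screen_library([rec], POLYOL_MODEL)
        outcome = report.results[0].stages
        assert outcome["pharmacophore"].passed
        assert not outcome["lipinski"].passed
        assert "hbd" in outcome["lipinski"].reason
        inclusive = screen_library([rec], POLYOL_MODEL, {"lipinski_inclusive": True})
        assert inclusive.results[0].stages["lipinski"].passed

    def test_unknown_filter_key_is_config_error(self, igf1r_model):
        with pytest.raises(ConfigError, match="bogus"):
            screen_library([make_record("CCO", "e")], igf1r_model, {"bogus": 1})

    def test_final_hits_equal_intersection_of_stage_pass_sets(self):
        smiles = {
            "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
            "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
            "paracetamol": "CC(=O)Nc1ccc(O)cc1",
            "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
            "xylitol": HBD5_POLYOL,
            "decane": "CCCCCCCCCC",
            "ethanol": "CCO",
            "naproxen": "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
            "diphenhydramine": "CN(C)CCOC(c1ccccc1)c1ccccc1",
            "glyceryl": "OCC(O)CO",
        }
        library = [make_record(s, n) for n, s in smiles.items()]
        report = screen_library(library, PERMISSIVE)

        from pharmnet.chemio_features import compute_descriptors

        pharm_pass = {r.id for r in library if compound_matches(r, PERMISSIVE)}
        lip_pass, drug_pass = set(), set()
        for r in library:
            d = compute_descriptors(r)
            if d.hbd_count < 5 and d.hba_count < 10:
                lip_pass.add(r.id)
            if d.rotatable_bonds <= 10 and 1 <= d.ring_count <= 6 and d.tpsa <= 140.0:
                drug_pass.add(r.id)
        assert set(report.hits) == pharm_pass & lip_pass & drug_pass
        assert len(report.hits) > 0

    def test_survivor_counts_non_increasing_and_order_invariant(self):
        library = [
            make_record(s, n)
            for n, s in [
                ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
                ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
                ("ethanol", "CCO"),
                ("xylitol", HBD5_POLYOL),
            ]
        ]
        report = screen_library(library, PERMISSIVE)
        counts = report.stage_survivors
        assert counts["input"] >= counts["pharmacophore"] >= counts["lipinski"] >= counts["druglike"]
        shuffled = screen_library(list(reversed(library)), PERMISSIVE)
        assert shuffled.stage_survivors == counts
        assert set(shuffled.hits) == set(report.hits)

    def test_empty_library_is_error(self, igf1r_model):
        with pytest.raises(DomainError):
            screen_library([], igf1r_model)


def test_filter_config_rejects_unknown_keys():
    with pytest.raises(ConfigError):
        FilterConfig.from_dict({"tpsa_max": 120.0, "nonsense": True})
    cfg = FilterConfig.from_dict({"tpsa_max": 120.0})
    assert cfg.tpsa_max == 120.0


def test_model_yaml_roundtrip(tmp_path, igf1r_model):
    path = tmp_path / "model.yaml"
    igf1r_model.to_yaml(path)
    back = PharmacophoreModel.from_yaml(path)
    assert back == igf1r_model
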