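"""Retention-time model: design matrix, LOOCV, flags, series diagnostics."""

import numpy as np
import pytest

from lipidqc import (
    MS1,
    MS2,
    RTModelConfig,
    SyntheticConfig,
    build_design_matrix,
    check_saturation_series,
    flag_outliers,
    generate_lipidome,
    internal_consistency,
    loocv_predict,
    run_qc,
)
from lipidqc.rt_qc import _loocv_fold

from conftest import make_table


@pytest.fixture
def config():
    return RTModelConfig()


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"C": 0},
            {"C": -1},
            {"epsilon": -0.1},
            {"threshold_frac": 0},
            {"threshold_frac": 1.0},
            {"runtime_min": 0},
            {"scaling": "none"},
            {"kernel": "rbf"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RTModelConfig(**kwargs)

    def test_default_threshold_is_three_quarters_of_a_minute(self, config):
        assert config.threshold_min == pytest.approx(0.75)


class TestDesignMatrix:
    def test_dimensions_and_column_order(self, config):
        table = make_table(
            [
                ("C51H98O6", "TG", 7.8),
                ("C53H102O6", "TG", 8.1),
                ("C55H106O6", "TG", 8.4),
                ("C36H64NO8P", "PC", 6.5),
                ("C38H68NO8P", "PC", 6.7),
            ]
        )
        m = build_design_matrix(table, config)
        assert m.X.shape == (5, 5 + 2)
        assert m.feature_names == ["C", "H", "N", "O", "P", "class:PC", "class:TG"]

    def test_one_hot_rows_sum_to_one(self, config):
        table = make_table(
            [("C51H98O6", "TG", 7.8), ("C36H64NO8P", "PC", 6.5), ("C33H62O5", "DG", 6.78)]
        )
        m = build_design_matrix(table, config)
        np.testing.assert_array_equal(m.X[:, m.n_numeric :].sum(axis=1), 1.0)

    def test_global_autoscaling_centres_numeric_block(self, config):
        table, _ = generate_lipidome(SyntheticConfig(n=40, seed=0))
        m = build_design_matrix(table, config)
        num = m.X[:, : m.n_numeric]
        np.testing.assert_allclose(num.mean(axis=0), 0.0, atol=1e-9)
        sd = num.std(axis=0)
        np.testing.assert_allclose(sd[sd > 0], 1.0, atol=1e-9)

    def test_single_row_table_rejected(self, config):
        with pytest.raises(ValueError):
            build_design_matrix(make_table([("C51H98O6", "TG", 7.8)]), config)

    def test_constant_target_warns(self, config):
        table = make_table([("C51H98O6", "TG", 5.0), ("C51H96O6", "TG", 5.0)])
        with pytest.warns(UserWarning):
            build_design_matrix(table, config)


class TestLOOCV:
    def test_matches_explicit_refit_loop(self, config):
        """The support-vector shortcut must equal the n-refit loop oracle."""
        table, _ = generate_lipidome(SyntheticConfig(n=12, noise_sd=0.3, seed=3))
        m = build_design_matrix(table, config)
        fast = loocv_predict(m, config)
        loop = np.array([_loocv_fold(m, config, i) for i in range(12)])
        np.testing.assert_allclose(fast, loop, atol=1e-3)

    def test_recovers_noiseless_linear_structure(self):
        config = RTModelConfig(epsilon=0.01)
        table, _ = generate_lipidome(SyntheticConfig(n=40, noise_sd=0.0, seed=7))
        m = build_design_matrix(table, config)
        residuals = m.y - loocv_predict(m, config)
        assert np.abs(residuals).max() < 0.05

    def test_duplicated_row_predicted_by_its_twin(self, config):
        rows = [
            ("C51H98O6", "TG", 7.8),
            ("C51H98O6", "TG", 7.8),
            ("C53H102O6", "TG", 8.1),
            ("C36H64NO8P", "PC", 6.5),
            ("C38H68NO8P", "PC", 6.7),
        ]
        m = build_design_matrix(make_table(rows), config)
        preds = loocv_predict(m, config)
        assert preds[0] == pytest.approx(preds[1], abs=1e-3)
        assert abs(preds[0] - 7.8) < 2 * config.epsilon + 1e-3

    def test_permutation_invariance(self, config):
        table, _ = generate_lipidome(SyntheticConfig(n=15, seed=11))
        m = build_design_matrix(table, config)
        preds = loocv_predict(m, config)
        order = np.random.default_rng(0).permutation(15)
        shuffled = table.replace([table.annotations[i] for i in order])
        m2 = build_design_matrix(shuffled, config)
        preds2 = loocv_predict(m2, config)
        np.testing.assert_allclose(preds2, preds[order], atol=1e-3)

    def test_too_small_table_rejected(self, config):
        table, _ = generate_lipidome(SyntheticConfig(n=5, seed=0))
        m = build_design_matrix(table, config)
        m.X, m.y = m.X[:1], m.y[:1]
        with pytest.raises(ValueError):
            loocv_predict(m, config)

    def test_per_fold_scaling_close_to_global(self):
        """Leakage-free scaling is a small perturbation, not a regime change."""
        table, _ = generate_lipidome(SyntheticConfig(n=30, seed=13))
        g = RTModelConfig(scaling="global")
        p = RTModelConfig(scaling="per_fold")
        pred_g = loocv_predict(build_design_matrix(table, g), g)
        pred_p = loocv_predict(build_design_matrix(table, p), p)
        assert np.abs(pred_g - pred_p).max() < 0.5


class TestFlagging:
    # residuals printed for the saturation/headgroup worked examples
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.07, False), (0.02, False), (-0.04, False), (1.12, True), (-1.08, True),
         (-0.03, False), (0.75, False), (0.7500001, True)],
    )
    def test_five_percent_runtime_rule(self, config, delta, expected):
        flags = flag_outliers(np.array([5.0 + delta]), np.array([5.0]), config)
        assert flags[0] == expected

    def test_length_mismatch_rejected(self, config):
        with pytest.raises(ValueError):
            flag_outliers(np.zeros(3), np.zeros(2), config)

    def test_internal_consistency(self):
        assert internal_consistency([True, False, False, False, False]) == pytest.approx(0.8)
        assert internal_consistency([False, False]) == 1.0
        with pytest.raises(ValueError):
            internal_consistency([])

    def test_consistency_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        actual = rng.uniform(2, 12, 50)
        predicted = actual + rng.normal(0, 0.6, 50)
        cons = []
        for frac in (0.01, 0.03, 0.05, 0.1, 0.2):
            cfg = RTModelConfig(threshold_frac=frac)
            cons.append(internal_consistency(flag_outliers(actual, predicted, cfg)))
        assert cons == sorted(cons)


class TestSaturationSeries:
    def test_monotone_series_is_clean(self):
        table = make_table(
            [("C51H92O6", "TG", 7.42), ("C51H94O6", "TG", 7.55), ("C51H96O6", "TG", 7.69)]
        )
        assert check_saturation_series(table) == []

    def test_inverted_member_reported_once(self):
        table = make_table(
            [
                ("C51H92O6", "TG", 7.42),
                ("C51H94O6", "TG", 7.55),
                ("C51H96O6", "TG", 7.69),
                ("C51H98O6", "TG", 6.62),
            ]
        )
        violations = check_saturation_series(table)
        assert len(violations) == 1
        v = violations[0]
        assert (v.h_low, v.h_high) == (96, 98)
        assert v.formula_high == "C51H98O6"

    def test_single_member_groups_never_violate(self):
        table = make_table(
            [("C51H92O6", "TG", 9.0), ("C53H92O6", "TG", 2.0), ("C36H64NO8P", "PC", 1.5)]
        )
        assert check_saturation_series(table) == []

    def test_groups_split_on_non_h_elements_and_class(self):
        # same C/H pattern, different class and O count: separate series
        table = make_table(
            [("C51H92O6", "TG", 7.42), ("C51H98O6", "TG", 6.62),
             ("C51H92O5", "DG", 7.42), ("C51H98O5", "DG", 7.60)]
        )
        violations = check_saturation_series(table)
        assert len(violations) == 1
        assert violations[0].lipid_class == "TG"


class TestRunQC:
    def test_noiseless_clean_pipeline_is_fully_consistent(self):
        table, _ = generate_lipidome(SyntheticConfig(n=60, noise_sd=0.0, seed=1))
        report = run_qc(table, RTModelConfig())
        assert report.consistency_overall == 1.0

    def test_void_volume_rows_are_excluded_from_evaluation(self):
        table, _ = generate_lipidome(SyntheticConfig(n=30, seed=2))
        low = table.annotations[0]
        import dataclasses

        table = table.replace(
            [dataclasses.replace(low, rt_min=0.4)] + table.annotations[1:]
        )
        report = run_qc(table, RTModelConfig())
        assert len(report.per_annotation) == 29
        assert low.id not in set(report.per_annotation["id"])

    def test_ms_level_consistencies_cover_split(self):
        table, _ = generate_lipidome(SyntheticConfig(n=40, seed=4))
        report = run_qc(table, RTModelConfig())
        levels = [a.ms_level for a in table]
        assert (MS1 in levels) and (MS2 in levels)
        assert report.consistency_ms1 is not None
        assert report.consistency_ms2 is not None
        n1 = levels.count(MS1)
        n2 = levels.count(MS2)
        overall = (n1 * report.consistency_ms1 + n2 * report.consistency_ms2) / (n1 + n2)
        assert report.consistency_overall == pytest.approx(overall)


def test_headgroup_offsets_order_predictions_at_matched_composition():
    """With a lower PC offset than DG in the generator, the fitted model
    predicts earlier elution for a PC than for a DG with identical
    element counts (choline headgroup is more hydrophilic)."""
    from lipidqc import SyntheticConfig, fit_full_model, generate_lipidome

    from lipidqc import composition_vector, parse_formula

    cfg = SyntheticConfig(n=120, seed=19)
    pc_spec, dg_spec = cfg.class_by_name("PC"), cfg.class_by_name("DG")
    assert pc_spec.offset_min < dg_spec.offset_min
    table, _ = generate_lipidome(cfg)
    config = RTModelConfig()
    m = build_design_matrix(table, config)
    model = fit_full_model(m, config)

    def predict(spec, carbons, dbe):
        raw = composition_vector(
            parse_formula(spec.formula(carbons, dbe)), m.feature_names[: m.n_numeric]
        )
        num = (np.asarray(raw, dtype=float) - m.numeric_mean) / m.numeric_scale
        onehot = np.zeros(len(m.feature_names) - m.n_numeric)
        onehot[m.feature_names[m.n_numeric :].index(f"class:{spec.name}")] = 1.0
        return model.predict(np.concatenate([num, onehot])[None, :])[0]

    grid = [(c, d) for c in range(34, 42) for d in range(0, 4)]
    pc_mean = np.mean([predict(pc_spec, c, d) for c, d in grid])
    dg_mean = np.mean([predict(dg_spec, c, d) for c, d in grid])
    assert pc_mean < dg_mean
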