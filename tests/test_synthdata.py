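"""Generator contracts: determinism, positivity, calibration, planted truth."""

import numpy as np
import pandas as pd
import pytest

import metaboaging as m
from metaboaging.association import partial_correlation
from metaboaging.errors import ConfigurationError, DataError
from metaboaging.synthdata import VariableSpec, _hinge


def slim_config(seed=0, **var_kwargs):
    spec = VariableSpec(name="met", baseline=np.log(0.2), **var_kwargs)
    return m.GeneratorConfig(
        n_subjects=138, variables=[spec], missing_rate=0.0, seed=seed
    )


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = m.GeneratorConfig(seed=5)
        a = m.generate_cohort(cfg)
        b = m.generate_cohort(m.GeneratorConfig(seed=5))
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.mask, b.mask)

    def test_shape_roles_and_positivity(self, default_cohort):
        t = default_cohort
        assert len(t.data) == 138
        assert sum(r == "age" for r in t.roles.values()) == 1
        assert sum(r == "bmi" for r in t.roles.values()) == 1
        assert sum(r == "sex" for r in t.roles.values()) == 1
        vals = t.data[t.variables("clinical", "metabolite")]
        assert (vals.stack() > 0).all()  # observed concentrations positive
        assert t.data["bmi"].max() < 30.0  # non-obese cohort
        assert t.data["age"].between(20, 70).all()

    def test_missingness_rate_and_cap(self):
        fracs = []
        for s in range(20):
            t = m.generate_cohort(m.GeneratorConfig(seed=s))
            cells = t.data[t.variables("clinical", "metabolite")]
            fracs.append(cells.isna().to_numpy().mean())
            assert cells.isna().mean().max() < 0.1  # per-variable invariant
        assert abs(np.mean(fracs) - 0.02) < 0.005

    def test_noiseless_monotone_trend_gives_perfect_partial_r(self):
        cfg = slim_config(noise_sd=0.0, pre_slope=-0.01, post_slope=-0.01)
        t = m.generate_cohort(cfg)
        r, _, _ = partial_correlation(
            np.log(t.data["met"]), t.data["age"], t.data["bmi"]
        )
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_partial_r_calibration(self):
        # mean realized BMI-partialled correlation within +/-0.05 of target
        cfg_kwargs = dict(
            target_partial_r=-0.28, pre_slope=-0.002, post_slope=-0.010,
            noise_sd=0.25,
        )
        rs = []
        for s in range(200):
            t = m.generate_cohort(slim_config(seed=s, **cfg_kwargs))
            r, _, _ = partial_correlation(
                np.log(t.data["met"]), t.data["age"], t.data["bmi"]
            )
            rs.append(r)
        assert abs(np.mean(rs) - (-0.28)) < 0.05

    def test_planted_hinge_location_exact_when_noiseless(self):
        tau = 37.0
        cfg = m.GeneratorConfig(
            n_subjects=120,
            breakpoint_age=tau,
            variables=[
                VariableSpec(name="met", baseline=0.0, pre_slope=0.004, post_slope=-0.01, noise_sd=0.0)
            ],
            missing_rate=0.0,
            seed=3,
        )
        t = m.generate_cohort(cfg)
        ages = t.data["age"].to_numpy()
        logy = np.log(t.data["met"].to_numpy())
        # each side of the hinge is exactly linear with the configured slope
        for side, slope in ((ages < tau, 0.004), (ages >= tau, -0.01)):
            coef = np.polyfit(ages[side], logy[side], 1)
            assert coef[0] == pytest.approx(slope, abs=1e-12)
        # and the two lines meet exactly at the planted age
        c1 = np.polyfit(ages[ages < tau], logy[ages < tau], 1)
        c2 = np.polyfit(ages[ages >= tau], logy[ages >= tau], 1)
        meet = (c2[1] - c1[1]) / (c1[0] - c2[0])
        assert meet == pytest.approx(tau, abs=1e-6)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="missing_rate"):
            m.generate_cohort(m.GeneratorConfig(seed=0, missing_rate=0.5))
        with pytest.raises(ConfigurationError, match="age_range"):
            m.generate_cohort(m.GeneratorConfig(seed=0, age_range=(50.0, 50.0)))
        with pytest.raises(ConfigurationError, match="target_partial_r"):
            m.generate_cohort(
                slim_config(target_partial_r=-0.99, pre_slope=0.004, post_slope=-0.01)
            )


class TestSplitCohort:
    def test_paper_split_counts(self, default_cohort):
        s = m.split_cohort(default_cohort, 105 / 138, seed=1)
        assert (s.split == "train").sum() == 105
        assert (s.split == "test").sum() == 33

    def test_even_split_small(self):
        t = m.generate_cohort(m.GeneratorConfig(seed=2, n_subjects=10))
        t.data = t.data.iloc[:4]
        t.mask = t.mask.iloc[:4]
        # 4 subjects at 0.5 -> 2/2 (direct construction below the generator minimum)
        s = m.split_cohort(t, 0.5, seed=0)
        assert (s.split == "train").sum() == 2
        assert (s.split == "test").sum() == 2

    def test_same_seed_same_assignment(self, default_cohort):
        a = m.split_cohort(default_cohort, 0.75, seed=9)
        b = m.split_cohort(default_cohort, 0.75, seed=9)
        pd.testing.assert_series_equal(a.split, b.split)

    def test_tiny_arm_rejected(self, default_cohort):
        with pytest.raises(DataError):
            m.split_cohort(default_cohort, 0.99, seed=0)


class TestFeatureTable:
    def test_qc_injections_in_triplicate(self, qc_fixture):
        n_qc = (qc_fixture.injection_class == "qc").sum()
        assert n_qc % 3 == 0 and n_qc == 9

    def test_ground_truth_by_brute_force(self, qc_fixture):
        # apply the three rules directly, independently of featureqc
        ft = qc_fixture
        X = ft.intensities.to_numpy()
        is_s = (ft.injection_class == "sample").to_numpy()
        is_b = (ft.injection_class == "blank").to_numpy()
        is_q = (ft.injection_class == "qc").to_numpy()
        survivors = []
        for i, fid in enumerate(ft.intensities.index):
            blank_ok = np.nanmean(X[i, is_b]) < 0.05 * np.nanmean(X[i, is_s])
            q = X[i, is_q]
            means = [np.nanmean(q[3 * g : 3 * g + 3]) for g in range(len(q) // 3)]
            cv = 100 * np.std(means, ddof=1) / np.mean(means)
            miss = np.isnan(X[i, is_s]).mean()
            if blank_ok and cv < 20 and miss < 0.10:
                survivors.append(fid)
        assert survivors == ft.true_retained
        assert len(survivors) == 6

    def test_determinism_and_positivity(self):
        a = m.generate_feature_table(8, 10, 2, 2, 0.2, seed=4)
        b = m.generate_feature_table(8, 10, 2, 2, 0.2, seed=4)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        assert np.nanmin(a.intensities.to_numpy()) > 0

    def test_zero_drift_zero_cv_gives_identical_qcs(self):
        ft = m.generate_feature_table(3, 8, 1, 2, 0.0, seed=5, qc_cv=0.0)
        is_q = (ft.injection_class == "qc").to_numpy()
        qc = ft.intensities.to_numpy()[:, is_q]
        assert np.allclose(qc, qc[:, [0]], rtol=1e-12)

    def test_bad_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            m.generate_feature_table(0, 5, 1, 1, 0.1, seed=0)
        with pytest.raises(ConfigurationError):
            m.generate_feature_table(4, 5, 1, 1, 0.1, seed=0, n_fail_blank=5)


def test_hinge_is_continuous_at_breakpoint():
    ages = np.array([20.0, 31.999999, 32.0, 32.000001, 70.0])
    t = _hinge(ages, 32.0, 0.004, -0.01)
    assert t[2] == 0.0
    assert abs(t[1] - t[3]) < 1e-4
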