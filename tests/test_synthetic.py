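"""Synthetic cohort generator: calibration, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eaamix.qgc import fit_qgc
from eaamix.simulate import (EXPOSURES, SyntheticSpec, generate_cohort,
                             latent_correlation, nearest_positive_definite,
                             spearman_matrix, standardize_exposures,
                             to_exam_records, NormalMargin,
                             ZeroInflatedLognormalMargin)
from eaamix.exposures import build_exposure_matrix


def test_same_seed_same_table():
    c1, t1 = generate_cohort(SyntheticSpec(seed=3), n=100)
    c2, t2 = generate_cohort(SyntheticSpec(seed=3), n=100)
    pd.testing.assert_frame_equal(c1, c2)
    assert np.array_equal(t1["signal"], t2["signal"])


def test_small_cohort_rejected():
    with pytest.raises(ValueError, match="at least 50"):
        SyntheticSpec(n=10)


def test_asymmetric_targets_rejected():
    bad = pd.DataFrame(np.eye(6), index=EXPOSURES, columns=EXPOSURES)
    bad.iloc[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        SyntheticSpec(spearman_targets=bad)


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self, default_cohort):
        sp = spearman_matrix(default_cohort[0])
        assert np.allclose(np.diag(sp), 1.0)
        assert np.allclose(sp, sp.T)

    def test_monotone_decreasing_pair(self):
        df = pd.DataFrame({e: np.arange(10.0) for e in EXPOSURES})
        df["sleep"] = -df["sleep"]
        sp = spearman_matrix(df)
        assert sp.loc["smoking", "sleep"] == pytest.approx(-1.0)
        assert sp.loc["smoking", "diet"] == pytest.approx(1.0)

    def test_hand_rank_oracle_five_rows(self):
        """Average-rank Spearman against a direct rank computation."""
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        b = np.array([2.0, 7.0, 1.0, 8.0, 2.0])
        df = pd.DataFrame({e: a if i % 2 == 0 else b
                           for i, e in enumerate(EXPOSURES)})
        sp = spearman_matrix(df)
        ra, rb = stats.rankdata(a), stats.rankdata(b)  # average ranks
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert sp.loc["smoking", "alcohol"] == pytest.approx(oracle)


class TestCalibration:
    def test_continuous_pair_matches_classical_conversion(self):
        """Without ties the calibrated latent correlation reduces to the
        classical 2 sin(pi rho_s / 6) rule."""
        m = NormalMargin(0, 1)
        got = latent_correlation(0.36, m, m)
        assert got == pytest.approx(2 * np.sin(np.pi * 0.36 / 6), abs=5e-3)

    def test_zero_inflation_needs_larger_latent_correlation(self):
        cont = NormalMargin(0, 1)
        zi = ZeroInflatedLognormalMargin(0.617, 1717.5, 3348.4)
        plain = latent_correlation(0.33, cont, cont)
        inflated = latent_correlation(0.33, zi, cont)
        assert inflated > plain

    def test_target_spearman_recovered_at_scale(self, big_cohort):
        cohort, _ = big_cohort
        sp = spearman_matrix(cohort)
        targets = SyntheticSpec(seed=1).spearman_targets
        err = (sp - targets).abs().to_numpy()
        np.fill_diagonal(err, 0.0)
        assert err.max() < 0.03

    def test_marginal_means_within_monte_carlo_error(self, big_cohort):
        cohort, _ = big_cohort
        n = len(cohort)
        spec = SyntheticSpec(seed=1)
        # zero-inflated smoking: compare the positive part
        pos = cohort.loc[cohort["smoking"] > 0, "smoking"]
        assert abs(pos.mean() - 1717.5) < 3 * pos.std() / np.sqrt(len(pos))
        assert abs((cohort["smoking"] == 0).mean() - 0.617) < \
            3 * np.sqrt(0.617 * 0.383 / n)
        for col, mean in [("alcohol", 227.5), ("diet", 67.6),
                          ("education", 15.1), ("physical_activity", 350.9),
                          ("sleep", 6.7), ("age", 45.9), ("bmi", 29.3)]:
            s = cohort[col]
            assert abs(s.mean() - mean) < 3 * s.std() / np.sqrt(n), col
        for col, sd in [("diet", 11.8), ("sleep", 1.3), ("education", 2.5)]:
            s = cohort[col]
            se_sd = s.std() * np.sqrt((stats.kurtosis(s) + 2) / (4 * n))
            assert abs(s.std() - sd) < 3 * se_sd + 0.05, col


def test_nearest_pd_repair_restores_definiteness():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    fixed = nearest_positive_definite(bad)
    assert np.linalg.eigvalsh(fixed).min() > 0
    assert np.allclose(np.diag(fixed), 1.0)


class TestGroundTruth:
    def test_zero_noise_zero_effects_outcome_is_covariate_signal(self):
        spec = SyntheticSpec(
            seed=4, noise_sd=0.0, alcohol_curvature=0.0,
            effects={k: 0.0 for k in EXPOSURES})
        cohort, truth = generate_cohort(spec, n=200)
        assert np.allclose(truth["signal"], 0.0)
        # epigenetic age - chronological age is exactly the covariate term
        gap = cohort["epigenetic_age"] - cohort["age"]
        ce = spec.covariate_effects
        expected = (ce["sex_male"] * (cohort["sex"] == "Men")
                    + ce["race_white"] * (cohort["race"] == "White")
                    + ce["bmi_per_unit"] * (cohort["bmi"] - spec.bmi_mean)
                    + [ce["center"][["Birmingham", "Chicago", "Minnesota",
                                     "Oakland"].index(c)]
                       for c in cohort["center"]])
        assert np.allclose(gap, expected, atol=1e-10)

    def test_truth_contrast_matches_manual_computation(self, default_cohort):
        cohort, truth = default_cohort
        z = standardize_exposures(cohort)
        hi, lo = z.quantile(0.75), z.quantile(0.25)
        manual = sum(truth["effects"][k] * (hi[k] - lo[k]) for k in EXPOSURES)
        manual += truth["alcohol_curvature"] * (hi["alcohol"] ** 2
                                                - lo["alcohol"] ** 2)
        assert truth["true_contrast_75_25"] == pytest.approx(manual)

    def test_quantile_effect_mode_yields_exact_psi(self):
        """Noiseless per-quantile effects: QGC recovers psi exactly."""
        qe = {"smoking": 2.0, "diet": -1.0}
        spec = SyntheticSpec(seed=5, noise_sd=0.0, quantile_effects=qe)
        cohort, truth = generate_cohort(spec, n=400)
        assert truth["true_psi"] == pytest.approx(1.0)
        fit = fit_qgc(cohort["epigenetic_age"] - cohort["age"],
                      cohort[list(EXPOSURES)],
                      cohort[["sex", "race", "bmi", "center"]])
        assert fit.psi == pytest.approx(1.0, abs=1e-8)


class TestExamRecordRoundtrip:
    def test_long_emitter_reproduces_cumulative_values(self):
        cohort, _ = generate_cohort(SyntheticSpec(seed=6), n=60)
        long_df = to_exam_records(cohort)
        mat = build_exposure_matrix(long_df)
        raw = mat.raw.loc[cohort["participant_id"]]
        for name in EXPOSURES:
            assert np.allclose(raw[name].to_numpy(),
                               cohort[name].to_numpy(), atol=1e-9), name
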