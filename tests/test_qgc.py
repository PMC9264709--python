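"""Quantile g-computation: quantization, psi, weights, inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from eaamix.qgc import quantize, fit_qgc, bootstrap_psi


class TestQuantize:
    def test_eight_point_quartiles(self):
        # empirical quartile cut-points 2.75 / 4.5 / 6.25
        got = quantize(np.arange(1.0, 9.0), q=4)
        assert got.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_constant_vector_codes_zero_with_warning(self):
        with pytest.warns(UserWarning, match="rank-based"):
            got = quantize(np.full(10, 7.0), q=4)
        assert got.tolist() == [0] * 10

    def test_few_distinct_values_fall_back_to_ranks(self):
        v = np.array([0.0] * 6 + [1.0] * 2)
        with pytest.warns(UserWarning, match="rank-based"):
            got = quantize(v, q=4)
        assert got.max() <= 3
        assert (got[v == 1.0] >= got[v == 0.0].max()).all()

    @given(st.lists(st.floats(-1e3, 1e3), min_size=8, max_size=60,
                    unique=True),
           st.integers(2, 6))
    def test_codes_bounded_and_monotone(self, values, q):
        v = np.array(values)
        if len(np.unique(v)) < q:
            return
        codes = quantize(v, q)
        assert codes.min() >= 0 and codes.max() <= q - 1
        order = np.argsort(v)
        assert (np.diff(codes[order]) >= 0).all()


def _exposure_frame(rng, n, m=4, names=None):
    names = names or [f"x{j}" for j in range(m)]
    return pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)


class TestFitQGC:
    def test_noiseless_mixed_sign_effects(self):
        rng = np.random.default_rng(1)
        expo = _exposure_frame(rng, 200, names=["smoking", "diet", "a", "b"])
        y = (2.0 * quantize(expo["smoking"].to_numpy())
             - 1.0 * quantize(expo["diet"].to_numpy()))
        fit = fit_qgc(y, expo)
        assert fit.psi == pytest.approx(1.0, abs=1e-10)
        assert fit.weights_positive == pytest.approx({"smoking": 1.0})
        assert fit.weights_negative == pytest.approx({"diet": -1.0})

    def test_noiseless_same_sign_weight_ratio(self):
        rng = np.random.default_rng(2)
        expo = _exposure_frame(rng, 150, names=["a", "b"])
        y = (1.5 * quantize(expo["a"].to_numpy())
             + 0.5 * quantize(expo["b"].to_numpy()))
        fit = fit_qgc(y, expo)
        assert fit.psi == pytest.approx(2.0, abs=1e-10)
        assert fit.weights_positive == pytest.approx({"a": 0.75, "b": 0.25})
        assert fit.weights_negative == {}

    def test_null_outcome_ci_covers_zero(self):
        rng = np.random.default_rng(3)
        expo = _exposure_frame(rng, 10_000, m=6)
        y = rng.normal(size=10_000)
        fit = fit_qgc(y, expo)
        assert fit.psi_ci_low < 0 < fit.psi_ci_high

    def test_psi_equals_plain_ols_coefficient_sum(self):
        """Oracle: psi must equal the exposure-coefficient sum of an
        independent least-squares fit on the identical design."""
        rng = np.random.default_rng(4)
        expo = _exposure_frame(rng, 300, m=5)
        covs = pd.DataFrame({"bmi": rng.normal(29, 6, 300),
                             "sex": rng.choice(["M", "W"], 300)})
        y = rng.normal(size=300) + quantize(expo["x0"].to_numpy())
        fit = fit_qgc(y, expo, covs)

        qmat = np.column_stack([quantize(expo[c].to_numpy()) for c in expo])
        dummies = pd.get_dummies(covs, drop_first=True, dtype=float).to_numpy()
        design = np.column_stack([np.ones(300), qmat, dummies])
        coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert fit.psi == pytest.approx(coefs[1:6].sum(), abs=1e-10)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(5)
        expo = _exposure_frame(rng, 200, m=4)
        y = rng.normal(size=200) + quantize(expo["x1"].to_numpy())
        f1 = fit_qgc(y, expo)
        f2 = fit_qgc(y, expo[["x3", "x1", "x0", "x2"]])
        assert f1.psi == pytest.approx(f2.psi, abs=1e-10)
        assert f1.psi_se == pytest.approx(f2.psi_se, abs=1e-10)
        for k, w in f1.weights_positive.items():
            assert f2.weights_positive[k] == pytest.approx(w, abs=1e-10)

    def test_outcome_shift_moves_only_intercept(self):
        rng = np.random.default_rng(6)
        expo = _exposure_frame(rng, 150, m=3)
        y = rng.normal(size=150)
        f1, f2 = fit_qgc(y, expo), fit_qgc(y + 10.0, expo)
        assert f2.beta0 == pytest.approx(f1.beta0 + 10.0)
        assert np.allclose(f1.betas, f2.betas, atol=1e-10)

    def test_constant_exposure_excluded_with_warning(self):
        rng = np.random.default_rng(7)
        expo = _exposure_frame(rng, 100, m=3)
        expo["smoking"] = 0.0  # never-smoker stratum
        y = rng.normal(size=100)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_qgc(y, expo)
        assert fit.excluded == ["smoking"]
        assert "smoking" not in fit.betas.index

    def test_collinear_design_errors_with_column_names(self):
        rng = np.random.default_rng(8)
        expo = _exposure_frame(rng, 100, m=2)
        covs = pd.DataFrame({"dup": quantize(expo["x0"].to_numpy()).astype(float)})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_qgc(rng.normal(size=100), expo, covs)

    def test_weight_sign_partition_sums(self):
        rng = np.random.default_rng(9)
        expo = _exposure_frame(rng, 500, m=6)
        signal = sum(b * quantize(expo[c].to_numpy())
                     for c, b in zip(expo, [2, -1, 0.5, -0.3, 0.1, 0.05]))
        y = signal + rng.normal(0, 1, 500)
        fit = fit_qgc(y, expo)
        assert sum(fit.weights_positive.values()) == pytest.approx(1.0, abs=1e-10)
        assert sum(fit.weights_negative.values()) == pytest.approx(-1.0, abs=1e-10)
        assert all(abs(w) <= 1 + 1e-12 for w in
                   list(fit.weights_positive.values())
                   + list(fit.weights_negative.values()))


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(10)
        expo = _exposure_frame(rng, 120, m=3)
        y = quantize(expo["x0"].to_numpy()) + rng.normal(0, 1, 120)
        ci1 = bootstrap_psi(y, expo, n_boot=200, seed=42)
        ci2 = bootstrap_psi(y, expo, n_boot=200, seed=42)
        assert ci1 == ci2

    def test_noiseless_interval_shrinks_with_sample_size(self):
        """On noiseless linear data the only bootstrap variation comes from
        re-estimated quantile cut-points, so the interval collapses as n
        grows."""
        widths = {}
        for n in (200, 1600):
            rng = np.random.default_rng(11)
            expo = _exposure_frame(rng, n, m=3)
            y = (1.0 * quantize(expo["x0"].to_numpy())
                 + 0.5 * quantize(expo["x1"].to_numpy())).astype(float)
            lo, hi = bootstrap_psi(y, expo, n_boot=200, seed=0)
            widths[n] = hi - lo
        assert widths[1600] < widths[200]
        assert widths[1600] < 0.1

    def test_agrees_with_wald_under_gaussian_noise(self):
        rng = np.random.default_rng(12)
        expo = _exposure_frame(rng, 400, m=4)
        y = quantize(expo["x0"].to_numpy()) + rng.normal(0, 1, 400)
        fit = fit_qgc(y, expo)
        lo, hi = bootstrap_psi(y, expo, n_boot=400, seed=1)
        wald_width = fit.psi_ci_high - fit.psi_ci_low
        assert (hi - lo) == pytest.approx(wald_width, rel=0.30)
        assert lo < fit.psi < hi

    def test_requires_enough_resamples(self):
        rng = np.random.default_rng(13)
        expo = _exposure_frame(rng, 50, m=2)
        with pytest.raises(ValueError, match="200"):
            bootstrap_psi(rng.normal(size=50), expo, n_boot=50)
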