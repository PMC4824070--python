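"""Coupling-model evaluation, grid fitting and bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

import termcouple as tc
from termcouple.coupling import TerminationCouplingModel


def brute_force_poisson_cdf(k: int, lam: float) -> float:
    """Independent oracle: direct pmf summation at high precision."""
    if k < 0:
        return 0.0
    total, term = 0.0, math.exp(-lam)
    for i in range(k + 1):
        total += term
        term *= lam / (i + 1)
    return total


class TestPoissonCdf:
    def test_closed_form_k0(self):
        assert tc.poisson_cdf(0, 1.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_degenerate_lambda_zero(self):
        assert tc.poisson_cdf(5, 0.0) == 1.0

    def test_k_minus_one_is_zero(self):
        assert tc.poisson_cdf(-1, 3.0) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            tc.poisson_cdf(3, -0.1)

    def test_frozen_oracle_value(self):
        # brute-force summation over 0..27 at lambda 33
        assert brute_force_poisson_cdf(27, 33.0) == pytest.approx(0.16952457136622645, abs=1e-12)
        assert tc.poisson_cdf(27, 33.0) == pytest.approx(0.16952457136622645, abs=1e-10)

    def test_agrees_with_brute_force_summation(self):
        for lam in (0.5, 1.0, 5.0, 20.0, 33.0, 60.0, 100.0):
            for k in (0, 1, 5, 27, 60, 120, 200):
                assert tc.poisson_cdf(k, lam) == pytest.approx(
                    brute_force_poisson_cdf(k, lam), abs=1e-12
                )


class TestPredictTe:
    def test_plateau_at_large_distance(self, paper_params):
        te = tc.predict_te(45, "W", paper_params)
        assert paper_params.te0 - te < 1e-4
        assert round(te, 1) == 0.9

    def test_w18_frozen_value(self, paper_params):
        # 0.9 * (1 - CDF(27, 33)); the measured W18 TE was ~0.8
        assert tc.predict_te(18, "W", paper_params) == pytest.approx(0.7474278857703962, abs=1e-9)

    def test_te0_zero_kills_curve(self):
        p = tc.CouplingParams(te0=0.0, alpha=27, offsets={"W": 15})
        assert all(tc.predict_te(d, "W", p) == 0.0 for d in (0, 10, 50))

    def test_unknown_series(self, paper_params):
        with pytest.raises(KeyError):
            tc.predict_te(10, "Q", paper_params)

    def test_negative_lambda_domain_rejected(self):
        p = tc.CouplingParams(te0=0.9, alpha=27, offsets={"W": -5})
        with pytest.raises(ValueError, match="d \\+ c"):
            tc.predict_te(2, "W", p)

    @given(
        te0=st.floats(0.1, 1.0),
        alpha=st.integers(0, 60),
        c=st.integers(0, 40),
        conv=st.sampled_from(["inclusive", "strict"]),
    )
    def test_monotone_and_bounded(self, te0, alpha, c, conv):
        """TE is non-decreasing in d, within [0, te0], and reaches te0."""
        p = tc.CouplingParams(te0=te0, alpha=alpha, offsets={"S": c}, cdf_convention=conv)
        te = tc.predict_te(np.arange(0, 201), "S", p)
        assert np.all(np.diff(te) >= -1e-12)
        assert np.all(te >= 0.0) and np.all(te <= te0 + 1e-12)
        assert te[-1] == pytest.approx(te0, abs=1e-6)

    def test_larger_offset_gives_higher_te(self, paper_params):
        """The W-series (c=15) lies above the R-series (c=7) at equal d: a
        larger offset pushes the ribosome distribution away from the hairpin."""
        d = np.arange(0, 60)
        te_w = tc.predict_te(d, "W", paper_params)
        te_r = tc.predict_te(d, "R", paper_params)
        assert np.all(te_w >= te_r - 1e-12)
        assert te_w[18] > te_r[18]  # the W18-vs-R17 contrast


class TestFitCoupling:
    def test_noiseless_single_series_exact_recovery(self, paper_params):
        table = tc.make_te_table(paper_params, distances={"W": range(5, 49)})
        fit = tc.fit_coupling(table)
        assert fit.params.alpha == 27
        assert fit.params.offsets == {"W": 15}
        assert fit.params.te0 == pytest.approx(0.9, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_noiseless_joint_fit_recovers_both_offsets(self, paper_params):
        table = tc.make_te_table(
            paper_params, distances={"W": range(5, 49), "R": range(9, 60)}
        )
        fit = tc.fit_coupling(table)
        assert fit.params.alpha == 27
        assert fit.params.offsets == {"W": 15, "R": 7}
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_noisy_recovery_within_tolerance(self, paper_params):
        noise = tc.NoiseModel(te_gaussian_sigma=0.02, replicates=3, seed=5)
        table = tc.make_te_table(
            paper_params, distances={"W": range(5, 49), "R": range(9, 60)}, noise=noise
        )
        fit = tc.fit_coupling(table)
        assert abs(fit.params.alpha - 27) <= 1
        assert fit.params.te0 == pytest.approx(0.9, abs=0.02)
        assert abs(fit.params.offsets["W"] - 15) <= 1
        assert abs(fit.params.offsets["R"] - 7) <= 1

    def test_strict_convention_shifts_threshold_consistently(self, paper_params):
        strict = tc.tr2_reference_params("strict")
        table = tc.make_te_table(strict, distances={"W": range(5, 49)})
        fit = tc.fit_coupling(table, cdf_convention="strict")
        assert fit.params.alpha == 27
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            tc.fit_coupling(pd.DataFrame(columns=["series", "distance_nt", "te"]))

    def test_too_few_points_per_series(self):
        df = pd.DataFrame({"series": ["W"] * 3, "distance_nt": [5, 10, 15], "te": [0.1, 0.5, 0.8]})
        with pytest.raises(ValueError, match="fewer than 4"):
            tc.fit_coupling(df)

    def test_unidentifiable_when_no_valid_grid_point(self):
        df = pd.DataFrame({"series": ["W"] * 5, "distance_nt": [0, 1, 2, 3, 4],
                           "te": [0.0, 0.0, 0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="unidentifiable"):
            tc.fit_coupling(df, c_range=(-10, -5))

    def test_objective_grid_contains_minimum(self, paper_params):
        table = tc.make_te_table(paper_params, distances={"W": range(5, 49)})
        fit = tc.fit_coupling(table, alpha_range=(25, 29), c_range=(13, 17), return_grid=True)
        grid = fit.objective_grid
        best = grid.loc[grid["rss"].idxmin()]
        assert best["alpha"] == fit.params.alpha
        assert best["c_W"] == fit.params.offsets["W"]


class TestBootstrap:
    def test_zero_B_rejected(self, paper_params):
        table = tc.make_te_table(paper_params, distances={"W": range(5, 49)})
        with pytest.raises(ValueError):
            tc.bootstrap_ci(table, B=0)

    def test_small_B_warns(self, paper_params):
        table = tc.make_te_table(paper_params, distances={"W": range(8, 49, 4)})
        with pytest.warns(UserWarning, match="small"):
            tc.bootstrap_ci(table, B=5, seed=1, alpha_range=(25, 29), c_range=(13, 17))

    def test_noiseless_intervals_have_zero_width(self, paper_params):
        table = tc.make_te_table(paper_params, distances={"W": range(5, 49, 2)})
        ci = tc.bootstrap_ci(table, B=100, seed=2, alpha_range=(24, 30), c_range=(12, 18))
        for name in ("te0", "alpha", "c_W"):
            lo, hi = ci[name]
            assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_noisy_interval_covers_te0(self, paper_params):
        noise = tc.NoiseModel(te_gaussian_sigma=0.02, replicates=3, seed=3)
        table = tc.make_te_table(paper_params, distances={"W": range(5, 49, 2)}, noise=noise)
        ci = tc.bootstrap_ci(table, B=120, seed=4, alpha_range=(24, 30), c_range=(12, 18))
        lo, hi = ci["te0"]
        assert lo <= 0.9 <= hi
        assert ci["n_degenerate_resamples"] < 120


class TestEstimator:
    def test_fit_predict_round_trip(self, paper_params):
        X = pd.DataFrame(
            {"distance_nt": list(range(5, 49)) + list(range(9, 60)),
             "series": ["W"] * 44 + ["R"] * 51}
        )
        y = np.concatenate(
            [tc.predict_te(np.arange(5, 49), "W", paper_params),
             tc.predict_te(np.arange(9, 60), "R", paper_params)]
        )
        model = TerminationCouplingModel().fit(X, y)
        assert model.alpha_ == 27
        assert model.offsets_ == {"W": 15, "R": 7}
        assert model.te0_ == pytest.approx(0.9, abs=1e-9)
        assert np.allclose(model.predict(X), y, atol=1e-12)
        assert model.score(X, y) == pytest.approx(1.0, abs=1e-12)

    def test_sklearn_protocol(self):
        model = TerminationCouplingModel(alpha_range=(20, 30))
        assert model.get_params()["alpha_range"] == (20, 30)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        with pytest.raises(AttributeError):
            model.predict(pd.DataFrame({"distance_nt": [5], "series": ["W"]}))

    def test_array_input(self, paper_params):
        d = np.arange(5, 49)
        y = tc.predict_te(d, "W", paper_params)
        X = np.array([[float(v), "W"] for v in d], dtype=object)
        model = TerminationCouplingModel().fit(X, y)
        assert model.alpha_ == 27
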