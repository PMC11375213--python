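"""Titleholder likelihood: validation, telescoping, oracles, fitting."""

import warnings

import numpy as np
import pytest
from scipy import integrate, optimize

import recordage as ra

TRUE = dict(alpha=0.01277, K=2.951e-5, gamma=0.08596)


class TestValidation:
    def test_consistent_pair_accepted(self):
        recs = [
            ra.TitleholderRecord(1990.0, 112.0, 110.0),
            ra.TitleholderRecord(1992.5, 112.5, 111.0),
        ]
        assert ra.validate_records(recs, tol=1e-6) == recs

    def test_violation_reports_index_and_residual(self):
        recs = [
            ra.TitleholderRecord(1990.0, 112.0, 110.0),
            ra.TitleholderRecord(1992.5, 112.6, 111.0),
        ]
        with pytest.raises(ra.ConsistencyError) as err:
            ra.validate_records(recs, tol=1e-6)
        assert err.value.index == 1
        assert err.value.residual == pytest.approx(0.1)

    def test_successor_older_than_incumbent_rejected(self):
        with pytest.raises(ra.ConsistencyError):
            ra.validate_records([ra.TitleholderRecord(1990.0, 110.0, 111.0)])

    def test_unsorted_rejected(self):
        recs = [
            ra.TitleholderRecord(1992.5, 112.5, 111.0),
            ra.TitleholderRecord(1990.0, 112.0, 110.0),
        ]
        with pytest.raises(ra.ConsistencyError):
            ra.validate_records(recs, tol=10.0)


class TestLogLikelihood:
    def test_single_record_against_independent_quadrature(self):
        # one transition, everything transcribed from first principles
        rec = ra.TitleholderRecord(t=2000.0, y=114.0, z=111.0)
        model = ra.TitleholderModel([rec])
        alpha, K, gamma, b = 0.013, 3e-5, 0.086, 0.09
        C, kappa = 6270.0, 0.004987

        level = lambda s: K * np.exp(-alpha * (s - 2000.0))
        sf = lambda a, x: (1.0 + a * gamma / b * (np.exp(b * x) - 1.0)) ** (-1.0 / gamma)
        pdf = lambda a, x: a * np.exp(b * x) * (
            1.0 + a * gamma / b * (np.exp(b * x) - 1.0)
        ) ** (-1.0 - 1.0 / gamma)
        lam = lambda s: C * np.exp(kappa * s)

        expo, _ = integrate.quad(
            lambda u: lam(rec.t - u) * sf(level(rec.t - u), u),
            rec.z,
            rec.y,
            epsabs=1e-12,
            limit=200,
        )
        expected = (
            np.log(pdf(level(rec.t - rec.y), rec.y))
            - expo
            + np.log(sf(level(rec.t - rec.z), rec.z))
            + np.log(lam(rec.t - rec.z))
        )
        got = model.loglik(alpha, K, gamma, include_constants=True)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_telescoping_against_per_record_terms(self, synthetic_records, default_proc):
        model = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6)
        chain, prev = 0.0, None
        for rec in synthetic_records:
            chain += ra.record_loglik_term(default_proc, prev, rec)
            prev = rec.z
        full = model.loglik(
            TRUE["alpha"], TRUE["K"], TRUE["gamma"], include_constants=True
        )
        assert full == pytest.approx(chain, abs=1e-8)

    def test_gauss_rule_matches_adaptive_quadrature(self, synthetic_records):
        model = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6)
        a = model.loglik(TRUE["alpha"], TRUE["K"], TRUE["gamma"])
        q = model.loglik(TRUE["alpha"], TRUE["K"], TRUE["gamma"], method="quad")
        assert a == pytest.approx(q, abs=1e-8)

    def test_constants_flag(self, synthetic_records):
        model = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6)
        base = model.loglik(**TRUE)
        full = model.loglik(**TRUE, include_constants=True)
        E = model.entry_age
        expected = model.n_records * np.log(6270.0) + 0.004987 * np.sum(
            model.t - model.z + E
        )
        assert full - base == pytest.approx(expected, rel=1e-12)

    def test_record_term_domain_errors(self, default_proc):
        with pytest.raises(ValueError):
            ra.record_loglik_term(
                default_proc, 115.0, ra.TitleholderRecord(2000.0, 114.0, 111.0)
            )

    def test_nonpositive_parameters_rejected(self, synthetic_records):
        model = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6)
        with pytest.raises(ValueError):
            model.loglik(0.01, -1e-5, 0.08)


@pytest.fixture(scope="module")
def fitted(synthetic_records):
    model = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6)
    return model, model.fit()


class TestFit:
    def test_optimum_beats_perturbed_gamma(self, fitted):
        model, res = fitted
        for factor in (0.5, 1.5):
            assert res.loglik > model.loglik(res.alpha, res.K, res.gamma * factor)

    def test_trace_logliks_nondecreasing(self, fitted):
        _, res = fitted
        lls = [l for l, _ in res.trace]
        assert np.all(np.diff(lls) >= 0)

    def test_log_and_raw_parameterisations_agree(self, synthetic_records):
        # the package optimises log-parameters; a raw-space Nelder-Mead
        # from the same start must reach an equivalent optimum
        model = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6)
        res = model.fit(start=(0.01, 1e-4, 0.1))

        def neg_raw(p):
            try:
                return -model.loglik(*p)
            except (ValueError, FloatingPointError):
                return np.inf

        raw = optimize.minimize(
            neg_raw,
            [0.01, 1e-4, 0.1],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
        )
        assert res.loglik == pytest.approx(-raw.fun, abs=1e-4)

    def test_free_b_degenerates_and_guard_fires(self, synthetic_records):
        # optimising the aging rate as well drives the level parameter
        # to zero: record data only see the far tail of the lifespan law
        model = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6)
        with pytest.warns(ra.DegenerateFitWarning):
            res = model.fit(free_b=True)
        assert res.degenerate
        assert res.K < 1e-10

    def test_summary_mentions_the_estimates(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "alpha" in text and "gamma" in text
        assert f"{res.alpha:.5g}" in text

    def test_results_expose_model_objects(self, fitted):
        _, res = fitted
        assert isinstance(res.trend, ra.MortalityTrend)
        assert isinstance(res.process, ra.RecordAgeProcess)
        frame = res.predict_mean_age([1960.0, 2000.0])
        assert list(frame.columns) == ["year", "mean", "sd"]
        assert frame["mean"].is_monotonic_increasing


class TestScanAndBacktest:
    def test_sensitivity_scan_shape_and_gamma_pattern(self, synthetic_records):
        scan = ra.sensitivity_scan(
            synthetic_records, entry_ages=(0,), bs=(0.09, 0.13), consistency_tol=1e-6
        )
        assert list(scan["b"]) == [0.09, 0.13]
        assert (scan["error"] == "").all()
        # larger fixed aging rate is compensated by larger heterogeneity
        g = scan.set_index("b")["gamma"]
        assert g[0.13] > g[0.09]

    def test_scan_records_per_cell_failures(self, synthetic_records):
        bad = {0: ra.BirthIntensity(C=1e-300, kappa=5.0)}  # overflows in loglik
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scan = ra.sensitivity_scan(
                synthetic_records, entry_ages=(0,), bs=(0.09,), intensities=bad,
                consistency_tol=1e-6,
            )
        assert (scan["error"] != "").any()
        assert not scan["converged"].any()

    def test_backtest_cutoff_beyond_data_has_empty_holdout(self, synthetic_records):
        report = ra.backtest_split(
            synthetic_records, cutoff=2050.0, consistency_tol=1e-6
        )
        assert report.n_holdout == 0
        full = ra.TitleholderModel(synthetic_records, consistency_tol=1e-6).fit()
        assert report.results.loglik == pytest.approx(full.loglik, abs=1e-6)

    def test_backtest_split_structure(self, synthetic_records):
        report = ra.backtest_split(synthetic_records, cutoff=1988.0, consistency_tol=1e-6)
        assert report.n_holdout == sum(r.t > 1988.0 for r in synthetic_records)
        assert len(report.comparison) == report.n_holdout
        assert report.n_outside <= report.n_holdout
        assert report.results.model.n_records == sum(r.t <= 1988.0 for r in synthetic_records)

    def test_backtest_requires_enough_training_records(self, synthetic_records):
        with pytest.raises(ValueError):
            ra.backtest_split(synthetic_records, cutoff=1956.0, consistency_tol=1e-6)

    def test_stationary_trend_train_and_full_fits_agree(self):
        # level frozen in time: truncated and full windows estimate the
        # same law, so the fits differ only by sampling noise
        trend = ra.MortalityTrend(K=1.3e-4, alpha=1e-9, b=0.09, gamma=0.086)
        df = ra.make_synthetic_titleholders(trend=trend, seed=9)
        recs = [
            ra.TitleholderRecord(r.date_death, r.age_death_years, r.successor_age_years)
            for r in df.itertuples()
        ]
        full = ra.TitleholderModel(recs, consistency_tol=1e-6).fit()
        report = ra.backtest_split(recs, cutoff=1995.0, consistency_tol=1e-6)
        assert report.results.gamma == pytest.approx(full.gamma, rel=0.5)
        assert 0.3 < report.results.K / full.K < 3.0
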