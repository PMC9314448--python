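"""Context rates, covariate adjustment, regional rescaling, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from conftest import make_site_table
from ultraselect.errors import ConfigError, NumericalError, ValidationError
from ultraselect.io_genomics import alt_alleles
from ultraselect.mutation_model import (
    ContextRateTable,
    CovariateModel,
    MutationModel,
    RegionalScaler,
    adjusted_logits,
    calibration_report,
    fit_context_rates,
    fit_covariate_model,
    fit_regional_scalers,
    predict_rates,
    window_starts,
)
from ultraselect.simulate import bernoulli_simulate


def truth_rate_table(contexts, rate_fn):
    """Build a ContextRateTable directly from a ground-truth rate function."""
    rows = []
    for ctx in contexts:
        ref = ctx[3]
        alts = alt_alleles(ref)
        rates = {alt: rate_fn(ctx, alt) for alt in alts}
        rates[ref] = 1.0 - sum(rates.values())
        for b, r in rates.items():
            rows.append((ctx, ref, b, r))
    df = pd.DataFrame(rows, columns=["context", "ref", "alt", "rate"])
    from ultraselect.mutation_model import _marginalize

    return ContextRateTable(df, *_marginalize(df))


def contexts_center(ref="A", n_flank_positions=2):
    """A small family of 7-mers sharing the center base."""
    flanks = ["".join(p) for p in itertools.product("ACGT", repeat=n_flank_positions)]
    return [f"{f}A{ref}AAA"[:7] for f in ("".join(x) + "A" for x in flanks)]


class TestContextRates:
    def _neutral_table(self, context, n, Y_per_alt):
        P = np.full(3 * n, 0.05)
        Y = np.zeros(3 * n, dtype=int)
        pos = 0
        for j, k in enumerate(Y_per_alt):
            for i in range(k):
                Y[(pos + i) * 3 + j] = 1
            pos += k
        return make_site_table(P, Y, context=context)

    def test_no_variants_gives_near_unit_self_rate(self):
        t = self._neutral_table("AAAAAAA", 1000, (0, 0, 0))
        rates = fit_context_rates(t)
        dist = rates.outcome_distribution("AAAAAAA")
        assert dist["A"] > 0.995
        assert all(dist[b] < 1e-3 for b in "CGT")

    def test_count_ratio_recovered(self):
        # 10 of 1000 sites carry a rare C variant
        t = self._neutral_table("AAAAAAA", 1000, (10, 0, 0))
        rates = fit_context_rates(t)
        assert rates.rate("AAAAAAA", "C") == pytest.approx(0.01, rel=0.06)

    def test_outcomes_sum_to_one(self):
        rng = np.random.default_rng(0)
        Y = (rng.random(3 * 500) < 0.1).astype(int)
        t = make_site_table(np.full(3 * 500, 0.05), Y, context="CATAGGC", ref="A")
        rates = fit_context_rates(t)
        total = sum(rates.outcome_distribution("CATAGGC").values())
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_unseen_context_falls_back_to_3mer(self):
        t = self._neutral_table("AAAAAAA", 200, (20, 0, 0))
        rates = fit_context_rates(t)
        # same 3-mer core AAA, different outer flanks
        assert rates.rate("CCAAACC", "C") == rates.rate("AAAAAAA", "C")
        with pytest.raises(NumericalError):
            rates.rate("CCAAACC", "C", fallback=False)

    def test_empty_neutral_table_rejected(self):
        from ultraselect.io_genomics import SiteTable

        with pytest.raises(ValidationError):
            fit_context_rates(SiteTable.empty())


class TestCovariateModel:
    def _simulated_table(self, n_sites, rate_fn, seed, covariate_noise=True):
        rng = np.random.default_rng(seed)
        ctxs = contexts_center()
        ctx = np.repeat(rng.choice(ctxs, size=n_sites), 3)
        coverage = rng.lognormal(np.log(30), 0.3, n_sites).repeat(3)
        gc = rng.uniform(0.3, 0.55, n_sites).repeat(3) if covariate_noise else 0.4
        cpg = (rng.random(n_sites) < 0.1).repeat(3) if covariate_noise else False
        alts = np.tile(np.array(alt_alleles("A"), dtype=object), n_sites)
        P = np.array([rate_fn(c, a) for c, a in zip(ctx, alts)])
        Y = (rng.random(3 * n_sites) < P).astype(int)
        t = make_site_table(P, Y, context=ctx, coverage=coverage, gc_frac=gc,
                            cpg_island=cpg)
        return t

    def test_recovers_identity_coefficient_on_true_rates(self):
        rng = np.random.default_rng(21)
        rate_lut = {}

        def rate_fn(ctx, alt):
            key = (ctx, alt)
            if key not in rate_lut:
                rate_lut[key] = float(np.clip(rng.lognormal(np.log(0.03), 0.6), 5e-4, 0.2))
            return rate_lut[key]

        t = self._simulated_table(70_000, rate_fn, seed=8)
        truth = truth_rate_table(sorted({c for c, _ in rate_lut}), rate_fn)
        model = fit_covariate_model(t, truth, sample_fraction=1.0, seed=0)
        coefs = model.coefficients
        assert coefs[1] == pytest.approx(1.0, abs=0.1)  # logit raw rate
        assert abs(coefs[2]) < 0.1 and abs(coefs[3]) < 0.35 and abs(coefs[4]) < 0.1

    def test_constant_covariates_recover_mean_rate(self):
        t = self._simulated_table(
            20_000, lambda c, a: 0.1, seed=3, covariate_noise=False
        )
        truth = truth_rate_table(contexts_center(), lambda c, a: 0.1)
        model = fit_covariate_model(t, truth, sample_fraction=1.0, seed=0)
        eta = adjusted_logits(t.retained, truth, model)
        assert expit(eta).mean() == pytest.approx(0.1, abs=0.01)

    def test_deterministic_given_seed(self):
        t = self._simulated_table(5_000, lambda c, a: 0.05, seed=4)
        truth = truth_rate_table(contexts_center(), lambda c, a: 0.05)
        m1 = fit_covariate_model(t, truth, sample_fraction=0.5, seed=7)
        m2 = fit_covariate_model(t, truth, sample_fraction=0.5, seed=7)
        assert np.array_equal(m1.coefficients, m2.coefficients)

    def test_invalid_sample_fraction(self):
        t = self._simulated_table(100, lambda c, a: 0.05, seed=4)
        truth = truth_rate_table(contexts_center(), lambda c, a: 0.05)
        with pytest.raises(ConfigError):
            fit_covariate_model(t, truth, sample_fraction=0.0, seed=1)


class TestRegionalScaler:
    def test_window_arithmetic(self):
        assert window_starts(250_000, 150_000, 50_000).tolist() == [0, 50_000, 100_000]
        assert window_starts(100_000, 150_000, 50_000).tolist() == [0]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValidationError):
            window_starts(1000, 0, 10)
        with pytest.raises(ValidationError):
            RegionalScaler(pd.DataFrame({"chrom": [], "win_start": [], "intercept": []}),
                           window=10, step=-1)

    def _calibration_table(self, n_sites, base_p, shift_window=None, seed=0):
        rng = np.random.default_rng(seed)
        P_true = np.full(3 * n_sites, base_p)
        pos = np.repeat(np.arange(n_sites), 3)
        if shift_window is not None:
            lo, hi = shift_window
            in_win = (pos >= lo) & (pos < hi)
            P_true[in_win] = expit(logit(base_p) + 0.5)
        Y = (rng.random(3 * n_sites) < P_true).astype(int)
        t = make_site_table(np.full(3 * n_sites, base_p), Y)
        return t

    def test_recovers_shifted_window_intercept(self):
        n = 120_000
        t = self._calibration_table(n, 0.05, shift_window=(40_000, 70_000), seed=5)
        eta = np.full(3 * n, logit(0.05))
        scaler = fit_regional_scalers(t, eta, window=30_000, step=10_000, min_sites=100)
        tbl = scaler.table.set_index("win_start")["intercept"]
        assert tbl.loc[40_000] == pytest.approx(0.5, abs=0.1)
        assert abs(tbl.loc[0]) < 0.05 and abs(tbl.loc[90_000]) < 0.05

    def test_well_calibrated_data_gives_zero_intercepts(self):
        n = 60_000
        t = self._calibration_table(n, 0.05, seed=6)
        eta = np.full(3 * n, logit(0.05))
        scaler = fit_regional_scalers(t, eta, window=30_000, step=10_000)
        assert np.all(np.abs(scaler.table["intercept"]) < 0.05)

    def test_site_scale_averages_overlapping_windows(self):
        tbl = pd.DataFrame(
            {"chrom": "c", "win_start": [0, 10, 20], "intercept": [0.0, 0.3, 0.6]}
        )
        scaler = RegionalScaler(tbl, window=30, step=10)
        # position 25 is covered by windows starting 0, 10, 20
        got = scaler.intercept_at(pd.Series(["c", "c"]), np.array([25, 5]))
        assert got[0] == pytest.approx((0.0 + 0.3 + 0.6) / 3)
        assert got[1] == pytest.approx(0.0)


class TestPredictAndCalibration:
    def test_identity_composition_reproduces_raw_rates(self):
        ctxs = contexts_center()
        rate_fn = lambda c, a: 0.02 + 0.01 * (hash((c, a)) % 7) / 7
        truth = truth_rate_table(ctxs, rate_fn)
        rng = np.random.default_rng(9)
        ctx = np.repeat(rng.choice(ctxs, size=500), 3)
        t = make_site_table(np.full(1500, np.nan), context=ctx)
        out = predict_rates(t, truth, CovariateModel.identity(), None)
        expected = truth.lookup(out.retained["context7"], out.retained["alt"])
        np.testing.assert_allclose(out.retained["P"].to_numpy(), expected, rtol=1e-12)

    def test_regional_intercept_shifts_logit(self):
        truth = truth_rate_table(["AAAAAAA"], lambda c, a: expit(-6.0))
        t = make_site_table(np.full(3, np.nan))
        scaler = RegionalScaler(
            pd.DataFrame({"chrom": ["t"], "win_start": [0], "intercept": [0.5]})
        )
        out = predict_rates(t, truth, CovariateModel.identity(), scaler)
        np.testing.assert_allclose(
            out.retained["P"].to_numpy(), expit(-5.5), rtol=1e-12
        )

    def test_calibration_on_self_simulated_data(self):
        rng = np.random.default_rng(10)
        n = 30_000
        P = np.clip(rng.lognormal(np.log(0.03), 0.7, 3 * n), 1e-4, 0.3)
        sim = bernoulli_simulate(P, 0.0, seed=11)
        t = make_site_table(P, sim.Y)
        rep = calibration_report(t, bins=10)
        se = np.sqrt(rep["mean_P"] * (1 - rep["mean_P"]) / rep["count"])
        assert np.all(np.abs(rep["observed"] - rep["mean_P"]) < 3 * se)
        assert rep["count"].sum() == 3 * n

    def test_calibration_scales_with_depletion(self):
        rng = np.random.default_rng(12)
        n = 40_000
        P = np.clip(rng.lognormal(np.log(0.05), 0.5, 3 * n), 1e-4, 0.3)
        sim = bernoulli_simulate(P, 0.5, seed=13)
        t = make_site_table(P, sim.Y)
        rep = calibration_report(t, bins=8)
        ratio = rep["observed"] / rep["mean_P"]
        assert np.all(np.abs(ratio - 0.5) < 0.08)

    def test_single_bin_is_overall_fraction(self):
        rng = np.random.default_rng(14)
        P = np.full(3 * 1000, 0.05)
        Y = (rng.random(3000) < 0.05).astype(int)
        t = make_site_table(P, Y)
        rep = calibration_report(t, bins=1)
        assert len(rep) == 1
        assert rep.loc[0, "observed"] == pytest.approx(Y.mean())

    def test_missing_p_raises(self):
        t = make_site_table(np.full(3, np.nan))
        with pytest.raises(ValidationError):
            calibration_report(t)


class TestModelBundle:
    def test_save_load_round_trip(self, tmp_path):
        ctxs = contexts_center()
        truth = truth_rate_table(ctxs, lambda c, a: 0.04)
        cov = CovariateModel(np.array([0.1, 1.0, -0.2, 0.3, 0.05]), loglik=-12.5)
        scaler = RegionalScaler(
            pd.DataFrame({"chrom": ["t"], "win_start": [0], "intercept": [0.1]}),
            window=1000, step=500,
        )
        m = MutationModel(truth, cov, scaler, metadata={"seed": 3})
        d = tmp_path / "bundle"
        m.save(str(d))
        back = MutationModel.load(str(d))
        assert np.array_equal(back.covariates.coefficients, cov.coefficients)
        assert back.scaler.window == 1000
        assert back.rates.rate("AAAAAAA", "C") == pytest.approx(
            truth.rate("AAAAAAA", "C")
        )
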