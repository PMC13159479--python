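"""Robust correlation, moderated regression, FDR, inflation and empirical null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from pestewas.ewas import (
    PRIOR_DF_CEILING,
    bh_adjust,
    bicor,
    bicor_matrix,
    empirical_null_correct,
    fit_variance_prior,
    genomic_inflation,
    moderated_fit,
    stratified_concordance,
    z_from_p,
)
from conftest import make_covariates


def bicor_oracle(x, y, c=9.0):
    """Literal transcription of the published biweight midcorrelation formulas."""
    def standardize(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1).astype(float)
        num = (v - med) * w
        return num / np.sqrt(np.sum(num**2))
    return float(np.sum(standardize(np.asarray(x, float)) * standardize(np.asarray(y, float))))


class TestBicor:
    def test_perfect_affine_relation(self):
        x = np.arange(1.0, 11.0)
        assert bicor(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative_relation(self):
        x = np.arange(1.0, 11.0)
        assert bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_outlier_example_matches_formula_oracle_and_beats_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = bicor(x, y)
        assert r == pytest.approx(bicor_oracle(x, y), abs=1e-12)
        # outlier distorts Pearson toward its own leverage; bicor resists
        assert abs(r - 1.0) < abs(stats.pearsonr(x, y)[0] - 1.0)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.normal(size=20)
            y = 0.4 * x + rng.normal(size=20)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(bicor(np.ones(5), np.arange(5.0)))

    def test_matrix_version_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(10, 25))
        x = rng.normal(size=25)
        rows = bicor_matrix(Y, x)
        for g in range(10):
            assert rows[g] == pytest.approx(bicor(Y[g], x), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-5, 5))
    def test_bounded_and_scale_invariant(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        r = bicor(x, y)
        assert -1.0 <= r <= 1.0
        assert bicor(scale * x + shift, y) == pytest.approx(r, abs=1e-9)


def _residual_frame(n_probes, n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_probes, n)),
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=[f"S{j:03d}" for j in range(n)],
    )


class TestModeratedFit:
    def test_zero_prior_df_recovers_ordinary_t(self):
        res = _residual_frame(50, 30, seed=1)
        x = np.random.default_rng(101).normal(size=30)
        table = moderated_fit(res, x, prior_df=0)
        for pid in res.index[:10]:
            lr = stats.linregress(x, res.loc[pid])
            t_ols = lr.slope / lr.stderr
            assert table.loc[pid, "t"] == pytest.approx(t_ols, abs=1e-10)
            assert table.loc[pid, "p"] == pytest.approx(lr.pvalue, rel=1e-8)

    def test_identical_residual_variances_cap_the_prior_df(self):
        # every probe the same response -> identical s^2 -> divergent moment fit
        y = np.random.default_rng(2).normal(size=40)
        res = pd.DataFrame(np.tile(y, (30, 1)),
                           index=[f"cg{i}" for i in range(30)],
                           columns=[f"S{j}" for j in range(40)])
        x = np.random.default_rng(3).normal(size=40)
        table = moderated_fit(res, x)
        assert table.attrs["prior_df"] == PRIOR_DF_CEILING
        np.testing.assert_allclose(table["p"], table["p"].iloc[0])

    def test_moment_fit_matches_independent_oracle(self):
        res = _residual_frame(200, 35, seed=4)
        x = np.random.default_rng(104).normal(size=35)
        table = moderated_fit(res, x)

        # independent step-by-step oracle for the scaled-F moment equations
        n = 35
        df = n - 2
        xc = x - x.mean()
        sxx = (xc**2).sum()
        s2 = np.empty(200)
        slope = np.empty(200)
        for g in range(200):
            yv = res.iloc[g].to_numpy()
            b = np.dot(xc, yv) / sxx
            a = yv.mean() - b * x.mean()
            rss = ((yv - a - b * x) ** 2).sum()
            s2[g] = rss / df
            slope[g] = b
        e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
        evar = e.var(ddof=1) - special.polygamma(1, df / 2)
        assert evar > 0
        d0 = 2 * optimize.brentq(
            lambda v: special.polygamma(1, v) - evar, 1e-6, 1e8
        )
        s02 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
        assert table.attrs["prior_df"] == pytest.approx(d0, rel=1e-8)
        assert table.attrs["prior_var"] == pytest.approx(s02, rel=1e-8)
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        t_expect = slope / np.sqrt(s2_post / sxx)
        np.testing.assert_allclose(
            table.loc[res.index, "t"].to_numpy(), t_expect, rtol=1e-8
        )

    def test_constant_exposure_rejected(self):
        res = _residual_frame(5, 10)
        with pytest.raises(ValueError, match="constant"):
            moderated_fit(res, np.ones(10))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(1e-8, 1, size=rng.integers(1, 40))
            expect = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expect, atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=50))
    def test_never_below_raw_p_and_sorted_monotone(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))


class TestGenomicInflation:
    def test_uniform_half_p_gives_lambda_one(self):
        assert genomic_inflation(p=np.full(100, 0.5)) == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_z_gives_zero(self):
        assert genomic_inflation(z=np.zeros(50)) == 0.0

    def test_uniform_p_sample_is_calibrated(self):
        p = np.random.default_rng(7).uniform(size=20000)
        assert 0.95 < genomic_inflation(p=p) < 1.05

    def test_zero_p_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            z = z_from_p(np.array([0.0, 0.5]))
        assert np.isfinite(z).all()
        assert "clamped" in caplog.text


class TestEmpiricalNull:
    def test_standard_normal_null_recovered(self):
        z = np.random.default_rng(11).normal(0, 1, 50000)
        rep = empirical_null_correct(z, seed=11)
        assert -0.05 < rep.null_mean < 0.05
        assert 0.95 < rep.null_sd < 1.05
        assert 0.9 < rep.lambda_corrected < 1.1
        # already-calibrated input is changed very little
        assert abs(rep.lambda_corrected - rep.lambda_raw) < 0.1

    def test_corrected_lambda_below_raw_when_overdispersed(self):
        z = np.random.default_rng(13).normal(0.2, 1.4, 20000)
        rep = empirical_null_correct(z, seed=13)
        assert rep.null_sd > 1
        assert rep.lambda_corrected <= rep.lambda_raw

    def test_small_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            empirical_null_correct(np.random.default_rng(1).normal(size=200), seed=1)
        assert "unreliable" in caplog.text


class TestStratifiedConcordance:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"bicor_r": rng.uniform(-0.5, 0.5, 20)},
            index=[f"cg{i}" for i in range(20)],
        )

    def test_self_concordance_is_one(self):
        t = self._table()
        assert stratified_concordance(t, t, t.index) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        t = self._table()
        flipped = -t
        assert stratified_concordance(t, flipped, t.index) == pytest.approx(-1.0)

    def test_subset_below_three_rejected(self):
        t = self._table()
        with pytest.raises(ValueError):
            stratified_concordance(t, t, t.index[:2])

    def test_split_halves_share_planted_signal(self, small_study):
        # planted effects are common to both halves of the cohort, so their
        # estimated coefficients must correlate positively across the split
        from pestewas.preprocess import filter_probes, residualize, residualize_exposure, winsorize
        study = small_study
        bf, af, _ = filter_probes(study.beta, study.annotation)
        bw = winsorize(bf)
        rng = np.random.default_rng(3)
        samples = np.array(bw.columns)
        rng.shuffle(samples)
        half = len(samples) // 2
        tables = []
        for ids in (samples[:half], samples[half:]):
            ids = list(ids)
            res = residualize(bw[ids], study.covariates.loc[ids])
            xa = residualize_exposure(
                study.covariates.loc[ids],
                study.counts.loc[ids, "copper_count"],
                sample_ids=ids,
            )
            tables.append(moderated_fit(res, xa))
        planted = [p for p in study.truth.planted_probe_ids if p in tables[0].index]
        r = stratified_concordance(tables[0], tables[1], planted)
        assert r > 0.3
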