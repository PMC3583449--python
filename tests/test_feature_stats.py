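"""Correlations, Storey q-values, and AIC best-subset density models."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import mutwave as mw
from mutwave.binning import BinConfig, BinnedTrack
from mutwave.feature_stats import qvalues


def _track(values, name="t", kind="mean"):
    values = np.asarray(values, dtype=float)
    return BinnedTrack(BinConfig(n_bins=len(values)), values, kind, 4_600_000, name)


class TestCorrelate:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=46)
        res = mw.correlate(_track(x, "counts", "count"), _track(x, "same"))
        assert res.rho_pearson == pytest.approx(1.0)
        assert res.p_pearson == 0.0

    def test_printed_statistic_p_value(self):
        assert mw.correlation_p_value(0.701, 23) == pytest.approx(2e-4, abs=5e-5)

    def test_toy_vectors_against_direct_formula_oracle(self):
        # 8-point toy with ties; oracle computes both coefficients from the
        # definition, including midrank tie handling
        x = np.array([3.0, 1, 4, 1, 5, 9, 2, 6])
        y = np.array([2.0, 7, 1, 8, 2, 8, 1, 8])
        res = mw.correlate(_track(x, "x", "count"), _track(y, "y"))

        def pearson(a, b):
            a, b = a - a.mean(), b - b.mean()
            return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rho_p = pearson(x, y)
        rho_s = pearson(midranks(x), midranks(y))
        assert res.rho_pearson == pytest.approx(rho_p, rel=1e-12)
        assert res.rho_spearman == pytest.approx(rho_s, rel=1e-12)
        t = rho_p * np.sqrt(6 / (1 - rho_p**2))
        assert res.p_pearson == pytest.approx(2 * stats.t.sf(abs(t), 6), rel=1e-10)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        base = mw.correlate(_track(x, "x", "count"), _track(y, "y")).rho_spearman
        exp_t = mw.correlate(_track(x, "x", "count"), _track(np.exp(y), "ey")).rho_spearman
        rank_t = mw.correlate(
            _track(x, "x", "count"), _track(stats.rankdata(y), "ry")
        ).rho_spearman
        assert exp_t == pytest.approx(base, rel=1e-12)
        assert rank_t == pytest.approx(base, rel=1e-12)

    def test_nan_bins_dropped_pairwise(self):
        x = np.arange(10.0)
        y = np.arange(10.0) * 2
        y[3] = np.nan
        res = mw.correlate(_track(x, "x", "count"), _track(y, "y"))
        assert res.n == 9
        assert res.rho_pearson == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            mw.correlate(_track(np.ones(10), "x", "count"), _track(np.arange(10.0), "y"))


class TestQvalues:
    def test_all_ones(self):
        np.testing.assert_allclose(qvalues([1.0] * 10), 1.0)

    def test_toy_battery_against_step_by_step_oracle(self):
        p = np.array([0.003, 0.5, 0.04, 0.9, 0.01, 0.2, 0.65, 0.08, 0.35, 0.7])

        # oracle: explicit-loop Storey algorithm written independently
        m = len(p)
        lams = [round(0.05 * i, 2) for i in range(19)]
        pi0s = []
        for lam in lams:
            pi0s.append(sum(1 for v in p if v > lam) / (m * (1 - lam)))
        coeffs = np.polyfit(lams, pi0s, 3)  # highest power first
        pi0 = sum(c * 0.90 ** (3 - i) for i, c in enumerate(coeffs))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
        order = sorted(range(m), key=lambda i: p[i])
        q_oracle = [None] * m
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(pi0 * m * p[i] / rank_from_top, prev, 1.0)
            q_oracle[i] = val
            prev = val

        np.testing.assert_allclose(qvalues(p), q_oracle, rtol=1e-10)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_reduces_to_bh_when_pi0_clamps_to_one(self):
        # a battery concentrated near 1 drives the smoother estimate to the
        # clamp, where Storey q-values equal Benjamini-Hochberg values
        rng = np.random.default_rng(3)
        p = np.clip(rng.uniform(0.5, 1.0, 40), 0, 1)
        q = qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-8)
        # and in general Storey q is never above BH by more than pi0 <= 1
        assert np.all(q <= bh + 1e-12)

    def test_pi0_calibration_on_uniform_batteries(self):
        # with m=200 truly null p-values the smoother's pi0 should sit near
        # 1; the cubic boundary fit carries binomial noise of sd ~0.1, so
        # most runs land within 0.15 and nearly all within 0.30
        devs = []
        for s in range(100):
            p = np.random.default_rng(500 + s).uniform(size=200)
            lam = np.arange(0.0, 0.95, 0.05)
            pi0_lam = np.array([(p > l).sum() / (200 * (1 - l)) for l in lam])
            coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, 3)
            pi0 = min(max(np.polynomial.polynomial.polyval(0.90, coef), 1 / 200), 1.0)
            devs.append(abs(pi0 - 1.0))
        devs = np.array(devs)
        assert (devs <= 0.15).mean() >= 0.70
        assert (devs <= 0.30).mean() >= 0.90

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.2])
        with pytest.raises(ValueError):
            qvalues([0.5])


class TestSelectModel:
    def test_noiseless_single_feature_recovered(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=46)
        tracks = [_track(f, "signal"), _track(rng.normal(size=46), "noise")]
        fit = mw.select_model(_track(3 + 2 * f, "y", "count"), tracks, max_terms=2)
        assert fit.features == ("signal",)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(3.0, abs=1e-8)
        assert fit.coefficients["signal"] == pytest.approx(2.0, abs=1e-8)

    def test_single_feature_fit_matches_closed_form(self):
        # closed-form simple regression: slope = cov(x,y)/var(x)
        xs = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        ys = np.array([1.0, 3.0, 4.0, 2.0, 5.0])
        fit = mw.select_model(
            BinnedTrack(BinConfig(n_bins=5), ys, "count", 300),
            [BinnedTrack(BinConfig(n_bins=5), xs, "mean", 300, "x")],
            max_terms=1,
        )
        slope = np.cov(xs, ys, ddof=1)[0, 1] / np.var(xs, ddof=1)
        intercept = ys.mean() - slope * xs.mean()
        if fit.features:  # AIC may prefer the intercept-only baseline
            assert fit.coefficients["x"] == pytest.approx(slope, rel=1e-8)
            assert fit.intercept == pytest.approx(intercept, rel=1e-6)
        # the one-feature candidate is in the ranking with the closed-form RSS
        row = fit.ranking[fit.ranking["features"] == ("x",)].iloc[0]
        rss = float(((ys - intercept - slope * xs) ** 2).sum())
        assert row["rss"] == pytest.approx(rss, rel=1e-10)

    def test_two_factor_recovery_among_ten_candidates(self):
        # counts generated as 16 + 7.8 f1 + 1.5 f2 + noise; best-subset AIC
        # must find both features and estimate their coefficients within
        # 2 standard errors in at least 80% of runs
        hits = 0
        n_runs = 100
        for s in range(n_runs):
            rng = np.random.default_rng(s)
            F = rng.normal(size=(46, 10))
            y = 16 + 7.8 * F[:, 0] + 1.5 * F[:, 1] + rng.normal(0, 2.5, 46)
            tracks = [_track(F[:, j], f"f{j}") for j in range(10)]
            fit = mw.select_model(_track(y, "y", "count"), tracks, max_terms=4)
            if {"f0", "f1"} <= set(fit.features):
                ok0 = abs(fit.coefficients["f0"] - 7.8) < 2 * fit.stderr["f0"]
                ok1 = abs(fit.coefficients["f1"] - 1.5) < 2 * fit.stderr["f1"]
                hits += ok0 and ok1
        assert hits >= 0.8 * n_runs

    def test_nested_rss_monotone_and_aic_penalized(self):
        rng = np.random.default_rng(6)
        F = rng.normal(size=(30, 3))
        y = F[:, 0] + rng.normal(0, 1, 30)
        tracks = [_track(F[:, j], f"f{j}") for j in range(3)]
        fit = mw.select_model(_track(y, "y", "count"), tracks, max_terms=3)
        ranking = fit.ranking
        # within any nested chain, RSS never increases with subset size
        by_feats = {row["features"]: row["rss"] for _, row in ranking.iterrows()}
        for feats, rss in by_feats.items():
            for other, rss2 in by_feats.items():
                if set(feats) < set(other):
                    assert rss2 <= rss + 1e-9
        # the selected model's AIC is the global minimum over candidates
        assert fit.aic == pytest.approx(ranking["aic"].min())

    def test_duplicate_feature_names_rejected(self):
        t = _track(np.arange(5.0), "dup")
        with pytest.raises(ValueError, match="unique"):
            mw.select_model(_track(np.arange(5.0) + 1, "y", "count"), [t, t], max_terms=1)

    def test_singular_subsets_skipped(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=20)
        tracks = [
            _track(f, "a"),
            _track(2 * f, "a_copy"),  # collinear with a
            _track(rng.normal(size=20), "b"),
        ]
        fit = mw.select_model(_track(f + 1, "y", "count"), tracks, max_terms=3)
        for feats in fit.ranking["features"]:
            assert not {"a", "a_copy"} <= set(feats)


class TestPredictTrack:
    def test_intercept_only_predicts_mean(self):
        y = np.arange(10.0)
        tracks = {"f": _track(np.random.default_rng(8).normal(size=10), "f")}
        fit = mw.select_model(_track(y, "y", "count"), list(tracks.values()), max_terms=0)
        pred = mw.predict_track(fit, tracks)
        np.testing.assert_allclose(pred.values, y.mean())

    def test_zero_noise_prediction_equals_observation(self):
        rng = np.random.default_rng(9)
        f1 = rng.normal(size=46)
        f2 = rng.normal(size=46)
        y = 16 + 7.8 * f1 + 1.5 * f2
        tracks = {"f1": _track(f1, "f1"), "f2": _track(f2, "f2")}
        fit = mw.select_model(_track(y, "y", "count"), list(tracks.values()), max_terms=2)
        pred = mw.predict_track(fit, tracks)
        np.testing.assert_allclose(pred.values, y, atol=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_prediction_r2_matches_fit(self, wave_genome, wave_intensity, wave_mutations):
        counts = mw.bin_mutations(wave_mutations)
        tracks = mw.generate_feature_tracks(
            wave_genome, wave_intensity,
            couplings=[("c1", 10.0, 3.0, "mean"), ("n1", 0.0, 3.0, "mean")],
            seed=12,
        )
        fit = mw.select_model(counts, list(tracks.values()), max_terms=2)
        pred = mw.predict_track(fit, tracks)
        rho = np.corrcoef(pred.values, counts.values)[0, 1]
        assert rho**2 == pytest.approx(fit.r_squared, abs=1e-8)

    def test_missing_feature_errors(self):
        fit = mw.ModelFit(
            features=("ghost",), intercept=0.0, coefficients={"ghost": 1.0},
            r_squared=0.5, p_value=0.01, aic=10.0, n=46,
        )
        with pytest.raises(ValueError, match="ghost"):
            mw.predict_track(fit, {"other": _track(np.arange(5.0), "other")})
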