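"""Feature correlations with FDR control and AIC-driven linear models.

Binned mutation counts are correlated with binned chromosomal feature tracks
(nucleoid-associated protein responses, expression, codon adaptation, ...)
using Pearson's product-moment coefficient — and Spearman's rank coefficient
with midrank tie correction, which catches monotone non-linear
relationships — with two-tailed p-values from the t-distribution.  Because a
feature battery is tested at once, Storey q-values estimate the false
discovery rate across the battery.

Density models are ordinary least-squares fits of counts on feature subsets,
selected by exhaustive best-subset search minimising Akaike's Information
Criterion; exhaustive search (feasible for batteries up to ~20 features) is
deterministic where stepwise selection is path-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .binning import BinnedTrack, correlation_p_value

__all__ = [
    "CorrelationResult",
    "ModelFit",
    "correlate",
    "correlate_battery",
    "qvalues",
    "select_model",
    "predict_track",
]


class CollinearityError(ValueError):
    """The regression design matrix is singular."""


@dataclass
class CorrelationResult:
    feature: str
    rho_pearson: float
    p_pearson: float
    rho_spearman: float
    p_spearman: float
    n: int
    q: float | None = None


def _paired_values(counts: BinnedTrack, feature: BinnedTrack):
    if counts.config.n_bins != feature.config.n_bins:
        raise ValueError(
            f"bin configurations differ: {counts.config.n_bins} vs "
            f"{feature.config.n_bins} bins"
        )
    x = np.asarray(counts.values, dtype=float)
    y = np.asarray(feature.values, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def correlate(counts: BinnedTrack, feature: BinnedTrack) -> CorrelationResult:
    """Pearson and tie-corrected Spearman correlation of two binned tracks.

    Bins where either track is missing (NaN from mean aggregation of an
    empty bin) are dropped pairwise.  Requires n >= 4 complete pairs.
    """
    x, y = _paired_values(counts, feature)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete bin pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero-variance track")
    rho_p = float(stats.pearsonr(x, y).statistic)
    # midranks implement the standard tie correction for Spearman's rho
    rho_s = float(stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic)
    return CorrelationResult(
        feature=feature.name or "feature",
        rho_pearson=rho_p,
        p_pearson=correlation_p_value(rho_p, n),
        rho_spearman=rho_s,
        p_spearman=correlation_p_value(rho_s, n),
        n=n,
    )


def qvalues(p_values: Sequence[float], smoother_degree: int = 3) -> np.ndarray:
    """Storey q-values for a battery of p-values.

    The null proportion pi0 is estimated by the smoother method: pi0(lambda)
    = #{p > lambda} / (m (1 - lambda)) over lambda = 0, 0.05, ..., 0.90 is
    fit with a cubic polynomial and evaluated at lambda = 0.90, clamped to
    (0, 1].  Then q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j),
    which is monotone nondecreasing in p and reduces to pi0-scaled
    Benjamini-Hochberg values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("need a 1-D battery of at least 2 p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    lam = np.arange(0.0, 0.95, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, deg=smoother_degree)
    pi0 = float(np.polynomial.polynomial.polyval(0.90, coef))
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * ranked / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def correlate_battery(
    counts: BinnedTrack, features: Sequence[BinnedTrack]
) -> pd.DataFrame:
    """Correlate counts with every feature and attach battery-wide q-values.

    q-values are computed jointly over the Pearson p-values of the full
    battery, matching how a multi-feature screen is reported.
    """
    results = [correlate(counts, f) for f in features]
    if len(results) >= 2:
        qs = qvalues([r.p_pearson for r in results])
        for r, qv in zip(results, qs):
            r.q = float(qv)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "rho_pearson": [r.rho_pearson for r in results],
            "p_pearson": [r.p_pearson for r in results],
            "rho_spearman": [r.rho_spearman for r in results],
            "p_spearman": [r.p_spearman for r in results],
            "q": [r.q for r in results],
            "n": [r.n for r in results],
        }
    )


@dataclass
class ModelFit:
    """A selected linear density model: counts ~ intercept + features."""

    features: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    p_value: float
    aic: float
    n: int
    ranking: pd.DataFrame | None = None  # all candidate subsets by AIC
    stderr: dict[str, float] | None = None


def _aic(n: int, rss: float, k: int) -> float:
    """AIC = n ln(RSS/n) + 2(k+2): k slopes + intercept + error variance."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 2)


def select_model(
    counts: BinnedTrack,
    features: Sequence[BinnedTrack],
    max_terms: int = 5,
    use_aicc: bool = False,
) -> ModelFit:
    """Exhaustive best-subset OLS of counts on features, minimising AIC.

    All subsets of size 0..max_terms are fit; the AIC convention
    n ln(RSS/n) + 2(k+2) is held fixed so rankings are comparable (AICc adds
    the small-sample correction 2(k+2)(k+3)/(n-k-3) when ``use_aicc``).
    Rank-deficient subsets are skipped during the search; if every subset of
    some requested size is singular an error names the offending features.
    """
    y = np.asarray(counts.values, dtype=float)
    n = len(y)
    names = [f.name or f"f{i}" for i, f in enumerate(features)]
    if len(set(names)) != len(names):
        raise ValueError("feature tracks must carry unique names")
    X_all = np.column_stack([np.asarray(f.values, dtype=float) for f in features])
    if np.any(np.isnan(X_all)) or np.any(np.isnan(y)):
        raise ValueError("NaN values in tracks; impute or drop bins first")
    if n <= max_terms + 2:
        raise ValueError(f"n={n} too small for max_terms={max_terms}")
    if len(features) > 20:
        raise ValueError(
            "exhaustive best-subset search is limited to 20 features"
        )

    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    singular: list[tuple[str, ...]] = []
    for k in range(0, max_terms + 1):
        for subset in combinations(range(len(features)), k):
            X = np.column_stack([np.ones(n)] + [X_all[:, j] for j in subset])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                singular.append(tuple(names[j] for j in subset))
                continue
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            aic = _aic(n, rss, k)
            if use_aicc and n - k - 3 > 0:
                aic += 2 * (k + 2) * (k + 3) / (n - k - 3)
            rows.append(
                {
                    "features": tuple(names[j] for j in subset),
                    "k": k,
                    "rss": rss,
                    "aic": aic,
                }
            )
    if not rows:
        raise CollinearityError(
            f"all candidate designs singular; offending features: {singular}"
        )
    ranking = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    best = ranking.iloc[0]
    best_idx = [names.index(f) for f in best["features"]]

    # refit the winning subset with statsmodels for coefficients and the F-test
    X_best = sm.add_constant(X_all[:, best_idx], has_constant="add")
    fit = sm.OLS(y, X_best).fit()
    coef_names = list(best["features"])
    coefficients = dict(zip(coef_names, fit.params[1:]))
    stderr = dict(zip(coef_names, fit.bse[1:]))
    r2 = float(1.0 - best["rss"] / tss) if tss > 0 else 0.0
    p_value = float(fit.f_pvalue) if len(coef_names) else 1.0
    if np.isnan(p_value):
        p_value = 1.0
    return ModelFit(
        features=tuple(coef_names),
        intercept=float(fit.params[0]),
        coefficients={k: float(v) for k, v in coefficients.items()},
        r_squared=r2,
        p_value=p_value,
        aic=float(best["aic"]),
        n=n,
        ranking=ranking,
        stderr={k: float(v) for k, v in stderr.items()},
    )


def predict_track(fit: ModelFit, features: Mapping[str, BinnedTrack]) -> BinnedTrack:
    """Per-bin counts predicted by a fitted density model."""
    missing = [f for f in fit.features if f not in features]
    if missing:
        raise ValueError(f"missing feature track(s): {missing}")
    if fit.features:
        some = features[fit.features[0]]
    else:
        some = next(iter(features.values()))
    pred = np.full(some.config.n_bins, fit.intercept, dtype=float)
    for name in fit.features:
        pred += fit.coefficients[name] * np.asarray(features[name].values, dtype=float)
    return BinnedTrack(some.config, pred, "count", some.genome_length, "predicted")
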