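"""Statistical operations for scored pullback cohorts.

ROC-based cutoff derivation (maximizing sensitivity + specificity),
Pearson correlation with a Fisher-z interval, Cohen's kappa for inter-rater
agreement, one-way ANOVA and Fisher exact group comparisons (Monte-Carlo
exact p for tables larger than 2×2) with optional Bonferroni adjustment,
and standardized regression coefficients with cluster-robust errors by
patient (a documented simplification of a random-intercept model; with few
multi-vessel patients the two are near-identical and only the sign and
ordering of coefficients are contractual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .errors import (
    CollinearityError,
    DegenerateLabelsError,
    InvalidParameterError,
    QfrPullbackError,
)

DIRECTION_LOW = "low-score-predicts-event"
DIRECTION_HIGH = "high-score-predicts-event"


@dataclass
class RocResult:
    """Empirical ROC analysis with the max(sens+spec) operating point.

    ``thresholds`` are on the original score scale; with the default
    direction (low score predicts the event) a score ≤ ``optimal_cutoff``
    predicts the event.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    sensitivity_at_optimum: float
    specificity_at_optimum: float
    direction: str = DIRECTION_LOW
    n_events: int = 0
    n_nonevents: int = 0


def roc_optimal_cutoff(
    scores, outcome, direction: str = DIRECTION_LOW
) -> RocResult:
    """Empirical ROC over all midpoints between adjacent distinct scores.

    AUC by the trapezoid rule; the optimal cutoff maximizes
    sensitivity + specificity, ties broken toward the smaller threshold on
    the original score scale.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidParameterError("scores and outcome must be equal-length 1-D")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both outcome classes must be present")
    if direction not in (DIRECTION_LOW, DIRECTION_HIGH):
        raise InvalidParameterError(f"unknown direction {direction!r}")

    # orient so that a LARGER oriented score predicts the event
    z = -s if direction == DIRECTION_LOW else s
    distinct = np.unique(z)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cuts = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    # predict event iff z >= cut
    sens = np.array([(z[y] >= c).mean() for c in cuts])
    spec = np.array([(z[~y] < c).mean() for c in cuts])

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # vertical ROC segments must ascend
    auc = float(np.trapezoid(sens[order], fpr[order]))

    youden = sens + spec
    best = np.flatnonzero(youden >= youden.max() - 1e-12)
    orig = -cuts if direction == DIRECTION_LOW else cuts
    i_opt = best[np.argmin(orig[best])]

    return RocResult(
        thresholds=orig,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float(orig[i_opt]),
        sensitivity_at_optimum=float(sens[i_opt]),
        specificity_at_optimum=float(spec[i_opt]),
        direction=direction,
        n_events=n_pos,
        n_nonevents=n_neg,
    )


class OptimalCutoff(BaseEstimator):
    """sklearn-style estimator deriving an ROC-optimal score cutoff.

    ``fit(scores, outcome)`` stores ``cutoff_``, ``auc_``, ``sensitivity_``
    and ``specificity_``; ``predict(scores)`` returns the binary event
    prediction implied by the fitted cutoff.
    """

    def __init__(self, direction: str = DIRECTION_LOW):
        self.direction = direction

    def fit(self, X, y) -> "OptimalCutoff":
        res = roc_optimal_cutoff(np.asarray(X, dtype=float).ravel(), y, self.direction)
        self.roc_ = res
        self.cutoff_ = res.optimal_cutoff
        self.auc_ = res.auc
        self.sensitivity_ = res.sensitivity_at_optimum
        self.specificity_ = res.specificity_at_optimum
        return self

    def predict(self, X) -> np.ndarray:
        s = np.asarray(X, dtype=float).ravel()
        if self.direction == DIRECTION_LOW:
            return s <= self.cutoff_
        return s >= self.cutoff_


def pearson_r(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Sample Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise InvalidParameterError("pearson_r needs equal-length samples with n ≥ 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise QfrPullbackError("correlation undefined for zero-variance input")
    r = float(sps.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    crit = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return r, (float(lo), float(hi))


def cohens_kappa(labels_a, labels_b, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa between two categorical label sequences, with the
    standard large-sample confidence interval."""
    a = pd.Series(list(labels_a), dtype="object")
    b = pd.Series(list(labels_b), dtype="object")
    if len(a) != len(b):
        raise InvalidParameterError("label sequences must have equal length")
    if len(a) < 2:
        raise InvalidParameterError("kappa needs at least 2 paired labels")
    cats = sorted(set(a) | set(b), key=str)
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats),
        dropna=False,
    ).reindex(index=cats, columns=cats, fill_value=0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # statsmodels divides by a zero chance-variance on degenerate tables
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = _sm_kappa(table.to_numpy(), return_results=True)
    kappa = float(res.kappa)
    crit = sps.norm.ppf(1 - alpha / 2)
    half = crit * float(res.var_kappa) ** 0.5
    return kappa, (kappa - half, kappa + half)


def anova_oneway(values, groups) -> float:
    """One-way ANOVA F-test p-value across pattern groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise InvalidParameterError("ANOVA needs ≥2 non-empty groups")
    return float(sps.f_oneway(*samples).pvalue)


def _table_logprob(table: np.ndarray) -> float:
    """Log-probability of an r×c table under the multivariate hypergeometric
    null with fixed margins."""
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact_test(
    table, n_resamples: int = 100_000, seed: int | None = 0
) -> float:
    """Fisher exact p-value for a contingency table.

    2×2 tables use the exact hypergeometric enumeration (two-sided); larger
    tables use a seeded Monte-Carlo estimate of the exact p (probability of
    a table at most as probable as the observed one under fixed margins),
    with ``n_resamples`` permutation replicates and the add-one correction.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.min() < 0:
        raise InvalidParameterError("table must be a non-negative 2-D array")
    if t.shape == (2, 2):
        return float(sps.fisher_exact(t).pvalue)
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1)).astype(np.int64)
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0)).astype(np.int64)
    n = rows.size
    ncol = t.shape[1]
    obs_lp = _table_logprob(t)
    k = t.shape[0] * ncol
    hits = 0
    chunk = max(1, min(n_resamples, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        perm = np.tile(cols, (m, 1))
        perm = rng.permuted(perm, axis=1)
        codes = rows[None, :] * ncol + perm
        codes += np.arange(m)[:, None] * k
        counts = np.bincount(codes.ravel(), minlength=m * k).reshape(m, k)
        lp = (
            gammaln(t.sum(axis=1) + 1).sum()
            + gammaln(t.sum(axis=0) + 1).sum()
            - gammaln(n + 1)
            - gammaln(counts + 1).sum(axis=1)
        )
        hits += int((lp <= obs_lp + 1e-9).sum())
        done += m
    return (1 + hits) / (1 + n_resamples)


def bonferroni(p_values) -> list[float]:
    """Bonferroni-adjusted p-values (multiplied by the family size, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    return list(np.minimum(p * p.size, 1.0))


@dataclass
class GroupTestResult:
    name: str
    p_raw: float
    p_bonferroni: float = np.nan


def group_tests(
    continuous: dict[str, np.ndarray] | None,
    categorical: dict[str, np.ndarray] | None,
    groups,
    n_resamples: int = 100_000,
    seed: int | None = 0,
) -> list[GroupTestResult]:
    """Compare variables between pattern groups: ANOVA for continuous,
    Fisher exact for categorical; Bonferroni across the family of tests."""
    groups = np.asarray(groups)
    results: list[GroupTestResult] = []
    for name, values in (continuous or {}).items():
        results.append(GroupTestResult(name, anova_oneway(values, groups)))
    for name, values in (categorical or {}).items():
        values = np.asarray(values)
        cats_r = np.unique(values)
        cats_c = np.unique(groups)
        table = np.array(
            [[(values[groups == g] == r).sum() for g in cats_c] for r in cats_r]
        )
        results.append(
            GroupTestResult(name, fisher_exact_test(table, n_resamples, seed))
        )
    adj = bonferroni([r.p_raw for r in results])
    for r, p in zip(results, adj):
        r.p_bonferroni = p
    return results


@dataclass
class BetaResult:
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float


def standardized_beta(
    outcome,
    predictors: pd.DataFrame,
    cluster=None,
    alpha: float = 0.05,
) -> list[BetaResult]:
    """Standardized linear-regression coefficients for a continuous outcome.

    Outcome and predictors are z-standardized before fitting.  When
    ``cluster`` (e.g. patient id) is given, confidence intervals use
    cluster-robust covariance — a simplification of a patient-level
    random-intercept model appropriate when few patients contribute more
    than one vessel.
    """
    y = np.asarray(outcome, dtype=float)
    X = predictors.astype(float).copy()
    if len(X) != y.size or y.size <= X.shape[1] + 2:
        raise InvalidParameterError("need n > p + 2 observations")
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise QfrPullbackError("outcome has zero variance")
    yz = (y - y.mean()) / sd_y
    for col in X.columns:
        sd = X[col].std(ddof=1)
        if sd == 0:
            raise CollinearityError(f"predictor {col!r} is constant")
        X[col] = (X[col] - X[col].mean()) / sd
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise CollinearityError("design matrix is singular")
    model = sm.OLS(yz, design)
    if cluster is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        fit = model.fit()
    ci = fit.conf_int(alpha=alpha)
    out = []
    for col in X.columns:
        out.append(
            BetaResult(
                predictor=str(col),
                beta=float(fit.params[col]),
                ci_low=float(ci.loc[col, 0]),
                ci_high=float(ci.loc[col, 1]),
                p_value=float(fit.pvalues[col]),
            )
        )
    return out
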