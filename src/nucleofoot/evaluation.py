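"""ROC/AUC analysis, rank-logistic score combination, two-group statistics.

AUC is the Mann–Whitney estimator (ties at half weight) with DeLong
confidence intervals. The nucleosome score and genome-wide z-score are
combined by logistic regression on the ranks of both scores; the apparent
AUC of the combined predictor is corrected for optimism with Harrell's
non-parametric bootstrap (default 500 iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "RocResult",
    "CombinedModel",
    "roc_auc",
    "combine_scores",
    "mann_whitney",
    "spearman_rho",
]


@dataclass
class CohortTable:
    """Per-sample scores and binary class labels for one comparison."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "nucleosome_score", "genome_wide_z", "label")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        labels = set(self.table["label"].unique())
        if len(labels) > 2:
            raise ValueError(f"labels must be binary, got {sorted(labels)}")
        for col in ("nucleosome_score", "genome_wide_z"):
            if self.table[col].isna().any():
                raise ValueError(f"missing values in {col}")

    def y(self, positive: str) -> np.ndarray:
        return (self.table["label"] == positive).to_numpy(dtype=int)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    points: pd.DataFrame  # threshold, sensitivity, specificity
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must contain the AUC point estimate")


@dataclass
class CombinedModel:
    coef: np.ndarray  # intercept, beta_rank_score1, beta_rank_score2
    apparent_auc: float
    optimism: float
    corrected_auc: float
    n_bootstrap: int
    seed: int
    penalized: bool = False
    train_scores: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )

    def linear_predictor(
        self, s1: np.ndarray, s2: np.ndarray
    ) -> np.ndarray:
        """Score new samples: ranks interpolated against the training scores."""
        r1 = _interp_ranks(s1, self.train_scores[0])
        r2 = _interp_ranks(s2, self.train_scores[1])
        return self.coef[0] + self.coef[1] * r1 + self.coef[2] * r2


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_midrank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC = (R_pos - n1(n1+1)/2) / (n1 n0): Mann–Whitney with 1/2 ties."""
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = _midrank(scores)
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong structural-component variance of the AUC estimator."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(scores)
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    # placement values V10 (per positive) and V01 (per negative)
    v10 = (all_r[y == 1] - pos_r) / n
    v01 = 1.0 - (all_r[y == 0] - neg_r) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, positive=1, alpha: float = 0.05
) -> RocResult:
    """AUC with a DeLong confidence interval and the full ROC curve.

    Higher scores are taken to indicate the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive).astype(int)
    auc = _auc_midrank(scores, y)
    var = _delong_variance(scores, y)
    zq = stats.norm.ppf(1 - alpha / 2)
    half = zq * np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    n1, n0 = int(y.sum()), int((1 - y).sum())
    sens = [(scores[y == 1] >= t).sum() / n1 for t in thresholds]
    spec = [(scores[y == 0] < t).sum() / n0 for t in thresholds]
    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    return RocResult(auc, min(lo, auc), max(hi, auc), points, n1, n0)


def _interp_ranks(new: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Average-rank transform of training scores, interpolated for new values."""
    order = np.sort(train)
    train_ranks = _midrank(order)
    return np.interp(new, order, train_ranks)


def _ridge_logistic(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """L2-penalized logistic MLE (intercept unpenalized); robust to
    separation and rank-deficient designs."""
    from scipy.optimize import minimize

    pen = np.ones(X.shape[1]) * alpha
    pen[0] = 0.0

    def nll_grad(beta):
        eta = X @ beta
        p = stats.logistic.cdf(eta)
        nll = -np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * pen @ beta**2
        grad = X.T @ (p - y) + pen * beta
        return nll, grad

    res = minimize(nll_grad, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B")
    return res.x


def _fit_rank_logistic(
    r1: np.ndarray, r2: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, bool]:
    import statsmodels.api as sm

    # explicit intercept column: add_constant would skip it when a score
    # column is itself constant, silently changing the design
    X = np.column_stack([np.ones(r1.size), r1, r2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.params)) and fit.mle_retvals.get(
                "converged", True
            ):
                return np.asarray(fit.params), False
        except Exception:
            pass
    # perfect separation / rank deficiency: small ridge penalty
    return _ridge_logistic(X, y.astype(float), alpha=1.0), True


def combine_scores(
    cohort: CohortTable,
    positive: str,
    seed: int,
    n_bootstrap: int = 500,
) -> CombinedModel:
    """Rank-logistic combination of the two scores with optimism correction.

    Both scores are average-rank transformed, a logistic regression with
    intercept is fitted by maximum likelihood, and the apparent AUC of
    the linear predictor is computed. Optimism is estimated per Harrell:
    for each bootstrap resample, (AUC of the resample-fitted model on the
    resample) minus (the same model applied to the original cohort),
    averaged over resamples; corrected AUC = apparent - mean optimism.
    """
    s1 = cohort.table["nucleosome_score"].to_numpy(dtype=float)
    s2 = cohort.table["genome_wide_z"].to_numpy(dtype=float)
    y = cohort.y(positive)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")

    def fit_and_auc(idx: np.ndarray):
        b1, b2, by = s1[idx], s2[idx], y[idx]
        coef, pen = _fit_rank_logistic(_midrank(b1), _midrank(b2), by)
        lp_boot = (
            coef[0]
            + coef[1] * _midrank(b1)
            + coef[2] * _midrank(b2)
        )
        lp_orig = (
            coef[0]
            + coef[1] * _interp_ranks(s1, b1)
            + coef[2] * _interp_ranks(s2, b2)
        )
        return coef, pen, lp_boot, lp_orig, by

    all_idx = np.arange(y.size)
    coef, penalized, lp, _, _ = fit_and_auc(all_idx)
    apparent = _auc_midrank(lp, y)

    rng = np.random.default_rng(seed)
    optimisms = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, y.size, y.size)
        if y[idx].sum() in (0, y.size):  # resample lost a class; redraw
            continue
        _, _, lp_boot, lp_orig, by = fit_and_auc(idx)
        optimisms.append(
            _auc_midrank(lp_boot, by) - _auc_midrank(lp_orig, y)
        )
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return CombinedModel(
        coef=coef,
        apparent_auc=apparent,
        optimism=optimism,
        corrected_auc=apparent - optimism,
        n_bootstrap=n_bootstrap,
        seed=seed,
        penalized=penalized,
        train_scores=(s1, s2),
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a vs b with half-weight ties (brute-force definition)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Mann–Whitney U (group a) and a two-sided p-value.

    Exact enumeration of all label assignments when the smaller group has
    at most ``exact_max_n`` observations (valid under ties); otherwise the
    normal approximation with tie correction and continuity correction.
    Returns ``(U_a, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2
    if min(n1, n2) <= exact_max_n:
        pooled = np.concatenate([a, b])
        n = pooled.size
        dev = abs(u - mu)
        hits = total = 0
        for comb in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        return u, hits / total
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    return u, float(2 * stats.norm.sf(max(z, 0.0)))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rx, ry = _midrank(x), _midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
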