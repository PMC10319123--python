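"""Group-discrimination metrics over congruency feature vectors.

Two aggregations of the per-component congruency scores:

* the cumulative metric — the plain sum of the top ``k_top`` (default 3)
  scores, the "knee" of the eigenvalue spectrum;
* the LASSO-weighted metric — an L1-regularized logistic regression over the
  top K = 10 scores, evaluated with leave-one-participant-out
  cross-validation; the reported per-participant value is the intercept-free
  linear predictor of the model trained without that participant.

Discrimination is summarized as the AUC of the cross-validated scores
(Mann-Whitney identity, ties counted 1/2) with permutation-based
significance: group labels are permuted and the *full* pipeline — component
extraction from the permuted reference set, leave-one-out congruency
features, LOO LASSO — is re-run per permutation.

The L1 logistic solver is an in-house vectorized FISTA over the whole
penalty grid (objective ``sum_i log(1 + exp(-y_i z_i)) + ||w||_1 / C``,
matching the common C parameterization; intercept unpenalized).  A single
permutation test refits this model thousands of times on tiny folds, which
is what the implementation is optimized for.  The reported decision value
deliberately excludes the intercept: under leave-one-out the training-fold
intercept reflects which class lost a member and is anti-predictive under
the null hypothesis, so including it would miscalibrate the permutation
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .congruency import CovarianceTable, congruency_features

#: Penalty grid for the inner CV.  Folds have tens of observations over ten
#: features, so penalties weaker than C = 10 are indistinguishable from
#: unregularized fits (and nearly separable, hence slow to optimize);
#: the grid spans strong to effectively-unregularized on that scale.
DEFAULT_C_GRID = np.logspace(-2.0, 1.0, 7)

try:  # JIT kernel: the permutation test refits this model ~10^5 times
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard runtime dep in practice
    njit = None


def _fista_core(xb, y, lam, step, max_iter, tol):
    """Accelerated proximal gradient for L1 logistic over a penalty grid.

    ``xb`` is (n, p+1) with the intercept column last (unpenalized);
    ``lam[c]`` is the soft threshold of grid column c.  Each column runs an
    independent FISTA with adaptive (function-value-free) restart and stops
    as soon as its iterate change falls below ``tol``; the loop is written
    out element-wise because the matrices are tiny and this routine is the
    innermost kernel of the permutation test.
    """
    n, p1 = xb.shape
    p = p1 - 1
    n_c = lam.shape[0]
    theta = np.zeros((p1, n_c))
    z = np.zeros((p1, n_c))
    t_mom = np.ones(n_c)
    done = np.zeros(n_c, dtype=np.bool_)
    grad = np.empty(p1)
    cand = np.empty(p1)
    for _ in range(max_iter):
        all_done = True
        for c in range(n_c):
            if done[c]:
                continue
            all_done = False
            for j in range(p1):
                grad[j] = 0.0
            for i in range(n):
                acc = 0.0
                for j in range(p1):
                    acc += xb[i, j] * z[j, c]
                m = y[i] * acc
                if m > 35.0:
                    m = 35.0
                elif m < -35.0:
                    m = -35.0
                coef = y[i] / (1.0 + np.exp(m))
                for j in range(p1):
                    grad[j] += xb[i, j] * coef
            thr = step * lam[c]
            restart_dot = 0.0
            delta = 0.0
            for j in range(p1):
                v = z[j, c] + step * grad[j] / n
                if j < p:
                    if v > thr:
                        v -= thr
                    elif v < -thr:
                        v += thr
                    else:
                        v = 0.0
                cand[j] = v
                restart_dot += (z[j, c] - v) * (v - theta[j, c])
                d = abs(v - theta[j, c])
                if d > delta:
                    delta = d
            if restart_dot > 0.0:
                t_mom[c] = 1.0
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom[c] * t_mom[c]))
            mom = (t_mom[c] - 1.0) / t_new
            for j in range(p1):
                z[j, c] = cand[j] + mom * (cand[j] - theta[j, c])
                theta[j, c] = cand[j]
            t_mom[c] = t_new
            if delta < tol:
                done[c] = True
        if all_done:
            break
    return theta


if njit is not None:
    _fista_core = njit(cache=False)(_fista_core)


def cumulative_metric(c: np.ndarray, k_top: int = 3) -> float:
    """Sum of the first ``k_top`` congruency scores (descending-eigenvalue
    order)."""
    c = np.asarray(c, dtype=float)
    if k_top < 1 or k_top > c.size:
        raise ValueError(f"k_top={k_top} out of range for {c.size} components")
    return float(c[:k_top].sum())


# ---------------------------------------------------------------------------
# sparse logistic regression (L1), FISTA over a penalty grid


def _l1_logreg_path(x: np.ndarray, y: np.ndarray, c_grid: np.ndarray,
                    max_iter: int = 1000, tol: float = 1e-7) -> np.ndarray:
    """Fit L1 logistic regression for every C in the grid at once.

    ``x`` is (n, p) standardized features, ``y`` in {-1, +1}.  Returns
    (p + 1, n_C): weight rows then the (unpenalized) intercept row.
    Accelerated proximal gradient with a shared Lipschitz step; each grid
    column converges independently.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, _ = x.shape
    xb = np.hstack([x, np.ones((n, 1))])
    lip = np.linalg.norm(xb, 2) ** 2 / (4.0 * n)
    step = 1.0 / max(lip, 1e-12)
    lam = np.ascontiguousarray(1.0 / (np.asarray(c_grid, dtype=np.float64) * n))
    return _fista_core(xb, y, lam, step, max_iter, tol)


def fit_sparse_logreg(x: np.ndarray, y: np.ndarray, c: float,
                      max_iter: int = 1000, tol: float = 1e-7):
    """Single-C fit; returns (weights, intercept)."""
    theta = _l1_logreg_path(np.asarray(x, float), np.asarray(y, float),
                            np.array([c]), max_iter=max_iter, tol=tol)
    return theta[:-1, 0], float(theta[-1, 0])


def _standardize(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _log_likelihood(x, y, theta):
    """Held-out log-likelihood per grid column."""
    xb = np.hstack([x, np.ones((len(x), 1))])
    margins = y[:, None] * (xb @ theta)
    return -np.log1p(np.exp(np.clip(-margins, -35, 35))).sum(axis=0)


@dataclass
class ClassifierResult:
    """Leave-one-participant-out LASSO evaluation."""

    cv_scores: np.ndarray  # one out-of-fold decision value per participant
    auc: float
    labels: list
    positive_label: str
    weights_per_fold: list = field(default_factory=list)  # (weights, intercept, C)
    perm_p: float | None = None
    n_perm: int = 0
    null_aucs: np.ndarray | None = None


def lasso_weighted_scores(
    features: np.ndarray,
    labels,
    positive_label: str = "CAC",
    c_grid=None,
    inner_folds: int = 5,
    seed: int = 0,
) -> ClassifierResult:
    """LOO-CV sparse-logistic decision values and their AUC.

    Per outer fold: features are z-scored with the training fold's
    statistics, the penalty C is selected by stratified ``inner_folds``-fold
    CV maximizing held-out log-likelihood (ties broken toward the stronger
    penalty), the model is refit on the whole training fold, and the held-out
    participant's score is the intercept-free linear predictor.
    """
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not in labels")
    if c_grid is None:
        c_grid = DEFAULT_C_GRID
    c_grid = np.asarray(c_grid, dtype=float)
    y = np.where(np.asarray(labels) == positive_label, 1.0, -1.0)
    n = len(labels)
    rng = np.random.default_rng(seed)
    scores = np.empty(n)
    fold_info = []
    for held in range(n):
        tr = np.arange(n) != held
        x_tr, y_tr = features[tr], y[tr]
        mu, sd = _standardize(x_tr)
        z_tr = (x_tr - mu) / sd
        n_splits = min(inner_folds, int(np.bincount((y_tr > 0).astype(int)).min()))
        if n_splits >= 2:
            skf = StratifiedKFold(
                n_splits=n_splits, shuffle=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            ll = np.zeros(c_grid.size)
            for itr, ival in skf.split(z_tr, y_tr):
                theta = _l1_logreg_path(z_tr[itr], y_tr[itr], c_grid)
                ll += _log_likelihood(z_tr[ival], y_tr[ival], theta)
            # ties toward the sparser model (smaller C)
            best = np.flatnonzero(ll >= ll.max() - 1e-10)[0]
        else:
            best = c_grid.size // 2
        w, b = fit_sparse_logreg(z_tr, y_tr, c_grid[best])
        z_held = (features[held] - mu) / sd
        scores[held] = float(w @ z_held)
        fold_info.append((w, b, float(c_grid[best])))
    auc = auc_score(scores, labels, positive_label=positive_label)
    return ClassifierResult(
        cv_scores=scores,
        auc=auc,
        labels=labels,
        positive_label=positive_label,
        weights_per_fold=fold_info,
    )


def auc_score(scores, labels, positive_label: str = "CAC") -> float:
    """Probability a random positive-class score exceeds a random
    negative-class score, ties counted 1/2 (Mann-Whitney identity)."""
    labels = np.asarray(labels)
    y = (labels == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        return 0.5  # all ties
    return float(roc_auc_score(y, scores))


def analyze_condition(
    table: CovarianceTable,
    labels,
    n_components: int = 10,
    k_top: int = 3,
    shrinkage: float = 0.05,
    reference_label: str = "CAC",
    positive_label: str = "CAC",
    c_grid=None,
    inner_folds: int = 5,
    seed: int = 0,
):
    """Full per-condition analysis: LOO congruency features, cumulative
    metric, LOO LASSO scores and AUC.  Returns (features, cumulative,
    ClassifierResult)."""
    features = congruency_features(
        table, labels, reference_label=reference_label,
        n_components=n_components, shrinkage=shrinkage,
    )
    cumulative = np.array([cumulative_metric(c, k_top=k_top) for c in features])
    result = lasso_weighted_scores(
        features, labels, positive_label=positive_label,
        c_grid=c_grid, inner_folds=inner_folds, seed=seed,
    )
    return features, cumulative, result


def permutation_test_auc(
    table: CovarianceTable,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    observed_auc: float | None = None,
    **analysis_kwargs,
):
    """Permutation significance of the LOO-LASSO AUC.

    Group labels are permuted and the full pipeline (component extraction
    from the permuted reference set, LOO congruency features, LOO LASSO,
    AUC) is re-run per permutation.  Returns
    ``(p, observed_auc, null_aucs)`` with
    ``p = (1 + #{AUC_perm >= AUC_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    if observed_auc is None:
        _, _, res = analyze_condition(
            table, labels, seed=int(rng.integers(0, 2**31 - 1)), **analysis_kwargs
        )
        observed_auc = res.auc
    null_aucs = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        _, _, res = analyze_condition(
            table, perm, seed=int(rng.integers(0, 2**31 - 1)), **analysis_kwargs
        )
        null_aucs[i] = res.auc
    p = (1.0 + np.count_nonzero(null_aucs >= observed_auc)) / (n_perm + 1.0)
    return p, float(observed_auc), null_aucs


# ---------------------------------------------------------------------------
# reporting ANOVAs


def anova_group_grade(metrics: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Two-way ANOVA (group x grade) on a congruency metric, Type II SS.

    ``metrics`` needs columns ``group``, ``grade`` and ``value_col``; every
    group x grade cell must be populated.  Zero-variance (degenerate) input
    is flagged via a ``degenerate`` attribute on the returned table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("group", "grade", value_col):
        if col not in metrics.columns:
            raise ValueError(f"missing column {col!r}")
    cells = metrics.groupby(["group", "grade"], observed=True).size()
    n_groups = metrics["group"].nunique()
    n_grades = metrics["grade"].nunique()
    if len(cells) < n_groups * n_grades:
        raise ValueError(f"empty group x grade cell; populated cells: {dict(cells)}")
    df = metrics.rename(columns={value_col: "_y"})
    model = smf.ols("_y ~ C(group) * C(grade)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.attrs["degenerate"] = bool(np.ptp(df["_y"].to_numpy()) == 0)
    return table


def rm_anova_modality_confusability(metrics: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Two-factor repeated-measures ANOVA: modality (rime vs visual) x
    confusability, within participants, over the four condition metrics.

    ``metrics`` needs columns ``participant``, ``condition`` and
    ``value_col`` with all four conditions per participant.
    """
    from statsmodels.stats.anova import AnovaRM

    from .containers import CONDITION_FACTORS

    df = metrics.copy()
    counts = df.groupby("participant")["condition"].nunique()
    incomplete = counts[counts < 4].index.tolist()
    if incomplete or df["condition"].nunique() != 4:
        raise ValueError(
            f"every participant needs all 4 condition metrics; incomplete: {incomplete}"
        )
    df["modality"] = df["condition"].map(lambda c: CONDITION_FACTORS[int(c)][0])
    df["confusability"] = df["condition"].map(lambda c: CONDITION_FACTORS[int(c)][1])
    res = AnovaRM(
        data=df, depvar=value_col, subject="participant",
        within=["modality", "confusability"],
    ).fit()
    return res.anova_table
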