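"""Statistical battery for nuclear feature tables.

Descriptives, two-group Welch t tests, two-sample Kolmogorov--Smirnov
comparisons, one-way linear-model (GLM) group contrasts, and stepwise
linear discriminant analysis driven by Wilks' lambda with F-to-enter /
F-to-remove thresholds, reporting resubstitution confusion matrices in
row percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: SPSS-conventional stepwise thresholds
DEFAULT_F_ENTER = 3.84
DEFAULT_F_REMOVE = 2.71


# --------------------------------------------------------------------------
# descriptives and univariate tests

def describe(table: pd.DataFrame, grouping: str | pd.Series) -> pd.DataFrame:
    """Mean, SD, min and max of every numeric feature per group."""
    if len(table) == 0:
        raise ValueError("feature table is empty")
    groups = table[grouping] if isinstance(grouping, str) else pd.Series(grouping, index=table.index)
    numeric = table.select_dtypes(include=[np.number])
    if isinstance(grouping, str):
        numeric = numeric.drop(columns=[grouping], errors="ignore")
    out = numeric.groupby(groups).agg(["mean", "std", "min", "max"])
    empty = [g for g, n in groups.value_counts().items() if n == 0]
    if empty:
        warnings.warn(f"empty groups omitted: {empty}", stacklevel=2)
    return out


def two_group_test(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    equal_var: bool = False,
) -> tuple[float, float, tuple[int, int]]:
    """Two-sided two-sample t test (Welch by default).

    Missing values are dropped pairwise-incomplete; returns
    ``(t, p, (n_a, n_b))``. If both groups are degenerate (zero variance)
    the test reduces to an equality check on the means.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 non-missing values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        same = np.isclose(a.mean(), b.mean())
        return (0.0, 1.0, (len(a), len(b))) if same else (np.inf, 0.0, (len(a), len(b)))
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), (len(a), len(b))


def ks_test(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series) -> tuple[float, float]:
    """Two-sample Kolmogorov--Smirnov test: ``D = sup |ECDF_a - ECDF_b|``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    grouping: str,
    features: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-feature two-group t test table with means, SDs and significance flags."""
    groups = table[grouping].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(groups)}")
    features = list(features) if features is not None else [
        c for c in table.select_dtypes(include=[np.number]).columns if c != grouping
    ]
    g0 = table.loc[table[grouping] == groups[0]]
    g1 = table.loc[table[grouping] == groups[1]]
    rows = []
    for f in features:
        t, p, (na, nb) = two_group_test(g0[f], g1[f], equal_var=equal_var)
        rows.append(
            {
                "feature": f,
                f"mean_{groups[0]}": g0[f].mean(), f"sd_{groups[0]}": g0[f].std(),
                f"mean_{groups[1]}": g1[f].mean(), f"sd_{groups[1]}": g1[f].std(),
                "n_a": na, "n_b": nb, "t": t, "p": p, "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def multi_group_comparison(
    table: pd.DataFrame,
    grouping: str,
    features: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One-way fixed-effects F test per feature across >= 2 groups.

    With exactly two groups the F statistic equals the squared pooled t.
    """
    levels = [g for g, sub in table.groupby(grouping) if len(sub) >= 2]
    if len(levels) < 2:
        raise ValueError("need at least two groups with >= 2 members")
    features = list(features) if features is not None else [
        c for c in table.select_dtypes(include=[np.number]).columns if c != grouping
    ]
    rows = []
    for f in features:
        samples = [
            table.loc[table[grouping] == g, f].dropna().to_numpy(float) for g in levels
        ]
        stat, p = sps.f_oneway(*samples)
        rows.append({"feature": f, "F": float(stat), "p": float(p), "significant": p < alpha})
    return pd.DataFrame(rows)


def cohort_summary(counts: Mapping[str, int]) -> pd.DataFrame:
    """Totals and percentage shares of categorical counts.

    Shares are ``100 * part / total`` rounded to one decimal; a ``total``
    row is appended.
    """
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = int(sum(counts.values()))
    if total == 0:
        raise ValueError("total count is zero")
    rows = [
        {"category": k, "count": int(v), "percent": round(100.0 * v / total, 1)}
        for k, v in counts.items()
    ]
    rows.append({"category": "total", "count": total, "percent": 100.0})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stepwise linear discriminant analysis

@dataclass
class ConfusionMatrix:
    """Resubstitution (or held-out) classification summary."""

    classes: list
    counts: np.ndarray  # (g, g), rows = true class
    percentages: np.ndarray = field(init=False)
    correct_rate: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, float)
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.percentages = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
        self.correct_rate = float(np.trace(counts) / counts.sum()) if counts.sum() else np.nan

    def to_frame(self, percentages: bool = True) -> pd.DataFrame:
        data = self.percentages if percentages else self.counts
        return pd.DataFrame(data, index=self.classes, columns=self.classes)


@dataclass
class LDAModel:
    """Fisher linear discriminant on a stepwise-selected feature subset."""

    features: list[str]
    classes: list
    class_means: np.ndarray       # (g, p)
    pooled_cov_inv: np.ndarray    # (p, p)
    wilks_lambda: float
    steps: list[tuple[str, str, float]]  # (action, feature, F)

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Nearest class in discriminant (Mahalanobis) metric, equal priors."""
        x = (
            table[self.features].to_numpy(float)
            if isinstance(table, pd.DataFrame)
            else np.asarray(table, float)
        )
        # linear score: x' S^-1 mu_k - 0.5 mu_k' S^-1 mu_k
        a = self.pooled_cov_inv @ self.class_means.T              # (p, g)
        scores = x @ a - 0.5 * np.einsum("kp,pk->k", self.class_means, a)
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


def _sscp(x: np.ndarray, y_codes: np.ndarray, g: int) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and total sum-of-squares-and-cross-products matrices."""
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    for k in range(g):
        xk = x[y_codes == k]
        if len(xk):
            d = xk - xk.mean(axis=0)
            w += d.T @ d
    return w, t


def _wilks(w: np.ndarray, t: np.ndarray, cols: list[int]) -> float:
    if not cols:
        return 1.0
    ws = w[np.ix_(cols, cols)]
    ts = t[np.ix_(cols, cols)]
    sign_w, logdet_w = np.linalg.slogdet(ws)
    sign_t, logdet_t = np.linalg.slogdet(ts)
    if sign_w <= 0 or sign_t <= 0:
        return np.nan
    return float(np.exp(logdet_w - logdet_t))


def stepwise_select(
    x: np.ndarray,
    y_codes: np.ndarray,
    g: int,
    f_enter: float = DEFAULT_F_ENTER,
    f_remove: float = DEFAULT_F_REMOVE,
    max_steps: int = 200,
) -> tuple[list[int], float, list[tuple[str, int, float]]]:
    """Forward-backward feature selection minimising Wilks' lambda.

    Returns ``(selected column indices, final lambda, step log)``. The
    partial-F statistics follow the standard multivariate formulation: for a
    candidate variable given p variables already entered,
    ``F = (n - g - p) / (g - 1) * (1 - L) / L`` with ``L`` the ratio of the
    Wilks' lambdas of the larger and smaller subsets.
    """
    n, n_feat = x.shape
    w, t = _sscp(x, y_codes, g)
    selected: list[int] = []
    lam = 1.0
    steps: list[tuple[str, int, float]] = []

    for _ in range(max_steps):
        changed = False
        # backward sweep
        if len(selected) > 1:
            worst, worst_f = None, np.inf
            for col in selected:
                reduced = [c for c in selected if c != col]
                lam_red = _wilks(w, t, reduced)
                if not np.isfinite(lam_red) or lam_red <= 0:
                    continue
                partial = lam / lam_red
                df2 = n - g - len(selected) + 1
                f = (df2 / (g - 1)) * (1 - partial) / max(partial, 1e-300)
                if f < worst_f:
                    worst, worst_f = col, f
            if worst is not None and worst_f < f_remove:
                selected.remove(worst)
                lam = _wilks(w, t, selected)
                steps.append(("remove", worst, worst_f))
                changed = True
        # forward sweep
        best, best_f, best_lam = None, -np.inf, None
        for col in range(n_feat):
            if col in selected:
                continue
            lam_new = _wilks(w, t, selected + [col])
            if not np.isfinite(lam_new) or lam_new <= 0 or lam_new > lam:
                continue
            partial = lam_new / lam
            df2 = n - g - len(selected)
            f = (df2 / (g - 1)) * (1 - partial) / max(partial, 1e-300)
            if f > best_f:
                best, best_f, best_lam = col, f, lam_new
        if best is not None and best_f > f_enter:
            selected.append(best)
            lam = best_lam
            steps.append(("enter", best, best_f))
            changed = True
        if not changed:
            break
    return selected, lam, steps


def stepwise_lda(
    table: pd.DataFrame,
    class_column: str,
    features: Sequence[str] | None = None,
    f_enter: float = DEFAULT_F_ENTER,
    f_remove: float = DEFAULT_F_REMOVE,
    ridge: float = 1e-8,
    cv_folds: int | None = None,
) -> tuple[LDAModel, ConfusionMatrix]:
    """Stepwise LDA: Wilks'-lambda feature selection, Fisher classification.

    Classification assigns each nucleus to the nearest class in the pooled
    within-class metric with equal priors; the confusion matrix is computed
    by resubstitution on the training table. With ``cv_folds`` set, the
    confusion matrix is instead aggregated over stratified k-fold held-out
    predictions (feature selection stays fixed from the full fit, as in
    conventional discriminant-analysis software).
    """
    features = list(features) if features is not None else [
        c for c in table.select_dtypes(include=[np.number]).columns if c != class_column
    ]
    work = table[features + [class_column]].dropna()
    classes = sorted(work[class_column].unique())
    g = len(classes)
    if g < 2:
        raise ValueError("need at least two classes")
    y_codes = work[class_column].map({c: i for i, c in enumerate(classes)}).to_numpy()
    x = work[features].to_numpy(float)
    counts = np.bincount(y_codes, minlength=g)
    if counts.min() < len(features) + 2:
        warnings.warn(
            f"smallest class has {counts.min()} rows for {len(features)} candidate "
            "features; selection may be unstable", stacklevel=2,
        )

    sel_idx, lam, raw_steps = stepwise_select(x, y_codes, g, f_enter, f_remove)
    if not sel_idx:
        warnings.warn(
            "no feature passed the F-to-enter threshold; falling back to the "
            "single best candidate", stacklevel=2,
        )
        w, t = _sscp(x, y_codes, g)
        lams = [_wilks(w, t, [c]) for c in range(len(features))]
        sel_idx = [int(np.nanargmin(lams))]
        lam = lams[sel_idx[0]]
    selected = [features[i] for i in sel_idx]

    xs = x[:, sel_idx]
    means = np.vstack([xs[y_codes == k].mean(axis=0) for k in range(g)])
    pooled = np.zeros((len(sel_idx), len(sel_idx)))
    for k in range(g):
        d = xs[y_codes == k] - means[k]
        pooled += d.T @ d
    pooled /= max(len(xs) - g, 1)
    try:
        cov_inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        log.warning("singular pooled covariance; adding ridge %.1e", ridge)
        pooled += ridge * np.eye(len(sel_idx)) * max(np.trace(pooled), 1.0)
        cov_inv = np.linalg.inv(pooled)

    model = LDAModel(
        features=selected,
        classes=classes,
        class_means=means,
        pooled_cov_inv=cov_inv,
        wilks_lambda=lam,
        steps=[(a, features[i], f) for a, i, f in raw_steps],
    )
    if cv_folds:
        truth_all, pred_all = [], []
        for fold in range(cv_folds):
            test_idx = np.zeros(len(work), dtype=bool)
            for k in range(g):  # stratified assignment, round-robin
                members = np.nonzero(y_codes == k)[0]
                test_idx[members[fold::cv_folds]] = True
            train, test = xs[~test_idx], xs[test_idx]
            y_train = y_codes[~test_idx]
            fold_means = np.vstack(
                [train[y_train == k].mean(axis=0) for k in range(g)]
            )
            fold_model = LDAModel(
                features=selected, classes=classes, class_means=fold_means,
                pooled_cov_inv=cov_inv, wilks_lambda=lam, steps=model.steps,
            )
            truth_all.append(work[class_column].to_numpy()[test_idx])
            pred_all.append(fold_model.predict(test))
        cm = confusion_matrix(
            np.concatenate(truth_all), np.concatenate(pred_all), classes
        )
        return model, cm

    predicted = model.predict(work)
    cm = confusion_matrix(work[class_column].to_numpy(), predicted, classes)
    return model, cm


def confusion_matrix(truth: np.ndarray, predicted: np.ndarray, classes: Sequence) -> ConfusionMatrix:
    """Raw-count confusion matrix for an explicit class ordering."""
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t_val, p_val in zip(truth, predicted):
        counts[index[t_val], index[p_val]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)
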