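"""Chemometrics for two-class lipid-profile discrimination.

The central model is a two-class orthogonal projection to latent
structures (O2PLS-DA / OPLS-DA): one predictive component after removal
of ``n_orth`` orthogonal (class-unrelated) components, the decomposition
of Trygg & Wold. Class membership is coded y in {0, 1}; a fitted model
reports R2X, R2Y, cross-validated Q2, a CV-ANOVA significance test, and
per-variable S-plot statistics (covariance and correlation with the
predictive score) for biomarker ranking.

Univariate support: Welch t-tests with Bonferroni familywise control,
fold-change tables, and the ddCt relative-expression transform for qPCR
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "O2PLSDAModel",
    "normalize_tag_pool",
    "scale_matrix",
    "fit_o2plsda",
    "predict_y",
    "cross_validated_q2",
    "cv_anova",
    "s_plot",
    "choose_n_orth",
    "ttest_bonferroni",
    "ttest_from_summary",
    "welch_from_summary",
    "fold_changes",
    "delta_delta_ct",
    "pca",
]


def normalize_tag_pool(X: pd.DataFrame, tag_variables: Sequence[str]) -> pd.DataFrame:
    """Convert TAG intensities to within-sample relative proportions.

    Each TAG variable is divided by that sample's total TAG signal, so the
    TAG columns of every returned row sum to 1. This removes between-sample
    differences in total TAG load and isolates pool *composition*.
    """
    tag_variables = list(tag_variables)
    if not tag_variables:
        raise ValueError("tag_variables must be non-empty")
    sub = X[tag_variables]
    totals = sub.sum(axis=1, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total TAG signal in sample(s): {list(zero.index)}")
    return sub.div(totals, axis=0)


def scale_matrix(
    X: np.ndarray, scaling: str = "uv"
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centering and scaling. Returns (scaled, mean, divisor).

    ``uv`` divides by the standard deviation (SIMCA's default), ``pareto``
    by its square root, ``none`` only centers. Zero-variance columns get a
    unit divisor (they carry no information either way).
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        div = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        div = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scaling == "none":
        div = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - mean) / div, mean, div


@dataclass
class O2PLSDAModel:
    """Fitted two-class OPLS model (one predictive component)."""

    columns: List[str]
    scaling: str
    x_mean: np.ndarray
    x_div: np.ndarray
    y_mean: float
    w: np.ndarray          # predictive weights, unit norm
    p: np.ndarray          # predictive X loadings
    q: float               # y loading
    t: np.ndarray          # predictive scores (training)
    w_orth: np.ndarray     # (n_orth, n_vars) orthogonal weights
    p_orth: np.ndarray     # (n_orth, n_vars) orthogonal loadings
    t_orth: np.ndarray     # (n_samples, n_orth) orthogonal scores
    n_orth: int
    r2x: float             # % of X variance captured (pred + orth)
    r2y: float             # % of y variance fitted
    q2: float              # % cross-validated (7-fold)
    cv_anova_p: float
    predicted_y: pd.Series          # fitted y-hat per training sample
    cv_predicted_y: np.ndarray      # cross-validated y-hat per sample
    y: np.ndarray = field(repr=False, default=None)

    def summary(self) -> Dict[str, float]:
        return {
            "n_pred": 1, "n_orth": self.n_orth,
            "R2X_pct": self.r2x, "R2Y_pct": self.r2y, "Q2_pct": self.q2,
            "cv_anova_p": self.cv_anova_p,
        }


def _opls_core(
    Xs: np.ndarray, yc: np.ndarray, n_orth: int
) -> Tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OPLS decomposition on pre-scaled X and centered y.

    Returns (w, p, q, t, W_orth, P_orth, T_orth). The predictive weight w
    is computed once from the undeflated X; orthogonal components are the
    parts of the X loading orthogonal to w, peeled off before the final
    predictive fit.
    """
    yy = float(yc @ yc)
    if yy == 0:
        raise ValueError("y has a single class (zero variance)")
    w = Xs.T @ yc / yy
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with y")
    w /= nw
    Xd = Xs.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orth):
        t = Xd @ w
        tt = float(t @ t)
        p_load = Xd.T @ t / tt
        w_o = p_load - float(w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xd @ w
    tt = float(t @ t)
    p_load = Xd.T @ t / tt
    q = float(yc @ t / tt)
    W_o = np.array(W_o) if W_o else np.empty((0, Xs.shape[1]))
    P_o = np.array(P_o) if P_o else np.empty((0, Xs.shape[1]))
    T_o = np.array(T_o).T if T_o else np.empty((Xs.shape[0], 0))
    return w, p_load, q, t, W_o, P_o, T_o


def _project(Xs: np.ndarray, w: np.ndarray, W_o: np.ndarray, P_o: np.ndarray) -> np.ndarray:
    """Predictive scores for pre-scaled X: strip orthogonal variation, then
    project onto w."""
    Xd = Xs.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xd @ w_o
        Xd = Xd - np.outer(t_o, p_o)
    return Xd @ w


def _encode_y(y: Sequence) -> Tuple[np.ndarray, Optional[List]]:
    arr = np.asarray(y)
    if arr.dtype.kind in "ifb":
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("numeric y must be coded 0/1")
        return arr.astype(float), None
    classes = sorted(pd.unique(arr))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return (arr == classes[1]).astype(float), classes


def fit_o2plsda(
    X: pd.DataFrame,
    y: Sequence,
    n_orth: int = 0,
    scaling: str = "uv",
    folds: int = 7,
    cv_seed: int = 0,
) -> O2PLSDAModel:
    """Fit a two-class O2PLS-DA model with one predictive component.

    ``y`` is 0/1 (or a two-level label vector; the lexicographically later
    level is coded 1). ``n_orth`` orthogonal components are removed by
    orthogonal-signal filtering before the predictive fit. Q2 comes from
    ``folds``-fold cross-validation with the whole pipeline (scaling
    included) re-estimated inside each training fold; fold assignment is
    venetian-blind after a seeded shuffle, so the fit is deterministic for
    fixed inputs and ``cv_seed``.
    """
    yv, _ = _encode_y(y)
    counts = pd.Series(yv).value_counts()
    if counts.min() < 3:
        raise ValueError("need at least 3 samples per class")
    Xv = X.to_numpy(dtype=float)
    if n_orth >= min(Xv.shape) - 1:
        raise ValueError(f"n_orth={n_orth} exceeds the rank budget of X {Xv.shape}")
    Xs, x_mean, x_div = scale_matrix(Xv, scaling)
    y_mean = float(yv.mean())
    yc = yv - y_mean

    w, p, q, t, W_o, P_o, T_o = _opls_core(Xs, yc, n_orth)
    yhat = t * q
    ssy = float(yc @ yc)
    r2y = 100.0 * (1.0 - float((yc - yhat) @ (yc - yhat)) / ssy)
    ssx = float((Xs ** 2).sum())
    explained = float(np.outer(t, p).__pow__(2).sum())
    for k in range(T_o.shape[1]):
        explained += float(np.outer(T_o[:, k], P_o[k]).__pow__(2).sum())
    r2x = 100.0 * explained / ssx if ssx > 0 else 0.0

    q2, cv_pred = _cross_validate(Xv, yv, n_orth, scaling, folds, cv_seed)
    press = float(((yv - cv_pred) ** 2).sum())
    p_cv = _cv_anova_p(ssy, press, len(yv), 1 + W_o.shape[0])

    index = X.index if hasattr(X, "index") else pd.RangeIndex(len(yv))
    model = O2PLSDAModel(
        columns=list(X.columns), scaling=scaling, x_mean=x_mean, x_div=x_div,
        y_mean=y_mean, w=w, p=p, q=q, t=t,
        w_orth=W_o, p_orth=P_o, t_orth=T_o, n_orth=W_o.shape[0],
        r2x=r2x, r2y=r2y, q2=q2, cv_anova_p=p_cv,
        predicted_y=pd.Series(yhat + y_mean, index=index, name="predicted_y"),
        cv_predicted_y=cv_pred, y=yv,
    )
    return model


def predict_y(model: O2PLSDAModel, X_new: pd.DataFrame) -> pd.Series:
    """Continuous class score for new samples (class call at 0.5).

    Applies the stored centering/scaling, strips the orthogonal
    components, and projects onto the predictive component.
    """
    if list(X_new.columns) != model.columns:
        raise ValueError("variables of X_new do not match the training variables")
    Xs = (X_new.to_numpy(dtype=float) - model.x_mean) / model.x_div
    t = _project(Xs, model.w, model.w_orth, model.p_orth)
    return pd.Series(t * model.q + model.y_mean, index=X_new.index, name="predicted_y")


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    assign[order] = np.arange(n) % folds  # venetian blind over shuffled order
    return assign


def _cross_validate(
    Xv: np.ndarray, yv: np.ndarray, n_orth: int, scaling: str, folds: int, seed: int
) -> Tuple[float, np.ndarray]:
    n = len(yv)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    folds = min(folds, n)
    assign = _fold_assignment(n, folds, seed)
    cv_pred = np.empty(n)
    for k in range(folds):
        test = assign == k
        train = ~test
        ytr = yv[train]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"fold {k} lost one class entirely")
        Xs_tr, m, d = scale_matrix(Xv[train], scaling)
        ym = float(ytr.mean())
        w, p, q, t, W_o, P_o, _ = _opls_core(Xs_tr, ytr - ym, n_orth)
        Xs_te = (Xv[test] - m) / d
        t_te = _project(Xs_te, w, W_o, P_o)
        cv_pred[test] = t_te * q + ym
    ss = float(((yv - yv.mean()) ** 2).sum())
    press = float(((yv - cv_pred) ** 2).sum())
    q2 = 100.0 * (1.0 - press / ss)
    return q2, cv_pred


def cross_validated_q2(
    X: pd.DataFrame, y: Sequence, n_orth: int = 0, scaling: str = "uv",
    folds: int = 7, seed: int = 0,
) -> float:
    """Q2 = 100 * (1 - PRESS/SS) under ``folds``-fold CV with full per-fold
    refitting (scaling re-estimated within each training fold)."""
    yv, _ = _encode_y(y)
    q2, _ = _cross_validate(X.to_numpy(dtype=float), yv, n_orth, scaling, folds, seed)
    return q2


def _cv_anova_p(ssy: float, press: float, n: int, n_components: int) -> float:
    """F-test on cross-validated residuals against the corrected SS of y
    (Eriksson-style CV-ANOVA). Model d.f. = fitted components."""
    d1 = n_components
    d2 = n - 1 - d1
    if d2 <= 0:
        return float("nan")
    ms_reg = (ssy - press) / d1
    ms_res = press / d2
    if ms_res <= 0:
        return 0.0
    f = ms_reg / ms_res
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, d1, d2))


def cv_anova(model: O2PLSDAModel) -> float:
    """CV-ANOVA p value of a fitted model (uses the stored CV residuals)."""
    if model.cv_predicted_y is None or model.y is None:
        raise ValueError("model carries no cross-validation residuals")
    yc = model.y - model.y.mean()
    press = float(((model.y - model.cv_predicted_y) ** 2).sum())
    return _cv_anova_p(float(yc @ yc), press, len(model.y), 1 + model.n_orth)


def choose_n_orth(
    X: pd.DataFrame, y: Sequence, max_orth: int = 5, scaling: str = "uv",
    folds: int = 7, seed: int = 0, min_gain: float = 1.0,
) -> int:
    """Add orthogonal components while Q2 improves by more than
    ``min_gain`` percentage points."""
    best_q2 = cross_validated_q2(X, y, 0, scaling, folds, seed)
    n_orth = 0
    for k in range(1, max_orth + 1):
        if k >= min(X.shape) - 1:
            break
        q2 = cross_validated_q2(X, y, k, scaling, folds, seed)
        if q2 > best_q2 + min_gain:
            best_q2, n_orth = q2, k
        else:
            break
    return n_orth


def s_plot(model: O2PLSDAModel, X: pd.DataFrame) -> pd.DataFrame:
    """S-plot statistics: per variable, covariance (p1) and correlation
    (p_corr) with the predictive score, ranked by |correlation| then
    |covariance|. Zero-variance variables get missing correlation."""
    Xs = (X.to_numpy(dtype=float) - model.x_mean) / model.x_div
    t = model.t
    n = len(t)
    tc = t - t.mean()
    Xc = Xs - Xs.mean(axis=0)
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sx > 0, cov / (sx * st), np.nan)
    df = pd.DataFrame({"p1": cov, "p_corr": corr}, index=model.columns)
    order = df.assign(a=df["p_corr"].abs(), b=df["p1"].abs()) \
              .sort_values(["a", "b"], ascending=False).index
    df["rank"] = pd.Series(range(1, len(df) + 1), index=order)
    return df


def ttest_bonferroni(
    X: pd.DataFrame, groups: pd.Series, labels: Tuple[str, str],
    alpha: float = 0.05, equal_var: bool = False,
) -> pd.DataFrame:
    """Per-variable two-sided t-test between two groups with Bonferroni
    familywise control: significance iff p <= alpha / m, m = number of
    variables. Welch by default (``equal_var=False``)."""
    a_label, b_label = labels
    A = X.loc[groups == a_label]
    B = X.loc[groups == b_label]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 samples")
    m = X.shape[1]
    threshold = alpha / m
    t_stat, p = stats.ttest_ind(A.to_numpy(float), B.to_numpy(float),
                                axis=0, equal_var=equal_var, nan_policy="omit")
    mean_a = A.mean().to_numpy()
    mean_b = B.mean().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
        log2fc = np.log2(fc)
    out = pd.DataFrame({
        f"mean_{a_label}": mean_a, f"mean_{b_label}": mean_b,
        "fold_change": fc, "log2_fc": log2fc,
        "t": t_stat, "p": p,
        "significant": p <= threshold,
    }, index=X.columns)
    out.attrs["alpha"] = alpha
    out.attrs["m"] = m
    out.attrs["threshold"] = threshold
    return out


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> Tuple[float, float]:
    """Two-sided t-test from summary statistics; returns (t, p).

    Welch by default; ``equal_var=True`` gives the pooled Student variant.
    """
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> Tuple[float, float]:
    """Welch t-test from summary statistics; returns (t, two-sided p)."""
    return ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)


def fold_changes(
    X: pd.DataFrame, groups: pd.Series, labels: Tuple[str, str]
) -> pd.DataFrame:
    """Group-mean fold change A/B per variable, with log2 and direction."""
    a_label, b_label = labels
    mean_a = X.loc[groups == a_label].mean()
    mean_b = X.loc[groups == b_label].mean()
    if (mean_b <= 0).any():
        bad = list(mean_b.index[mean_b <= 0])
        raise ValueError(f"non-positive denominator group mean for {bad}")
    fc = mean_a / mean_b
    return pd.DataFrame({
        f"mean_{a_label}": mean_a, f"mean_{b_label}": mean_b,
        "fold_change": fc, "log2_fc": np.log2(fc),
        "direction": np.where(fc >= 1, f"up_in_{a_label}", f"down_in_{a_label}"),
    })


def delta_delta_ct(
    ct: pd.DataFrame, reference_gene: str, reference_group: str
) -> pd.DataFrame:
    """ddCt relative expression from a tidy Ct table.

    ``ct`` needs columns sample_id, group, gene, ct. Per sample,
    dCt = Ct(gene) - Ct(reference gene); per group,
    ddCt = mean dCt(group) - mean dCt(reference group); relative
    expression = 2 ** (-ddCt), so the reference group sits at 1.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    wide = ct.pivot_table(index=["sample_id", "group"], columns="gene",
                          values="ct", aggfunc="mean")
    if reference_gene not in wide.columns or wide[reference_gene].isna().any():
        raise ValueError(f"reference gene {reference_gene!r} missing for some samples")
    dct = wide.drop(columns=reference_gene).sub(wide[reference_gene], axis=0)
    group_means = dct.groupby(level="group").mean()
    if reference_group not in group_means.index:
        raise ValueError(f"reference group {reference_group!r} absent")
    ddct = group_means - group_means.loc[reference_group]
    rel = 2.0 ** (-ddct)
    long = rel.reset_index().melt(id_vars="group", var_name="gene",
                                  value_name="relative_expression")
    long["ddct"] = ddct.reset_index().melt(
        id_vars="group", var_name="gene", value_name="v")["v"]
    return long


def pca(
    X: pd.DataFrame, n_components: int = 2, scaling: str = "none"
) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Centered (optionally scaled) PCA via SVD.

    Returns (scores, loadings, explained_variance_pct). Sign convention:
    the largest-magnitude loading of each component is positive.
    """
    Xv = X.to_numpy(dtype=float)
    if n_components > min(Xv.shape[0] - 1, Xv.shape[1]):
        raise ValueError("n_components exceeds the rank of the centered matrix")
    Xs, _, _ = scale_matrix(Xv, scaling)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    total = float((S ** 2).sum())
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = pd.DataFrame(U[:, :n_components] * S[:n_components],
                          index=X.index,
                          columns=[f"PC{i+1}" for i in range(n_components)])
    loadings = pd.DataFrame(Vt[:n_components].T, index=X.columns,
                            columns=scores.columns)
    explained = 100.0 * (S[:n_components] ** 2) / total if total > 0 else \
        np.zeros(n_components)
    return scores, loadings, explained
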