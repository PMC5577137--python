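"""Compound covariate prediction of ER-true vs TN-like class.

Feature selection uses the random-variance t-test: per-feature variances
are shrunk toward an inverse-gamma prior fitted across all features by
the method of moments (the marginal distribution of a sample variance
under the prior is a scaled F).  The shrunken variance is

    sigma~^2 = ((n-2) s^2 + 2ab) / (n - 2 + 2a),   df = n - 2 + 2a

where ab is the prior mean variance.  The compound covariate predictor
scores a sample by the t-weighted sum of its selected features and
thresholds at the midpoint of the two class-mean scores.  Error is
estimated by leave-one-out cross-validation with full re-selection in
every fold, and significance by permuting class labels and repeating the
whole LOOCV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CcpClassifier",
    "CvReport",
    "fit_variance_prior",
    "random_variance_t",
    "fit_ccp",
    "loocv",
    "permutation_significance",
    "apply_classifier",
]


@dataclass
class CcpClassifier:
    """A fitted compound covariate predictor."""

    features: pd.Index
    weights: pd.Series               # random-variance t statistic per feature
    class_means: pd.DataFrame        # per-feature mean expression per class
    classes: tuple                   # (class1, class2); predict class1 if score >= threshold side
    threshold: float
    alpha: float
    a: float
    b: float

    def score(self, matrix: pd.DataFrame, features=None) -> pd.Series:
        feats = self.features if features is None else features
        return matrix.loc[feats].mul(self.weights.loc[feats], axis=0).sum(axis=0)

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        return apply_classifier(self, matrix)


@dataclass
class CvReport:
    """LOOCV error with optional label-permutation significance."""

    loocv_error: float
    predictions: pd.Series
    permutation_p: float | None = None
    n_label_permutations: int = 0
    n_empty_folds: int = 0


def fit_variance_prior(variances) -> tuple[float, float]:
    """Method-of-moments inverse-gamma fit to the per-feature variances.

    With sigma^2 ~ InvGamma(shape a, scale ab) the squared coefficient of
    variation is 1/(a-2) and the mean is ab/(a-1), giving

        a = 2 + 1/CV^2,        b = mean * (a-1) / a.

    Fitting the observed s^2 rather than the latent sigma^2 inflates the
    dispersion slightly, which only makes the shrinkage conservative.
    Degenerate inputs (near-constant variances, too few features) fall
    back to a = 0, i.e. no shrinkage.
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < 50:
        warnings.warn("fewer than 50 features: variance prior not fitted (no shrinkage)")
        return 0.0, 0.0
    m = v.mean()
    k = v.var(ddof=1) / m**2
    if not np.isfinite(k) or k <= 1e-8:
        return 0.0, 0.0  # essentially constant variances: shrinkage is a no-op
    a = 2.0 + 1.0 / k
    b = m * (a - 1.0) / a
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        return 0.0, 0.0
    return float(a), float(b)


def random_variance_t(x, y, a: float, b: float):
    """Random-variance (shrunken) two-sample t statistic and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    if n < 4:
        raise ValueError("need >= 4 samples in total")
    ss = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    s2 = ss / (n - 2)
    sig2 = ((n - 2) * s2 + 2 * a * b) / (n - 2 + 2 * a)
    df = n - 2 + 2 * a
    t = (x.mean() - y.mean()) / np.sqrt(sig2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _rv_t_matrix(x: np.ndarray, mask1: np.ndarray, a: float, b: float):
    """Vectorised random-variance t over all features; mask1 = group-1 columns."""
    n1 = int(mask1.sum())
    n2 = x.shape[1] - n1
    n = n1 + n2
    x1, x2g = x[:, mask1], x[:, ~mask1]
    m1, m2 = x1.mean(axis=1), x2g.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2g - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / (n - 2)
    sig2 = ((n - 2) * s2 + 2 * a * b) / (n - 2 + 2 * a)
    df = n - 2 + 2 * a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sig2 * (1.0 / n1 + 1.0 / n2))
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, m1, m2


def fit_ccp(matrix: pd.DataFrame, labels, alpha: float = 0.05) -> CcpClassifier:
    """Fit the compound covariate predictor.

    Selects features with random-variance p < ``alpha``, weights them by
    their t statistics, and thresholds sample scores at the midpoint of
    the two class-mean scores.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.columns)
    classes = tuple(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if min((labels == c).sum() for c in classes) < 3:
        raise ValueError("each class needs >= 3 samples")

    x = matrix.to_numpy(dtype=float)
    mask1 = (labels == classes[0]).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b = fit_variance_prior(x.var(axis=1, ddof=1))
    t, p, m1, m2 = _rv_t_matrix(x, mask1, a, b)
    sel = p < alpha
    if not sel.any():
        raise ValueError("no feature passed the selection level; fit fails")

    feats = matrix.index[sel]
    weights = pd.Series(t[sel], index=feats)
    class_means = pd.DataFrame(
        {classes[0]: m1[sel], classes[1]: m2[sel]}, index=feats
    )
    mean_scores = class_means.mul(weights, axis=0).sum(axis=0)
    threshold = float(mean_scores.mean())
    return CcpClassifier(
        features=feats,
        weights=weights,
        class_means=class_means,
        classes=classes,
        threshold=threshold,
        alpha=alpha,
        a=a,
        b=b,
    )


def apply_classifier(clf: CcpClassifier, matrix: pd.DataFrame) -> pd.Series:
    """Predict classes for new (per-feature normalised) samples.

    Features absent from ``matrix`` are dropped from the score; the
    threshold is recomputed from the stored per-feature class means on the
    available features.  Fails if under half the features are present.
    """
    present = clf.features.intersection(matrix.index)
    if len(present) * 2 < len(clf.features):
        raise ValueError(
            f"only {len(present)}/{len(clf.features)} classifier features present"
        )
    w = clf.weights.loc[present]
    scores = matrix.loc[present].mul(w, axis=0).sum(axis=0)
    mean_scores = clf.class_means.loc[present].mul(w, axis=0).sum(axis=0)
    thr = float(mean_scores.mean())
    side1 = mean_scores[clf.classes[0]] >= thr
    pred = np.where(
        (scores >= thr) == side1, clf.classes[0], clf.classes[1]
    )
    return pd.Series(pred, index=matrix.columns, name="prediction")


def loocv(matrix: pd.DataFrame, labels, alpha: float = 0.05) -> CvReport:
    """Leave-one-out cross-validation with full re-selection per fold.

    Each fold refits the variance prior, reselects features and refits the
    predictor on n-1 samples; a fold whose selection is empty counts as a
    misclassification.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.columns)
    n = matrix.shape[1]
    if n < 6:
        raise ValueError("need >= 6 samples for LOOCV")
    preds, errors, empty = {}, 0, 0
    for sid in matrix.columns:
        train = matrix.drop(columns=[sid])
        try:
            clf = fit_ccp(train, labels.drop(sid), alpha=alpha)
            pred = apply_classifier(clf, matrix[[sid]]).iloc[0]
        except ValueError:
            empty += 1
            pred = None
        preds[sid] = pred
        if pred != labels[sid]:
            errors += 1
    return CvReport(
        loocv_error=errors / n,
        predictions=pd.Series(preds, name="loocv_prediction"),
        n_empty_folds=empty,
    )


def permutation_significance(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    observed_error: float | None = None,
) -> CvReport:
    """Label-permutation significance of the LOOCV error.

    p = (1 + #{permuted error <= observed error}) / (1 + n_perm) — the
    add-one estimator, so p is never zero and ties count in favour of the
    null.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-value resolution is coarse")
    labels = pd.Series(np.asarray(labels), index=matrix.columns)
    if observed_error is None:
        report = loocv(matrix, labels, alpha=alpha)
        observed_error = report.loocv_error
    else:
        report = CvReport(loocv_error=observed_error, predictions=pd.Series(dtype=object))
    rng = np.random.default_rng(seed)
    hits = 0
    lab_arr = labels.to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(lab_arr)
        err = loocv(matrix, pd.Series(perm, index=matrix.columns), alpha=alpha).loocv_error
        if err <= observed_error:
            hits += 1
    report.permutation_p = (1 + hits) / (1 + n_perm)
    report.n_label_permutations = n_perm
    return report
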