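"""Condition-comparison statistics and a pluggable detectability score.

Paired two-sided t tests at the 95% level compare feature values between
conditions; Shapiro-Wilk with sample skewness and excess kurtosis
(normal = 0 convention) characterises group distributions;
quantile-quantile pairs compare distributions; confusion-matrix ratios
summarise detection performance. `detectability_score` replaces a deep
classifier with a cross-validated linear discriminant over feature
columns — any object with fit/predict can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts", "paired_compare", "moments_and_normality",
    "confusion_metrics", "qq_points", "detectability_score",
    "compare_feature_tables",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def paired_compare(a, b) -> dict:
    """Paired two-sided t comparison of two matched samples.

    Returns group means +/- SD, the t statistic, p value and a flag for
    significance at the 95% level. A zero-variance difference is flagged
    `degenerate`; identical samples give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    row = {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "degenerate": False,
    }
    if np.all(diff == diff[0]):
        # constant difference: the t statistic is undefined (0/0 or +/-inf)
        row["degenerate"] = True
        if diff[0] == 0:
            row.update(test_statistic=0.0, p_value=1.0)
        else:
            row.update(test_statistic=float(np.sign(diff[0]) * np.inf),
                       p_value=0.0)
    else:
        t, p = sps.ttest_rel(a, b)
        row.update(test_statistic=float(t), p_value=float(p))
    row["significant_at_95"] = bool(row["p_value"] < 0.05)
    return row


def moments_and_normality(x) -> dict:
    """Sample excess kurtosis, skewness and a Shapiro-Wilk normality test.

    Both moments are bias-corrected; kurtosis uses the excess convention
    (normal distribution = 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]):
        raise ValueError("constant input has undefined moments")
    stat, p = sps.shapiro(x)
    return {
        "kurtosis": float(sps.kurtosis(x, fisher=True, bias=False)),
        "skewness": float(sps.skew(x, bias=False)),
        "statistic": float(stat),
        "p": float(p),
    }


def confusion_metrics(
    c: ConfusionCounts,
    metrics=("sensitivity", "specificity", "accuracy"),
) -> dict:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy.

    Only the requested metrics are computed; a zero denominator for a
    requested metric raises.
    """
    out = {}
    for name in metrics:
        if name == "sensitivity":
            den = c.tp + c.fn
        elif name == "specificity":
            den = c.tn + c.fp
        elif name == "accuracy":
            den = c.tp + c.fn + c.tn + c.fp
        else:
            raise ValueError(f"unknown metric {name!r}")
        if den == 0:
            raise ZeroDivisionError(f"{name} undefined: empty denominator")
        num = {"sensitivity": c.tp, "specificity": c.tn,
               "accuracy": c.tp + c.tn}[name]
        out[name] = num / den
    return out


def qq_points(a, b):
    """Matched empirical quantiles of two samples on a shared grid.

    The grid holds min(len(a), len(b)) plotting positions (i+0.5)/n; both
    coordinate sequences are monotone nondecreasing.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    n = min(a.size, b.size)
    probs = (np.arange(n) + 0.5) / n
    return np.quantile(a, probs), np.quantile(b, probs)


def detectability_score(features_rest, features_move, folds: int = 10,
                        seed: int = 0, classifier=None) -> dict:
    """Cross-validated rest-vs-movement detectability of feature vectors.

    A linear discriminant (or any supplied fit/predict classifier) is
    scored by stratified k-fold cross-validation; movement is the positive
    class. Deterministic given the seed.
    """
    X_rest = np.atleast_2d(np.asarray(features_rest, dtype=float))
    X_move = np.atleast_2d(np.asarray(features_move, dtype=float))
    if min(len(X_rest), len(X_move)) < max(10, folds):
        raise ValueError(
            f"need >= {max(10, folds)} examples per class, got "
            f"{len(X_rest)} rest / {len(X_move)} movement"
        )
    X = np.vstack([X_rest, X_move])
    y = np.r_[np.zeros(len(X_rest)), np.ones(len(X_move))]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fn = tn = fp = 0
    for train, test in skf.split(X, y):
        clf = classifier if classifier is not None \
            else LinearDiscriminantAnalysis()
        clf.fit(X[train], y[train])
        pred = np.asarray(clf.predict(X[test]))
        truth = y[test]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
    return confusion_metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))


def compare_feature_tables(df_a, df_b, label_a="a", label_b="b") -> dict:
    """Feature-by-feature paired comparison of two FeatureTables.

    Rows are paired by position (e.g. per-session datasets). Produces, per
    shared numeric column, the paired t row; per group, moments/normality
    when the sample allows it; and the Pearson correlation of the
    characteristic frequencies across bands when present.
    """
    report = {"groups": [label_a, label_b], "features": {}}
    shared = [c for c in df_a.columns if c in df_b.columns]
    for col in shared:
        a = np.asarray(df_a[col], dtype=float)
        b = np.asarray(df_b[col], dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            report["features"][col] = {"skipped": "fewer than 3 valid pairs"}
            continue
        entry = paired_compare(a[ok], b[ok])
        for label, x in ((label_a, a[ok]), (label_b, b[ok])):
            try:
                entry[f"normality_{label}"] = moments_and_normality(x)
            except ValueError:
                entry[f"normality_{label}"] = None
        report["features"][col] = entry
    cf_cols = [c for c in ("char_freq_alpha", "char_freq_beta")
               if c in shared]
    if cf_cols:
        a = np.concatenate([np.asarray(df_a[c], dtype=float)
                            for c in cf_cols])
        b = np.concatenate([np.asarray(df_b[c], dtype=float)
                            for c in cf_cols])
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
            r, p = sps.pearsonr(a[ok], b[ok])
            report["char_freq_correlation"] = {"r": float(r), "p": float(p)}
    return report
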