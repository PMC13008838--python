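"""Two-group statistics and the LDA genotype classifier.

The statistical battery gates each comparison on normality (Shapiro-Wilk,
alpha 0.05 per group) and variance homogeneity (median-centred Levene):
both pass -> independent-samples t-test, otherwise Mann-Whitney U; raw
p-values receive Bonferroni-Dunn correction for the size of the metric
family being scanned.

Classification is two-class linear discriminant analysis (SVD solver)
evaluated by leave-one-out cross-validation, reporting the confusion
matrix, macro-averaged F1 and the ROC-AUC of pooled held-out decision
scores.  Features are Z-scored on the full matrix before cross-validation
(the conventional protocol); a fold-safe variant standardizing inside each
training fold is available because the global variant leaks a small amount
of held-out information into the scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import f1_score, roc_auc_score

PRESET_B_BEHAVIORS = ("Running", "Trotting", "Walking", "Pausing")


@dataclass
class GroupComparison:
    metric_name: str
    test_used: str  # "t_test" or "mann_whitney_u"
    statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    significant: bool
    note: str = ""


@dataclass
class ClassifierReport:
    features_used: list[str]
    animals: list[str]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    decision_scores: np.ndarray
    confusion: pd.DataFrame
    macro_f1: float
    auc: float
    projection: np.ndarray  # full-data 1-D LDA coordinate per animal
    positive_class: str = ""


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(x) == 0:
        return False  # Shapiro-Wilk undefined for constant samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue > alpha


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_comparisons: int = 1,
    metric_name: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated two-group comparison with Bonferroni-Dunn correction.

    Both groups normal (Shapiro-Wilk) and variances homogeneous
    (median-centred Levene) -> two-sided independent t-test; otherwise
    two-sided Mann-Whitney U.  ``p_adjusted = min(1, n_comparisons * p_raw)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    note = ""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        note = "constant group; Shapiro-Wilk undefined, using Mann-Whitney U"
        normal = False
    else:
        normal = _is_normal(a, alpha) and _is_normal(b, alpha)
    if normal:
        homoscedastic = sps.levene(a, b, center="median").pvalue > alpha
    else:
        homoscedastic = False
    if normal and homoscedastic:
        res = sps.ttest_ind(a, b)
        test_used = "t_test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_used = "mann_whitney_u"
    p_raw = float(res.pvalue)
    p_adj = min(1.0, n_comparisons * p_raw)
    return GroupComparison(
        metric_name=metric_name,
        test_used=test_used,
        statistic=float(res.statistic),
        p_raw=p_raw,
        p_adjusted=p_adj,
        n_comparisons=n_comparisons,
        significant=p_adj < alpha,
        note=note,
    )


def compare_metric_family(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> list[GroupComparison]:
    """Compare every shared column of two per-animal metric tables; the
    Bonferroni-Dunn family size is the number of columns."""
    cols = [c for c in table_a.columns if c in table_b.columns]
    return [
        compare_groups(
            table_a[c].to_numpy(), table_b[c].to_numpy(),
            n_comparisons=len(cols), metric_name=str(c), alpha=alpha,
        )
        for c in cols
    ]


def zscore_features(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise Z-score with population SD; constant columns become zeros."""
    x = np.asarray(matrix, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant feature column(s) zeroed")
    sd = np.where(zero, 1.0, sd)
    z = (x - mu) / sd
    z[:, zero] = 0.0
    return z


def lda_loocv_classify(
    features: np.ndarray | pd.DataFrame,
    groups: np.ndarray,
    feature_names: list[str] | None = None,
    animals: list[str] | None = None,
    standardize: str = "global",
    cv: str = "loo",
    n_folds: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Two-class LDA with leave-one-out (or k-fold) cross-validation.

    Returns held-out predictions and continuous decision scores per animal,
    the 2x2 confusion matrix, macro-F1, the ROC-AUC of pooled scores, and a
    full-data 1-D discriminant projection for visualization.

    Class priors are fixed at 1/2 rather than estimated per training fold:
    the study design is balanced, and empirical fold priors would tilt every
    leave-one-out fold against the held-out animal, biasing pooled null
    scores pessimistically (null mean AUC well below 0.5).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(groups)
    n = len(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two groups required")
    if min((y == c).sum() for c in classes) < 4:
        raise ValueError("need at least 4 animals per group")
    if feature_names is None:
        feature_names = (
            list(features.columns)
            if isinstance(features, pd.DataFrame)
            else [f"f{i}" for i in range(x.shape[1])]
        )
    if animals is None:
        animals = [f"animal_{i}" for i in range(n)]

    if standardize == "global":
        xz = zscore_features(x)
    elif standardize == "per_fold":
        xz = x  # standardized inside each training fold below
    else:
        raise ValueError("standardize must be 'global' or 'per_fold'")

    if cv == "loo":
        folds = [([j for j in range(n) if j != i], [i]) for i in range(n)]
    elif cv == "kfold":
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [(list(tr), list(te)) for tr, te in skf.split(x, y)]
    else:
        raise ValueError("cv must be 'loo' or 'kfold'")

    positive = classes[1]
    preds = np.empty(n, dtype=object)
    scores = np.empty(n, dtype=float)
    for train, test in folds:
        xtr, xte = xz[train], xz[test]
        if standardize == "per_fold":
            mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            xtr, xte = (xtr - mu) / sd, (xte - mu) / sd
        clf = LinearDiscriminantAnalysis(solver="svd", priors=[0.5, 0.5])
        clf.fit(xtr, y[train])
        preds[test] = clf.predict(xte)
        # signed distance to the boundary, positive toward classes_[1]
        df = clf.decision_function(xte)
        sign = 1.0 if clf.classes_[1] == positive else -1.0
        scores[test] = sign * df

    y_bin = (y == positive).astype(int)
    confusion = pd.DataFrame(
        0, index=[f"true_{c}" for c in classes], columns=[f"pred_{c}" for c in classes]
    )
    for t, p in zip(y, preds):
        confusion.loc[f"true_{t}", f"pred_{p}"] += 1
    macro_f1 = float(f1_score(y.astype(str), preds.astype(str), average="macro"))
    auc = float(roc_auc_score(y_bin, scores))
    full = LinearDiscriminantAnalysis(solver="svd", priors=[0.5, 0.5]).fit(
        zscore_features(x) if standardize == "global" else x, y
    )
    projection = full.transform(zscore_features(x) if standardize == "global" else x)[:, 0]
    return ClassifierReport(
        features_used=list(feature_names),
        animals=list(animals),
        true_labels=y,
        predicted_labels=preds,
        decision_scores=scores,
        confusion=confusion,
        macro_f1=macro_f1,
        auc=auc,
        projection=projection,
        positive_class=str(positive),
    )


def classify_presets(
    count_matrix: pd.DataFrame,
    fraction_matrix: pd.DataFrame,
    groups: np.ndarray,
    **kwargs,
) -> dict[str, ClassifierReport]:
    """The two standard feature presets.

    ``counts13``: per-animal segment counts of all 13 behaviors.
    ``fractions4``: per-animal frame fractions of Running, Trotting,
    Walking and Pausing — the behaviors with the strongest group contrasts.
    """
    report_a = lda_loocv_classify(
        count_matrix, groups, feature_names=list(count_matrix.columns), **kwargs
    )
    sub = fraction_matrix[list(PRESET_B_BEHAVIORS)]
    report_b = lda_loocv_classify(
        sub, groups, feature_names=list(PRESET_B_BEHAVIORS), **kwargs
    )
    return {"counts13": report_a, "fractions4": report_b}


def null_family_significance_rate(
    n_families: int = 1000,
    n_per_group: int = 19,
    n_metrics: int = 13,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Family-wise and per-test false-positive rates under the null.

    Each family draws two groups of ``n_per_group`` animals for
    ``n_metrics`` metrics from identical standard-normal distributions, runs
    the gated battery with Bonferroni-Dunn correction, and records whether
    any adjusted p falls below alpha.  Returns (fraction of significant
    families, fraction of significant tests).
    """
    rng = np.random.default_rng(seed)
    fam_hits = 0
    test_hits = 0
    for _ in range(n_families):
        a = rng.standard_normal((n_per_group, n_metrics))
        b = rng.standard_normal((n_per_group, n_metrics))
        sig = [
            compare_groups(a[:, m], b[:, m], n_comparisons=n_metrics).significant
            for m in range(n_metrics)
        ]
        fam_hits += any(sig)
        test_hits += sum(sig)
    return fam_hits / n_families, test_hits / (n_families * n_metrics)
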