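"""Hold-out evaluation of the screening models.

Subjects are split 70/30 into training and test sets.  Each model is
trained on the training set (standardisation, penalty selection, refit),
its probability cut-point is fixed by the Youden index on the *training*
predictions, and discrimination (ROC-AUC, PR-AUC) plus the thresholded
operating characteristics (sensitivity, specificity, PPV, NPV) are
measured on the untouched test set.

Also provides the descriptive cohort machinery: per-group mean (SD) or
count (%) summaries with two-group comparisons (Welch t-test for
continuous variables; chi-squared, or Fisher's exact test when an expected
cell is below 5, for categorical ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .model import (
    FittedScreeningModel,
    ModelSpec,
    StandardizationParams,
    build_design,
    cv_select_lambda,
    finalize_model,
    predict_prob,
    standard_specs,
)

__all__ = [
    "SplitAssignment",
    "ConfusionCounts",
    "EvaluationReport",
    "CohortSummary",
    "AnalysisResult",
    "split_train_test",
    "roc_auc",
    "pr_auc",
    "youden_threshold",
    "confusion_metrics",
    "evaluate_scores",
    "cohort_summary",
    "group_compare",
    "run_full_analysis",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Random 70/30 partition of subject ids."""

    train_ids: tuple
    test_ids: tuple
    fraction: float
    seed: int


def split_train_test(ids, fraction: float = 0.7, seed: int = 0) -> SplitAssignment:
    """Simple random (unstratified) split; ``round(fraction * n)`` ids train."""
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 subjects to split, got {n}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ids[i] for i in sorted(perm[n_train:]))
    return SplitAssignment(train_ids=train, test_ids=test, fraction=fraction, seed=seed)


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isin(labels, [0.0, 1.0]).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all score thresholds and the trapezoidal AUC.

    The trapezoidal area equals the Mann-Whitney pair statistic with ties
    counted one half.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both outcome classes")
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def pr_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Precision-recall points and the average-precision area (step-wise sum,
    no linear interpolation of precision)."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("PR curve needs at least one positive")
    precision, recall, _ = skmetrics.precision_recall_curve(labels, scores)
    ap = float(skmetrics.average_precision_score(labels, scores))
    points = np.column_stack([recall[::-1], precision[::-1]])  # recall ascending
    return points, ap


def youden_threshold(scores, labels) -> float:
    """Cut-point maximising J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct sorted scores plus
    -inf/+inf sentinels; a subject is predicted positive iff
    ``score >= threshold``.  Ties in J are broken toward the lower
    threshold (higher sensitivity).
    """
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("Youden threshold needs both outcome classes")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    pred = scores[None, :] >= candidates[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    j = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    best = np.flatnonzero(j == j.max())[0]  # candidates ascending -> lowest wins
    return float(candidates[best])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class EvaluationReport:
    """Discrimination and thresholded operating characteristics on one dataset."""

    roc_points: np.ndarray
    pr_points: np.ndarray
    roc_auc: float
    pr_auc: float
    threshold: float
    se: float
    sp: float
    ppv: float
    npv: float
    confusion: ConfusionCounts

    def metrics_row(self) -> dict[str, float]:
        return {
            "roc_auc": self.roc_auc,
            "se_pct": self.se,
            "sp_pct": self.sp,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "pr_auc": self.pr_auc,
        }


def _ratio_pct(num: int, denom: int) -> float:
    # undefined ratios are NaN, never silently 0
    return 100.0 * num / denom if denom > 0 else float("nan")


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Confusion counts and Se/Sp/PPV/NPV (%) at ``score >= threshold``."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(scores) == 0:
        raise ValueError("empty input")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    return {
        "confusion": ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn),
        "se": _ratio_pct(tp, tp + fn),
        "sp": _ratio_pct(tn, tn + fp),
        "ppv": _ratio_pct(tp, tp + fp),
        "npv": _ratio_pct(tn, tn + fn),
    }


def evaluate_scores(scores, labels, threshold: float) -> EvaluationReport:
    """Full report: ROC/PR curves and AUCs plus thresholded metrics."""
    roc_points, roc_a = roc_auc(scores, labels)
    pr_points, pr_a = pr_auc(scores, labels)
    frag = confusion_metrics(scores, labels, threshold)
    return EvaluationReport(
        roc_points=roc_points,
        pr_points=pr_points,
        roc_auc=roc_a,
        pr_auc=pr_a,
        threshold=float(threshold),
        se=frag["se"],
        sp=frag["sp"],
        ppv=frag["ppv"],
        npv=frag["npv"],
        confusion=frag["confusion"],
    )


def group_compare(
    records: pd.DataFrame, variable: str, group_col: str = "group"
) -> tuple[float, float, str]:
    """Two-group comparison: Welch t-test (continuous) or chi-squared /
    Fisher's exact (categorical; Fisher when any expected cell < 5).

    Returns ``(statistic, p_value, test_name)``; Fisher's statistic is the
    sample odds ratio.
    """
    if variable not in records.columns:
        raise KeyError(f"unknown variable {variable!r}")
    groups = records[group_col]
    levels = np.sort(groups.unique())
    if len(levels) != 2:
        raise ValueError("group comparison needs exactly two outcome groups")
    col = records[variable]
    if _is_categorical(col):
        table = pd.crosstab(col, groups).to_numpy()
        expected = stats.contingency.expected_freq(table)
        # chi-squared requires every expected cell to exceed 5
        if table.shape == (2, 2) and (expected <= 5).any():
            stat, p = stats.fisher_exact(table, alternative="two-sided")
            return float(stat), float(p), "fisher"
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "chi2"
    a = col[groups == levels[0]].to_numpy(dtype=float)
    b = col[groups == levels[1]].to_numpy(dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError(f"variable {variable!r} is degenerate in both groups")
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p), "welch_t"


def _is_categorical(col: pd.Series) -> bool:
    if col.dtype == object or col.dtype == bool or isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        return True
    values = col.dropna().unique()
    return values.size > 0 and np.isin(values, [0, 1]).all()


@dataclass
class CohortSummary:
    """Two-group descriptive table with overall column and group comparisons."""

    table: pd.DataFrame
    group_n: dict
    n: int

    @property
    def prevalence_pct(self) -> float:
        """Percent of subjects in the positive (label 1) group."""
        return 100.0 * self.group_n.get(1, 0) / self.n

    def overall_mean(self, variable: str) -> float:
        return float(self.table.loc[variable, "overall_mean"])

    def overall_pct(self, variable: str) -> float:
        return float(self.table.loc[variable, "overall_pct"])

    def group_pct(self, variable: str, group) -> float:
        return float(self.table.loc[variable, f"group{group}_pct"])


def cohort_summary(
    records: pd.DataFrame, variables, group_col: str = "group"
) -> CohortSummary:
    """Per-group mean (SD) for continuous variables, count (%) for
    categorical ones, with overall values and comparison p-values.

    Overall means are group-size-weighted combinations; overall percentages
    use the total n as denominator.  Comparison tests that cannot run
    (degenerate variables) leave NaN p-values.
    """
    groups = records[group_col]
    levels = np.sort(groups.unique())
    counts = {int(g): int((groups == g).sum()) for g in levels}
    n = len(records)
    rows = []
    for variable in variables:
        if variable not in records.columns:
            raise KeyError(f"unknown variable {variable!r}")
        col = records[variable]
        row: dict = {"variable": variable}
        if _is_categorical(col):
            row["kind"] = "categorical"
            ind = _positive_indicator(col)
            total = int(ind.sum())
            for g in levels:
                cnt = int(ind[groups == g].sum())
                row[f"group{int(g)}_count"] = cnt
                row[f"group{int(g)}_pct"] = _ratio_pct(cnt, counts[int(g)])
            row["overall_count"] = total
            row["overall_pct"] = _ratio_pct(total, n)
        else:
            row["kind"] = "continuous"
            means = {}
            for g in levels:
                vals = col[groups == g].to_numpy(dtype=float)
                means[int(g)] = vals.mean()
                row[f"group{int(g)}_mean"] = vals.mean()
                row[f"group{int(g)}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row["overall_mean"] = sum(
                counts[g] * means[g] for g in counts
            ) / n
            row["overall_sd"] = col.to_numpy(dtype=float).std(ddof=1)
        try:
            stat, p, test = group_compare(records, variable, group_col)
        except ValueError:
            stat, p, test = float("nan"), float("nan"), "none"
        row.update({"statistic": stat, "p_value": p, "test": test})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variable")
    return CohortSummary(table=table, group_n=counts, n=n)


def _positive_indicator(col: pd.Series) -> np.ndarray:
    """Map a categorical column to a 0/1 'positive level' indicator.

    Binary numeric/bool columns use level 1/True; string columns with two
    levels use the lexicographically later level (e.g. 'male' vs 'female'
    counts males — pass explicit indicators to control the level)."""
    if col.dtype == bool:
        return col.to_numpy(dtype=float)
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        if len(levels) > 2:
            raise ValueError(
                f"multi-level variable {col.name!r}: summarise one indicator at a time"
            )
        return (col.astype(str) == levels[-1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


@dataclass
class AnalysisResult:
    """Everything one seeded end-to-end run produces."""

    split: SplitAssignment
    models: dict[str, FittedScreeningModel]
    reports: dict[str, EvaluationReport]
    metrics_table: pd.DataFrame
    summary: CohortSummary | None
    seed: int


_SUMMARY_VARIABLES = ("age", "bmi", "median_pixel", "iqr_pixel", "fast_density")


def run_full_analysis(
    records: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    seed: int = 0,
    fraction: float = 0.7,
    folds: int = 10,
    threshold_on: str = "train",
) -> AnalysisResult:
    """One seeded split; per model: standardise on train, CV-select the
    penalty, refit, fix the Youden cut-point, measure everything on test.

    ``threshold_on="test"`` derives the cut-point from test predictions
    instead — this leaks the test labels into the threshold and is offered
    for sensitivity checks only.
    """
    if threshold_on not in ("train", "test"):
        raise ValueError("threshold_on must be 'train' or 'test'")
    if specs is None:
        specs = standard_specs()
    records = records.reset_index(drop=True)
    ids = (
        records["subject_id"].tolist()
        if "subject_id" in records.columns
        else list(records.index)
    )
    split = split_train_test(ids, fraction=fraction, seed=seed)
    id_col = records["subject_id"] if "subject_id" in records.columns else records.index
    train_mask = id_col.isin(split.train_ids).to_numpy()
    train = records[train_mask]
    test = records[~train_mask]

    models: dict[str, FittedScreeningModel] = {}
    reports: dict[str, EvaluationReport] = {}
    rows = []
    for spec in specs:
        X_train, y_train, columns = build_design(train, spec)
        standardization = StandardizationParams.fit(X_train, columns)
        Xs = standardization.transform(X_train, columns)
        lam = cv_select_lambda(Xs, y_train, folds=folds, seed=seed)
        fitted = finalize_model(
            Xs, y_train, spec, lam, standardization, columns=columns, seed=seed
        )
        p_train = predict_prob(fitted, train)
        p_test = predict_prob(fitted, test)
        y_test = test["outcome" if "outcome" in test.columns else "group"].to_numpy(
            dtype=float
        )
        thr_scores, thr_labels = (
            (p_train, y_train) if threshold_on == "train" else (p_test, y_test)
        )
        fitted.threshold = youden_threshold(thr_scores, thr_labels)
        report = evaluate_scores(p_test, y_test, fitted.threshold)
        models[spec.name] = fitted
        reports[spec.name] = report
        rows.append({"model": spec.name, **report.metrics_row()})

    metrics_table = pd.DataFrame(rows).set_index("model")
    present = [v for v in _SUMMARY_VARIABLES if v in records.columns]
    outcome_col = "group" if "group" in records.columns else "outcome"
    summary = (
        cohort_summary(records, present, group_col=outcome_col) if present else None
    )
    return AnalysisResult(
        split=split,
        models=models,
        reports=reports,
        metrics_table=metrics_table,
        summary=summary,
        seed=seed,
    )
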