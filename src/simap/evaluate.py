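"""Cross-assay agreement, external-score rescaling, pathogenicity models.

LoF scores from different assays (mini-array, liquid growth, external
fitness metrics rescaled onto the same 0=wt / 1=null scale) are aligned by
variant and compared with pairwise-complete Pearson correlation.  A
logistic-regression classifier per sentinel predicts the binary
pathogenicity label from the LoF score; performance is reported from the
confusion counts on a stratified 70-30 held-out split with the standard
identities

    accuracy    = (TP+TN)/(TP+TN+FP+FN)
    precision   = TP/(TP+FP)
    sensitivity = TP/(TP+FN)
    F1          = 2TP/(2TP+FP+FN)

plus the mean accuracy of a stratified fivefold cross-validation on the
full labeled set.  Undefined metrics (zero denominators) are reported as
NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .errors import ConfigurationError, SchemaError


def align_scores(
    tables: Sequence[pd.DataFrame],
    assay_ids: Sequence[str],
    how: str = "inner",
    exclude: Sequence[str] = ("wt", "vector"),
) -> pd.DataFrame:
    """Variant x assay matrix of LoF scores.

    Each input table needs ``variant_id`` and ``lof`` columns with one row
    per variant.  ``inner`` keeps complete cases only; ``outer`` keeps all
    variants with missing cells as NaN.  Reserved control rows are dropped.
    """
    if len(tables) != len(assay_ids):
        raise ConfigurationError("one assay id per table required")
    if how not in ("inner", "outer"):
        raise ConfigurationError(f"how must be inner/outer, got {how!r}")
    columns = []
    for table, assay in zip(tables, assay_ids):
        sub = table[~table["variant_id"].isin(exclude)]
        if sub["variant_id"].duplicated().any():
            dups = sub.loc[sub["variant_id"].duplicated(), "variant_id"].tolist()[:5]
            raise SchemaError(f"assay {assay!r}: duplicate variant(s) {dups}")
        columns.append(sub.set_index("variant_id")["lof"].rename(assay))
    return pd.concat(columns, axis=1, join=how).rename_axis("variant_id")


def pearson_matrix(matrix: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations; symmetric, unit diagonal.

    Cells with fewer than ``min_pairs`` complete pairs, or with a
    zero-variance column, are undefined (NaN).
    """
    corr = matrix.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def rescale_external_fitness(scores, anchors: tuple[float, float]) -> np.ndarray:
    """Affine map sending the wt-like anchor to 0 and the null anchor to 1.

    External fitness metrics use arbitrary scales; two anchor values (the
    metric's value for wt-like and for null alleles) define the unique
    affine transform onto the LoF scale.  No clipping is applied.
    """
    wt_like, null = anchors
    if wt_like == null:
        raise ConfigurationError("anchors must be distinct")
    return (np.asarray(scores, dtype=float) - wt_like) / (null - wt_like)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and the metrics printed from them."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    cv_accuracy: float
    split_seed: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int,
                    cv_accuracy: float = math.nan,
                    split_seed: int = -1) -> "ClassificationReport":
        total = tp + tn + fp + fn
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            accuracy=(tp + tn) / total if total else math.nan,
            precision=tp / (tp + fp) if (tp + fp) else math.nan,
            sensitivity=tp / (tp + fn) if (tp + fn) else math.nan,
            f1=2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else math.nan,
            cv_accuracy=cv_accuracy, split_seed=split_seed)


def train_pathogenicity_model(
    features,
    labels,
    split: float = 0.7,
    seed: int = 0,
    folds: int = 5,
    C: float = 1.0,
) -> ClassificationReport:
    """Logistic regression from LoF score(s) to the pathogenicity label.

    The labeled set is split 70-30 (stratified by class); confusion counts
    come from the held-out 30% and the printed-formula metrics from those
    counts.  ``cv_accuracy`` is the mean accuracy of a stratified fivefold
    cross-validation on the full labeled set.  Rows with missing labels
    (uncertain/conflicting annotations) must be excluded by the caller or
    passed as NaN, in which case they are dropped here.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y_raw = np.asarray(labels, dtype=float)
    keep = ~np.isnan(y_raw) & ~np.isnan(X).any(axis=1)
    X, y = X[keep], y_raw[keep].astype(int)
    if len(y) < 10:
        raise ConfigurationError(f"only {len(y)} labeled variants; need >= 10")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("labels contain a single class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed)
    if len(np.unique(y_tr)) < 2:
        raise ConfigurationError("training split contains a single class")
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000, random_state=seed)
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    tn = int(np.sum((pred == 0) & (y_te == 0)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    cv = cross_val_score(
        LogisticRegression(C=C, solver="lbfgs", max_iter=1000, random_state=seed),
        X, y, scoring="accuracy",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed))
    return ClassificationReport.from_counts(
        tp, fp, tn, fn, cv_accuracy=float(cv.mean()), split_seed=seed)


def recovery_report(
    estimated: pd.DataFrame,
    truth: pd.DataFrame,
) -> dict:
    """Compare estimated LoF scores with the planted truth (lof_true = 1 - f).

    ``estimated`` needs (variant_id, lof); ``truth`` needs (variant_id, f).
    Reports overall RMSE, bias (mean estimated - true) and Pearson r, plus
    the same per truth class (lof / partial / wtlike / gof).
    """
    est = estimated[["variant_id", "lof"]].copy()
    tru = truth[["variant_id", "f"]].copy()
    missing = sorted(set(est["variant_id"]) - set(tru["variant_id"]))
    if missing:
        raise SchemaError(f"truth missing variant(s) {missing[:8]}")
    merged = est.merge(tru, on="variant_id")
    merged["lof_true"] = 1.0 - merged["f"]
    err = merged["lof"] - merged["lof_true"]

    def _summary(sub_err: pd.Series, sub: pd.DataFrame) -> dict:
        if len(sub_err) == 0:
            return {"n": 0, "rmse": math.nan, "bias": math.nan, "pearson_r": math.nan}
        r = (float(np.corrcoef(sub["lof"], sub["lof_true"])[0, 1])
             if len(sub) >= 3 and sub["lof_true"].nunique() > 1
             and sub["lof"].nunique() > 1 else math.nan)
        return {"n": int(len(sub_err)),
                "rmse": float(np.sqrt(np.mean(sub_err ** 2))),
                "bias": float(sub_err.mean()),
                "pearson_r": r}

    report = {"overall": _summary(err, merged), "per_class": {}}
    classes = {
        "lof": merged["f"] == 0,
        "partial": (merged["f"] > 0) & (merged["f"] < 1),
        "wtlike": merged["f"] == 1,
        "gof": merged["f"] > 1,
    }
    for name, mask in classes.items():
        report["per_class"][name] = _summary(err[mask], merged[mask])
    return report
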