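"""Utility-evaluation suite comparing real and synthetic cohorts.

Covers the standard battery for synthetic clinical data: pairwise Pearson
correlation structure and its cross-cohort Spearman similarity, per-arm
summary statistics, a clinical-process statistic (how often a medication is
added when a participant is above their arm's blood-pressure goal), a
train-on-synthetic/test-on-real (TSTR) transfer-learning comparison across
four classifier families, concordance of fitted coefficients/importances,
and a Mann-Whitney comparison of reviewer scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cohort import ARMS, Cohort, normalize

__all__ = [
    "EvaluationReport",
    "pairwise_pearson",
    "structure_similarity",
    "summary_stats",
    "med_addition_rate",
    "transfer_learning_eval",
    "coefficient_concordance",
    "score_comparison",
    "evaluate_cohorts",
]

#: Arm-specific systolic goals (mmHg) used by the medication-addition statistic.
DEFAULT_GOALS = {"standard": 140.0, "intensive": 120.0}

CLASSIFIERS = ("logistic_regression", "svm", "random_forest", "nearest_neighbors")


def pairwise_pearson(cohort: Cohort) -> np.ndarray:
    """Pairwise Pearson correlation between the cohort's feature columns.

    Columns are variable-major (all visits of SBP, then DBP, then the
    medication count), matching the layout of the correlation heatmaps.
    Zero-variance columns get correlation 0 off-diagonal, with a warning.
    """
    X = cohort.feature_matrix()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    sd = X.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        warnings.warn(f"{flat.size} zero-variance column(s); correlations set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(X, rowvar=False)
    mat = np.nan_to_num(mat, nan=0.0)
    np.fill_diagonal(mat, 1.0)
    return mat


def structure_similarity(mat_a: np.ndarray, mat_b: np.ndarray) -> tuple[float, float]:
    """Spearman correlation between two correlation structures.

    Compares the strictly-lower-triangle entries (diagonal excluded) of the
    two matrices; returns (rho, p).
    """
    mat_a, mat_b = np.asarray(mat_a), np.asarray(mat_b)
    if mat_a.shape != mat_b.shape:
        raise ValueError(f"shape mismatch: {mat_a.shape} vs {mat_b.shape}")
    idx = np.tril_indices_from(mat_a, k=-1)
    rho, p = stats.spearmanr(mat_a[idx], mat_b[idx])
    return float(rho), float(p)


def summary_stats(cohort: Cohort) -> pd.DataFrame:
    """Per-arm, per-visit, per-variable mean and SD table.

    Returns a DataFrame indexed by (arm, visit, variable) with columns
    ``mean`` and ``sd`` (sample SD, ddof=1).  Empty arms are omitted with a
    warning.
    """
    schema = cohort.schema
    vals = cohort.values()
    arm_idx = cohort.arms
    rows = []
    for a, arm in enumerate(ARMS):
        mask = arm_idx == a
        if not mask.any():
            warnings.warn(f"arm {arm!r} is empty; omitted from summary", stacklevel=2)
            continue
        sub = vals[mask]
        for i, visit in enumerate(schema.schedule):
            for j, var in enumerate(schema.variables):
                col = sub[:, i, j]
                rows.append(
                    {
                        "arm": arm,
                        "visit": visit,
                        "variable": var,
                        "mean": float(col.mean()),
                        "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                    }
                )
    return pd.DataFrame(rows).set_index(["arm", "visit", "variable"])


def med_addition_rate(
    cohort: Cohort, goals: Mapping[str, float] = DEFAULT_GOALS
) -> dict[str, float | None]:
    """Proportion of above-goal visit transitions followed by a medication addition.

    Over all transitions t -> t+1: the denominator counts transitions where
    SBP_t exceeds the arm's goal; the numerator counts those where the
    medication count increased.  Returns pooled and per-arm rates; an empty
    denominator yields None (undefined), never 0.
    """
    schema = cohort.schema
    if schema.n_visits < 2:
        raise ValueError("need at least 2 visits to observe transitions")
    sbp_col = schema.variables.index("SBP")
    med_col = schema.variables.index("MED")
    vals = cohort.values()
    arm_idx = cohort.arms

    out: dict[str, float | None] = {}
    num_all = den_all = 0
    for a, arm in enumerate(ARMS):
        sub = vals[arm_idx == a]
        if sub.size == 0:
            out[arm] = None
            continue
        sbp, med = sub[:, :, sbp_col], sub[:, :, med_col]
        above = sbp[:, :-1] > goals[arm]
        added = med[:, 1:] > med[:, :-1]
        den = int(above.sum())
        num = int((above & added).sum())
        out[arm] = (num / den) if den else None
        num_all += num
        den_all += den
    out["overall"] = (num_all / den_all) if den_all else None
    return out


def _make_classifier(name: str, seed: int):
    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "svm":
        return SVC(kernel="linear", random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "nearest_neighbors":
        return KNeighborsClassifier()
    raise ValueError(f"unknown classifier {name!r}")


def transfer_learning_eval(
    train_cohort: Cohort,
    test_cohort: Cohort,
    model_names: Sequence[str] = CLASSIFIERS,
    seed: int = 0,
) -> dict[str, dict]:
    """Train arm classifiers on one cohort, evaluate AUROC on a real test cohort.

    Features are the normalized flattened visit-by-variable values, so
    coefficient vectors are comparable across training sources.  Returns,
    per model, the AUROC on the test set plus the coefficient vector
    (linear models) or feature importances (random forest).
    """
    y_train = train_cohort.arms
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    X_train = normalize(train_cohort)
    X_test = normalize(test_cohort)
    y_test = test_cohort.arms

    results: dict[str, dict] = {}
    for name in model_names:
        clf = _make_classifier(name, seed)
        clf.fit(X_train, y_train)
        if hasattr(clf, "decision_function"):
            scores = clf.decision_function(X_test)
        else:
            scores = clf.predict_proba(X_test)[:, 1]
        auroc = float(roc_auc_score(y_test, scores))
        if hasattr(clf, "coef_"):
            weights = np.asarray(clf.coef_).ravel().tolist()
        elif hasattr(clf, "feature_importances_"):
            weights = np.asarray(clf.feature_importances_).tolist()
        else:
            weights = None
        results[name] = {"auroc": auroc, "weights": weights}
    return results


def coefficient_concordance(
    vec_real: Sequence[float], vec_synthetic: Sequence[float]
) -> dict[str, float]:
    """Pearson and Spearman correlation between two coefficient/importance vectors."""
    a = np.asarray(vec_real, dtype=float)
    b = np.asarray(vec_synthetic, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    pr, pp = stats.pearsonr(a, b)
    sr, sp = stats.spearmanr(a, b)
    return {"pearson_r": float(pr), "pearson_p": float(pp),
            "spearman_rho": float(sr), "spearman_p": float(sp)}


def score_comparison(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (first sample) with two-sided p.

    Exact enumeration for small samples without ties; otherwise the normal
    approximation with tie correction (scipy's automatic policy).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("score lists must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Bundled report


@dataclass
class EvaluationReport:
    """Everything the evaluation suite computes for one real/synthetic pair."""

    correlation_real: list = field(default_factory=list)
    correlation_synthetic: list = field(default_factory=list)
    structure_spearman_rho: float = float("nan")
    structure_spearman_p: float = float("nan")
    summary_real: dict = field(default_factory=dict)
    summary_synthetic: dict = field(default_factory=dict)
    med_addition_real: dict = field(default_factory=dict)
    med_addition_synthetic: dict = field(default_factory=dict)
    transfer_real: dict = field(default_factory=dict)
    transfer_synthetic: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


def _summary_as_dict(table: pd.DataFrame) -> dict:
    return {
        "|".join(map(str, key)): {"mean": row["mean"], "sd": row["sd"]}
        for key, row in table.iterrows()
    }


def evaluate_cohorts(
    real_train: Cohort,
    real_test: Cohort,
    synthetic: Cohort,
    seed: int = 0,
) -> EvaluationReport:
    """Run the full suite: correlation structure, summaries, medication-addition
    rates, TSTR transfer learning and coefficient concordance."""
    corr_real = pairwise_pearson(real_train)
    corr_syn = pairwise_pearson(synthetic)
    rho, p = structure_similarity(corr_real, corr_syn)

    transfer_real = transfer_learning_eval(real_train, real_test, seed=seed)
    transfer_syn = transfer_learning_eval(synthetic, real_test, seed=seed)
    concordance = {
        name: coefficient_concordance(
            transfer_real[name]["weights"], transfer_syn[name]["weights"]
        )
        for name in transfer_real
        if transfer_real[name]["weights"] is not None
        and transfer_syn[name]["weights"] is not None
    }

    return EvaluationReport(
        correlation_real=corr_real.tolist(),
        correlation_synthetic=corr_syn.tolist(),
        structure_spearman_rho=rho,
        structure_spearman_p=p,
        summary_real=_summary_as_dict(summary_stats(real_train)),
        summary_synthetic=_summary_as_dict(summary_stats(synthetic)),
        med_addition_real=med_addition_rate(real_train),
        med_addition_synthetic=med_addition_rate(synthetic),
        transfer_real=transfer_real,
        transfer_synthetic=transfer_syn,
        concordance=concordance,
    )
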