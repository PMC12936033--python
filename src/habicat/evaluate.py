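"""Classifier evaluation: ROC/AUC, DeLong machinery, operating-point
metrics, exact linear SHAP attributions, and the clinical Spearman screen.

AUC uses the Mann-Whitney estimator (ties count 1/2); variances,
confidence intervals and paired comparisons come from the DeLong
structural-components estimator; balanced accuracy is the mean of
sensitivity and specificity.  SHAP values are computed exactly for the
linear-logistic models: phi_j(x) = coef_j (x_j - mean_j) in log-odds
space, which sums with the base value to the model's log-odds.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import TrainedClassifier, TwoStepResult


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-subject DeLong structural components (V10 for positives,
    V01 for negatives) and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n  # one per positive
    v01 = 1.0 - (tz[m:] - ty) / m  # one per negative
    auc = float(v10.mean())
    return v10, v01, auc


@dataclass(frozen=True)
class DeLongResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    auc_b: float | None = None
    delta_auc: float | None = None
    p_value: float | None = None


def delong(
    scores_a: np.ndarray,
    scores_b: np.ndarray | None,
    labels: np.ndarray,
    alpha: float = 0.95,
) -> DeLongResult:
    """DeLong variance/CI for one AUC, and the paired two-sided test
    between two score vectors on the same subjects when ``scores_b`` is
    given.  CI bounds are clipped to [0, 1]; a degenerate variance (e.g.
    AUC = 1 with tiny n) yields p = NaN with a warning.
    """
    labels = _check_binary(labels)
    z_crit = stats.norm.ppf(0.5 + alpha / 2)
    v10_a, v01_a, auc_a = _structural_components(np.asarray(scores_a), labels)
    m, n = len(v10_a), len(v01_a)
    var_a = (
        (np.var(v10_a, ddof=1) if m > 1 else 0.0) / m
        + (np.var(v01_a, ddof=1) if n > 1 else 0.0) / n
    )
    se_a = np.sqrt(var_a)
    ci = (
        float(np.clip(auc_a - z_crit * se_a, 0, 1)),
        float(np.clip(auc_a + z_crit * se_a, 0, 1)),
    )
    if scores_b is None:
        return DeLongResult(auc_a, float(var_a), *ci)

    v10_b, v01_b, auc_b = _structural_components(np.asarray(scores_b), labels)
    delta = auc_a - auc_b
    cov10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    cov01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_delta = (
        (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m
        + (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    )
    if var_delta <= 0:
        if abs(delta) < 1e-12:
            p = 1.0  # identical scores: no evidence of a difference
        else:
            warnings.warn(
                "degenerate DeLong variance; p-value undefined", stacklevel=2
            )
            p = float("nan")
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(
        auc_a, float(var_a), *ci, auc_b=auc_b, delta_auc=float(delta), p_value=p
    )


def operating_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """Sensitivity, specificity, and balanced accuracy at a threshold.

    The threshold must come from training data; BACC = (SENS + SPEC)/2.
    """
    labels = _check_binary(labels)
    pred = np.asarray(scores) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {"SENS": sens, "SPEC": spec, "BACC": (sens + spec) / 2}


def shap_linear(
    classifier: TrainedClassifier, table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact SHAP attributions of a linear-logistic classifier.

    Returns (per-row contributions phi, summary).  phi_j(x) =
    coef_j (z_j - mean_j) with the mean over the analyzed rows, so
    base + sum_j phi_j equals the model log-odds exactly.  The summary
    ranks features by mean |phi| and reports the signed spread.
    """
    z = classifier.preprocessor.transform(table)[classifier.selected_features]
    zv = z.to_numpy()
    mean = zv.mean(axis=0)
    phi = (zv - mean) * classifier.coef[None, :]
    contrib = pd.DataFrame(
        phi, columns=classifier.selected_features, index=table.index
    )
    contrib.attrs["base_value"] = float(
        classifier.intercept + classifier.coef @ mean
    )
    summary = (
        pd.DataFrame(
            {
                "feature": classifier.selected_features,
                "mean_abs_shap": np.abs(phi).mean(axis=0),
                "shap_min": phi.min(axis=0),
                "shap_max": phi.max(axis=0),
            }
        )
        .sort_values("mean_abs_shap", ascending=False)
        .reset_index(drop=True)
    )
    return contrib, summary


def clinical_spearman(
    clinical: pd.DataFrame, grades: np.ndarray
) -> pd.DataFrame:
    """Spearman rank correlation (tie-corrected p) of each clinical
    feature with pathological grade."""
    rows = []
    for col in clinical.columns:
        rho, p = stats.spearmanr(clinical[col], grades)
        rows.append({"feature": col, "rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(rows)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (0.005 -> 0.01)."""
    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass
class EvaluationReport:
    """Per-classifier metrics and the pairwise DeLong p-value matrix."""

    metrics: pd.DataFrame  # model, classifier, split, AUC, CI, SENS, SPEC, BACC
    delong_matrices: dict[str, pd.DataFrame]  # model -> classifiers x classifiers

    def rounded(self) -> pd.DataFrame:
        out = self.metrics.copy()
        for col in ("AUC", "CI_low", "CI_high", "SENS", "SPEC", "BACC"):
            out[col] = out[col].map(lambda v: round_half_up(v, 2))
        return out


def evaluate_two_step(
    result: TwoStepResult, table: pd.DataFrame
) -> EvaluationReport:
    """Score every trained classifier on its model's train and test split."""
    table = table.set_index("subject_id")
    rows = []
    matrices: dict[str, pd.DataFrame] = {}
    for model, clfs in result.classifiers.items():
        split = result.splits[model]
        labels = result.labels[model]
        test_scores: dict[str, np.ndarray] = {}
        for split_name, ids in (("train", split.train_ids),
                                ("test", split.test_ids)):
            sub = table.loc[list(ids)]
            y = labels.loc[list(ids)].to_numpy()
            for name, clf in clfs.items():
                probs, _ = clf.predict(sub)
                dl = delong(probs, None, y)
                om = operating_metrics(probs, y, clf.threshold)
                rows.append(
                    {
                        "model": model,
                        "classifier": name,
                        "split": split_name,
                        "AUC": dl.auc,
                        "CI_low": dl.ci_low,
                        "CI_high": dl.ci_high,
                        **om,
                    }
                )
                if split_name == "test":
                    test_scores[name] = probs
        names = list(clfs)
        y_test = labels.loc[list(split.test_ids)].to_numpy()
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j <= i:
                    continue
                p = delong(test_scores[a], test_scores[b], y_test).p_value
                mat.loc[a, b] = mat.loc[b, a] = p
        matrices[model] = mat
    return EvaluationReport(metrics=pd.DataFrame(rows), delong_matrices=matrices)
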