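"""Two-step grade classifiers: preprocessing, SMOTE, mRMR + LASSO
feature selection, and logistic regression.

Model-1 separates grade 3 from grades 1-2; Model-2 separates grade 1
from grade 2 on the G1/G2 subset.  For each model four classifiers are
trained on different feature groups: whole-volume radiomics (Clf_WVOI),
habitat radiomics (Clf_Habitats, habitat-1 + habitat-2 columns), the 13
clinical features (Clf_Clinical), and the union of the optimal features
selected by those three (Clf_Total).  Per classifier the pipeline is
outlier clipping + z-scoring (fitted on train), SMOTE balancing of the
training data, mRMR filtering, LASSO-logistic selection with
cross-validated penalty, and a final ridge-stabilized logistic fit; the
decision threshold is Youden's J on the training ROC.  Nothing is ever
fitted on test rows.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .phantom import CLINICAL_SPEC

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS: tuple[str, ...] = tuple(CLINICAL_SPEC)


# ---------------------------------------------------------------------------
# Split

@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple
    test_ids: tuple
    ratio: float
    folds: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def make_split(
    ids: np.ndarray,
    labels: np.ndarray,
    ratio: float = 0.7,
    folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/test split of subject ids (train fraction ``ratio``)."""
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1); an empty test set is not allowed")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to stratify")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    train, test = train_test_split(
        np.asarray(ids),
        train_size=ratio,
        stratify=labels,
        random_state=seed,
    )
    return SplitPlan(tuple(train), tuple(test), ratio, folds, seed)


# ---------------------------------------------------------------------------
# Preprocessing: IQR outlier clipping + z-scoring

@dataclass
class Preprocessor:
    features: list[str]
    clip_low: np.ndarray
    clip_high: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        x = table[self.features].to_numpy(dtype=np.float64)
        x = np.clip(x, self.clip_low, self.clip_high)
        x = (x - self.mean) / self.sd
        return pd.DataFrame(x, columns=self.features, index=table.index)


def preprocess_fit(table: pd.DataFrame, features: list[str]) -> Preprocessor:
    """Fit clipping fences [Q1 - 3 IQR, Q3 + 3 IQR] and z-score parameters.

    Zero-SD (post-clip constant) features are dropped with a log entry.
    """
    x = table[features].to_numpy(dtype=np.float64)
    q1, q3 = np.percentile(x, [25, 75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
    xc = np.clip(x, lo, hi)
    mean, sd = xc.mean(axis=0), xc.std(axis=0)
    keep = sd > 0
    dropped = [f for f, k in zip(features, keep) if not k]
    if dropped:
        logger.info("dropped %d zero-variance feature(s): %s",
                    len(dropped), dropped[:5])
    kept = [f for f, k in zip(features, keep) if k]
    return Preprocessor(
        features=kept,
        clip_low=lo[keep],
        clip_high=hi[keep],
        mean=mean[keep],
        sd=sd[keep],
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# SMOTE

def smote(
    x: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary problem by synthetic minority over-sampling.

    Each synthetic sample is x_i + u (x_nn - x_i) with u ~ Uniform(0,1)
    and x_nn one of the k nearest minority neighbors of x_i.  Returns the
    augmented (x, y) with classes exactly balanced.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects a binary label")
    if counts[0] == counts[1]:
        return x, y
    minority = classes[np.argmin(counts)]
    x_min = x[y == minority]
    n_syn = int(abs(counts[0] - counts[1]))
    k = k_neighbors
    if len(x_min) <= k:
        k = len(x_min) - 1
        warnings.warn(
            f"minority count {len(x_min)} <= k_neighbors; reducing k to {k}",
            stacklevel=2,
        )
    if k < 1:
        raise ValueError("minority class too small for SMOTE (needs >= 2)")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    _, idx = nn.kneighbors(x_min)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(x_min), size=n_syn)
    pick = rng.integers(1, k + 1, size=n_syn)  # skip self at column 0
    u = rng.uniform(size=n_syn)[:, None]
    neigh = x_min[idx[base, pick]]
    synth = x_min[base] + u * (neigh - x_min[base])
    return (
        np.vstack([x, synth]),
        np.concatenate([y, np.full(n_syn, minority, dtype=y.dtype)]),
    )


# ---------------------------------------------------------------------------
# mRMR

def mrmr_select(
    x: pd.DataFrame, y: np.ndarray, m: int
) -> list[str]:
    """Greedy max-relevance / min-redundancy ranking (quotient scheme).

    Relevance is the ANOVA F statistic of feature vs label; redundancy
    the mean absolute Pearson correlation with already-selected features;
    the next pick maximizes relevance / redundancy.  Deterministic; ties
    break by column order.
    """
    features = list(x.columns)
    if m > len(features):
        raise ValueError(f"m={m} exceeds the {len(features)} features")
    xv = x.to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(xv, y)
    relevance = np.nan_to_num(f_stat, nan=0.0, posinf=0.0)
    sd = xv.std(axis=0)
    xs = (xv - xv.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = len(xv)

    selected: list[int] = []
    redundancy_sum = np.zeros(len(features))
    candidates = np.ones(len(features), dtype=bool)
    for _ in range(m):
        if selected:
            red = np.maximum(redundancy_sum / len(selected), 1e-12)
            score = relevance / red
        else:
            score = relevance.copy()
        score[~candidates] = -np.inf
        best = int(np.argmax(score))  # argmax takes first max: column order
        selected.append(best)
        candidates[best] = False
        corr = np.abs(xs.T @ xs[:, best]) / n
        redundancy_sum += np.nan_to_num(corr, nan=0.0)
    return [features[i] for i in selected]


# ---------------------------------------------------------------------------
# LASSO-logistic selection

@dataclass(frozen=True)
class ModelSettings:
    """Hyperparameters of the per-classifier training pipeline."""

    ratio: float = 0.7
    folds: int = 5
    smote_k: int = 5
    mrmr_m: int = 30
    lasso_cs: tuple[float, ...] = tuple(np.logspace(-2, 2, 10))
    lr_cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    smote_in_folds: bool = True
    refit_total_with_lasso: bool = False


def _cv_log_loss(
    x: np.ndarray,
    y: np.ndarray,
    c: float,
    l1_ratio: float,
    folds: int,
    seed: int,
    smote_k: int,
    smote_in_folds: bool,
) -> float:
    """Mean validation log-loss of a penalized logistic fit (l1_ratio 1 =
    lasso, 0 = ridge); SMOTE is applied
    inside each training fold only, so validation rows stay untouched.
    The fold count drops to the minority-class size on very small data."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(folds, counts.min()))
    if n_splits < 2:
        raise ValueError(
            f"cannot cross-validate: minority class has {counts.min()} member(s)"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    losses = []
    for fold_i, (tr, va) in enumerate(skf.split(x, y)):
        x_tr, y_tr = x[tr], y[tr]
        _, tr_counts = np.unique(y_tr, return_counts=True)
        if smote_in_folds and len(tr_counts) == 2 and tr_counts.min() >= 2:
            x_tr, y_tr = smote(x_tr, y_tr, smote_k, seed + fold_i)
        clf = LogisticRegression(
            l1_ratio=l1_ratio, C=c, solver="liblinear", max_iter=2000,
            random_state=seed,
        ).fit(x_tr, y_tr)
        p = np.clip(clf.predict_proba(x[va])[:, 1], 1e-12, 1 - 1e-12)
        losses.append(
            -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
        )
    return float(np.mean(losses))


def lasso_select(
    x: pd.DataFrame,
    y: np.ndarray,
    cs: tuple[float, ...] = tuple(np.logspace(-2, 2, 10)),
    folds: int = 5,
    seed: int = 0,
    smote_k: int = 5,
    smote_in_folds: bool = True,
) -> tuple[list[str], float]:
    """L1-logistic feature selection with CV-deviance choice of penalty.

    Returns (selected features, chosen C).  If every C zeroes out all
    coefficients, falls back to the weakest penalty with a warning.
    """
    if folds < 2:
        raise ValueError("need >= 2 folds")
    xv = x.to_numpy(dtype=np.float64)
    losses = [
        _cv_log_loss(xv, y, c, 1.0, folds, seed, smote_k, smote_in_folds)
        for c in cs
    ]
    best_c = float(cs[int(np.argmin(losses))])

    def fit_at(c):
        x_fit, y_fit = smote(xv, y, smote_k, seed) if smote_in_folds else (xv, y)
        return LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000,
            random_state=seed,
        ).fit(x_fit, y_fit)

    clf = fit_at(best_c)
    mask = np.abs(clf.coef_[0]) > 1e-8
    if not mask.any():
        warnings.warn(
            "all LASSO coefficients zero at the CV-chosen penalty; "
            "falling back to the weakest penalty", stacklevel=2,
        )
        best_c = float(max(cs))
        clf = fit_at(best_c)
        mask = np.abs(clf.coef_[0]) > 1e-8
    return [f for f, k in zip(x.columns, mask) if k], best_c


# ---------------------------------------------------------------------------
# Trained classifier

@dataclass
class TrainedClassifier:
    name: str
    preprocessor: Preprocessor
    selected_features: list[str]
    intercept: float
    coef: np.ndarray
    threshold: float
    lasso_c: float | None
    lr_c: float
    seed: int

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing[:5]}")
        z = self.preprocessor.transform(table)[self.selected_features]
        return self.intercept + z.to_numpy() @ self.coef

    def predict(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return (probabilities, hard labels at the stored threshold)."""
        logits = self.decision_scores(table)
        probs = 1.0 / (1.0 + np.exp(-logits))
        return probs, (probs >= self.threshold).astype(int)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "selected_features": self.selected_features,
                "intercept": self.intercept,
                "coef": self.coef.tolist(),
                "threshold": self.threshold,
                "lasso_c": self.lasso_c,
                "lr_c": self.lr_c,
                "seed": self.seed,
                "preprocessing": {
                    "features": self.preprocessor.features,
                    "clip_low": self.preprocessor.clip_low.tolist(),
                    "clip_high": self.preprocessor.clip_high.tolist(),
                    "mean": self.preprocessor.mean.tolist(),
                    "sd": self.preprocessor.sd.tolist(),
                },
            },
            indent=1,
        )


def predict(classifier: TrainedClassifier, table: pd.DataFrame):
    return classifier.predict(table)


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability threshold maximizing sensitivity + specificity - 1."""
    order = np.argsort(-scores)
    s, lab = scores[order], labels[order]
    n_pos, n_neg = lab.sum(), len(lab) - lab.sum()
    tp = np.cumsum(lab)
    fp = np.cumsum(1 - lab)
    youden = tp / n_pos - fp / n_neg
    best = int(np.argmax(youden))
    # threshold halfway between the included and the next score
    lo = s[best + 1] if best + 1 < len(s) else s[best] - 1e-6
    return float((s[best] + lo) / 2)


def train_classifier(
    table: pd.DataFrame,
    labels: np.ndarray,
    feature_cols: list[str],
    name: str,
    settings: ModelSettings | None = None,
    seed: int = 0,
    skip_selection: bool = False,
) -> TrainedClassifier:
    """Fit one classifier on training rows only.

    Pipeline: clip/z-score fit -> SMOTE -> mRMR (top-m) -> LASSO ->
    L2-logistic with CV-tuned C; threshold via Youden's J on the original
    (un-oversampled) training scores.  ``skip_selection`` refits the
    final model on the given columns verbatim (used for Clf_Total).
    """
    settings = settings or ModelSettings()
    labels = np.asarray(labels, dtype=int)
    pre = preprocess_fit(table, feature_cols)
    z = pre.transform(table)
    if not pre.features:
        raise ValueError(f"{name}: all candidate features were constant")

    if skip_selection:
        selected, lasso_c = list(pre.features), None
    else:
        x_bal, y_bal = smote(
            z.to_numpy(), labels, settings.smote_k, seed
        )
        bal = pd.DataFrame(x_bal, columns=pre.features)
        m = min(settings.mrmr_m, len(pre.features))
        ranked = mrmr_select(bal, y_bal, m)
        selected, lasso_c = lasso_select(
            z[ranked], labels, settings.lasso_cs, settings.folds,
            seed, settings.smote_k, settings.smote_in_folds,
        )

    xv = z[selected].to_numpy()
    losses = [
        _cv_log_loss(xv, labels, c, 0.0, settings.folds, seed,
                     settings.smote_k, settings.smote_in_folds)
        for c in settings.lr_cs
    ]
    lr_c = float(settings.lr_cs[int(np.argmin(losses))])
    x_fit, y_fit = smote(xv, labels, settings.smote_k, seed)
    clf = LogisticRegression(
        l1_ratio=0.0, C=lr_c, solver="liblinear", max_iter=2000,
        random_state=seed,
    ).fit(x_fit, y_fit)

    train_probs = clf.predict_proba(xv)[:, 1]
    threshold = _youden_threshold(train_probs, labels)
    return TrainedClassifier(
        name=name,
        preprocessor=pre,
        selected_features=selected,
        intercept=float(clf.intercept_[0]),
        coef=clf.coef_[0].copy(),
        threshold=threshold,
        lasso_c=lasso_c,
        lr_c=lr_c,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Two-step architecture

CLASSIFIER_GROUPS = ("Clf_WVOI", "Clf_Habitats", "Clf_Clinical", "Clf_Total")


def _group_columns(table: pd.DataFrame, group: str) -> list[str]:
    if group == "Clf_WVOI":
        return [c for c in table.columns if c.startswith("WVOI__")]
    if group == "Clf_Habitats":
        return [c for c in table.columns
                if c.startswith("H1__") or c.startswith("H2__")]
    if group == "Clf_Clinical":
        return [c for c in CLINICAL_COLUMNS if c in table.columns]
    raise ValueError(f"unknown classifier group {group!r}")


@dataclass
class TwoStepResult:
    """Classifiers, splits and labels for Model-1 and Model-2."""

    classifiers: dict[str, dict[str, TrainedClassifier]]
    splits: dict[str, SplitPlan]
    labels: dict[str, pd.Series]


def binary_labels(grades: pd.Series, model: str) -> pd.Series:
    """Model-1: grade 3 vs grades 1-2; Model-2: grade 2 vs grade 1."""
    if model == "model1":
        return (grades == 3).astype(int)
    if model == "model2":
        if not set(np.unique(grades)) <= {1, 2}:
            raise ValueError("model2 expects only grade-1/2 subjects")
        return (grades == 2).astype(int)
    raise ValueError(f"unknown model {model!r}")


def train_two_step(
    table: pd.DataFrame,
    settings: ModelSettings | None = None,
    seed: int = 0,
) -> TwoStepResult:
    """Train the 2 x 4 classifier grid on a subject-level feature table.

    ``table`` needs a ``subject_id`` and ``grade`` column plus
    region-prefixed radiomic columns (``WVOI__*``, ``H1__*``, ``H2__*``)
    and the clinical columns.  Each model gets its own stratified 7:3
    split.  Clf_Total's candidate pool is exactly the union of the
    features selected by the three single-modality classifiers.
    """
    settings = settings or ModelSettings()
    result = TwoStepResult(classifiers={}, splits={}, labels={})
    for model_i, model in enumerate(("model1", "model2")):
        sub = table if model == "model1" else table[table["grade"] < 3]
        sub = sub.set_index("subject_id")
        y_all = binary_labels(sub["grade"], model)
        split = make_split(
            sub.index.to_numpy(), y_all.to_numpy(),
            ratio=settings.ratio, folds=settings.folds,
            seed=seed + 17 * model_i,
        )
        train = sub.loc[list(split.train_ids)]
        y_train = y_all.loc[list(split.train_ids)].to_numpy()

        clfs: dict[str, TrainedClassifier] = {}
        for group in ("Clf_WVOI", "Clf_Habitats", "Clf_Clinical"):
            clfs[group] = train_classifier(
                train, y_train, _group_columns(sub, group), group,
                settings, seed=seed + 17 * model_i,
            )
        pool = sorted(
            set().union(*(clfs[g].selected_features
                          for g in ("Clf_WVOI", "Clf_Habitats", "Clf_Clinical")))
        )
        if not pool:
            report = {g: clfs[g].selected_features for g in clfs}
            raise RuntimeError(
                f"{model}: empty Clf_Total pool; per-classifier selections: "
                f"{report}"
            )
        clfs["Clf_Total"] = train_classifier(
            train, y_train, pool, "Clf_Total", settings,
            seed=seed + 17 * model_i,
            skip_selection=not settings.refit_total_with_lasso,
        )
        result.classifiers[model] = clfs
        result.splits[model] = split
        result.labels[model] = y_all
    return result
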