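"""Reference-batch empirical-Bayes ComBat harmonization.

Removes per-batch location (mean) and scale (variance) shifts from each
feature while leaving the reference batch untouched.  Features are first
standardized against the reference batch's mean and standard deviation;
per-batch shifts are then estimated and shrunk across features with the
parametric empirical-Bayes scheme (normal prior on the location shift
gamma, inverse-gamma prior on the squared scale shift delta^2, fitted by
fixed-point iteration), and the adjustment (z - gamma*)/delta* is mapped
back to the reference scale.  No biological covariates are modeled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters for a fixed feature set."""

    features: list[str]
    batches: list
    reference_batch: object
    alpha: np.ndarray  # per-feature reference mean
    sigma: np.ndarray  # per-feature reference SD
    gamma_star: dict  # batch -> per-feature location shift (standardized)
    delta_star: dict  # batch -> per-feature scale shift (> 0)
    eb_enabled: bool
    adjust_location: bool
    adjust_scale: bool
    skipped_features: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        doc = {
            "features": self.features,
            "batches": [str(b) for b in self.batches],
            "reference_batch": str(self.reference_batch),
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": {str(b): g.tolist() for b, g in self.gamma_star.items()},
            "delta_star": {str(b): d.tolist() for b, d in self.delta_star.items()},
            "eb_enabled": self.eb_enabled,
            "adjust_location": self.adjust_location,
            "adjust_scale": self.adjust_scale,
            "skipped_features": self.skipped_features,
        }
        return json.dumps(doc, indent=1)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_fit(z_b: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """Shrink per-feature location/scale estimates of one batch.

    ``z_b``: standardized data of the batch, rows x features.  Returns
    (gamma_star, delta_sq_star).
    """
    n = z_b.shape[0]
    gamma_hat = z_b.mean(axis=0)
    delta_hat = z_b.var(axis=0, ddof=1)
    g_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    a_prior = _aprior(delta_hat)
    b_prior = _bprior(delta_hat)

    g_new, d_new = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new.copy(), d_new.copy()
        g_new = _postmean(gamma_hat, g_bar, n, d_new, t2)
        sum_sq = ((z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum_sq, n, a_prior, b_prior)
        change = max(
            np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-30),
            np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-30),
        )
        if change < tol:
            break
    return g_new, d_new


def fit_combat(
    table: pd.DataFrame,
    batch_ids: pd.Series | np.ndarray,
    reference_batch,
    features: list[str] | None = None,
    eb: bool = True,
    adjust_location: bool = True,
    adjust_scale: bool = True,
) -> HarmonizationModel:
    """Fit reference-batch ComBat on a feature table.

    ``table`` holds only feature columns unless ``features`` selects a
    subset.  Every batch needs >= 2 rows.  A feature with zero variance
    inside any batch is passed through unharmonized and flagged.
    """
    batch_ids = np.asarray(batch_ids)
    if features is None:
        features = [c for c in table.columns]
    x = table[features].to_numpy(dtype=np.float64)
    batches = list(pd.unique(batch_ids))
    if len(batches) < 2 and not (
        len(batches) == 1 and batches[0] == reference_batch
    ):
        # single-batch data is only legal when it IS the reference, in
        # which case the fitted model is the identity
        raise ValueError("ComBat needs at least 2 batches")
    if reference_batch not in batches:
        raise ValueError(f"reference batch {reference_batch!r} not in data")
    for b in batches:
        if (batch_ids == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 rows")

    # features unusable when constant within some batch
    skipped_idx = []
    for jf in range(x.shape[1]):
        for b in batches:
            if x[batch_ids == b, jf].std() == 0:
                skipped_idx.append(jf)
                break
    skipped = [features[j] for j in skipped_idx]
    if skipped:
        logger.warning(
            "%d feature(s) constant within a batch passed through "
            "unharmonized: %s", len(skipped), skipped[:5],
        )
    keep = np.array([j for j in range(x.shape[1]) if j not in set(skipped_idx)])

    ref_rows = x[batch_ids == reference_batch]
    alpha = np.zeros(x.shape[1])
    sigma = np.ones(x.shape[1])
    alpha[keep] = ref_rows[:, keep].mean(axis=0)
    sigma[keep] = ref_rows[:, keep].std(axis=0, ddof=1)

    gamma_star: dict = {}
    delta_star: dict = {}
    for b in batches:
        g = np.zeros(x.shape[1])
        d = np.ones(x.shape[1])
        if b != reference_batch and len(keep):
            z_b = (x[batch_ids == b][:, keep] - alpha[keep]) / sigma[keep]
            if eb and len(keep) >= 2:
                g_k, d2_k = _eb_fit(z_b)
            else:
                g_k = z_b.mean(axis=0)
                d2_k = z_b.var(axis=0, ddof=1)
            if adjust_location:
                g[keep] = g_k
            if adjust_scale:
                d[keep] = np.sqrt(np.clip(d2_k, 1e-12, None))
        gamma_star[b] = g
        delta_star[b] = d

    return HarmonizationModel(
        features=list(features),
        batches=batches,
        reference_batch=reference_batch,
        alpha=alpha,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=delta_star,
        eb_enabled=eb,
        adjust_location=adjust_location,
        adjust_scale=adjust_scale,
        skipped_features=skipped,
    )


def apply_combat(
    model: HarmonizationModel,
    table: pd.DataFrame,
    batch_ids: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Harmonize a table with a fitted model.

    Reference-batch rows are returned unchanged; rows of other batches
    are adjusted by (z - gamma*)/delta* in standardized space and mapped
    back to the reference scale.  Unseen batch ids are an error.
    """
    batch_ids = np.asarray(batch_ids)
    missing = [c for c in model.features if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks model features, e.g. {missing[:3]}")
    unseen = set(pd.unique(batch_ids)) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch id(s): {sorted(map(str, unseen))}")

    out = table.copy()
    x = out[model.features].to_numpy(dtype=np.float64)
    for b in model.batches:
        if b == model.reference_batch:
            continue
        rows = batch_ids == b
        if not rows.any():
            continue
        z = (x[rows] - model.alpha[None, :]) / model.sigma[None, :]
        z = (z - model.gamma_star[b][None, :]) / model.delta_star[b][None, :]
        x[rows] = z * model.sigma[None, :] + model.alpha[None, :]
    # skipped (within-batch-constant) features pass through untouched
    if model.skipped_features:
        skip_idx = [model.features.index(f) for f in model.skipped_features]
        x[:, skip_idx] = table[model.features].to_numpy()[:, skip_idx]
    out[model.features] = x
    return out


def batch_variance_fraction(
    table: pd.DataFrame, batch_ids, features: list[str] | None = None
) -> float:
    """Mean (over features) fraction of variance explained by batch.

    One-way ANOVA decomposition per feature: SS_between / SS_total.
    Used to quantify how much batch signal harmonization removed.
    """
    batch_ids = np.asarray(batch_ids)
    if features is None:
        features = list(table.columns)
    x = table[features].to_numpy(dtype=np.float64)
    grand = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=0)
    ss_between = np.zeros(x.shape[1])
    for b in pd.unique(batch_ids):
        rows = batch_ids == b
        ss_between += rows.sum() * (x[rows].mean(axis=0) - grand) ** 2
    ok = ss_total > 0
    return float((ss_between[ok] / ss_total[ok]).mean())
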