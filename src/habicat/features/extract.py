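"""Region-level feature extraction and cohort feature tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..geometry import ImageVolume, RegionMask
from .firstorder import firstorder_features
from .schema import (
    FIRSTORDER_WAVELET,
    FeatureSchema,
    TEXTURE_CLASSES,
    WAVELET_BANDS,
)
from .shape import shape_features
from .texture import discretize, texture_features
from .wavelet import wavelet_bands

logger = logging.getLogger(__name__)


def _bbox_crop(values: np.ndarray, mask: np.ndarray, margin: int = 2):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def extract_features(
    volume: ImageVolume,
    region: RegionMask,
    schema: FeatureSchema | None = None,
) -> tuple[dict[str, float], set[str]]:
    """Extract the full 851-feature vector for one region.

    Returns ``(features, flags)`` where ``flags`` names features that hit
    the degenerate-value policy (analytic limit where defined, else 0).
    Regions smaller than ``schema.min_region_voxels`` are processed but
    flagged wholesale.
    """
    schema = schema or FeatureSchema()
    if region.n_voxels == 0:
        raise ValueError("region is empty")
    if region.shape != volume.shape:
        raise ValueError("region and volume grids differ")

    vals, mask = _bbox_crop(volume.values, region.values)
    voxel_volume = float(np.prod(volume.spacing_mm))
    out: dict[str, float] = {}
    flags: set[str] = set()
    if region.n_voxels < schema.min_region_voxels:
        flags.add("__small_region__")

    sf, fl = shape_features(mask, volume.spacing_mm)
    out.update({f"original_shape_{k}": v for k, v in sf.items()})
    flags |= {f"original_shape_{k}" for k in fl}

    fo, fl = firstorder_features(vals[mask], voxel_volume, schema.n_bins)
    out.update({f"original_firstorder_{k}": v for k, v in fo.items()})
    flags |= {f"original_firstorder_{k}" for k in fl}

    disc = discretize(vals, mask, schema.n_bins)
    tex, _ = texture_features(disc, schema.n_bins)
    for cls, feats in tex.items():
        out.update({f"original_{cls}_{k}": v for k, v in feats.items()})

    for band_name, band in wavelet_bands(vals, schema.wavelet).items():
        prefix = f"wavelet-{band_name}"
        fo, fl = firstorder_features(band[mask], voxel_volume, schema.n_bins)
        out.update(
            {f"{prefix}_firstorder_{k}": fo[k] for k in FIRSTORDER_WAVELET}
        )
        flags |= {f"{prefix}_firstorder_{k}" for k in fl if k in FIRSTORDER_WAVELET}
        band_disc = discretize(band, mask, schema.n_bins)
        tex, _ = texture_features(band_disc, schema.n_bins)
        for cls, feats in tex.items():
            out.update({f"{prefix}_{cls}_{k}": v for k, v in feats.items()})

    ordered = {name: out[name] for name in schema.feature_names}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        logger.warning("non-finite features set to 0 and flagged: %s", bad[:5])
        for k in bad:
            ordered[k] = 0.0
            flags.add(k)
    return ordered, flags


REGION_NAMES = ("WVOI", "H1", "H2")


def extract_cohort(
    subjects: list[dict],
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Build the subjects x regions feature table.

    Each entry of ``subjects`` is a dict with keys ``subject_id``,
    ``volume`` (ImageVolume), ``regions`` (mapping region name ->
    RegionMask), and optional ``grade`` / ``batch`` metadata.  A region
    that collapsed below the minimum voxel count is extracted but its row
    is flagged; a missing/empty region drops the row with a logged reason.
    Output columns: metadata (subject_id, region, grade, batch, flagged)
    then the schema features in fixed order.
    """
    schema = schema or FeatureSchema()
    rows = []
    for sub in subjects:
        for region_name, region in sub["regions"].items():
            if region is None or region.n_voxels == 0:
                logger.warning(
                    "subject %s region %s is empty; row skipped",
                    sub["subject_id"], region_name,
                )
                continue
            feats, flags = extract_features(sub["volume"], region, schema)
            row = {
                "subject_id": sub["subject_id"],
                "region": region_name,
                "grade": sub.get("grade"),
                "batch": sub.get("batch"),
                "flagged": bool(flags),
            }
            row.update(feats)
            rows.append(row)
    df = pd.DataFrame(rows)
    meta = ["subject_id", "region", "grade", "batch", "flagged"]
    return df[meta + list(schema.feature_names)]


def wide_table(cohort: pd.DataFrame, schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Pivot a cohort table to one row per subject with region-prefixed
    feature columns (``WVOI__original_...``, ``H1__...``, ``H2__...``)."""
    schema = schema or FeatureSchema()
    feature_cols = [c for c in cohort.columns if c in set(schema.feature_names)]
    parts = []
    for region, grp in cohort.groupby("region"):
        sub = grp.set_index("subject_id")[feature_cols]
        sub.columns = [f"{region}__{c}" for c in sub.columns]
        parts.append(sub)
    wide = pd.concat(parts, axis=1)
    meta = cohort.drop_duplicates("subject_id").set_index("subject_id")[
        ["grade", "batch"]
    ]
    return meta.join(wide).reset_index()
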