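"""Synthetic 3-D phantom cohorts with known ground truth.

Each phantom subject is an ellipsoidal "tumor" inside a lung-like
background.  The tumor mixes two texture-distinct components: a darker
core component A and a brighter component B, with the A-fraction drawn
around a grade-specific mean that increases with pathological grade
(the planted habitat signal).  Thirteen clinical/semantic features are
generated from grade-loaded latent Gaussians so that each one's Spearman
correlation with grade has a configured sign.  Batch structure is
assigned orthogonally to grade, and batch effects are injected at the
feature level (additive location + multiplicative scale per batch and
feature) with the planted shifts recorded for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ImageVolume, RegionMask, save_mask, save_volume

#: Clinical feature -> (sign of grade correlation, latent loading, kind).
#: Signs mirror the direction each semantic CT descriptor moves with
#: tumor grade (e.g. denser, more spiculated lesions at higher grade;
#: clearer tumor-lung interface and air bronchograms at lower grade).
CLINICAL_SPEC: dict[str, tuple[int, float, str]] = {
    "age": (+1, 0.10, "continuous"),
    "size": (+1, 0.40, "continuous"),
    "gender": (+1, 0.30, "binary"),
    "smoke": (+1, 0.26, "binary"),
    "tumor_lung_interface": (-1, 0.55, "binary"),
    "vacuole_sign": (-1, 0.28, "binary"),
    "air_bronchogram": (-1, 0.40, "binary"),
    "lobulation": (+1, 0.28, "binary"),
    "spiculation": (+1, 0.50, "binary"),
    "pleural_indentation": (+1, 0.06, "binary"),
    "vascular_convergence": (+1, 0.17, "binary"),
    "density": (+1, 1.00, "ordinal3"),
    "position": (-1, 0.10, "ordinal7"),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; the defaults define the study conditions."""

    n_subjects_per_grade: int = 20
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range_mm: tuple[float, float] = (6.0, 10.0)
    core_fraction_by_grade: dict[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.35, 3: 0.6}
    )
    core_fraction_sd: float = 0.06
    habitat_intensity_means: tuple[float, float] = (-50.0, 50.0)  # (A, B)
    habitat_texture_scales: tuple[float, float] = (25.0, 10.0)
    lung_intensity: tuple[float, float] = (-800.0, 30.0)  # (mean, sd)
    n_batches: int = 3
    batch_location_shift: tuple[float, ...] = (0.0, 0.6, -0.4)
    batch_scale_shift: tuple[float, ...] = (1.0, 1.3, 0.8)
    clinical_effect_signs: dict[str, int] = field(
        default_factory=lambda: {k: v[0] for k, v in CLINICAL_SPEC.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [self.core_fraction_by_grade[g] for g in sorted(
            self.core_fraction_by_grade)]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("core fractions must lie in [0, 1]")
        if any(b >= a for a, b in zip(fracs[1:], fracs[:-1])):
            raise ValueError("core fractions must strictly increase with grade")
        if self.n_batches < 2:
            raise ValueError("n_batches must be >= 2")
        if len(self.batch_location_shift) != self.n_batches or len(
            self.batch_scale_shift
        ) != self.n_batches:
            raise ValueError("batch shift tuples must have n_batches entries")
        r_max = self.tumor_radius_range_mm[1]
        for axis in range(3):
            half_extent_mm = self.grid_shape[axis] * self.spacing_mm[axis] / 2
            if r_max + 3.0 + 3.0 * self.spacing_mm[axis] > half_extent_mm:
                raise ValueError(
                    f"tumor (radius {r_max} mm) plus 3 mm margin does not fit "
                    f"axis {axis} of the grid; enlarge grid_shape or shrink "
                    "tumor_radius_range_mm"
                )


@dataclass
class PhantomSubject:
    """One synthetic subject with ground-truth habitat labels."""

    subject_id: str
    image: ImageVolume
    gtv_mask: RegionMask
    lung_mask: RegionMask
    true_habitat_labels: np.ndarray  # 0 outside GTV, 1 = component A, 2 = B
    grade: int
    batch: int
    clinical: dict[str, float]

    @property
    def core_fraction(self) -> float:
        n = self.gtv_mask.n_voxels
        return float((self.true_habitat_labels == 1).sum() / n) if n else 0.0


def _ellipsoid(shape, center, radii, spacing) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _clinical_record(
    rng: np.random.Generator,
    grade: int,
    signs: dict[str, int],
) -> dict[str, float]:
    grade_c = (grade - 2) / np.sqrt(2 / 3)  # balanced-grade standardization
    record: dict[str, float] = {}
    for name, (default_sign, loading, kind) in CLINICAL_SPEC.items():
        sign = signs.get(name, default_sign)
        latent = sign * loading * grade_c + rng.normal()
        if kind == "continuous":
            if name == "age":
                record[name] = float(np.clip(55 + 8 * latent, 30, 90))
            else:  # size in mm
                record[name] = float(np.clip(20 + 10 * latent, 4, 80))
        elif kind == "binary":
            record[name] = float(latent > 0)
        elif kind == "ordinal3":
            record[name] = float(np.searchsorted([-0.6, 0.6], latent))
        else:  # ordinal7
            cuts = [-1.07, -0.57, -0.18, 0.18, 0.57, 1.07]
            record[name] = float(np.searchsorted(cuts, latent))
    return record


def generate_cohort(config: PhantomConfig) -> list[PhantomSubject]:
    """Generate the synthetic cohort; bit-deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    spacing = tuple(config.spacing_mm)
    extent = np.array(shape) * np.array(spacing)

    lung_values = np.ones(shape, dtype=bool)
    border = 2
    lung_values[:border], lung_values[-border:] = False, False
    lung_values[:, :border], lung_values[:, -border:] = False, False
    lung_values[:, :, :border], lung_values[:, :, -border:] = False, False
    lung = RegionMask(lung_values, spacing)

    mean_a, mean_b = config.habitat_intensity_means
    sd_a, sd_b = config.habitat_texture_scales
    lung_mean, lung_sd = config.lung_intensity

    subjects: list[PhantomSubject] = []
    grades = sorted(config.core_fraction_by_grade)
    for grade in grades:
        for i in range(config.n_subjects_per_grade):
            radii = rng.uniform(*config.tumor_radius_range_mm, size=3)
            jitter = rng.uniform(-3, 3, size=3)
            center = extent / 2 + jitter
            gtv_values = _ellipsoid(shape, center, radii, spacing)
            if not gtv_values.any():
                raise RuntimeError("degenerate phantom: empty tumor")

            frac = float(
                np.clip(
                    rng.normal(
                        config.core_fraction_by_grade[grade],
                        config.core_fraction_sd,
                    ),
                    0.0,
                    1.0,
                )
            )
            core_values = (
                _ellipsoid(shape, center, radii * frac ** (1 / 3), spacing)
                & gtv_values
                if frac > 0
                else np.zeros(shape, dtype=bool)
            )
            if frac >= 1.0:
                core_values = gtv_values.copy()

            labels = np.zeros(shape, dtype=np.uint8)
            labels[gtv_values] = 2
            labels[core_values] = 1

            values = rng.normal(lung_mean, lung_sd, size=shape)
            values[labels == 2] = rng.normal(mean_b, sd_b, size=int(
                (labels == 2).sum()))
            values[labels == 1] = rng.normal(mean_a, sd_a, size=int(
                (labels == 1).sum()))

            subjects.append(
                PhantomSubject(
                    subject_id=f"G{grade}_{i:03d}",
                    image=ImageVolume(values, spacing),
                    gtv_mask=RegionMask(gtv_values, spacing),
                    lung_mask=lung,
                    true_habitat_labels=labels,
                    grade=grade,
                    batch=i % config.n_batches,
                    clinical=_clinical_record(
                        rng, grade, config.clinical_effect_signs
                    ),
                )
            )
    return subjects


def clinical_table(subjects: list[PhantomSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "grade": s.grade, "batch": s.batch}
        row.update(s.clinical)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BatchEffectTruth:
    """Planted per-batch, per-feature shifts (for recovery tests)."""

    shift: pd.DataFrame  # batches x features, additive
    scale: pd.DataFrame  # batches x features, multiplicative


def inject_batch_effects(
    table: pd.DataFrame,
    config: PhantomConfig,
    features: list[str] | None = None,
    batch_column: str = "batch",
) -> tuple[pd.DataFrame, BatchEffectTruth]:
    """Perturb feature columns per batch: value * scale(b, g) + shift(b, g).

    Additive shifts are drawn per batch and feature around the configured
    per-batch level (expressed in units of each feature's SD); scale
    factors vary log-normally around the configured per-batch factor.
    Returns the perturbed table and the planted ground truth.
    """
    if batch_column not in table.columns:
        raise ValueError(f"table lacks a {batch_column!r} column")
    if features is None:
        features = [
            c for c in table.columns
            if c not in (batch_column, "subject_id", "grade", "region", "flagged")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    batches = sorted(pd.unique(table[batch_column]))
    unknown = [b for b in batches if not 0 <= int(b) < config.n_batches]
    if unknown:
        bad_rows = table.index[table[batch_column].isin(unknown)].tolist()
        raise ValueError(
            f"unknown batch id(s) {unknown} (rows {bad_rows[:5]}...)"
        )

    rng = np.random.default_rng(config.seed + 104729)
    x = table[features].to_numpy(dtype=np.float64)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)

    shift_rows, scale_rows = [], []
    for b in range(config.n_batches):
        loc = config.batch_location_shift[b]
        sc = config.batch_scale_shift[b]
        # per-feature jitter only where an effect is planted at all, so a
        # configured identity component stays exactly identity
        if loc == 0.0:
            shift_rows.append(np.zeros(len(features)))
        else:
            shift_rows.append(
                loc * sd * (1.0 + 0.5 * rng.normal(size=len(features)))
            )
        if sc == 1.0:
            scale_rows.append(np.ones(len(features)))
        else:
            scale_rows.append(sc * np.exp(0.15 * rng.normal(size=len(features))))
    shift = pd.DataFrame(shift_rows, index=range(config.n_batches),
                         columns=features)
    scale = pd.DataFrame(scale_rows, index=range(config.n_batches),
                         columns=features)

    out = table.copy()
    for b in batches:
        rows = (table[batch_column] == b).to_numpy()
        x[rows] = x[rows] * scale.loc[int(b)].to_numpy() + shift.loc[
            int(b)].to_numpy()
    out[features] = x
    return out, BatchEffectTruth(shift=shift, scale=scale)


def write_cohort(subjects: list[PhantomSubject], out_dir) -> None:
    """Write per-subject NIfTI triplets and the cohort CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        save_volume(s.image, out / f"{s.subject_id}_image.nii.gz")
        save_mask(s.gtv_mask, out / f"{s.subject_id}_gtv.nii.gz")
        save_mask(s.lung_mask, out / f"{s.subject_id}_lung.nii.gz")
    clinical_table(subjects).to_csv(out / "cohort.csv", index=False)


# ---------------------------------------------------------------------------
# Feature-level phantom (fast model-stage studies)

def generate_feature_table(
    n_per_grade: int = 30,
    n_wvoi: int = 20,
    n_habitat: int = 20,
    signal: str = "habitat",
    effect_size: float = 1.0,
    n_informative: int = 5,
    n_batches: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject-level feature table with a planted grade signal.

    A fast surrogate for the image pipeline when studying the modeling
    stages in isolation: Gaussian noise feature blocks for the WVOI and
    the two habitats (columns ``WVOI__f*``, ``H1__f*``, ``H2__f*``) plus
    the 13 clinical columns, with a linear grade effect of ``effect_size``
    SD planted in ``n_informative`` columns of the chosen block(s)
    (``signal`` in {"habitat", "wvoi", "both", "none"}).
    """
    if signal not in ("habitat", "wvoi", "both", "none"):
        raise ValueError(f"unknown signal location {signal!r}")
    rng = np.random.default_rng(seed)
    grades = np.repeat([1, 2, 3], n_per_grade)
    n = len(grades)
    grade_c = (grades - grades.mean()) / grades.std()

    data = {"subject_id": [f"S{i:04d}" for i in range(n)],
            "grade": grades,
            "batch": np.arange(n) % n_batches}
    half = n_habitat // 2

    def block(prefix: str, m: int, informative: bool):
        for j in range(m):
            col = rng.normal(size=n)
            if informative and j < n_informative:
                col = col + effect_size * grade_c
            data[f"{prefix}__f{j:02d}"] = col

    block("WVOI", n_wvoi, signal in ("wvoi", "both"))
    block("H1", half, signal in ("habitat", "both"))
    block("H2", n_habitat - half, signal in ("habitat", "both"))
    grade_std = (grades - 2) / np.sqrt(2 / 3)
    for name, (sign, loading, kind) in CLINICAL_SPEC.items():
        latent = sign * loading * grade_std + rng.normal(size=n)
        if kind == "continuous":
            base, sc = (55, 8) if name == "age" else (20, 10)
            data[name] = base + sc * latent
        elif kind == "binary":
            data[name] = (latent > 0).astype(float)
        elif kind == "ordinal3":
            data[name] = np.searchsorted([-0.6, 0.6], latent).astype(float)
        else:
            cuts = [-1.07, -0.57, -0.18, 0.18, 0.57, 1.07]
            data[name] = np.searchsorted(cuts, latent).astype(float)
    return pd.DataFrame(data)
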