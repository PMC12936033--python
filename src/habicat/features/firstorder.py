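"""First-order (intensity histogram and moment) features.

Kurtosis follows the Pearson convention (a normal distribution scores 3);
variance and standard deviation are population (ddof = 0) statistics.
Undefined values on degenerate regions (e.g. skewness of a constant
region) take their analytic limit where one exists, else 0, and the
feature name is recorded in the returned flag set.
"""

from __future__ import annotations

import numpy as np

EPS = 2.2e-16


def firstorder_features(
    values: np.ndarray,
    voxel_volume_mm3: float,
    n_bins: int = 25,
) -> tuple[dict[str, float], set[str]]:
    """Compute the 19 first-order features on a 1-D array of region values."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    flags: set[str] = set()
    out: dict[str, float] = {}

    mean = float(x.mean())
    out["Mean"] = mean
    out["Median"] = float(np.median(x))
    out["Minimum"] = float(x.min())
    out["Maximum"] = float(x.max())
    out["Range"] = out["Maximum"] - out["Minimum"]
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    out["10Percentile"] = float(p10)
    out["90Percentile"] = float(p90)
    out["InterquartileRange"] = float(p75 - p25)
    var = float(x.var())
    out["Variance"] = var
    out["StandardDeviation"] = float(np.sqrt(var))

    if var > 0:
        z = x - mean
        out["Skewness"] = float(np.mean(z**3) / var**1.5)
        out["Kurtosis"] = float(np.mean(z**4) / var**2)
    else:
        # constant region: third/fourth standardized moments undefined
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
        flags.update({"Skewness", "Kurtosis"})

    out["MeanAbsoluteDeviation"] = float(np.abs(x - mean).mean())
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        out["RobustMeanAbsoluteDeviation"] = float(
            np.abs(robust - robust.mean()).mean()
        )
    else:  # cannot happen for nonempty x, kept for safety
        out["RobustMeanAbsoluteDeviation"] = 0.0
        flags.add("RobustMeanAbsoluteDeviation")
    out["RootMeanSquared"] = float(np.sqrt(np.mean(x**2)))
    energy = float(np.sum(x**2))
    out["Energy"] = energy
    out["TotalEnergy"] = energy * float(voxel_volume_mm3)

    # histogram entropy / uniformity over n_bins equal-width bins
    lo, hi = out["Minimum"], out["Maximum"]
    if hi > lo:
        idx = np.minimum(
            ((x - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1
        )
        p = np.bincount(idx, minlength=n_bins) / x.size
    else:
        p = np.zeros(n_bins)
        p[0] = 1.0
    nz = p[p > 0]
    out["Entropy"] = float(-np.sum(nz * np.log2(nz + EPS)))
    out["Uniformity"] = float(np.sum(p**2))
    return out, flags
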