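"""Gray-level texture matrices and their features.

Intensities are discretized to a fixed bin count over the region's
min-max range (range-relative, so all texture features are invariant to
affine rescaling of the intensities).  GLCM and GLRLM aggregate over the
13 unique 3-D directions by computing each feature per direction and
averaging; GLSZM zones and GLDM/NGTDM neighborhoods use 26-connectivity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS = 2.2e-16

#: The 13 unique direction vectors of the 26-neighborhood (one per
#: antipodal pair), and all 26 offsets.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin in-region intensities to 1..n_bins; 0 outside the region.

    Equal-width bins over the in-region min-max range; a constant region
    maps entirely to level 1.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(values.shape, dtype=np.int64)
    inside = values[mask]
    lo, hi = float(inside.min()), float(inside.max())
    if hi > lo:
        idx = np.minimum(
            ((inside - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1
        )
    else:
        idx = np.zeros(inside.shape, dtype=np.int64)
    out[mask] = idx + 1
    return out


def _shift_slices(offset):
    """(source, destination) slice tuples so arr[src] pairs with arr[dst]."""
    src, dst = [], []
    for d in offset:
        if d == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif d > 0:
            src.append(slice(None, -d))
            dst.append(slice(d, None))
        else:
            src.append(slice(-d, None))
            dst.append(slice(None, d))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrices(disc: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrix per direction (n_bins x n_bins)."""
    mats = []
    for offset in DIRECTIONS_13:
        src, dst = _shift_slices(offset)
        a, b = disc[src].ravel(), disc[dst].ravel()
        ok = (a > 0) & (b > 0)
        c = np.zeros((n_bins, n_bins), dtype=np.float64)
        np.add.at(c, (a[ok] - 1, b[ok] - 1), 1.0)
        mats.append(c + c.T)
    return mats


def _glcm_features_single(c: np.ndarray) -> dict[str, float]:
    total = c.sum()
    if total == 0:
        return {name: 0.0 for name in _GLCM_NAMES}
    present = np.where(c.sum(axis=0) + c.sum(axis=1) > 0)[0]
    p = c[np.ix_(present, present)] / total
    iv = (present + 1).astype(np.float64)  # actual gray levels
    ng = c.shape[0]
    i = iv[:, None]
    j = iv[None, :]
    px = p.sum(axis=1)
    mu = float((px * iv).sum())
    sigma2 = float((px * (iv - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(i - j)
    kvals = np.arange(int(iv.max() - iv.min()) + 1, dtype=np.float64)
    pxmy = np.zeros(kvals.size)
    np.add.at(pxmy, np.abs(
        (present[:, None] - present[None, :])).ravel(), p.ravel())
    svals = np.arange(2 * iv.min(), 2 * iv.max() + 1)
    pxpy = np.zeros(svals.size)
    np.add.at(
        pxpy,
        ((present[:, None] + present[None, :]) + 2 - int(svals[0])).ravel(),
        p.ravel(),
    )

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((p * i * j).sum())
    out["JointAverage"] = mu
    ipj = i + j - 2 * mu
    out["ClusterProminence"] = float((p * ipj**4).sum())
    out["ClusterShade"] = float((p * ipj**3).sum())
    out["ClusterTendency"] = float((p * ipj**2).sum())
    out["Contrast"] = float((p * (i - j) ** 2).sum())
    if sigma2 > 0:
        out["Correlation"] = float(
            ((p * i * j).sum() - mu * mu) / sigma2
        )
    else:
        out["Correlation"] = 1.0
    da = float((pxmy * kvals).sum())
    out["DifferenceAverage"] = da
    nzd = pxmy[pxmy > 0]
    out["DifferenceEntropy"] = float(-(nzd * np.log2(nzd + EPS)).sum())
    out["DifferenceVariance"] = float((pxmy * (kvals - da) ** 2).sum())
    out["JointEnergy"] = float((p**2).sum())
    nzp = p[p > 0]
    hxy = float(-(nzp * np.log2(nzp + EPS)).sum())
    out["JointEntropy"] = hxy
    pxpy_outer = px[:, None] * px[None, :]
    hx = float(-(px[px > 0] * np.log2(px[px > 0] + EPS)).sum())
    with np.errstate(divide="ignore"):
        hxy1 = float(-(p * np.log2(pxpy_outer + EPS)).sum())
        hxy2 = float(
            -(pxpy_outer[pxpy_outer > 0]
              * np.log2(pxpy_outer[pxpy_outer > 0] + EPS)).sum()
        )
    div = max(hx, hx)  # symmetric matrix: hy == hx
    out["Imc1"] = float((hxy - hxy1) / div) if div > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))))
    out["Idm"] = float((p / (1 + (i - j) ** 2)).sum())
    out["Idmn"] = float((p / (1 + ((i - j) / ng) ** 2)).sum())
    out["Id"] = float((p / (1 + diff)).sum())
    out["Idn"] = float((p / (1 + diff / ng)).sum())
    offdiag = diff > 0
    out["InverseVariance"] = float((p[offdiag] / diff[offdiag] ** 2).sum())
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((pxpy * svals).sum())
    nzs = pxpy[pxpy > 0]
    out["SumEntropy"] = float(-(nzs * np.log2(nzs + EPS)).sum())
    out["SumSquares"] = sigma2
    # maximal correlation coefficient
    if len(iv) < 2 or sigma2 == 0:
        out["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.einsum("ik,jk->ij", p / px[:, None], p / px[None, :])
        q = np.nan_to_num(q)
        eig = np.sort(np.abs(np.linalg.eigvals(q)))[::-1]
        out["MCC"] = float(np.sqrt(max(0.0, eig[1].real))) if len(eig) > 1 else 1.0
    return out


_GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)


def glcm_features(disc: np.ndarray, n_bins: int) -> dict[str, float]:
    """GLCM features averaged over the 13 directions."""
    per_dir = [
        _glcm_features_single(c)
        for c in glcm_matrices(disc, n_bins)
        if c.sum() > 0
    ]
    if not per_dir:  # single isolated voxel: no pairs in any direction
        return {name: 0.0 for name in _GLCM_NAMES}
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in _GLCM_NAMES
    }


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(disc: np.ndarray, n_bins: int, offset) -> np.ndarray:
    """Run-length count matrix (n_bins x max_len) for one direction."""
    in_region = disc > 0
    shape = disc.shape
    src, dst = _shift_slices(offset)
    same = np.zeros(shape, dtype=bool)  # voxel has same-level successor at +d
    same[src] = in_region[src] & in_region[dst] & (disc[src] == disc[dst])
    # start voxels: in-region without a same-level predecessor at -d
    pred_same = np.zeros(shape, dtype=bool)
    pred_same[dst] = same[src]
    starts = np.argwhere(in_region & ~pred_same)
    d = np.asarray(offset)
    lengths = np.ones(len(starts), dtype=np.int64)
    pos = starts.copy()
    active = np.ones(len(starts), dtype=bool)
    while active.any():
        cur = pos[active]
        cont = same[cur[:, 0], cur[:, 1], cur[:, 2]]
        idx = np.where(active)[0]
        lengths[idx[cont]] += 1
        still = idx[cont]
        pos[still] += d
        active[:] = False
        active[still] = True
    max_len = int(lengths.max()) if len(lengths) else 1
    r = np.zeros((n_bins, max_len), dtype=np.float64)
    levels = disc[starts[:, 0], starts[:, 1], starts[:, 2]]
    np.add.at(r, (levels - 1, lengths - 1), 1.0)
    return r


def _weighted_stats(mat: np.ndarray) -> dict[str, np.ndarray]:
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    return {"i": i, "j": j, "ri": mat.sum(axis=1), "rj": mat.sum(axis=0)}


def glrlm_features_single(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = r.sum()
    s = _weighted_stats(r)
    i, j, ri, rj = s["i"], s["j"], s["ri"], s["rj"]
    p = r / nr
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p[p > 0]
    return {
        "ShortRunEmphasis": float((r / j**2).sum() / nr),
        "LongRunEmphasis": float((r * j**2).sum() / nr),
        "GrayLevelNonUniformity": float((ri**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rj**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rj**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (j - mu_j) ** 2).sum()),
        "RunEntropy": float(-(nz * np.log2(nz + EPS)).sum()),
        "LowGrayLevelRunEmphasis": float((r / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((r * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((r / (i**2 * j**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((r * i**2 / j**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((r * j**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((r * i**2 * j**2).sum() / nr),
    }


def glrlm_features(disc: np.ndarray, n_bins: int) -> dict[str, float]:
    """GLRLM features averaged over the 13 directions."""
    n_voxels = int((disc > 0).sum())
    per_dir = [
        glrlm_features_single(glrlm_matrix(disc, n_bins, off), n_voxels)
        for off in DIRECTIONS_13
    ]
    names = per_dir[0].keys()
    return {name: float(np.mean([d[name] for d in per_dir])) for name in names}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(disc: np.ndarray, n_bins: int) -> np.ndarray:
    """Zone-size count matrix (n_bins x max_zone); 26-connected zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    for level in np.unique(disc[disc > 0]):
        labeled, n = ndimage.label(disc == level, structure=structure)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones += [(int(level), int(sz)) for sz in sizes]
    max_size = max(sz for _, sz in zones)
    z = np.zeros((n_bins, max_size), dtype=np.float64)
    for level, sz in zones:
        z[level - 1, sz - 1] += 1
    return z


def glszm_features(disc: np.ndarray, n_bins: int) -> dict[str, float]:
    z = glszm_matrix(disc, n_bins)
    nz_total = z.sum()
    n_voxels = int((disc > 0).sum())
    s = _weighted_stats(z)
    i, j, zi, zj = s["i"], s["j"], s["ri"], s["rj"]
    p = z / nz_total
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p[p > 0]
    return {
        "SmallAreaEmphasis": float((z / j**2).sum() / nz_total),
        "LargeAreaEmphasis": float((z * j**2).sum() / nz_total),
        "GrayLevelNonUniformity": float((zi**2).sum() / nz_total),
        "GrayLevelNonUniformityNormalized": float((zi**2).sum() / nz_total**2),
        "SizeZoneNonUniformity": float((zj**2).sum() / nz_total),
        "SizeZoneNonUniformityNormalized": float((zj**2).sum() / nz_total**2),
        "ZonePercentage": float(nz_total / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (j - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(nz * np.log2(nz + EPS)).sum()),
        "LowGrayLevelZoneEmphasis": float((z / i**2).sum() / nz_total),
        "HighGrayLevelZoneEmphasis": float((z * i**2).sum() / nz_total),
        "SmallAreaLowGrayLevelEmphasis": float((z / (i**2 * j**2)).sum() / nz_total),
        "SmallAreaHighGrayLevelEmphasis": float((z * i**2 / j**2).sum() / nz_total),
        "LargeAreaLowGrayLevelEmphasis": float((z * j**2 / i**2).sum() / nz_total),
        "LargeAreaHighGrayLevelEmphasis": float((z * i**2 * j**2).sum() / nz_total),
    }


# ---------------------------------------------------------------------------
# GLDM

def gldm_matrix(disc: np.ndarray, n_bins: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix; dependence of a voxel = 1 + number of
    26-neighbors whose discretized level differs by at most ``alpha``."""
    in_region = disc > 0
    dep = np.zeros(disc.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        src, dst = _shift_slices(offset)
        ok = in_region[src] & in_region[dst] & (
            np.abs(disc[src] - disc[dst]) <= alpha
        )
        dep[src] += ok
    dep += 1
    levels = disc[in_region]
    deps = dep[in_region]
    m = np.zeros((n_bins, int(deps.max())), dtype=np.float64)
    np.add.at(m, (levels - 1, deps - 1), 1.0)
    return m


def gldm_features(disc: np.ndarray, n_bins: int, alpha: int = 0) -> dict[str, float]:
    m = gldm_matrix(disc, n_bins, alpha)
    nz_total = m.sum()
    s = _weighted_stats(m)
    i, j, mi, mj = s["i"], s["j"], s["ri"], s["rj"]
    p = m / nz_total
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((m / j**2).sum() / nz_total),
        "LargeDependenceEmphasis": float((m * j**2).sum() / nz_total),
        "GrayLevelNonUniformity": float((mi**2).sum() / nz_total),
        "DependenceNonUniformity": float((mj**2).sum() / nz_total),
        "DependenceNonUniformityNormalized": float((mj**2).sum() / nz_total**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(nz * np.log2(nz + EPS)).sum()),
        "LowGrayLevelEmphasis": float((m / i**2).sum() / nz_total),
        "HighGrayLevelEmphasis": float((m * i**2).sum() / nz_total),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (m / (i**2 * j**2)).sum() / nz_total
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (m * i**2 / j**2).sum() / nz_total
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (m * j**2 / i**2).sum() / nz_total
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (m * i**2 * j**2).sum() / nz_total
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features(disc: np.ndarray, n_bins: int) -> dict[str, float]:
    """Neighborhood gray-tone difference features (26-neighborhood)."""
    in_region = disc > 0
    nb_sum = np.zeros(disc.shape, dtype=np.float64)
    nb_cnt = np.zeros(disc.shape, dtype=np.float64)
    for offset in OFFSETS_26:
        src, dst = _shift_slices(offset)
        ok = in_region[src] & in_region[dst]
        nb_sum[src] += np.where(ok, disc[dst], 0)
        nb_cnt[src] += ok
    valid = in_region & (nb_cnt > 0)
    with np.errstate(invalid="ignore"):
        nb_mean = nb_sum / nb_cnt
    levels = disc[valid]
    absdiff = np.abs(levels - nb_mean[valid])
    n_i = np.bincount(levels - 1, minlength=n_bins).astype(np.float64)
    s_i = np.zeros(n_bins)
    np.add.at(s_i, levels - 1, absdiff)
    nv = float(n_i.sum())
    if nv == 0:
        return {name: 0.0 for name in
                ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p_i = n_i / nv
    present = p_i > 0
    iv = np.arange(1, n_bins + 1, dtype=np.float64)
    ngp = int(present.sum())

    out: dict[str, float] = {}
    denom = float((p_i * s_i).sum())
    out["Coarseness"] = float(1.0 / denom) if denom > 0 else 1e6
    if ngp > 1:
        pij = p_i[present][:, None] * p_i[present][None, :]
        dij2 = (iv[present][:, None] - iv[present][None, :]) ** 2
        out["Contrast"] = float(
            pij.ravel() @ dij2.ravel() / (ngp * (ngp - 1)) * s_i.sum() / nv
        )
    else:
        out["Contrast"] = 0.0
    ipi = iv[present] * p_i[present]
    bus_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    out["Busyness"] = float(denom / bus_den) if bus_den > 0 else 0.0
    if ngp > 1:
        pi_, si_, iv_ = p_i[present], s_i[present], iv[present]
        num = (
            np.abs(iv_[:, None] - iv_[None, :])
            * (pi_[:, None] * si_[:, None] + pi_[None, :] * si_[None, :])
            / (pi_[:, None] + pi_[None, :])
        )
        out["Complexity"] = float(num.sum() / nv)
        str_num = float(
            ((pi_[:, None] + pi_[None, :])
             * (iv_[:, None] - iv_[None, :]) ** 2).sum()
        )
        s_tot = float(s_i.sum())
        out["Strength"] = float(str_num / s_tot) if s_tot > 0 else 0.0
    else:
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    return out


def texture_features(
    disc: np.ndarray, n_bins: int
) -> tuple[dict[str, dict[str, float]], set[str]]:
    """All five texture families on a discretized (0 = outside) volume."""
    flags: set[str] = set()
    out = {
        "glcm": glcm_features(disc, n_bins),
        "glrlm": glrlm_features(disc, n_bins),
        "glszm": glszm_features(disc, n_bins),
        "gldm": gldm_features(disc, n_bins),
        "ngtdm": ngtdm_features(disc, n_bins),
    }
    return out, flags
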