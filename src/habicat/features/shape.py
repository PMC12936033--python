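"""Shape (morphology) features of a binary region.

Surface area comes from a marching-cubes mesh of the mask; axis lengths
from the eigenvalues of the physical-coordinate covariance of the voxel
centers (principal-axes lengths 4*sqrt(lambda), as for an ellipsoid);
maximum diameters are largest pairwise distances between surface-voxel
centers (computed on the convex hull for speed).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; hull-accelerated."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 40 and pts.shape[1] >= 2:
        try:
            pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except QhullError:
            pass
    return float(pdist(pts).max())


def shape_features(
    mask: np.ndarray, spacing_mm: tuple[float, float, float]
) -> tuple[dict[str, float], set[str]]:
    """Compute the 13 shape features for a binary 3-D mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    spacing = np.asarray(spacing_mm, dtype=float)
    flags: set[str] = set()
    out: dict[str, float] = {}

    n = int(mask.sum())
    voxel_volume = float(np.prod(spacing))
    volume = n * voxel_volume
    out["VoxelVolume"] = volume

    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    tri = verts[faces]
    area = float(
        0.5
        * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
    )
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / volume
    out["Sphericity"] = float((36 * np.pi * volume**2) ** (1 / 3) / area)

    coords = np.argwhere(mask) * spacing
    # surface voxels: region voxels with at least one out-of-region 6-neighbor
    eroded = ndimage.binary_erosion(mask)
    surf = np.argwhere(mask & ~eroded) * spacing
    out["Maximum3DDiameter"] = _max_pairwise(surf)
    out["Maximum2DDiameterSlice"] = _max_pairwise(surf[:, (0, 1)])
    out["Maximum2DDiameterColumn"] = _max_pairwise(surf[:, (0, 2)])
    out["Maximum2DDiameterRow"] = _max_pairwise(surf[:, (1, 2)])

    if n > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    else:
        eig = np.zeros(3)
    out["MajorAxisLength"] = float(4 * np.sqrt(eig[0]))
    out["MinorAxisLength"] = float(4 * np.sqrt(eig[1]))
    out["LeastAxisLength"] = float(4 * np.sqrt(eig[2]))
    if eig[0] > 0:
        out["Elongation"] = float(np.sqrt(eig[1] / eig[0]))
        out["Flatness"] = float(np.sqrt(eig[2] / eig[0]))
    else:
        # point-like region: isotropic limit
        out["Elongation"] = 1.0
        out["Flatness"] = 1.0
        flags.update({"Elongation", "Flatness"})
    return out, flags
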