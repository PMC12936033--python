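"""Independent brute-force oracles shared by the test suites."""

import numpy as np

from habicat.features import DIRECTIONS_13

EPS = 2.2e-16


# ---------------------------------------------------------------------------
# Independent GLCM oracle (plain loops, textbook formulas)

def naive_glcm_single(disc, offset, n_bins):
    counts = {}
    shape = disc.shape
    for idx in np.ndindex(shape):
        j = tuple(np.add(idx, offset))
        if any(c < 0 or c >= s for c, s in zip(j, shape)):
            continue
        a, b = disc[idx], disc[j]
        if a > 0 and b > 0:
            counts[(a, b)] = counts.get((a, b), 0) + 1
            counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None
    p = {k: v / total for k, v in counts.items()}
    px = {}
    for (a, b), v in p.items():
        px[a] = px.get(a, 0) + v
    mu = sum(i * v for i, v in px.items())
    sigma2 = sum(v * (i - mu) ** 2 for i, v in px.items())
    pxmy, pxpy = {}, {}
    for (a, b), v in p.items():
        pxmy[abs(a - b)] = pxmy.get(abs(a - b), 0) + v
        pxpy[a + b] = pxpy.get(a + b, 0) + v
    da = sum(k * v for k, v in pxmy.items())
    hxy = -sum(v * np.log2(v + EPS) for v in p.values())
    hx = -sum(v * np.log2(v + EPS) for v in px.items() for v in [v[1]])
    hxy1 = -sum(v * np.log2(px[a] * px[b] + EPS) for (a, b), v in p.items())
    hxy2 = -sum(
        px[a] * px[b] * np.log2(px[a] * px[b] + EPS)
        for a in px for b in px
    )
    out = {
        "Autocorrelation": sum(a * b * v for (a, b), v in p.items()),
        "JointAverage": mu,
        "ClusterProminence": sum(
            (a + b - 2 * mu) ** 4 * v for (a, b), v in p.items()
        ),
        "ClusterShade": sum(
            (a + b - 2 * mu) ** 3 * v for (a, b), v in p.items()
        ),
        "ClusterTendency": sum(
            (a + b - 2 * mu) ** 2 * v for (a, b), v in p.items()
        ),
        "Contrast": sum((a - b) ** 2 * v for (a, b), v in p.items()),
        "Correlation": (
            (sum(a * b * v for (a, b), v in p.items()) - mu * mu) / sigma2
            if sigma2 > 0 else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(
            v * np.log2(v + EPS) for v in pxmy.values()
        ),
        "DifferenceVariance": sum(
            (k - da) ** 2 * v for k, v in pxmy.items()
        ),
        "JointEnergy": sum(v**2 for v in p.values()),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))),
        "Idm": sum(v / (1 + (a - b) ** 2) for (a, b), v in p.items()),
        "Idmn": sum(
            v / (1 + ((a - b) / n_bins) ** 2) for (a, b), v in p.items()
        ),
        "Id": sum(v / (1 + abs(a - b)) for (a, b), v in p.items()),
        "Idn": sum(v / (1 + abs(a - b) / n_bins) for (a, b), v in p.items()),
        "InverseVariance": sum(
            v / (a - b) ** 2 for (a, b), v in p.items() if a != b
        ),
        "MaximumProbability": max(p.values()),
        "SumAverage": sum(k * v for k, v in pxpy.items()),
        "SumEntropy": -sum(v * np.log2(v + EPS) for v in pxpy.values()),
        "SumSquares": sigma2,
    }
    levels = sorted(px)
    if len(levels) < 2 or sigma2 == 0:
        out["MCC"] = 1.0
    else:
        q = np.zeros((len(levels), len(levels)))
        for ii, a in enumerate(levels):
            for jj, b in enumerate(levels):
                q[ii, jj] = sum(
                    p.get((a, k), 0) * p.get((b, k), 0) / (px[a] * px[k])
                    for k in levels
                )
        eig = np.sort(np.abs(np.linalg.eigvals(q)))[::-1]
        out["MCC"] = float(np.sqrt(max(0.0, eig[1].real)))
    return out


def naive_glcm_features(disc, n_bins):
    per_dir = [
        f for off in DIRECTIONS_13
        if (f := naive_glcm_single(disc, off, n_bins)) is not None
    ]
    return {k: np.mean([d[k] for d in per_dir]) for k in per_dir[0]}


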