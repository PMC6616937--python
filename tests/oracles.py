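"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(explicit 2x2 blocks, explicit pair loops, formula-by-formula sums) and
shares no code with the package.
"""

import numpy as np


# ---------------------------------------------------------------------------
# orthonormal 2x2 block Haar transform

def block_haar_level(x: np.ndarray) -> dict[str, np.ndarray]:
    """One Haar level as explicit non-overlapping 2x2 block sums/differences
    (low = (u+v)/sqrt2, high = (u-v)/sqrt2 applied to rows then columns)."""
    if x.shape[0] % 2:
        x = np.vstack([x, x[-1:]])
    if x.shape[1] % 2:
        x = np.hstack([x, x[:, -1:]])
    R, C = x.shape[0] // 2, x.shape[1] // 2
    out = {k: np.zeros((R, C)) for k in ("LL", "HL", "LH", "HH")}
    for r in range(R):
        for c in range(C):
            a, b = x[2 * r, 2 * c], x[2 * r, 2 * c + 1]
            d, e = x[2 * r + 1, 2 * c], x[2 * r + 1, 2 * c + 1]
            out["LL"][r, c] = (a + b + d + e) / 2.0
            out["LH"][r, c] = ((a - b) + (d - e)) / 2.0
            out["HL"][r, c] = ((a + b) - (d + e)) / 2.0
            out["HH"][r, c] = ((a - b) - (d - e)) / 2.0
    return out


def block_haar_pyramid(x: np.ndarray) -> dict[str, np.ndarray]:
    lvl1 = block_haar_level(x)
    lvl2 = block_haar_level(lvl1["LL"])
    out = {f"{k}1": v for k, v in lvl1.items()}
    out.update({f"{k}2": v for k, v in lvl2.items()})
    return out


# ---------------------------------------------------------------------------
# brute-force GLCM (pair enumeration) and Haralick statistics

GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(quantized: np.ndarray, n_levels: int, distance: int,
               direction_deg: int, symmetric: bool = True,
               normalized: bool = True) -> np.ndarray:
    dr, dc = GLCM_OFFSETS[direction_deg]
    dr, dc = dr * distance, dc * distance
    G = np.zeros((n_levels, n_levels))
    rows, cols = quantized.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                G[quantized[r, c], quantized[r2, c2]] += 1
                if symmetric:
                    G[quantized[r2, c2], quantized[r, c]] += 1
    if normalized:
        G = G / G.sum()
    return G


def brute_haralick(p: np.ndarray) -> dict[str, float]:
    """The 13 statistics as literal loops over the matrix entries."""
    g = p.shape[0]
    mu_x = sum(i * p[i, j] for i in range(g) for j in range(g))
    mu_y = sum(j * p[i, j] for i in range(g) for j in range(g))
    var_x = sum((i - mu_x) ** 2 * p[i, j] for i in range(g) for j in range(g))
    var_y = sum((j - mu_y) ** 2 * p[i, j] for i in range(g) for j in range(g))
    p_sum = np.zeros(2 * g - 1)
    p_diff = np.zeros(g)
    for i in range(g):
        for j in range(g):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def h(q):
        return -sum(v * np.log2(v) for v in np.ravel(q) if v > 0)

    sum_avg = sum(k * p_sum[k] for k in range(2 * g - 1))
    out = {
        "Contrast": sum(p[i, j] * (i - j) ** 2
                        for i in range(g) for j in range(g)),
        "ClusterProminence": sum((i + j - mu_x - mu_y) ** 4 * p[i, j]
                                 for i in range(g) for j in range(g)),
        "ClusterShade": sum((i + j - mu_x - mu_y) ** 3 * p[i, j]
                            for i in range(g) for j in range(g)),
        "Dissimilarity": sum(p[i, j] * abs(i - j)
                             for i in range(g) for j in range(g)),
        "Energy": sum(p[i, j] ** 2 for i in range(g) for j in range(g)),
        "Entropy": h(p),
        "Homogeneity": sum(p[i, j] / (1 + (i - j) ** 2)
                           for i in range(g) for j in range(g)),
        "SumAverage": sum_avg,
        "SumVariance": sum((k - sum_avg) ** 2 * p_sum[k]
                           for k in range(2 * g - 1)),
        "SumEntropy": h(p_sum),
        "DifferenceEntropy": h(p_diff),
        "InverseDifferenceNormalized": sum(p[i, j] / (1 + abs(i - j) / g)
                                           for i in range(g) for j in range(g)),
    }
    if var_x > 0 and var_y > 0:
        out["Correlation"] = sum(
            (i - mu_x) * (j - mu_y) * p[i, j]
            for i in range(g) for j in range(g)) / np.sqrt(var_x * var_y)
    else:
        out["Correlation"] = 0.0
    return out


# ---------------------------------------------------------------------------
# rank (Mann-Whitney) AUC with half credit for ties

def rank_auc(scores, labels01) -> float:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels01)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
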