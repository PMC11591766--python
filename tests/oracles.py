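"""Independent brute-force oracles used by the test suite.

Everything here is written as plain double loops / literal formula
transcription, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_bruteforce(levels: np.ndarray, offset, ng: int = 8) -> np.ndarray:
    """Count co-occurrences by looping over every pixel."""
    rows, cols = levels.shape
    dr, dc = offset
    counts = np.zeros((ng, ng), dtype=int)
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    return counts


def bilinear_resize_oracle(img: np.ndarray, side: int) -> np.ndarray:
    """Hand-computed bilinear interpolation with pixel-center alignment."""
    in_r, in_c = img.shape
    sr, sc = in_r / side, in_c / side
    out = np.zeros((side, side))

    def at(rr, cc):
        return img[min(max(rr, 0), in_r - 1), min(max(cc, 0), in_c - 1)]

    for r in range(side):
        for c in range(side):
            y = (r + 0.5) * sr - 0.5
            x = (c + 0.5) * sc - 0.5
            y0, x0 = math.floor(y), math.floor(x)
            wy, wx = y - y0, x - x0
            out[r, c] = (at(y0, x0) * (1 - wy) * (1 - wx)
                         + at(y0, x0 + 1) * (1 - wy) * wx
                         + at(y0 + 1, x0) * wy * (1 - wx)
                         + at(y0 + 1, x0 + 1) * wy * wx)
    return out


def texture_features_oracle(p: np.ndarray, ng: int = 8) -> dict[str, float]:
    """Literal transcription of the 22 texture formulas with explicit loops.

    Levels i, j run 1..ng.  Entropies are base-2 with 0*log(0) := 0;
    correlations and IMC1 fall back to 0 when denominators vanish.
    """

    def xlog2(v):
        return v * math.log2(v) if v > 0 else 0.0

    px = [sum(p[i - 1][j - 1] for j in range(1, ng + 1)) for i in range(1, ng + 1)]
    py = [sum(p[i - 1][j - 1] for i in range(1, ng + 1)) for j in range(1, ng + 1)]
    mu_x = sum(i * px[i - 1] for i in range(1, ng + 1))
    mu_y = sum(j * py[j - 1] for j in range(1, ng + 1))
    sigma_x = math.sqrt(sum((i - mu_x) ** 2 * px[i - 1] for i in range(1, ng + 1)))
    sigma_y = math.sqrt(sum((j - mu_y) ** 2 * py[j - 1] for j in range(1, ng + 1)))

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            p_sum[i + j] += p[i - 1][j - 1]
            p_diff[abs(i - j)] += p[i - 1][j - 1]

    HX = -sum(xlog2(v) for v in px)
    HY = -sum(xlog2(v) for v in py)
    HXY = -sum(xlog2(p[i][j]) for i in range(ng) for j in range(ng))
    HXY1 = -sum(p[i][j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if p[i][j] > 0 and px[i] * py[j] > 0)
    HXY2 = -sum(xlog2(px[i] * py[j]) for i in range(ng) for j in range(ng))

    f = {}
    f["autocorrelation"] = sum(i * j * p[i - 1][j - 1]
                               for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["contrast"] = sum(k ** 2 * p_diff[k] for k in p_diff)
    if sigma_x * sigma_y > 0:
        f["correlation1"] = sum((i - mu_x) * (j - mu_y) * p[i - 1][j - 1]
                                for i in range(1, ng + 1)
                                for j in range(1, ng + 1)) / (sigma_x * sigma_y)
        f["correlation2"] = (f["autocorrelation"] - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        f["correlation1"] = f["correlation2"] = 0.0
    f["cluster_prominence"] = sum((i + j - mu_x - mu_y) ** 4 * p[i - 1][j - 1]
                                  for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["cluster_shade"] = sum((i + j - mu_x - mu_y) ** 3 * p[i - 1][j - 1]
                             for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["dissimilarity"] = sum(abs(i - j) * p[i - 1][j - 1]
                             for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["entropy"] = HXY
    f["homogeneity1"] = sum(p[i - 1][j - 1] / (1 + abs(i - j))
                            for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["homogeneity2"] = sum(p[i - 1][j - 1] / (1 + (i - j) ** 2)
                            for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["max_probability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    mu = sum(0.5 * (i + j) * p[i - 1][j - 1]
             for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["variance"] = sum((i - mu) ** 2 * p[i - 1][j - 1]
                        for i in range(1, ng + 1) for j in range(1, ng + 1))
    f["sum_average"] = sum(k * p_sum[k] for k in p_sum)
    f["sum_variance"] = sum((k - f["sum_average"]) ** 2 * p_sum[k] for k in p_sum)
    f["sum_entropy"] = -sum(xlog2(p_sum[k]) for k in p_sum)
    dmean = sum(k * p_diff[k] for k in p_diff)
    f["difference_variance"] = sum((k - dmean) ** 2 * p_diff[k] for k in p_diff)
    f["difference_entropy"] = -sum(xlog2(p_diff[k]) for k in p_diff)
    hmax = max(HX, HY)
    f["imc1"] = (HXY - HXY1) / hmax if hmax > 0 else 0.0
    f["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (HXY2 - HXY))))
    f["inverse_difference_normalized"] = sum(p_diff[k] / (1 + k / ng) for k in p_diff)
    f["inverse_difference_moment_normalized"] = sum(p_diff[k] / (1 + k ** 2 / ng ** 2)
                                                    for k in p_diff)
    return f


def fscore_oracle(X: np.ndarray, y) -> np.ndarray:
    """Per-column F-score via explicit loops over classes and rows."""
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    n_cols = X.shape[1]
    scores = np.zeros(n_cols)
    for j in range(n_cols):
        col = X[:, j]
        grand = col.mean()
        numer = 0.0
        denom = 0.0
        for c in classes:
            vals = col[y == c]
            cbar = vals.mean()
            numer += (cbar - grand) ** 2
            denom += sum((v - cbar) ** 2 for v in vals) / (len(vals) - 1)
        if denom == 0:
            scores[j] = 0.0 if numer == 0 else np.inf
        else:
            scores[j] = numer / denom
    return scores
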