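"""Gray-level co-occurrence matrices and the 22-feature texture battery.

A GLCM at a directed offset (dr, dc) counts, over every in-bounds pixel pair,
how often gray level i co-occurs with gray level j at that displacement.
Accumulation is non-symmetric (one direction per offset) and four offsets are
used by default — horizontal, both diagonals and vertical:
(0,1), (-1,1), (-1,0), (-1,-1).

From each normalized 8x8 table p(i,j) and its marginals the battery computes
22 scalar texture statistics in the Haralick tradition: contrast, correlation,
energy, entropy, homogeneity, cluster shade/prominence, the sum/difference
distributions p_{x+y} and p_{x-y} and their moments/entropies, the two
information measures of correlation, and the normalized inverse-difference
pair.  All entropies use base-2 logs with 0*log(0) := 0.

Degenerate conventions (constant slices): correlations and IMC1 are 0 when
their denominators vanish, keeping every feature finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from braintex.volume_prep import QuantizedSlice

#: the four directed offsets, in fixed reporting order
OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
OFFSET_LABELS = tuple(f"{dr}_{dc}" for dr, dc in OFFSETS)

FEATURE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation1",
    "correlation2",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "max_probability",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

DEFAULT_NG = 8


class DegenerateGLCMError(ValueError):
    """Image too small for the offset: no in-bounds pixel pairs."""


@dataclass
class GLCMTable:
    counts: np.ndarray  # Ng x Ng non-negative ints
    p: np.ndarray       # counts normalized to sum 1
    Ng: int
    offset: tuple[int, int]


@dataclass
class GLCMMarginals:
    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    mu: float           # symmetric GLCM mean, sum of 0.5*(i+j)*p(i,j)
    p_sum: np.ndarray   # p_{x+y}(k), k = 2 .. 2*Ng
    p_diff: np.ndarray  # p_{x-y}(k), k = 0 .. Ng-1
    HX: float
    HY: float
    HXY: float
    HXY1: float
    HXY2: float


def _xlog2(v: np.ndarray) -> np.ndarray:
    """v * log2(v) with the 0*log(0) := 0 convention."""
    out = np.zeros_like(v, dtype=np.float64)
    nz = v > 0
    out[nz] = v[nz] * np.log2(v[nz])
    return out


def compute_glcm(q: QuantizedSlice | np.ndarray, offset: tuple[int, int],
                 n_levels: int = DEFAULT_NG) -> GLCMTable:
    """Count directed co-occurrences of gray levels at one offset."""
    levels = q.levels if isinstance(q, QuantizedSlice) else np.asarray(q)
    dr, dc = int(offset[0]), int(offset[1])
    rows, cols = levels.shape
    if rows - abs(dr) <= 0 or cols - abs(dc) <= 0:
        raise DegenerateGLCMError(f"offset {offset} leaves no pairs in a "
                                  f"{rows}x{cols} image")
    r0, r1 = max(0, -dr), rows - max(0, dr)
    c0, c1 = max(0, -dc), cols - max(0, dc)
    src = levels[r0:r1, c0:c1]
    dst = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    flat = (src.ravel() - 1) * n_levels + (dst.ravel() - 1)
    counts = np.bincount(flat, minlength=n_levels * n_levels)
    counts = counts.reshape(n_levels, n_levels)
    total = counts.sum()
    return GLCMTable(counts=counts, p=counts / total, Ng=n_levels, offset=(dr, dc))


def compute_marginals(g: GLCMTable) -> GLCMMarginals:
    """Marginal distributions, sum/difference distributions and entropies."""
    p, ng = g.p, g.Ng
    lv = np.arange(1, ng + 1, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(lv @ px)
    mu_y = float(lv @ py)
    sigma_x = float(np.sqrt(((lv - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((lv - mu_y) ** 2) @ py))
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    mu = float((0.5 * (ii + jj) * p).sum())

    sums = (ii + jj).astype(int)          # 2 .. 2*Ng
    diffs = np.abs(ii - jj).astype(int)   # 0 .. Ng-1
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, diffs.ravel(), p.ravel())

    HX = float(-_xlog2(px).sum())
    HY = float(-_xlog2(py).sum())
    HXY = float(-_xlog2(p).sum())
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    HXY1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    HXY2 = float(-_xlog2(pxpy).sum())
    return GLCMMarginals(px=px, py=py, mu_x=mu_x, mu_y=mu_y,
                         sigma_x=sigma_x, sigma_y=sigma_y, mu=mu,
                         p_sum=p_sum, p_diff=p_diff,
                         HX=HX, HY=HY, HXY=HXY, HXY1=HXY1, HXY2=HXY2)


def compute_features(g: GLCMTable, m: GLCMMarginals | None = None) -> np.ndarray:
    """The 22 texture statistics of one GLCM, in ``FEATURE_NAMES`` order."""
    if m is None:
        m = compute_marginals(g)
    p, ng = g.p, g.Ng
    lv = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(0, ng, dtype=np.float64)

    autocorrelation = float((ii * jj * p).sum())
    contrast = float((k_diff ** 2 * m.p_diff).sum())
    sig_prod = m.sigma_x * m.sigma_y
    if sig_prod > 0:
        correlation1 = float(((ii - m.mu_x) * (jj - m.mu_y) * p).sum() / sig_prod)
        correlation2 = (autocorrelation - m.mu_x * m.mu_y) / sig_prod
    else:
        correlation1 = correlation2 = 0.0
    centered = ii + jj - m.mu_x - m.mu_y
    cluster_prominence = float((centered ** 4 * p).sum())
    cluster_shade = float((centered ** 3 * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    energy = float((p ** 2).sum())
    entropy = float(-_xlog2(p).sum())
    homogeneity1 = float((p / (1.0 + np.abs(ii - jj))).sum())
    homogeneity2 = float((p / (1.0 + (ii - jj) ** 2)).sum())
    max_probability = float(p.max())
    variance = float(((ii - m.mu) ** 2 * p).sum())
    sum_average = float((k_sum * m.p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * m.p_sum).sum())
    sum_entropy = float(-_xlog2(m.p_sum).sum())
    diff_mean = float((k_diff * m.p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * m.p_diff).sum())
    difference_entropy = float(-_xlog2(m.p_diff).sum())
    hmax = max(m.HX, m.HY)
    imc1 = (m.HXY - m.HXY1) / hmax if hmax > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (m.HXY2 - m.HXY)))))
    idn = float((m.p_diff / (1.0 + k_diff / ng)).sum())
    idmn = float((m.p_diff / (1.0 + k_diff ** 2 / ng ** 2)).sum())

    return np.array([
        autocorrelation, contrast, correlation1, correlation2,
        cluster_prominence, cluster_shade, dissimilarity, energy, entropy,
        homogeneity1, homogeneity2, max_probability, variance, sum_average,
        sum_variance, sum_entropy, difference_variance, difference_entropy,
        imc1, imc2, idn, idmn,
    ])


def features_for_slice(q: QuantizedSlice, offsets=OFFSETS) -> np.ndarray:
    """All 22 features at every offset for one quantized slice.

    Returns an array of shape (22, n_offsets): rows follow ``FEATURE_NAMES``,
    columns follow the offsets in their fixed reporting order.
    """
    cols = [compute_features(compute_glcm(q, off)) for off in offsets]
    return np.column_stack(cols)


def feature_column_labels(offsets=OFFSETS) -> list[str]:
    """Labels ``<feature>.<offset>`` matching ``features_for_slice`` flattened
    row-major (feature-major, then offset)."""
    labels = [f"{dr}_{dc}" for dr, dc in offsets]
    return [f"{feat}.{lab}" for feat in FEATURE_NAMES for lab in labels]
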