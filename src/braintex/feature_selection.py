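"""F-score filter ranking and incremental nested feature subsets.

The F-score of a single feature is the ratio of its between-class scatter to
the sum of its within-class variances,

    F_j = sum_c (xbar_cj - xbar_j)^2  /  sum_c s2_cj

with s2_cj the (n_c - 1)-denominator within-class variance.  The two-class
form generalizes to three classes by summing over the classes present.
Scores are computed on training data only; ranking ties break by ascending
column index so subset sequences are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass
class FScoreRanking:
    scores: np.ndarray          # one non-negative value per column
    order: np.ndarray           # column indices, descending score
    columns: Sequence[str] | None = None
    tie_rule: str = "ascending column index"


def fscore(train_matrix, labels) -> FScoreRanking:
    """Rank every column of ``train_matrix`` by its F-score.

    ``train_matrix`` may be a DataFrame or 2D array; ``labels`` one label per
    row.  Every class needs >= 2 rows.  A column with zero within-class
    variance gets score +inf when its class means differ, 0 when they don't.
    """
    if isinstance(train_matrix, pd.DataFrame):
        X = train_matrix.to_numpy(dtype=np.float64)
        columns = list(train_matrix.columns)
    else:
        X = np.asarray(train_matrix, dtype=np.float64)
        columns = None
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    grand = X.mean(axis=0)
    numer = np.zeros(X.shape[1])
    denom = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training rows")
        numer += (Xc.mean(axis=0) - grand) ** 2
        denom += Xc.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numer / denom
    scores[(denom == 0) & (numer == 0)] = 0.0
    scores[(denom == 0) & (numer > 0)] = np.inf

    order = np.lexsort((np.arange(scores.size), -scores))
    return FScoreRanking(scores=scores, order=order, columns=columns)


def incremental_subsets(r: FScoreRanking, k_min: int = 2,
                        k_max: int | None = None,
                        stride: int = 1) -> Iterator[np.ndarray]:
    """Nested prefixes of the ranking, sizes k_min .. k_max inclusive.

    ``stride`` thins the sweep for speed; the final ``k_max`` subset is always
    yielded.  Subset of size k is exactly the size-(k-1) subset plus the
    next-ranked column.
    """
    n = r.order.size
    if k_max is None:
        k_max = n
    if k_min < 1 or k_min > k_max:
        raise ValueError(f"invalid k range [{k_min}, {k_max}]")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds column count {n}")
    ks = list(range(k_min, k_max + 1, max(1, stride)))
    if ks[-1] != k_max:
        ks.append(k_max)
    for k in ks:
        yield r.order[:k]


def ranking_frame(r: FScoreRanking) -> pd.DataFrame:
    """Tidy ranking table: rank, column descriptor, score."""
    cols = r.columns if r.columns is not None else [str(i) for i in range(r.scores.size)]
    return pd.DataFrame({
        "rank": np.arange(1, r.order.size + 1),
        "column_descriptor": [cols[i] for i in r.order],
        "score": r.scores[r.order],
    })
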