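#!/usr/bin/env python
"""Rank texture features by their F-score for the CN-vs-AD comparison.

Loads the assembled feature matrix from results/ (building it if absent),
z-scores it, takes the stratified 80% training fold of the CN-vs-AD rows and
ranks all 2112 columns by F-score computed on training data only.  Writes
the full ranking to results/fscore_ranking_CN_vs_AD.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from braintex.dataset_assembly import SubjectFeatureMatrix, zscore_columns
from braintex.feature_selection import fscore, ranking_frame
from braintex.classification import SplitSpec, holdout_split

SEED = 20240
RESULTS = Path("results")
FEATURES = Path("scratch/features")


def load_matrix() -> SubjectFeatureMatrix:
    values = FEATURES / "feature_matrix.csv"
    if not values.exists():
        import importlib
        importlib.import_module("02_extract_features").main()
    data = pd.read_csv(values, index_col=0)
    labels = pd.read_csv(FEATURES / "feature_labels.csv", index_col=0)["group"]
    return SubjectFeatureMatrix(data, labels, ("axial", "coronal", "sagittal"))


def main() -> None:
    matrix = load_matrix()
    pair = matrix.subset_groups(["CN", "AD"])
    scaled = zscore_columns(pair)
    Xtr, _, ytr, _ = holdout_split(scaled.data, scaled.groups, SplitSpec(0.8, SEED))
    ranking = fscore(Xtr, ytr)
    df = ranking_frame(ranking)
    df.to_csv(RESULTS / "fscore_ranking_CN_vs_AD.csv", index=False,
              float_format="%.6g")
    print(f"ranked {len(df)} features on {len(Xtr)} training subjects "
          f"(CN vs AD, all three planes)")
    print("top 10 discriminative feature columns:")
    print(df.head(10).to_string(index=False))


if __name__ == "__main__":
    sys.path.insert(0, str(Path(__file__).parent))
    main()
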