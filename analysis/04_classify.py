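#!/usr/bin/env python
"""Benchmark the classifier grid on the synthetic cohort, with and without
feature selection.

Stage 1 (no selection): all 17 grid classifiers on the full feature set for
every pair x plane-set; stage 2: the seven feature-selection classifiers over
an F-score-ranked incremental k-sweep (thinned with stride 128) on the
three-plane matrices.  Per-cell best rows and full sweeps land in results/.
"""

import importlib
import sys
import time
from pathlib import Path

from braintex.classification import ExperimentConfig, run_experiment

SEED = 20240
RESULTS = Path("results")


def main() -> None:
    sys.path.insert(0, str(Path(__file__).parent))
    matrix = importlib.import_module("03_rank_features").load_matrix()
    print(f"cohort: {matrix.data.shape[0]} subjects x {matrix.data.shape[1]} features")

    t0 = time.time()
    no_fs = ExperimentConfig(feature_selection=False, seed=SEED)
    best, _ = run_experiment(matrix, no_fs, out_dir=RESULTS / "no_fs")
    print(f"\nno-selection stage ({time.time()-t0:.0f}s): best row per pair/plane-set")
    print(best.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

    t0 = time.time()
    fs = ExperimentConfig(feature_selection=True, k_stride=128, seed=SEED,
                          plane_sets=(("axial", "coronal", "sagittal"),))
    best_fs, _ = run_experiment(matrix, fs, out_dir=RESULTS / "fs")
    print(f"\nF-score selection stage ({time.time()-t0:.0f}s): "
          f"best row per pair (3 planes)")
    print(best_fs.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print(f"\nfull sweeps: {RESULTS/'no_fs'} and {RESULTS/'fs'}")


if __name__ == "__main__":
    main()
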