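#!/usr/bin/env python
"""Slice every cohort volume and assemble the texture feature matrix.

Reads the NIfTI cohort written by 01_simulate_cohort.py (regenerating it if
absent), cuts 8 slices per anatomical plane per subject, computes the
22-feature co-occurrence battery at 4 offsets per slice, and writes the
subjects x 2112 feature matrix and its row labels under scratch/features/
(a large regenerable intermediate; the small report tables go to results/).
"""

import csv
from pathlib import Path

from braintex.dataset_assembly import write_matrix_csv
from braintex.pipeline import extract_cohort_features
from braintex.volume_prep import load_volume

COHORT = Path("scratch/cohort")
OUT = Path("scratch/features")


def load_cohort():
    meta = COHORT / "cohort.csv"
    if not meta.exists():
        import importlib
        sim = importlib.import_module("01_simulate_cohort")
        sim.main()
    with open(meta) as fh:
        rows = list(csv.DictReader(fh))
    return [load_volume(COHORT / f"{r['subject_id']}.nii",
                        subject_id=r["subject_id"], group=r["group"])
            for r in rows]


def main() -> None:
    vols = load_cohort()
    print(f"loaded {len(vols)} volumes; extracting 24 slices x 88 features each ...")
    matrix = extract_cohort_features(vols)
    OUT.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(matrix, OUT / "feature_matrix.csv", OUT / "feature_labels.csv")
    print(f"feature matrix: {matrix.data.shape[0]} subjects x "
          f"{matrix.data.shape[1]} features "
          f"(22 features x 4 offsets x 8 slices x 3 planes)")
    print(f"wrote {OUT/'feature_matrix.csv'} and {OUT/'feature_labels.csv'}")


if __name__ == "__main__":
    import sys
    sys.path.insert(0, str(Path(__file__).parent))
    main()
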