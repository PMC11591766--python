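"""Positive and null control experiments on the synthetic cohort.

These are the package's built-in sanity experiments:

* the positive control generates a strongly separated two-group cohort
  (default effect sizes), runs the feature-selection benchmarking stage on
  the three-plane matrix with a reduced classifier pair and a thinned k-sweep,
  and returns the best hold-out accuracy — which should be near-perfect;
* the null control generates cohorts whose groups share identical parameters,
  evaluates one fixed classifier on the full feature set over several seeds,
  and returns the per-seed accuracies — whose mean should sit within binomial
  noise of 50%.
"""

from __future__ import annotations

import numpy as np

from braintex.synthetic_data import CohortConfig, generate_cohort
from braintex.pipeline import extract_cohort_features
from braintex.classification import ExperimentConfig, run_experiment

THREE_PLANES = (("axial", "coronal", "sagittal"),)


def positive_control_best_accuracy(seed: int = 0, n_per_group: int = 60,
                                   k_stride: int = 64) -> float:
    """Best 3-plane FS-mode accuracy on a separable CN-vs-AD phantom cohort."""
    cfg = CohortConfig.default({"CN": n_per_group, "AD": n_per_group}, seed=seed)
    matrix = extract_cohort_features(generate_cohort(cfg))
    ec = ExperimentConfig(pairs=(("CN", "AD"),), plane_sets=THREE_PLANES,
                         feature_selection=True,
                         classifiers=("LinSVC", "ExTreeC"),
                         k_stride=k_stride, seed=seed)
    best, _ = run_experiment(matrix, ec)
    return float(best["accuracy"].iloc[0])


def null_control_accuracies(seed: int = 0, n_seeds: int = 5,
                            n_per_group: int = 60) -> list[float]:
    """Hold-out accuracies of logistic regression on null cohorts.

    With identical group parameters the test accuracy per seed is a draw from
    Binomial(n_test, 0.5)/n_test, so the mean over seeds should lie within a
    few binomial standard errors of 50%.
    """
    accs = []
    for k in range(n_seeds):
        s = (seed + k) & 0x7FFFFFFF
        cfg = CohortConfig.null({"CN": n_per_group, "AD": n_per_group}, seed=s)
        matrix = extract_cohort_features(generate_cohort(cfg))
        ec = ExperimentConfig(pairs=(("CN", "AD"),), plane_sets=THREE_PLANES,
                             feature_selection=False, classifiers=("LogReg",),
                             seed=s)
        best, _ = run_experiment(matrix, ec)
        accs.append(float(best["accuracy"].iloc[0]))
    return accs
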