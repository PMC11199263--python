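"""Planted-map recovery runs: simulate a cohort, run both clustering
stages, and score the result against the generator's ground truth.

This is the package's end-to-end validation workhorse: it checks that the
two-level clustering recovers the planted group topographies (spatial
correlation after optimal matching) and that the meta-criterion recovers
the planted model order.

The clustering here uses a scaled-down sampling configuration (fewer
resampling epochs and restarts, a 1-8/1-10 k-range, and a random
GFP-peak subsample per subject) chosen so a full cohort run takes on the
order of a minute on one CPU; the cohort's generative conditions are the
package defaults (105 channels, 250 Hz, K=5 states, ~60 ms durations,
SNR 4).  See docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import (
    ClusteringResult,
    group_level_clustering,
    individual_clustering,
    match_maps,
)
from .synth import CohortGroundTruth, SyntheticSpec, generate_cohort

# Scaled-down two-level clustering configuration (see module docstring).
RECOVERY_CLUSTER_PARAMS = dict(
    k_range=range(1, 9),
    n_epochs=10,
    n_repeats=8,
    coverage_target=0.999,
    max_peaks=800,
)
RECOVERY_GROUP_PARAMS = dict(
    k_range=range(1, 11),
    n_epochs=20,
    n_repeats=10,
    coverage_target=0.999,
)


@dataclass
class RecoveryRun:
    """Result of one simulate-and-recover run."""

    chosen_k: int
    map_abs_corr: np.ndarray  # per matched planted map
    mean_abs_corr: float
    group_result: ClusteringResult
    truth: CohortGroundTruth


def run_map_recovery(
    master_seed: int,
    n_subjects: int = 20,
    minutes: float = 2.0,
    K_true: int = 5,
    snr: float = 4.0,
    cluster_params: dict | None = None,
    group_params: dict | None = None,
) -> RecoveryRun:
    """Generate a cohort and run the full two-level clustering against it.

    The master seed drives both the generator and (via an independent
    spawned stream) all clustering subsampling and restarts.
    """
    spec = SyntheticSpec(
        n_subjects=n_subjects,
        minutes=minutes,
        K_true=K_true,
        snr=snr,
        seed=master_seed,
    )
    cohort, truth = generate_cohort(spec)
    cp = dict(RECOVERY_CLUSTER_PARAMS)
    cp.update(cluster_params or {})
    gp = dict(RECOVERY_GROUP_PARAMS)
    gp.update(group_params or {})
    seeds = np.random.SeedSequence([master_seed, 1]).spawn(len(cohort) + 1)
    indiv = [
        individual_clustering(rec, seed=s, **cp)
        for rec, s in zip(cohort, seeds[:-1])
    ]
    result = group_level_clustering(indiv, seed=seeds[-1], **gp)
    _, corr, _ = match_maps(truth.group_maps, result.maps)
    return RecoveryRun(
        chosen_k=result.chosen_k,
        map_abs_corr=corr,
        mean_abs_corr=float(corr.mean()),
        group_result=result,
        truth=truth,
    )


def run_splithalf_trend(
    master_seed: int,
    n_subjects: int = 30,
    minutes: float = 5.0,
    between_subject_sd: float = 0.3,
    durations: tuple = (1.0, 5.0),
):
    """Even/odd split-half reliability of a synthetic cohort, per duration.

    Backfitting uses the planted group maps (the quantity under test is the
    split-half machinery, not map estimation).  Returns the mean
    Spearman-Brown coefficient of state coverage per duration (outliers
    removed) along with the full tidy table.
    """
    from .reliability import internal_consistency_suite

    spec = SyntheticSpec(
        n_subjects=n_subjects,
        minutes=minutes,
        between_subject_sd=between_subject_sd,
        seed=master_seed,
    )
    cohort, truth = generate_cohort(spec)
    table = internal_consistency_suite(
        cohort, truth.group_maps, durations=durations
    )
    cov = table[(table.metric == "coverage") & table.outliers_removed]
    means = cov.groupby("duration_min").spearman_brown.mean().to_dict()
    return means, table
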