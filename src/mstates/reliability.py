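"""Reliability battery: split-half internal consistency, duration-truncation
stability, outlier screening, and slice-wise Dice overlap of binary volumes.

Internal consistency follows the classic psychometric recipe: each
recording is divided into six equal contiguous segments, the backfitting
stack is run once on the odd segments and once on the even segments, and
the resulting per-subject metric vectors are correlated across subjects.
The half-length Pearson r is stepped up to full length with the
Spearman-Brown formula sb = 2r / (1 + r) and summarized with conventional
qualitative bands (poor / fair / good / excellent).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .backfit import backfit_pipeline
from .clustering import (
    EpochResult,
    TopographySet,
    group_level_clustering,
    individual_clustering,
    match_maps,
)
from .io import BinaryVolume
from .recording import Recording, crop_to_duration

DESCRIPTOR_BANDS = {"poor": 0.40, "fair": 0.60, "good": 0.75}


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

def split_even_odd(
    rec: Recording, n_segments: int = 6
) -> tuple[Recording, Recording]:
    """Split a recording into odd and even contiguous blocks.

    The recording is divided into ``n_segments`` equal blocks (any trailing
    remainder is dropped); the first returned recording concatenates blocks
    1, 3, 5, ... (1-based, "odd"), the second blocks 2, 4, 6, ... ("even").
    With an even ``n_segments`` the halves have identical length.
    """
    if rec.n_samples < n_segments:
        raise ValueError(
            f"recording of {rec.n_samples} samples cannot be split into "
            f"{n_segments} segments"
        )
    block = rec.n_samples // n_segments
    blocks = [
        rec.data[:, i * block : (i + 1) * block] for i in range(n_segments)
    ]
    odd = np.concatenate(blocks[0::2], axis=1)
    even = np.concatenate(blocks[1::2], axis=1)
    return (
        dc_replace(rec, data=odd.copy()),
        dc_replace(rec, data=even.copy()),
    )


def spearman_brown(x, y) -> tuple[float, float]:
    """Pearson r between the two halves and its Spearman-Brown step-up.

    sb = 2r / (1 + r); undefined (NaN) when r = -1 or either half has zero
    variance.  Requires at least 3 paired finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired finite values")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one half")
    import warnings

    with warnings.catch_warnings():
        # numerically near-constant inputs: scipy returns NaN, which is the
        # "undefined" reporting we want, without the warning
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        r = float(stats.pearsonr(x, y)[0])
    if not np.isfinite(r):
        raise ValueError("correlation undefined (near-constant input)")
    sb = np.nan if r <= -1 else 2 * r / (1 + r)
    return r, float(sb)


def boxplot_outliers(values, factor: float = 3.0) -> np.ndarray:
    """Tukey-style extreme-outlier mask: outside [Q1 - f*IQR, Q3 + f*IQR].

    Quartiles use linear interpolation between order statistics (the
    default of mainstream statistical environments).  NaNs are never
    flagged.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    with np.errstate(invalid="ignore"):
        return (values < lo) | (values > hi)


def qualitative_descriptor(value: float) -> str:
    """Band a reliability coefficient: poor < 0.40 <= fair < 0.60 <= good
    < 0.75 <= excellent."""
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if value < DESCRIPTOR_BANDS["poor"]:
        return "poor"
    if value < DESCRIPTOR_BANDS["fair"]:
        return "fair"
    if value < DESCRIPTOR_BANDS["good"]:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Internal consistency suite
# ---------------------------------------------------------------------------

def _half_metrics(rec: Recording, maps: TopographySet, backfit_params: dict,
                  boundaries=None):
    """Tidy rows (metric, state/direction, value) for one half-recording."""
    _, metrics, trans = backfit_pipeline(
        rec, maps, boundaries=boundaries, **backfit_params
    )
    rows = {}
    for k in range(metrics.K):
        rows[("gev", str(k + 1))] = metrics.gev[k]
        rows[("duration", str(k + 1))] = metrics.mean_duration_ms[k]
        rows[("coverage", str(k + 1))] = metrics.coverage[k]
        rows[("occurrence", str(k + 1))] = metrics.occurrence[k]
    for a in range(trans.K):
        for b in range(trans.K):
            if a != b:
                rows[("transition", f"{a + 1}->{b + 1}")] = trans.observed[a, b]
    return rows


def internal_consistency_suite(
    cohort: Sequence[Recording],
    maps: TopographySet,
    durations: Sequence[float] = (1, 2, 3, 4, 5),
    n_segments: int = 6,
    outlier_factor: float = 3.0,
    backfit_params: dict | None = None,
    respect_joins: bool = True,
) -> pd.DataFrame:
    """Even/odd split-half reliability of every metric, state and duration.

    For each duration: crop each subject, split into even/odd segment
    halves, run the full backfitting stack on each half, and correlate the
    per-subject values of every metric cell (metric x state, plus every
    transition direction) across subjects.  Returns a tidy frame with both
    the all-subjects coefficients and the coefficients after removing
    extreme boxplot outliers (per cell, per half).  Cells whose coefficient
    is undefined (zero variance, too few subjects) are reported as NaN
    rather than aborting the table.
    """
    backfit_params = backfit_params or {}
    records = []
    for dur in durations:
        halves = []
        for rec in cohort:
            cropped = crop_to_duration(rec, dur)
            odd, even = split_even_odd(cropped, n_segments)
            if respect_joins:
                block = cropped.n_samples // n_segments
                n_blocks = (n_segments + 1) // 2
                joins = tuple(block * i for i in range(1, n_blocks))
            else:
                joins = None
            halves.append(
                (
                    _half_metrics(odd, maps, backfit_params, joins),
                    _half_metrics(even, maps, backfit_params, joins),
                )
            )
        cells = sorted({c for h in halves for c in h[0]})
        for metric, state in cells:
            a = np.array([h[0].get((metric, state), np.nan) for h in halves])
            b = np.array([h[1].get((metric, state), np.nan) for h in halves])
            for remove_outliers in (False, True):
                xa, xb = a.copy(), b.copy()
                if remove_outliers:
                    try:
                        bad = boxplot_outliers(xa, outlier_factor) | (
                            boxplot_outliers(xb, outlier_factor)
                        )
                    except ValueError:
                        bad = np.zeros(len(xa), dtype=bool)
                    xa[bad] = np.nan
                    xb[bad] = np.nan
                try:
                    r, sb = spearman_brown(xa, xb)
                    desc = (
                        qualitative_descriptor(sb) if np.isfinite(sb) else None
                    )
                except ValueError:
                    r, sb, desc = np.nan, np.nan, None
                records.append(
                    {
                        "duration_min": dur,
                        "metric": metric,
                        "state": state,
                        "outliers_removed": remove_outliers,
                        "pearson_r": r,
                        "spearman_brown": sb,
                        "descriptor": desc,
                        "n_subjects_used": int(
                            np.sum(np.isfinite(xa) & np.isfinite(xb))
                        ),
                    }
                )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Stability across data durations
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Cross-duration stability: map correlations and metric agreement."""

    map_correlations: pd.DataFrame  # duration_a, duration_b, state, abs_corr
    chosen_k: dict[float, int]
    metric_pairs: pd.DataFrame  # per duration pair x metric x state
    metrics_long: pd.DataFrame  # tidy per subject x duration x metric x state
    subsample_sweep: pd.DataFrame | None = None  # per (n, duration): k, corr


def stability_suite(
    cohort: Sequence[Recording],
    durations: Sequence[float] = (1, 2, 3, 4, 5),
    cluster_params: dict | None = None,
    group_params: dict | None = None,
    backfit_params: dict | None = None,
    seed=None,
    subsample_sizes: Sequence[int] = (),
) -> StabilityReport:
    """Re-run the full two-level clustering at each data duration and
    compare maps and backfit metrics across durations.

    Maps of every duration are matched (by |spatial correlation|) to the
    longest duration's maps so that state labels correspond; per metric,
    state and duration pair the paired differences across subjects are
    summarized (mean, SD) together with the cross-duration Pearson r.
    ``subsample_sizes`` optionally re-runs stages 1-2 on random subject
    subsets of each size at every duration, reporting the chosen k and the
    mean map correlation to the full-cohort solution.
    """
    cluster_params = cluster_params or {}
    group_params = group_params or {}
    backfit_params = backfit_params or {}
    durations = sorted(durations)
    ss = np.random.SeedSequence(seed)
    per_dur_seeds = ss.spawn(len(durations))
    maps_by_dur: dict[float, TopographySet] = {}
    chosen_k: dict[float, int] = {}
    for dur, dseed in zip(durations, per_dur_seeds):
        subj_seeds = dseed.spawn(len(cohort) + 1)
        indiv: list[list[EpochResult]] = []
        for rec, sseed in zip(cohort, subj_seeds[:-1]):
            indiv.append(
                individual_clustering(
                    crop_to_duration(rec, dur), seed=sseed, **cluster_params
                )
            )
        result = group_level_clustering(
            indiv, seed=subj_seeds[-1], **group_params
        )
        maps_by_dur[dur] = result.maps
        chosen_k[dur] = result.chosen_k
    # Align every duration's maps to the longest duration's ordering.
    ref = maps_by_dur[durations[-1]]
    aligned: dict[float, TopographySet] = {}
    for dur in durations:
        pairs, _, _ = match_maps(ref, maps_by_dur[dur])
        order = [j for _, j in sorted(pairs)]
        aligned[dur] = TopographySet(
            maps=maps_by_dur[dur].maps[order],
            provenance={"duration_min": dur},
        )
    corr_rows = []
    for i, da in enumerate(durations):
        for db in durations[i + 1 :]:
            pairs, corr, _ = match_maps(aligned[da], aligned[db])
            for (ia, _), c in zip(pairs, corr):
                corr_rows.append(
                    {
                        "duration_a": da,
                        "duration_b": db,
                        "state": ia + 1,
                        "abs_corr": float(c),
                    }
                )
    # Backfit each duration with its aligned maps.
    metric_rows = []
    for dur in durations:
        for s, rec in enumerate(cohort):
            _, metrics, trans = backfit_pipeline(
                crop_to_duration(rec, dur), aligned[dur], **backfit_params
            )
            frame = metrics.to_frame()
            frame["subject"] = s
            frame["duration_min"] = dur
            metric_rows.append(frame)
            tframe = trans.to_frame()
            tframe["subject"] = s
            tframe["duration_min"] = dur
            tframe["metric"] = "transition"
            tframe["state"] = (
                tframe["from"].astype(str) + "->" + tframe["to"].astype(str)
            )
            metric_rows.append(
                tframe[["subject", "duration_min", "metric", "state", "observed"]]
                .rename(columns={"observed": "value"})
            )
    metrics_long = pd.concat(metric_rows, ignore_index=True)
    pair_rows = []
    for i, da in enumerate(durations):
        for db in durations[i + 1 :]:
            wa = metrics_long[metrics_long.duration_min == da]
            wb = metrics_long[metrics_long.duration_min == db]
            merged = wa.merge(
                wb, on=["subject", "metric", "state"], suffixes=("_a", "_b")
            )
            for (metric, state), grp in merged.groupby(["metric", "state"]):
                diff = grp.value_a - grp.value_b
                ok = np.isfinite(grp.value_a) & np.isfinite(grp.value_b)
                r = (
                    float(stats.pearsonr(grp.value_a[ok], grp.value_b[ok])[0])
                    if ok.sum() >= 3
                    and grp.value_a[ok].std() > 0
                    and grp.value_b[ok].std() > 0
                    else np.nan
                )
                pair_rows.append(
                    {
                        "duration_a": da,
                        "duration_b": db,
                        "metric": metric,
                        "state": state,
                        "mean_diff": float(np.nanmean(diff)),
                        "sd_diff": float(np.nanstd(diff, ddof=1))
                        if ok.sum() > 1
                        else np.nan,
                        "pearson_r": r,
                        "n": int(ok.sum()),
                    }
                )
    sweep = None
    if subsample_sizes:
        sweep_rows = []
        rng = np.random.default_rng(ss.spawn(1)[0])
        for n in subsample_sizes:
            n = min(int(n), len(cohort))
            pick = sorted(rng.choice(len(cohort), n, replace=False))
            for dur in durations:
                sub_seeds = np.random.SeedSequence(
                    rng.integers(2**31)
                ).spawn(n + 1)
                sub_indiv = [
                    individual_clustering(
                        crop_to_duration(cohort[i], dur), seed=sd,
                        **cluster_params,
                    )
                    for i, sd in zip(pick, sub_seeds[:-1])
                ]
                sub_res = group_level_clustering(
                    sub_indiv, seed=sub_seeds[-1], **group_params
                )
                _, c, _ = match_maps(aligned[dur], sub_res.maps)
                sweep_rows.append(
                    {
                        "n_subjects": n,
                        "duration_min": dur,
                        "chosen_k": sub_res.chosen_k,
                        "mean_abs_corr_to_full": float(c.mean()),
                    }
                )
        sweep = pd.DataFrame(sweep_rows)
    return StabilityReport(
        map_correlations=pd.DataFrame(corr_rows),
        chosen_k=chosen_k,
        metric_pairs=pd.DataFrame(pair_rows),
        metrics_long=metrics_long,
        subsample_sweep=sweep,
    )


# ---------------------------------------------------------------------------
# Slice-wise Dice
# ---------------------------------------------------------------------------

def dice_slicewise(a: BinaryVolume, b: BinaryVolume) -> tuple[float, np.ndarray]:
    """Mean slice-wise Dice similarity coefficient of two binary volumes.

    For each of the three axes, the Dice coefficient 2|A&B|/(|A|+|B|) is
    computed on every slice where either volume has at least one nonzero
    voxel and averaged over those slices; the returned mean averages the
    three per-axis values.  Returns ``(mean, per_axis)``.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError("volume shapes differ")
    if a.n_voxels == 0 and b.n_voxels == 0:
        raise ValueError("both volumes are empty")
    ga = a.grid.astype(bool)
    gb = b.grid.astype(bool)
    per_axis = []
    for axis in range(3):
        vals = []
        for i in range(ga.shape[axis]):
            sa = np.take(ga, i, axis=axis)
            sb_ = np.take(gb, i, axis=axis)
            na, nb = int(sa.sum()), int(sb_.sum())
            if na == 0 and nb == 0:
                continue
            vals.append(2.0 * int((sa & sb_).sum()) / (na + nb))
        per_axis.append(float(np.mean(vals)) if vals else np.nan)
    per_axis = np.array(per_axis)
    return float(np.nanmean(per_axis)), per_axis


def dice_global(a: BinaryVolume, b: BinaryVolume) -> float:
    """Whole-volume Dice coefficient 2|A&B|/(|A|+|B|)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("volume shapes differ")
    inter = int((a.grid.astype(bool) & b.grid.astype(bool)).sum())
    denom = a.n_voxels + b.n_voxels
    if denom == 0:
        raise ValueError("both volumes are empty")
    return 2.0 * inter / denom
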