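"""Stage 3: backfitting group maps to continuous data.

Every sample of a (median-GFP-normalized) recording is labeled with the
group map it correlates best with, polarity ignored, subject to a 0.50
correlation floor; the label sequence is then smoothed with a windowed
Besag-style penalty and improbably short segments are dissolved into their
neighbors.  From the final segmentation the module computes the standard
temporal descriptors (GEV, mean duration, coverage, occurrence) and
first-order Markov transition statistics (observed, expected, and their
ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .clustering import TopographySet, gfp as _gfp
from .recording import Recording


def _ms_to_samples(ms: float, srate: float) -> int:
    """Milliseconds to samples, rounding half up (32 ms at 250 Hz -> 8)."""
    return int(np.floor(ms * srate / 1000.0 + 0.5))


def normalize_by_median_gfp(rec: Recording) -> Recording:
    """Divide the whole recording by the scalar median of its GFP series.

    Equalizes overall scalp-potential scale across subjects (skull
    conductivity differences); the result has median GFP exactly 1.
    """
    med = float(np.median(_gfp(rec)))
    if med <= 0:
        raise ValueError("median GFP is zero; cannot normalize")
    return dc_replace(rec, data=rec.data / med)


@dataclass
class Segmentation:
    """Per-sample microstate labeling of one recording.

    ``labels`` take values 1..K, with 0 = unlabeled (correlation floor not
    met).  ``abs_corr`` is each sample's |spatial correlation| with the map
    of its label (0 where unlabeled); ``corr`` keeps the full K x T
    map-sample correlation matrix for smoothing and GEV recomputation.
    """

    labels: np.ndarray
    abs_corr: np.ndarray
    gfp: np.ndarray
    srate: float
    K: int
    corr: np.ndarray | None = None
    maps: TopographySet | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.abs_corr = np.asarray(self.abs_corr, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        n = len(self.labels)
        if len(self.abs_corr) != n or len(self.gfp) != n:
            raise ValueError("labels/abs_corr/gfp length mismatch")
        if np.any((self.abs_corr < -1e-12) | (self.abs_corr > 1 + 1e-12)):
            raise ValueError("abs_corr outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.labels)


def backfit(
    rec: Recording, maps: TopographySet, min_corr: float = 0.50
) -> Segmentation:
    """Winner-take-all labeling of every sample with the best group map.

    The winner is the map with the largest |spatial correlation| with the
    sample's topography (polarity ignored; ties go to the smallest state
    index).  Samples whose winning correlation is below ``min_corr`` stay
    unlabeled (0).
    """
    if rec.n_channels != maps.n_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels but maps have "
            f"{maps.n_channels}"
        )
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    corr = maps.maps @ (X / safe)  # (K, T)
    corr[:, norms == 0] = 0.0
    a = np.abs(corr)
    # ties to the smallest index: argmax returns the first maximum
    winner = np.argmax(a, axis=0)
    best = a[winner, np.arange(a.shape[1])]
    labels = np.where(best >= min_corr, winner + 1, 0)
    abs_corr = np.where(labels > 0, best, 0.0)
    return Segmentation(
        labels=labels,
        abs_corr=abs_corr,
        gfp=_gfp(rec),
        srate=rec.srate,
        K=maps.k,
        corr=corr,
        maps=maps,
    )


def smooth_labels(
    seg: Segmentation,
    window_half_size_ms: float = 32.0,
    besag_factor: float = 10.0,
    max_sweeps: int = 50,
) -> Segmentation:
    """Windowed label smoothing discouraging isolated short labels.

    Each labeled sample t is (re)assigned to the state minimizing

        misfit_k(t) / (2 * sigma^2)  -  besag_factor * N_k(t)

    where ``misfit_k(t) = (1 - corr(v_t, map_k)^2) * GFP(t)^2`` is the
    per-sample unexplained topographic variance, ``N_k(t)`` counts samples
    within +/- w (w = window half-size in samples) currently labeled k, and
    ``sigma^2`` is the mean misfit of the current labeling — the
    noise-variance normalization of the classical microstate segmentation
    smoother, which makes the score scale-free (invariant to microvolt
    rescaling) and the Besag factor dimensionless.  Sweeps (simultaneous
    update, sigma^2 refreshed each sweep) repeat until the labeling is a
    fixed point or ``max_sweeps``.  Unlabeled samples are never relabeled
    and do not count as neighbors.  After convergence ``abs_corr`` is
    recomputed against each sample's final map.
    """
    if seg.corr is None:
        raise ValueError("segmentation lacks the map-correlation matrix")
    w = max(1, _ms_to_samples(window_half_size_ms, seg.srate))
    T = seg.n_samples
    K = seg.K
    g2 = seg.gfp**2
    misfit = (1.0 - seg.corr**2) * g2[None, :]  # (K, T)
    labels = seg.labels.copy()
    labeled = labels > 0
    if not np.any(labeled):
        return _relabeled(seg, labels)
    kernel = np.ones(2 * w + 1)
    tt = np.arange(T)
    for _ in range(max_sweeps):
        cur = misfit[np.maximum(labels - 1, 0), tt]
        sigma2 = float(np.mean(cur[labeled]))
        sigma2 = max(sigma2, 1e-30)
        counts = np.empty((K, T))
        for k in range(K):
            onehot = (labels == k + 1).astype(float)
            counts[k] = np.convolve(onehot, kernel, mode="same")
        score = misfit / (2.0 * sigma2) - besag_factor * counts
        new = np.where(labeled, np.argmin(score, axis=0) + 1, 0)
        if np.array_equal(new, labels):
            break
        labels = new
    return _relabeled(seg, labels)


def _relabeled(seg: Segmentation, labels: np.ndarray) -> Segmentation:
    """Rebuild a segmentation after labels changed, refreshing abs_corr."""
    if seg.corr is not None:
        idx = np.maximum(labels - 1, 0)
        abs_corr = np.where(
            labels > 0, np.abs(seg.corr[idx, np.arange(len(labels))]), 0.0
        )
    else:
        abs_corr = np.where(labels == seg.labels, seg.abs_corr, np.nan)
    return Segmentation(
        labels=labels,
        abs_corr=abs_corr,
        gfp=seg.gfp,
        srate=seg.srate,
        K=seg.K,
        corr=seg.corr,
        maps=seg.maps,
    )


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encoding: list of (label, start, length)."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    starts = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    lengths = np.diff(np.r_[starts, len(labels)])
    return [
        (int(labels[s]), int(s), int(ln)) for s, ln in zip(starts, lengths)
    ]


def _chunk_bounds(n: int, boundaries) -> list[tuple[int, int]]:
    """Half-open [start, end) chunks from boundary start offsets."""
    if not boundaries:
        return [(0, n)]
    cuts = sorted({0, n, *(int(b) for b in boundaries if 0 < int(b) < n)})
    return list(zip(cuts[:-1], cuts[1:]))


def _runs_bounded(labels: np.ndarray, boundaries=None):
    """RLE that never lets a run span a chunk boundary."""
    out = []
    for a, b in _chunk_bounds(len(labels), boundaries):
        out.extend(
            [(lab, start + a, ln) for lab, start, ln in _runs(labels[a:b])]
        )
    return out


def _slice_segmentation(seg: Segmentation, a: int, b: int) -> Segmentation:
    return Segmentation(
        labels=seg.labels[a:b],
        abs_corr=seg.abs_corr[a:b],
        gfp=seg.gfp[a:b],
        srate=seg.srate,
        K=seg.K,
        corr=None if seg.corr is None else seg.corr[:, a:b],
        maps=seg.maps,
    )


def _concat_labels(seg: Segmentation, parts) -> Segmentation:
    return _relabeled(seg, np.concatenate([p.labels for p in parts]))


def reject_small_segments(
    seg: Segmentation, min_duration_ms: float = 32.0
) -> Segmentation:
    """Dissolve segments shorter than ``min_duration_ms`` into neighbors.

    A short interior run of length L gives its first ceil(L/2) samples to
    the preceding segment and the remaining floor(L/2) to the following
    one; short runs touching a sequence edge merge entirely into their only
    neighbor.  Unlabeled runs are treated like any other state.  Applied
    iteratively (merged runs only grow) until no fixable short run remains.
    """
    min_len = _ms_to_samples(min_duration_ms, seg.srate)
    runs = [[lab, length] for lab, _, length in _runs(seg.labels)]
    i = 0
    while len(runs) > 1 and i < len(runs):
        lab, length = runs[i]
        if length >= min_len:
            i += 1
            continue
        if i == 0:
            runs[1][1] += length
            del runs[0]
        elif i == len(runs) - 1:
            runs[-2][1] += length
            del runs[-1]
        else:
            first = int(np.ceil(length / 2))
            runs[i - 1][1] += first
            runs[i + 1][1] += length - first
            del runs[i]
            if runs[i - 1][0] == runs[i][0]:
                runs[i - 1][1] += runs[i][1]
                del runs[i]
        i = max(i - 1, 0)
    labels = np.concatenate(
        [np.full(length, lab, dtype=int) for lab, length in runs]
    )
    return _relabeled(seg, labels)


@dataclass
class TemporalMetrics:
    """Per-state temporal descriptors of a segmentation."""

    gev: np.ndarray            # per state, fraction of total GFP^2 variance
    mean_duration_ms: np.ndarray  # NaN where the state never (validly) occurs
    coverage: np.ndarray
    occurrence: np.ndarray     # segments per second
    total_gev: float
    unlabeled_fraction: float
    K: int
    edge_exclusion: bool = True

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: state, metric, value."""
        rows = []
        for k in range(self.K):
            for metric, arr in (
                ("gev", self.gev),
                ("duration", self.mean_duration_ms),
                ("coverage", self.coverage),
                ("occurrence", self.occurrence),
            ):
                rows.append({"state": k + 1, "metric": metric, "value": arr[k]})
        return pd.DataFrame(rows)


def temporal_metrics(
    seg: Segmentation,
    edge_exclusion: bool = True,
    boundaries=None,
) -> TemporalMetrics:
    """GEV, mean duration, coverage and occurrence per state.

    GEV_k sums ``(GFP * |corr|)^2`` over samples labeled k, relative to the
    total ``GFP^2``; coverage is the labeled-sample fraction; duration is
    the mean length of maximal runs and occurrence their rate per second.
    With ``edge_exclusion`` (default), runs touching the recording edges —
    truncated by the crop — are excluded from duration and occurrence
    (coverage and GEV keep them).  ``boundaries`` (sample offsets of
    within-recording joins, e.g. between concatenated split-half blocks)
    split runs and count as additional edges.  Absent states report
    duration NaN and zero elsewhere.
    """
    T = seg.n_samples
    if T == 0:
        raise ValueError("empty segmentation")
    K = seg.K
    total_g2 = float(np.sum(seg.gfp**2))
    gev = np.zeros(K)
    coverage = np.zeros(K)
    duration = np.full(K, np.nan)
    occurrence = np.zeros(K)
    runs = _runs_bounded(seg.labels, boundaries)
    chunks = _chunk_bounds(T, boundaries)
    starts = {a for a, _ in chunks}
    ends = {b for _, b in chunks}
    total_s = T / seg.srate
    for k in range(1, K + 1):
        mask = seg.labels == k
        coverage[k - 1] = mask.sum() / T
        if total_g2 > 0:
            gev[k - 1] = float(
                np.sum((seg.gfp[mask] * seg.abs_corr[mask]) ** 2) / total_g2
            )
        k_runs = [r for r in runs if r[0] == k]
        if edge_exclusion:
            k_runs = [
                (lab, s, ln) for lab, s, ln in k_runs
                if s not in starts and s + ln not in ends
            ]
        if k_runs:
            lengths = np.array([ln for _, _, ln in k_runs], dtype=float)
            duration[k - 1] = lengths.mean() * 1000.0 / seg.srate
            occurrence[k - 1] = len(k_runs) / total_s
    unlabeled = float(np.sum(seg.labels == 0) / T)
    return TemporalMetrics(
        gev=gev,
        mean_duration_ms=duration,
        coverage=coverage,
        occurrence=occurrence,
        total_gev=float(gev.sum()),
        unlabeled_fraction=unlabeled,
        K=K,
        edge_exclusion=edge_exclusion,
    )


@dataclass
class TransitionStats:
    """First-order Markov transition statistics between microstates.

    ``observed[a, b]`` is the fraction of a's outgoing transitions that go
    to b; ``expected[a, b]`` is the occurrence-matched null,
    ``seg_count(b) / sum_{c != a} seg_count(c)``; ``normalized`` is their
    elementwise ratio (NaN where expected is 0).  Diagonals are
    structurally 0 (a segment cannot transition to itself).
    """

    observed: np.ndarray
    expected: np.ndarray
    normalized: np.ndarray
    n_transitions: int
    K: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in range(self.K):
            for b in range(self.K):
                if a == b:
                    continue
                rows.append(
                    {
                        "from": a + 1,
                        "to": b + 1,
                        "observed": self.observed[a, b],
                        "expected": self.expected[a, b],
                        "normalized": self.normalized[a, b],
                    }
                )
        return pd.DataFrame(rows)


def transition_probabilities(seg: Segmentation, boundaries=None) -> TransitionStats:
    """Observed, expected and normalized transition probabilities.

    Transitions are counted between consecutive labeled segments; an
    unlabeled run breaks the chain, and so does a ``boundaries`` join (no
    transition across either).  Requires at least two labeled segments.
    """
    runs = _runs_bounded(seg.labels, boundaries)
    K = seg.K
    labeled_runs = [r for r in runs if r[0] > 0]
    if len(labeled_runs) < 2:
        raise ValueError("need at least 2 labeled segments for transitions")
    interior_joins = {
        a for a, _ in _chunk_bounds(seg.n_samples, boundaries) if a > 0
    }
    counts = np.zeros((K, K))
    for prev, nxt in zip(runs[:-1], runs[1:]):
        if nxt[1] in interior_joins:  # chain broken at the chunk join
            continue
        if prev[0] > 0 and nxt[0] > 0:
            counts[prev[0] - 1, nxt[0] - 1] += 1
    seg_count = np.zeros(K)
    for lab, _, _ in labeled_runs:
        seg_count[lab - 1] += 1
    out_totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(out_totals > 0, counts / out_totals, 0.0)
        expected = np.zeros((K, K))
        for a in range(K):
            denom = seg_count.sum() - seg_count[a]
            if denom > 0:
                expected[a] = seg_count / denom
            expected[a, a] = 0.0
        normalized = np.where(expected > 0, observed / expected, np.nan)
    np.fill_diagonal(observed, 0.0)
    np.fill_diagonal(normalized, 0.0)
    return TransitionStats(
        observed=observed,
        expected=expected,
        normalized=normalized,
        n_transitions=int(counts.sum()),
        K=K,
    )


def backfit_pipeline(
    rec: Recording,
    maps: TopographySet,
    min_corr: float = 0.50,
    window_half_size_ms: float = 32.0,
    besag_factor: float = 10.0,
    min_segment_ms: float = 32.0,
    normalize: bool = True,
    edge_exclusion: bool = True,
    boundaries=None,
) -> tuple[Segmentation, TemporalMetrics, TransitionStats]:
    """Full stage-3 stack: normalize, backfit, smooth, reject, measure.

    ``boundaries`` marks within-recording joins (sample start offsets of
    concatenated pieces, e.g. split-half blocks): smoothing windows and
    segment rejection are confined to each piece, joins count as edges for
    duration/occurrence, and transition chains break there.
    """
    if normalize:
        rec = normalize_by_median_gfp(rec)
    seg = backfit(rec, maps, min_corr=min_corr)
    if boundaries:
        parts = []
        for a, b in _chunk_bounds(seg.n_samples, boundaries):
            part = _slice_segmentation(seg, a, b)
            part = smooth_labels(part, window_half_size_ms, besag_factor)
            part = reject_small_segments(part, min_segment_ms)
            parts.append(part)
        seg = _concat_labels(seg, parts)
    else:
        seg = smooth_labels(seg, window_half_size_ms, besag_factor)
        seg = reject_small_segments(seg, min_segment_ms)
    metrics = temporal_metrics(
        seg, edge_exclusion=edge_exclusion, boundaries=boundaries
    )
    trans = transition_probabilities(seg, boundaries=boundaries)
    return seg, metrics, trans
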