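"""Synthetic EEG cohorts with planted microstate structure.

The generator emulates the kind of infant resting-state data the pipeline
targets: a dense net (105 channels by default) sampled at 250 Hz, a small
number of quasi-stable scalp topographies (K = 5) alternating with ~50-80 ms
mean segment durations, an oscillatory amplitude envelope that flips the
polarity of the active topography within segments (exercising polarity
invariance by construction), spatially white sensor noise at a controlled
GFP-level SNR, and per-subject variation of both the maps (small rotations)
and the temporal parameters (log-normal jitter).

Segment lengths are geometric (memoryless), so the planted sequence is an
exact first-order Markov chain and the transition statistics under test
have a known ground truth.  Everything is deterministic under a master
seed; per-subject and per-component seeds are spawned with numpy's
SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import TopographySet, spatial_correlation
from .io import BinaryVolume
from .montage import ChannelMontage, spherical_cap_montage
from .recording import Recording


def uniform_offdiag_transitions(K: int) -> np.ndarray:
    """Row-stochastic K x K matrix, zero diagonal, uniform off-diagonal."""
    if K == 1:
        return np.zeros((1, 1))
    tm = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(tm, 0.0)
    return tm


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic cohort.

    ``snr`` is the ratio of signal GFP RMS to noise GFP RMS;
    ``between_subject_sd`` is the SD of the log-normal multiplicative
    jitter applied per subject and state to duration and transition
    parameters; ``map_jitter_corr`` is the spatial correlation between each
    subject's maps and the shared group maps.
    """

    n_channels: int = 105
    srate: float = 250.0
    K_true: int = 5
    mean_duration_ms: float = 60.0
    transition_matrix: np.ndarray | None = None
    snr: float = 4.0
    envelope_freq_hz: float = 10.0
    n_subjects: int = 20
    minutes: float = 5.0
    seed: int = 0
    between_subject_sd: float = 0.2
    map_jitter_corr: float = 0.95
    max_abs_corr: float = 0.6
    signal_gfp_uv: float = 5.0

    def __post_init__(self):
        if self.transition_matrix is None:
            self.transition_matrix = uniform_offdiag_transitions(self.K_true)
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (self.K_true, self.K_true):
            raise ValueError("transition_matrix must be K x K")
        if np.any(np.abs(np.diag(tm)) > 0):
            raise ValueError("transition_matrix diagonal must be zero")
        if self.K_true > 1 and np.any(np.abs(tm.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition_matrix rows must sum to 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.mean_duration_ms <= 0:
            raise ValueError("mean_duration_ms must be positive")
        self.transition_matrix = tm

    @property
    def n_samples(self) -> int:
        return int(round(self.minutes * 60 * self.srate))


def _dipole_map(montage: ChannelMontage, rng: np.random.Generator) -> np.ndarray:
    """Scalp field of a randomly placed, randomly oriented dipole pair."""
    pos = montage.positions
    radius = float(np.linalg.norm(pos, axis=1).mean())
    v = np.zeros(montage.n_channels)
    for _ in range(2):
        loc = rng.normal(size=3)
        loc *= (0.3 + 0.4 * rng.random()) * radius / np.linalg.norm(loc)
        moment = rng.normal(size=3)
        moment /= np.linalg.norm(moment)
        r = pos - loc
        dist = np.linalg.norm(r, axis=1)
        v += (r @ moment) / dist**3
    return v


def generate_prototype_maps(
    K: int,
    montage: ChannelMontage,
    max_abs_corr: float = 0.6,
    seed=None,
    max_retries: int = 500,
) -> TopographySet:
    """K dipolar prototype maps with bounded pairwise |spatial correlation|.

    Maps are accepted greedily; a candidate correlating more than
    ``max_abs_corr`` (absolute) with any accepted map is rejected.  Raises
    after ``max_retries`` consecutive rejections.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 < max_abs_corr < 1:
        raise ValueError("max_abs_corr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < K:
        cand = _dipole_map(montage, rng)
        if accepted:
            corr = np.abs(spatial_correlation(np.array(accepted), cand)).max()
            if corr > max_abs_corr:
                tries += 1
                if tries > max_retries:
                    raise RuntimeError(
                        f"could not place {K} maps with |corr| <= {max_abs_corr}; "
                        "use a larger montage or a looser bound"
                    )
                continue
        accepted.append(cand)
        tries = 0
    return TopographySet(
        maps=np.array(accepted), provenance={"kind": "planted", "seed": seed}
    )


def generate_state_sequence(
    K: int,
    n_samples: int,
    mean_duration_ms: float | np.ndarray,
    transition_matrix: np.ndarray,
    srate: float,
    seed=None,
) -> np.ndarray:
    """Planted label sequence: geometric segment lengths, Markov successors.

    ``mean_duration_ms`` may be a scalar or a per-state vector.  Labels are
    1..K.  The first state is drawn uniformly.
    """
    rng = np.random.default_rng(seed)
    means = np.broadcast_to(
        np.asarray(mean_duration_ms, dtype=float), (K,)
    ) * srate / 1000.0
    p = np.clip(1.0 / np.maximum(means, 1.0), 1e-9, 1.0)
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(K))
    t = 0
    while t < n_samples:
        length = int(rng.geometric(p[state]))
        labels[t : t + length] = state + 1
        t += length
        if K > 1:
            state = int(rng.choice(K, p=transition_matrix[state]))
    return labels


def generate_recording(
    maps: TopographySet,
    labels: np.ndarray,
    spec: SyntheticSpec,
    seed=None,
    montage: ChannelMontage | None = None,
) -> Recording:
    """Render a label sequence into a noisy average-referenced recording.

    At sample t the signal is ``maps[label(t)] * A(t)`` with a sinusoidal
    envelope ``A(t) = sin(2 pi f t / srate + phi_segment)`` (phase
    redrawn per segment), scaled so the signal/noise GFP RMS ratio equals
    ``spec.snr``; noise is spatially white Gaussian.  The sinusoid changes
    sign within segments, so the rendered topography flips polarity while
    the state stays the same.
    """
    if maps.k < int(labels.max()):
        raise ValueError("fewer maps than planted states")
    rng = np.random.default_rng(seed)
    T = len(labels)
    t = np.arange(T)
    # one random envelope phase per segment
    starts = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    seg_lens = np.diff(np.r_[starts, T])
    phase = np.repeat(rng.uniform(0, 2 * np.pi, size=len(starts)), seg_lens)
    A = np.sin(2 * np.pi * spec.envelope_freq_hz * t / spec.srate + phase)
    S = maps.maps[labels - 1].T * A[None, :]  # (C, T), zero-mean columns
    sig_gfp_rms = float(np.sqrt(np.mean(S.std(axis=0, ddof=0) ** 2)))
    if sig_gfp_rms == 0:
        sig_gfp_rms = 1.0
    S *= spec.signal_gfp_uv / sig_gfp_rms
    noise = rng.standard_normal(S.shape)
    noise -= noise.mean(axis=0, keepdims=True)
    noise_gfp_rms = float(np.sqrt(np.mean(noise.std(axis=0, ddof=0) ** 2)))
    noise *= spec.signal_gfp_uv / (spec.snr * noise_gfp_rms)
    if montage is None:
        montage = spherical_cap_montage(maps.n_channels)
    # S and noise are both column-zero-mean by construction, so the sum is
    # already average-referenced
    return Recording(
        data=S + noise, srate=spec.srate, montage=montage, is_avg_ref=True
    )


def _perturb_maps(
    maps: TopographySet, target_corr: float, rng: np.random.Generator
) -> TopographySet:
    """Rotate each map toward a random orthogonal direction so that
    corr(subject map, group map) = ``target_corr`` exactly."""
    out = []
    for v in maps.maps:
        u = rng.standard_normal(len(v))
        u -= u.mean()
        u -= (u @ v) * v
        u /= np.linalg.norm(u)
        theta = np.arccos(np.clip(target_corr, -1, 1))
        out.append(np.cos(theta) * v + np.sin(theta) * u)
    return TopographySet(maps=np.array(out), provenance=dict(maps.provenance))


@dataclass
class CohortGroundTruth:
    """Everything the generator planted, for recovery tests."""

    group_maps: TopographySet
    subject_maps: list[TopographySet]
    labels: list[np.ndarray]
    mean_duration_ms: list[np.ndarray]
    transition_matrices: list[np.ndarray]
    spec: SyntheticSpec


def generate_cohort(
    spec: SyntheticSpec, montage: ChannelMontage | None = None
) -> tuple[list[Recording], CohortGroundTruth]:
    """Generate a cohort of recordings sharing planted group maps.

    Per subject: state-wise mean durations and transition-row weights are
    jittered log-normally (``between_subject_sd``), the shared maps are
    rotated to ``map_jitter_corr`` spatial correlation, and fresh noise is
    drawn.  All seeds are spawned from ``spec.seed``.
    """
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if montage is None:
        montage = spherical_cap_montage(spec.n_channels)
    ss = np.random.SeedSequence(spec.seed)
    s_maps, s_subjects = ss.spawn(2)
    group_maps = generate_prototype_maps(
        spec.K_true, montage, spec.max_abs_corr, seed=s_maps
    )
    recordings: list[Recording] = []
    subject_maps: list[TopographySet] = []
    all_labels: list[np.ndarray] = []
    durations: list[np.ndarray] = []
    tms: list[np.ndarray] = []
    for child in s_subjects.spawn(spec.n_subjects):
        rng = np.random.default_rng(child)
        sd = spec.between_subject_sd
        dur = spec.mean_duration_ms * np.exp(
            rng.normal(0, sd, size=spec.K_true) if sd > 0 else np.zeros(spec.K_true)
        )
        tm = spec.transition_matrix.copy()
        if sd > 0 and spec.K_true > 1:
            jitter = np.exp(rng.normal(0, sd, size=tm.shape))
            tm = tm * jitter
            np.fill_diagonal(tm, 0.0)
            tm /= tm.sum(axis=1, keepdims=True)
        smaps = (
            _perturb_maps(group_maps, spec.map_jitter_corr, rng)
            if spec.map_jitter_corr < 1
            else group_maps
        )
        labels = generate_state_sequence(
            spec.K_true, spec.n_samples, dur, tm, spec.srate, seed=rng
        )
        rec = generate_recording(smaps, labels, spec, seed=rng, montage=montage)
        recordings.append(rec)
        subject_maps.append(smaps)
        all_labels.append(labels)
        durations.append(dur)
        tms.append(tm)
    truth = CohortGroundTruth(
        group_maps=group_maps,
        subject_maps=subject_maps,
        labels=all_labels,
        mean_duration_ms=durations,
        transition_matrices=tms,
        spec=spec,
    )
    return recordings, truth


def generate_volume_pair(
    shape: tuple[int, int, int],
    n_blobs: int = 3,
    overlap_fraction: float = 0.8,
    seed=None,
    target_size: int | None = None,
) -> tuple[BinaryVolume, BinaryVolume]:
    """Two blobby binary volumes with a prescribed global Dice overlap.

    Both volumes have the same voxel count S, sharing exactly
    ``round(overlap_fraction * S)`` voxels, so the global Dice
    2|A&B|/(|A|+|B|) equals ``overlap_fraction`` up to the rounding of one
    voxel.  A is a union of random balls; B reuses a contiguous part of A
    and grows the remainder just outside A's boundary.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    total = int(np.prod(shape))
    if target_size is None:
        target_size = max(total // 8, n_blobs)
    S = int(target_size)
    if 2 * S - int(round(overlap_fraction * S)) > total:
        raise ValueError("shape too small for the requested blob volumes")
    grid_idx = np.indices(shape).reshape(3, -1).T  # (total, 3)
    # Build A: distance to nearest of n_blobs random centers, take S closest.
    centers = rng.random((n_blobs, 3)) * (np.array(shape) - 1)
    dist_a = np.min(
        np.linalg.norm(grid_idx[:, None, :] - centers[None, :, :], axis=2), axis=1
    )
    order_a = np.argsort(dist_a, kind="stable")
    a_lin = order_a[:S]
    A = np.zeros(total, dtype=np.uint8)
    A[a_lin] = 1
    # B: the O voxels of A closest to the first center, plus the nearest
    # non-A voxels to fill up to S.
    O = int(round(overlap_fraction * S))
    d0 = np.linalg.norm(grid_idx - centers[0], axis=1)
    a_sorted_by_d0 = a_lin[np.argsort(d0[a_lin], kind="stable")]
    b_core = a_sorted_by_d0[:O]
    non_a = order_a[S:]
    b_ext = non_a[np.argsort(d0[non_a], kind="stable")][: S - O]
    B = np.zeros(total, dtype=np.uint8)
    B[b_core] = 1
    B[b_ext] = 1
    return (
        BinaryVolume(grid=A.reshape(shape)),
        BinaryVolume(grid=B.reshape(shape)),
    )
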