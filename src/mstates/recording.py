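"""Continuous EEG recordings and channel-space preprocessing helpers.

A :class:`Recording` is a channels x samples matrix in microvolts with a
sampling rate and montage.  Everything downstream (GFP, clustering,
backfitting) assumes average-referenced data, i.e. each time point's channel
values sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .montage import ChannelMontage

_AVG_REF_RTOL = 1e-8


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    srate: float
    montage: ChannelMontage
    is_avg_ref: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (channels x samples)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} data rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if self.is_avg_ref and self.n_samples:
            col_sums = np.abs(self.data.sum(axis=0))
            scale = np.abs(self.data).max(axis=0)
            if np.any(col_sums > _AVG_REF_RTOL * np.maximum(scale, 1e-30) + 1e-12):
                raise ValueError("is_avg_ref set but columns do not sum to zero")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def times_ms(self) -> np.ndarray:
        """0-based sample times in milliseconds."""
        return np.arange(self.n_samples) * 1000.0 / self.srate


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract each column's mean.

    Idempotent; marks the result ``is_avg_ref``.
    """
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, is_avg_ref=True)


def crop_to_duration(rec: Recording, minutes: float) -> Recording:
    """Keep the first ``minutes`` of the recording.

    Crops are nested: ``crop(rec, 1)`` is an exact prefix of ``crop(rec, 2)``.
    """
    n = int(round(minutes * 60.0 * rec.srate))
    if n > rec.n_samples:
        raise ValueError(
            f"requested {n} samples ({minutes} min at {rec.srate} Hz) but "
            f"recording has only {rec.n_samples}"
        )
    return replace(rec, data=rec.data[:, :n].copy())


def spatial_filter(
    rec: Recording,
    n_neighbors: int = 6,
    mad_factor: float = 3.0,
    blend: float = 0.5,
    chunk: int = 4096,
) -> Recording:
    """Instantaneous topographic outlier rejection plus smoothing.

    For every time point each channel is compared to the median of its
    ``n_neighbors`` nearest channels.  Channels whose residual from that
    median exceeds ``mad_factor`` times the MAD of all channel residuals at
    that time point are replaced by the neighbor median; all channels are
    then blended ``blend``/(1-``blend``) with their neighbor medians.  The
    output is re-average-referenced.

    This is a neighbor-median approximation of the topographic filters used
    by interactive microstate tools; it is optional everywhere it appears.
    """
    if n_neighbors < 3:
        raise ValueError("n_neighbors must be >= 3")
    nbr = rec.montage.neighbor_indices(n_neighbors)  # raises if too many
    out = np.empty_like(rec.data)
    X = rec.data
    for start in range(0, rec.n_samples, chunk):
        sl = slice(start, min(start + chunk, rec.n_samples))
        block = X[:, sl]  # (C, t)
        med = np.median(block[nbr, :], axis=1)  # (C, t)
        resid = block - med
        center = np.median(resid, axis=0, keepdims=True)
        mad = np.median(np.abs(resid - center), axis=0, keepdims=True)
        bad = np.abs(resid - center) > mad_factor * mad
        cleaned = np.where(bad, med, block)
        out[:, sl] = (1.0 - blend) * cleaned + blend * med
    filtered = replace(rec, data=out, is_avg_ref=False)
    return average_reference(filtered)
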