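"""Sensor montages: channel names plus 3D head-centered positions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered set of EEG channels with head-centered 3D positions.

    Positions are in arbitrary but mutually consistent units (typically
    meters); only relative geometry is ever used (nearest-neighbor lookup
    for the spatial filter, dipole projection for synthetic maps).
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        if len(names) < 2:
            raise ValueError("montage needs at least 2 channels")
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ValueError("channel names must be unique and non-empty")
        if pos.shape != (len(names), 3):
            raise ValueError(
                f"positions shape {pos.shape} != ({len(names)}, 3)"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def neighbor_indices(self, n_neighbors: int) -> np.ndarray:
        """Indices of the ``n_neighbors`` nearest channels to each channel.

        Returns an (n_channels, n_neighbors) integer array; a channel is
        never its own neighbor.
        """
        if n_neighbors >= self.n_channels:
            raise ValueError(
                f"n_neighbors={n_neighbors} must be < n_channels={self.n_channels}"
            )
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        return np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]


def spherical_cap_montage(n_channels: int = 105, radius: float = 0.09) -> ChannelMontage:
    """Quasi-uniform electrode layout on the upper ~3/4 of a sphere.

    A Fibonacci lattice restricted to z > -0.45*radius, mimicking a dense
    geodesic net covering scalp down to just below the ears.  Deterministic.
    """
    z_lo = -0.45
    # Fibonacci lattice over the cap [z_lo, 1] in normalized z.
    golden = (1 + 5**0.5) / 2
    i = np.arange(n_channels)
    z = z_lo + (1.0 - z_lo) * (i + 0.5) / n_channels
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(np.clip(1 - z**2, 0, None))
    pos = radius * np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    names = tuple(f"E{k + 1}" for k in range(n_channels))
    return ChannelMontage(names=names, positions=pos)
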