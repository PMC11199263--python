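"""Readers/writers for recordings, topography sets, segmentations, volumes.

Native interchange format for continuous EEG is a channels x samples TSV
(channels as rows, no header) next to a JSON sidecar::

    {"srate_hz": 250.0, "channel_names": [...], "reference": "average",
     "units": "uV", "positions": [[x, y, z], ...]}

EEGLAB ``.set``, BrainVision ``.vhdr`` and EDF are read through MNE when it
is installed.  3D binary volumes use NIfTI-1 via nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import ChannelMontage
from .recording import Recording

TABULAR = "tabular"
KNOWN_FORMATS = (TABULAR, "eeglab-set", "brainvision", "edf")


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording as TSV + JSON sidecar (``<stem>.json``)."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.17g")
    sidecar = {
        "srate_hz": rec.srate,
        "channel_names": list(rec.montage.names),
        "reference": "average" if rec.is_avg_ref else "unknown",
        "units": "uV",
        "positions": rec.montage.positions.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_tabular(path: Path) -> Recording:
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    for key in ("srate_hz", "channel_names"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field '{key}'")
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as err:
        raise ValueError(f"non-numeric cell in {path}: {err}") from err
    names = meta["channel_names"]
    if data.shape[0] != len(names):
        raise ValueError(
            f"{path}: {data.shape[0]} rows but sidecar lists "
            f"{len(names)} channels"
        )
    positions = meta.get("positions")
    if positions is None:
        # Positions are only needed by the spatial filter / simulator;
        # fall back to a placeholder ring so the montage invariants hold.
        angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
        positions = np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(len(names))]
        )
    montage = ChannelMontage(names=tuple(names), positions=np.asarray(positions))
    return Recording(
        data=data,
        srate=float(meta["srate_hz"]),
        montage=montage,
        is_avg_ref=meta.get("reference") == "average",
    )


def _read_mne(path: Path, format_name: str) -> Recording:
    import mne  # optional dependency, only needed for container formats

    readers = {
        "eeglab-set": mne.io.read_raw_eeglab,
        "brainvision": mne.io.read_raw_brainvision,
        "edf": mne.io.read_raw_edf,
    }
    raw = readers[format_name](str(path), preload=True, verbose="error")
    raw.pick("eeg")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    mont = raw.get_montage()
    if mont is not None:
        pos_map = mont.get_positions()["ch_pos"]
        positions = np.array([pos_map[ch] for ch in raw.ch_names])
    else:
        angles = np.linspace(0, 2 * np.pi, len(raw.ch_names), endpoint=False)
        positions = np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(len(raw.ch_names))]
        )
    montage = ChannelMontage(names=tuple(raw.ch_names), positions=positions)
    return Recording(data=data, srate=float(raw.info["sfreq"]), montage=montage)


def read_recording(path: str | Path, format_name: str = TABULAR) -> Recording:
    """Read a continuous EEG recording.

    ``format_name`` is one of ``tabular`` (native TSV + sidecar),
    ``eeglab-set``, ``brainvision`` or ``edf`` (via MNE).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_name == TABULAR:
        return _read_tabular(path)
    if format_name in KNOWN_FORMATS:
        return _read_mne(path, format_name)
    raise ValueError(f"unknown format '{format_name}' (choose from {KNOWN_FORMATS})")


# ---------------------------------------------------------------------------
# Topography sets (microstate maps)
# ---------------------------------------------------------------------------

def write_maps(path: str | Path, maps: np.ndarray, channel_names) -> None:
    """Write K maps as a channels x K TSV with a channel-name header column."""
    maps = np.asarray(maps)
    df = pd.DataFrame(
        maps.T, index=list(channel_names),
        columns=[str(k + 1) for k in range(maps.shape[0])],
    )
    df.to_csv(path, sep="\t", index_label="channel", float_format="%.17g")


def read_maps(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read maps written by :func:`write_maps`; returns (K x N array, names)."""
    df = pd.read_csv(path, sep="\t", index_col="channel")
    return df.to_numpy().T, list(df.index)


# ---------------------------------------------------------------------------
# Segmentations
# ---------------------------------------------------------------------------

def write_segmentation(path: str | Path, seg) -> None:
    """Per-sample TSV: sample, time_ms, label, abs_corr, gfp."""
    n = len(seg.labels)
    df = pd.DataFrame(
        {
            "sample": np.arange(n),
            "time_ms": np.arange(n) * 1000.0 / seg.srate,
            "label": seg.labels,
            "abs_corr": seg.abs_corr,
            "gfp": seg.gfp,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_segmentation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Binary volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryVolume:
    """3D 0/1 grid with per-axis voxel size in millimeters."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("grid must be 3D")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("grid values must be 0 or 1")
        grid = grid.astype(np.uint8)
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


def write_volume(path: str | Path, vol: BinaryVolume) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.grid.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_volume(path: str | Path, binarize: bool = False, threshold: float = 0.5) -> BinaryVolume:
    """Read a NIfTI volume as a BinaryVolume.

    Non-binary data raises unless ``binarize=True`` (values > ``threshold``
    become 1).
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.isin(data, (0, 1)).all():
        if not binarize:
            raise ValueError(
                f"{path} is not binary; pass binarize=True to threshold it"
            )
        data = (data > threshold).astype(np.uint8)
    return BinaryVolume(grid=data.astype(np.uint8), voxel_size=voxel_size)
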