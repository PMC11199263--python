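"""End-to-end pipeline: simulate/ingest -> cluster -> backfit -> reliability.

A :class:`PipelineConfig` collects every stage parameter with its default;
``run_pipeline`` executes the stages in order into a run directory and
writes a manifest of SHA-256 hashes of every artifact, so two runs with
the same config and master seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .backfit import backfit_pipeline
from .clustering import group_level_clustering, individual_clustering
from .io import write_maps, write_recording, write_segmentation
from .recording import crop_to_duration, spatial_filter
from .reliability import internal_consistency_suite
from .synth import SyntheticSpec, generate_cohort

# Which defaults come from the published protocol vs this implementation;
# rendered into the config file by `mstates init`.
PARAM_PROVENANCE = {
    "n_channels": "protocol (105-channel net)",
    "srate": "protocol (250 Hz)",
    "individual_epochs": "protocol (50 epochs)",
    "individual_repeats": "protocol (repeat 50 times)",
    "individual_k_max": "protocol (1-12 clusters)",
    "group_epochs": "protocol (100 epochs)",
    "group_repeats": "protocol (repeat 100 times)",
    "group_k_max": "protocol (1-15 clusters)",
    "coverage_target": "protocol (99.9% of the data)",
    "min_corr": "protocol (minimum correlation 0.50)",
    "smooth_half_ms": "protocol (window half-size 32 ms)",
    "besag_factor": "protocol (Besag factor 10)",
    "min_segment_ms": "protocol (segments smaller than 32 ms)",
    "split_segments": "protocol (six equal segments)",
    "outlier_factor": "protocol (Q3 + 3*IQR rule)",
}


@dataclass
class PipelineConfig:
    """All stage parameters with their protocol defaults."""

    # simulation (only used when no input directory is given)
    n_subjects: int = 10
    minutes: float = 2.0
    n_channels: int = 105
    srate: float = 250.0
    K_true: int = 5
    snr: float = 4.0
    mean_duration_ms: float = 60.0
    between_subject_sd: float = 0.2
    # spatial filter
    apply_spatial_filter: bool = False
    spatial_filter_neighbors: int = 6
    # stage 1
    individual_epochs: int = 50
    individual_repeats: int = 50
    individual_k_min: int = 1
    individual_k_max: int = 12
    coverage_target: float = 0.999
    max_peaks: int | None = None
    # stage 2
    group_epochs: int = 100
    group_repeats: int = 100
    group_k_min: int = 1
    group_k_max: int = 15
    force_k: int | None = None
    # stage 3
    min_corr: float = 0.50
    smooth_half_ms: float = 32.0
    besag_factor: float = 10.0
    min_segment_ms: float = 32.0
    # reliability
    split_segments: int = 6
    outlier_factor: float = 3.0
    reliability_durations: tuple = ()
    # global
    seed: int = 0

    def to_yaml(self, path: str | Path, annotate: bool = True) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            tag = PARAM_PROVENANCE.get(f.name, "implementation default")
            if isinstance(value, (tuple, list)):
                dumped = f"{f.name}: [{', '.join(str(v) for v in value)}]"
            else:
                dumped = yaml.safe_dump(
                    {f.name: value}, default_flow_style=False
                ).strip()
            lines.append(f"{dumped}" + (f"  # {tag}" if annotate else ""))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reliability_durations" in raw:
            raw["reliability_durations"] = tuple(raw["reliability_durations"] or ())
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
) -> Path:
    """Run simulate/ingest -> stage 1 -> stage 2 -> stage 3 -> reliability.

    With ``input_dir``, tabular recordings (``*.tsv`` + sidecars) are
    ingested instead of simulating.  Artifacts: config snapshot, per-subject
    recordings/segmentations, group maps, tidy metric and transition
    tables, the split-half reliability table, a stage log with seeds, and
    ``manifest.json`` mapping every artifact to its SHA-256 hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    t0 = time.time()

    config.to_yaml(out / "config.yaml", annotate=False)
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_cluster, s_group = ss.spawn(3)

    # --- ingest or simulate -----------------------------------------------
    if input_dir is not None:
        paths = sorted(Path(input_dir).glob("*.tsv"))
        if not paths:
            raise FileNotFoundError(f"no .tsv recordings in {input_dir}")
        cohort = [mio.read_recording(p) for p in paths]
        names = [p.stem for p in paths]
    else:
        spec = SyntheticSpec(
            n_channels=config.n_channels,
            srate=config.srate,
            K_true=config.K_true,
            mean_duration_ms=config.mean_duration_ms,
            snr=config.snr,
            n_subjects=config.n_subjects,
            minutes=config.minutes,
            seed=int(s_sim.generate_state(1)[0] % (2**31)),
            between_subject_sd=config.between_subject_sd,
        )
        cohort, _ = generate_cohort(spec)
        names = [f"sub-{i + 1:02d}" for i in range(len(cohort))]
    needed = config.minutes
    for name, rec in zip(names, cohort):
        if rec.duration_s < needed * 60 - 1e-9:
            raise ValueError(
                f"subject {name} has {rec.duration_s / 60:.2f} min but the "
                f"config requires {needed} min"
            )
    cohort = [crop_to_duration(rec, needed) for rec in cohort]
    if config.apply_spatial_filter:
        cohort = [
            spatial_filter(rec, config.spatial_filter_neighbors) for rec in cohort
        ]
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for name, rec in zip(names, cohort):
        write_recording(rec_dir / f"{name}.tsv", rec)
    log.append({"stage": "ingest", "n_subjects": len(cohort)})

    # --- stage 1 ----------------------------------------------------------
    subj_seeds = s_cluster.spawn(len(cohort))
    indiv = []
    for name, rec, sseed in zip(names, cohort, subj_seeds):
        epochs = individual_clustering(
            rec,
            k_range=range(config.individual_k_min, config.individual_k_max + 1),
            n_epochs=config.individual_epochs,
            coverage_target=config.coverage_target,
            n_repeats=config.individual_repeats,
            seed=sseed,
            max_peaks=config.max_peaks,
        )
        indiv.append(epochs)
        log.append(
            {
                "stage": "individual_clustering",
                "subject": name,
                "chosen_k": [ep.chosen_k for ep in epochs],
            }
        )

    # --- stage 2 ----------------------------------------------------------
    result = group_level_clustering(
        indiv,
        k_range=range(config.group_k_min, config.group_k_max + 1),
        n_epochs=config.group_epochs,
        n_repeats=config.group_repeats,
        coverage_target=config.coverage_target,
        seed=s_group,
        force_k=config.force_k,
    )
    write_maps(out / "group_maps.tsv", result.maps.maps, cohort[0].montage.names)
    crit = pd.DataFrame(result.criteria).T.sort_index()
    crit["meta"] = result.meta_curve
    crit.to_csv(out / "criteria_curves.csv", index_label="k")
    log.append(
        {
            "stage": "group_clustering",
            "chosen_k": result.chosen_k,
            "forced": result.forced,
        }
    )

    # --- stage 3 ----------------------------------------------------------
    seg_dir = out / "segmentations"
    seg_dir.mkdir(exist_ok=True)
    metric_frames, trans_frames = [], []
    for name, rec in zip(names, cohort):
        seg, metrics, trans = backfit_pipeline(
            rec,
            result.maps,
            min_corr=config.min_corr,
            window_half_size_ms=config.smooth_half_ms,
            besag_factor=config.besag_factor,
            min_segment_ms=config.min_segment_ms,
        )
        write_segmentation(seg_dir / f"{name}_seg.tsv", seg)
        mf = metrics.to_frame()
        mf.insert(0, "subject", name)
        mf.insert(1, "duration_min", config.minutes)
        metric_frames.append(mf)
        tf = trans.to_frame()
        tf.insert(0, "subject", name)
        trans_frames.append(tf)
    pd.concat(metric_frames, ignore_index=True).to_csv(
        out / "metrics.csv", index=False
    )
    pd.concat(trans_frames, ignore_index=True).to_csv(
        out / "transitions.csv", index=False
    )
    log.append({"stage": "backfitting", "n_subjects": len(cohort)})

    # --- reliability ------------------------------------------------------
    if config.reliability_durations:
        table = internal_consistency_suite(
            cohort,
            result.maps,
            durations=config.reliability_durations,
            n_segments=config.split_segments,
            outlier_factor=config.outlier_factor,
        )
        table.to_csv(out / "split_half.csv", index=False)
        log.append({"stage": "reliability", "cells": len(table)})

    # --- provenance -------------------------------------------------------
    (out / "log.json").write_text(
        json.dumps({"stages": log, "wall_s": time.time() - t0}, indent=1)
    )
    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "log.json")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
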