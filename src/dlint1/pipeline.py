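"""End-to-end orchestration of the morphology and electrophysiology arms.

Reads a YAML run configuration, executes the enabled analyses, and writes
tidy CSV reports plus a JSON run log carrying provenance (config hash, seed,
input digests, row counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ephys_features import (
    PERIODS,
    SpikeTrainTrial,
    compare_groups_ephys,
    features_per_neuron,
    rate_profile,
)
from .morph_io import MorphTree, SubregionSet, load_manifest_trees, split_subregions
from .morphometrics import compare_groups_scalar, compute_all_measures
from .spatial_density import (
    classify_voxels,
    clip_length_to_shells,
    clip_length_to_voxels,
    normalized_change,
    percent_pl_annotate,
    shell_group_test,
    voxel_group_test,
)

__all__ = ["RunConfig", "run_morphology", "run_ephys", "auto_split", "load_spike_csv"]

logger = logging.getLogger(__name__)

SHELL_SUBREGIONS = ("WA", "DB", "VB")  # MB excluded: unbranched, < 50 μm


@dataclass
class RunConfig:
    """Run configuration (YAML-serializable, schema version 1)."""

    output_dir: str = "out"
    seed: int = 0
    version: int = 1
    # morphology arm
    manifest: str | None = None
    scalar: bool = True
    shell: bool = True
    voxel: bool = True
    partition: bool = True
    shell_thickness: float = 20.0
    voxel_size: float = 20.0
    voxel_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shell_center: tuple[float, float, float] | None = None  # default: reference WA root
    pl_threshold: float = 90.0
    alpha: float = 0.05
    bonferroni: bool = True
    # ephys arm
    spike_csv: str | None = None
    ephys: bool = True
    profile_resolution: float = 0.005
    profile_bootstrap: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for name in ("shell_thickness", "voxel_size", "pl_threshold", "alpha"):
            if getattr(cfg, name) <= 0:
                raise ValueError(f"config {name} must be positive")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def auto_split(tree: MorphTree) -> SubregionSet:
    """Split a whole arborization whose root has exactly two children; the
    daughter reaching the higher mean y coordinate is taken as dorsal."""
    kids = tree.children_of(tree.root.id)
    if len(kids) != 2:
        raise ValueError(
            f"{tree.name}: auto subregion split needs a root with exactly two "
            f"children, found {len(kids)}"
        )
    mean_y = []
    for k in kids:
        ids = tree.subtree_ids(k)
        mean_y.append(np.mean([tree.node(i).position[1] for i in ids]))
    dorsal, ventral = (kids[0], kids[1]) if mean_y[0] >= mean_y[1] else (kids[1], kids[0])
    return split_subregions(tree, dorsal, ventral)


def _provenance(cfg: RunConfig, inputs: dict[str, str]) -> dict:
    return dict(
        package_version=__version__,
        config_hash=cfg.digest(),
        seed=cfg.seed,
        input_digests=inputs,
    )


def run_morphology(cfg: RunConfig) -> dict[str, Path]:
    """Execute the enabled morphology analyses; returns {report: path}."""
    if cfg.manifest is None:
        raise ValueError("morphology run requires a manifest path in the config")
    t_start = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    trees = load_manifest_trees(cfg.manifest)
    groups = {t.group for t in trees}
    if not {"NE", "F"} <= groups:
        raise ValueError(
            f"manifest {cfg.manifest} must provide morphologies for both groups "
            f"NE and F, found {sorted(groups)}"
        )
    subsets = [auto_split(t) for t in trees]
    written: dict[str, Path] = {}
    log = _provenance(cfg, {"manifest": _file_digest(cfg.manifest)})
    log["stages"] = []

    def stage(name: str, t0: float, rows: int) -> None:
        entry = dict(stage=name, wall_s=round(time.perf_counter() - t0, 3), rows=rows)
        log["stages"].append(entry)
        logger.info("%s: %d rows in %.2fs", name, rows, entry["wall_s"])

    regparams = sorted({t.regparam_id for t in trees})
    first_rp = regparams[0]

    if cfg.scalar:
        t0 = time.perf_counter()
        # one representative registration per sample: scalar measures are
        # per-neuron quantities, not nuisance-replicated ones
        scalar_rows = pd.concat(
            [
                compute_all_measures(s)
                for s in subsets
                if s.WA.regparam_id in ("", first_rp)
            ],
            ignore_index=True,
        )
        scalar_rows.to_csv(out / "scalar_measures.csv", index=False)
        summary = compare_groups_scalar(scalar_rows, alpha=cfg.alpha)
        summary.to_csv(out / "scalar_group_summary.csv", index=False)
        written["scalar_measures"] = out / "scalar_measures.csv"
        written["scalar_group_summary"] = out / "scalar_group_summary.csv"
        stage("scalar", t0, len(summary))

    if cfg.shell:
        t0 = time.perf_counter()
        if cfg.shell_center is not None:
            center = tuple(cfg.shell_center)
        else:
            ref = min(subsets, key=lambda s: (s.group != "NE", s.sample_id))
            center = ref.WA.root.position
        shell_frames = []
        for subregion in SHELL_SUBREGIONS:
            profiles = [
                clip_length_to_shells(tr, center, cfg.shell_thickness)
                for s in subsets
                if (tr := s.get(subregion)) is not None and tr.total_length() > 0
            ]
            if not profiles:
                continue
            df = shell_group_test(profiles, alpha=cfg.alpha)
            df.insert(0, "subregion", subregion)
            shell_frames.append(df)
        shells = pd.concat(shell_frames, ignore_index=True)
        shells.to_csv(out / "shell_analysis.csv", index=False)
        written["shell_analysis"] = out / "shell_analysis.csv"
        stage("shell", t0, len(shells))

    if cfg.voxel or cfg.partition:
        t0 = time.perf_counter()
        annotations = [percent_pl_annotate(s.WA) for s in subsets]
        voxel_frames, part_frames, change_frames = [], [], []
        for subregion in SHELL_SUBREGIONS:
            fields = [
                clip_length_to_voxels(tr, cfg.voxel_origin, cfg.voxel_size)
                for s in subsets
                if (tr := s.get(subregion)) is not None and tr.total_length() > 0
            ]
            if not fields:
                continue
            part = (
                classify_voxels(fields, annotations, cfg.pl_threshold)
                if cfg.partition
                else None
            )
            vox_df, part_df = voxel_group_test(fields, part, alpha=cfg.alpha)
            vox_df.insert(0, "subregion", subregion)
            voxel_frames.append(vox_df)
            if not part_df.empty:
                part_df.insert(0, "subregion", subregion)
                part_frames.append(part_df)
            change = normalized_change(fields)
            change_frames.append(
                pd.DataFrame(
                    [
                        dict(subregion=subregion, i=k[0], j=k[1], k=k[2],
                             delta_pdl_norm=v)
                        for k, v in change.values.items()
                    ]
                )
            )
        if cfg.voxel and voxel_frames:
            voxels = pd.concat(voxel_frames, ignore_index=True)
            voxels.to_csv(out / "voxel_analysis.csv", index=False)
            written["voxel_analysis"] = out / "voxel_analysis.csv"
            changes = pd.concat(change_frames, ignore_index=True)
            changes.to_csv(out / "voxel_normalized_change.csv", index=False)
            written["voxel_normalized_change"] = out / "voxel_normalized_change.csv"
            stage("voxel", t0, len(voxels))
        if cfg.partition and part_frames:
            parts = pd.concat(part_frames, ignore_index=True)
            parts.to_csv(out / "partition_summary.csv", index=False)
            written["partition_summary"] = out / "partition_summary.csv"
            stage("partition", t0, len(parts))

    log["wall_s"] = round(time.perf_counter() - t_start, 3)
    with open(out / "morphology_run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    written["run_log"] = out / "morphology_run_log.json"
    return written


def load_spike_csv(path: str | Path) -> dict[str, list[SpikeTrainTrial]]:
    """Read trial-segmented spike times from the pipeline's CSV format.

    Columns: neuron_id, trial_id, spike_time_s, onset_s, offset_s, group.
    A row with an empty spike_time_s marks a spike-free trial.
    """
    df = pd.read_csv(path)
    out: dict[str, list[SpikeTrainTrial]] = {}
    for (nid, _tid), grp in df.groupby(["neuron_id", "trial_id"], sort=True):
        spikes = grp["spike_time_s"].dropna().to_numpy(dtype=float)
        first = grp.iloc[0]
        out.setdefault(str(nid), []).append(
            SpikeTrainTrial(
                np.sort(spikes),
                stim_offset=float(first["offset_s"]),
                stim_onset=float(first["onset_s"]),
                neuron_id=str(nid),
                group=str(first["group"]),
            )
        )
    return out


def run_ephys(cfg: RunConfig) -> dict[str, Path]:
    """Execute the electrophysiology arm; returns {report: path}."""
    if cfg.spike_csv is None:
        raise ValueError("ephys run requires a spike_csv path in the config")
    t0 = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_by_neuron = load_spike_csv(cfg.spike_csv)
    groups = {ts[0].group for ts in trials_by_neuron.values() if ts}
    for g in ("NE", "F"):
        if g not in groups:
            raise ValueError(
                f"spike input {cfg.spike_csv} has no neurons in group {g!r}; "
                "both NE and F are required for comparison"
            )
    features = features_per_neuron(trials_by_neuron)
    features.to_csv(out / "ephys_features.csv", index=False)
    comparison = compare_groups_ephys(features, alpha=cfg.alpha)
    comparison.to_csv(out / "ephys_group_comparison.csv", index=False)

    profile_frames = []
    rng = np.random.default_rng(cfg.seed)
    for g in ("NE", "F"):
        pooled = [
            t
            for ts in trials_by_neuron.values()
            for t in ts
            if t.group == g
        ]
        prof = rate_profile(
            pooled,
            resolution=cfg.profile_resolution,
            span=(-1.0, pooled[0].stim_offset + 0.2),
            n_boot=cfg.profile_bootstrap,
            rng=rng,
        )
        profile_frames.append(
            pd.DataFrame(
                dict(group=g, time_s=prof.times, rate_hz=prof.rate,
                     ci_low=prof.ci_low, ci_high=prof.ci_high)
            )
        )
    profiles = pd.concat(profile_frames, ignore_index=True)
    profiles.to_csv(out / "rate_profiles.csv", index=False)

    log = _provenance(cfg, {"spike_csv": _file_digest(cfg.spike_csv)})
    log["n_neurons"] = len(trials_by_neuron)
    log["wall_s"] = round(time.perf_counter() - t0, 3)
    with open(out / "ephys_run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return {
        "ephys_features": out / "ephys_features.csv",
        "ephys_group_comparison": out / "ephys_group_comparison.csv",
        "rate_profiles": out / "rate_profiles.csv",
        "run_log": out / "ephys_run_log.json",
    }
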