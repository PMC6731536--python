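"""Synthetic morphologies and spike data with known ground truth.

The generators emulate the study conditions so every pipeline stage can be
exercised end to end without the deposited recordings:

* Morphologies: 6-vs-6 groups of branched SWC trees.  Because the study
  compares co-registered reconstructions of the *same identified neuron*
  across animals, one archetype tree is grown per population by stochastic
  binary outgrowth (two labeled daughter trunks, dorsal/ventral, so the
  MB/DB/VB subregion split applies; short terminal twigs decorate every radial
  zone) and each sample is an independent structural variant of it (random
  terminal-branch pruning plus a small affine deformation and node jitter).
  Group differences are imposed as multiplicative dendritic-cable factors per
  radial zone (proximal r < r_split vs distal): cable is pruned (terminal
  branch removal) or added (extra twigs) until each tree's per-zone cable
  matches the factor, giving direct control of the quantity the shell/voxel
  analyses measure.  Registration-parameter sets are emulated as small
  residual rigid jitters of the same per-sample reconstruction.
* Spike trains: inhomogeneous Poisson with piecewise-constant rates over the
  four activity periods and a dead-time refractory (hazard-corrected so the
  realized rate matches the nominal rate), plus optional spike-templated
  voltage traces at the study's 20.833 kHz sampling rate.

The rate profile is piecewise-constant rather than biophysically modeled: the
point is recovery of known parameters, not realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ephys_features import (
    SPONTANEOUS_DURATION,
    STUDY_SAMPLING_RATE,
    ON_PHASIC_DURATION,
    REBOUND_DELAY,
    REBOUND_DURATION,
    SpikeTrainTrial,
    VoltageTrace,
)
from .morph_io import MorphNode, MorphTree, SubregionSet, split_subregions, write_swc

__all__ = [
    "MorphGenParams",
    "SpikeGenParams",
    "gen_morph_population",
    "gen_spike_population",
    "gen_ephys_population",
    "write_morph_population",
    "write_spike_csv",
    "PAPER_LIKE_NE_RATES",
    "PAPER_LIKE_F_RATES",
]

# Paper-like rate presets (Hz): NE baseline; F scaled to give ~+40% spontaneous
# and ~+95% rebound change with on-phasic/inhibitory roughly unchanged.  These
# presets are conventions for end-to-end rehearsal, not measured values.
PAPER_LIKE_NE_RATES = dict(spontaneous=13.0, on_phasic=100.0, inhibitory=7.0, rebound=30.0)
PAPER_LIKE_F_RATES = dict(spontaneous=18.2, on_phasic=105.0, inhibitory=8.0, rebound=58.5)


@dataclass
class MorphGenParams:
    """Parameters of the stochastic binary-outgrowth morphology generator."""

    n_per_group: int = 6
    n_regparam: int = 9
    segment_length_mean: float = 8.0  # μm
    segment_length_sd: float = 2.0  # μm
    trunk_segments: int = 4  # unbranched MB daughter path length, segments
    branch_probability: float = 0.15  # per grown segment
    branch_probability_distal: float = 0.09  # beyond r_split
    termination_probability: float = 0.05
    direction_jitter: float = 0.45  # radial jitter of growth direction
    branch_angle: float = 0.6  # rad, half-angle at bifurcations
    twig_probability: float = 0.35  # short terminal twig per grown segment
    twig_length_mean: float = 9.0  # μm
    host_pl_max: float = 85.0  # %PL ceiling for hosts of prunable twigs
    prune_class_threshold: float = 75.0  # %PL-median core for prunable voxels
    min_nodes: int = 600  # regrow undersized archetypes
    max_order: int = 10
    max_radius: float = 220.0  # μm, growth stops beyond this
    radius_start: float = 1.2  # μm
    radius_taper: float = 0.97  # per segment
    r_split: float = 120.0  # μm, proximal/distal zone boundary
    group_effect: tuple[float, float] = (1.0, 1.0)  # (proximal, distal) factors on F
    # conserve total arbor cable under zone factors by compensatory outgrowth
    # at the distal fringe (maturation redistributes cable rather than
    # shrinking the arbor); new cable extends beyond existing terminals
    conserve_total_cable: bool = True
    # per-sample structural variation of the shared archetype; kept at or
    # below the registration jitter so the imposed group effect is the only
    # systematic between-group difference
    sample_prune_probability: float = 0.005  # terminal twigs dropped per sample
    sample_rotation_sd: float = 0.003  # rad
    sample_scale_sd: float = 0.001  # log-scale SD
    sample_translation_sd: float = 0.2  # μm
    sample_node_jitter_sd: float = 0.5  # μm
    # residual registration variability per parameter set
    regparam_translation_sd: float = 2.5  # μm
    regparam_rotation_sd: float = 0.03  # rad


@dataclass
class SpikeGenParams:
    """Parameters of the four-period inhomogeneous Poisson spike generator."""

    n_trials: int = 10
    rates: dict = field(default_factory=lambda: dict(PAPER_LIKE_NE_RATES))
    refractory: float = 0.002  # s dead time
    onset: float = 0.0
    offset: float = 1.0
    trial_span: tuple[float, float] = (-SPONTANEOUS_DURATION, 1.2)
    voltage: bool = False
    voltage_noise_sd: float = 0.6  # mV
    spike_amplitude: float = 45.0  # mV
    baseline_mv: float = -60.0


# -- morphology generation -----------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = rng.standard_normal(3)
    r -= r @ v * v
    return _unit(r)


class _Builder:
    def __init__(self) -> None:
        self.nodes: list[MorphNode] = []
        self._next = 1

    def add(self, parent: int, pos: np.ndarray, radius: float) -> int:
        nid = self._next
        self._next += 1
        self.nodes.append(MorphNode(nid, parent, tuple(float(x) for x in pos), radius, 3))
        return nid


def _grow_tree(params: MorphGenParams, rng: np.random.Generator) -> tuple[_Builder, int, int]:
    """Grow one tree; returns (builder, dorsal_child_id, ventral_child_id)."""
    b = _Builder()
    root = b.add(-1, np.zeros(3), params.radius_start)
    daughters = {}
    for side, base_dir in (("dorsal", np.array([0.3, 1.0, 0.1])),
                           ("ventral", np.array([0.3, -1.0, -0.1]))):
        d = _unit(base_dir + params.direction_jitter * rng.standard_normal(3))
        seg = abs(rng.normal(params.segment_length_mean, params.segment_length_sd)) + 1.0
        child = b.add(root, seg * d, params.radius_start)
        daughters[side] = child
        # unbranched trunk, then a forced first bifurcation
        cur, pos, radius = child, seg * d, params.radius_start
        for _ in range(params.trunk_segments - 1):
            d = _unit(d + params.direction_jitter * rng.standard_normal(3))
            seg = abs(rng.normal(params.segment_length_mean, params.segment_length_sd)) + 1.0
            pos = pos + seg * d
            radius *= params.radius_taper
            cur = b.add(cur, pos, radius)
        frontier = []
        axis = _perp(d, rng)
        for sign in (1.0, -1.0):
            nd = _unit(
                math.cos(params.branch_angle) * d
                + math.sin(params.branch_angle) * sign * axis
            )
            frontier.append((cur, pos, nd, 1, radius * params.radius_taper))
        # stochastic outgrowth
        while frontier:
            nid, pos, d, order, radius = frontier.pop()
            r_here = float(np.linalg.norm(pos))
            if r_here > params.max_radius:
                continue
            d = _unit(d + params.direction_jitter * rng.standard_normal(3))
            seg = abs(rng.normal(params.segment_length_mean, params.segment_length_sd)) + 1.0
            new_pos = pos + seg * d
            new_id = b.add(nid, new_pos, radius)
            if rng.random() < params.twig_probability:
                # short terminal twig (fine branchlet); prunable material
                tl = abs(rng.normal(params.twig_length_mean, 1.5)) + 0.5
                b.add(new_id, new_pos + tl * _unit(rng.standard_normal(3)), 0.4)
            if rng.random() < params.termination_probability:
                continue
            p_branch = (
                params.branch_probability
                if r_here < params.r_split
                else params.branch_probability_distal
            )
            if order < params.max_order and rng.random() < p_branch:
                axis = _perp(d, rng)
                for sign in (1.0, -1.0):
                    nd = _unit(
                        math.cos(params.branch_angle) * d
                        + math.sin(params.branch_angle) * sign * axis
                    )
                    frontier.append(
                        (new_id, new_pos, nd, order + 1, radius * params.radius_taper)
                    )
            else:
                frontier.append((new_id, new_pos, d, order, radius * params.radius_taper))
    return b, daughters["dorsal"], daughters["ventral"]


def _zone_cable(tree: MorphTree, r_split: float) -> tuple[float, float]:
    """(proximal, distal) cable, split by edge-midpoint radius from the root."""
    c, p, _, _ = tree.edge_arrays()
    if len(c) == 0:
        return 0.0, 0.0
    root = np.asarray(tree.root.position)
    mid_r = np.linalg.norm((c + p) / 2 - root, axis=1)
    lengths = np.linalg.norm(c - p, axis=1)
    prox = float(lengths[mid_r < r_split].sum())
    return prox, float(lengths.sum()) - prox


def _terminal_sections_in_zone(
    tree: MorphTree, r_split: float, zone: str
) -> list[list[int]]:
    """Terminal branch sections whose every edge midpoint lies in the zone
    (nodes strictly after the section head are removable)."""
    root = np.asarray(tree.root.position)
    critical = {tree.root.id} | set(tree.bifurcations())
    sections = []
    for tip in tree.tips():
        path = [tip]
        cur = tip
        while tree.parent_of(cur) != -1 and cur not in critical:
            cur = tree.parent_of(cur)
            path.append(cur)
        path.reverse()  # head (critical node) .. tip
        if len(path) < 2:
            continue
        ok = True
        for a, bnode in zip(path[:-1], path[1:]):
            mid = (
                np.asarray(tree.node(a).position) + np.asarray(tree.node(bnode).position)
            ) / 2
            r = float(np.linalg.norm(mid - root))
            in_prox = r < r_split
            if (zone == "proximal") != in_prox:
                ok = False
                break
        if ok:
            sections.append(path)
    return sections


def _section_cable(tree: MorphTree, path: list[int]) -> float:
    return float(
        sum(
            math.dist(tree.node(a).position, tree.node(b).position)
            for a, b in zip(path[:-1], path[1:])
        )
    )


def _protected_ids(tree: MorphTree) -> set[int]:
    """Root, the two daughter paths up to their first bifurcations, and those
    bifurcations' children (so the MB skeleton survives any pruning)."""
    protected = {tree.root.id}
    for child in tree.children_of(tree.root.id):
        cur = child
        protected.add(cur)
        while True:
            kids = tree.children_of(cur)
            if len(kids) >= 2:
                protected.update(kids)
                break
            if not kids:
                break
            cur = kids[0]
            protected.add(cur)
    return protected


def _apply_zone_factor(
    tree: MorphTree, zone: str, factor: float, params: MorphGenParams,
    rng: np.random.Generator,
) -> MorphTree:
    """Prune (factor < 1) or add twigs (factor > 1) until the zone's cable is
    approximately factor times its original value."""
    if abs(factor - 1.0) < 1e-12:
        return tree
    prox, dist = _zone_cable(tree, params.r_split)
    zone_cable = prox if zone == "proximal" else dist
    target = abs(factor - 1.0) * zone_cable
    if target <= 0:
        return tree
    if factor < 1.0:
        # a density reduction is diffuse: remove many short terminal twigs
        # spread across the zone rather than whole subtrees, so every voxel of
        # the zone loses a little cable instead of a few voxels losing all.
        # Only twigs on path-proximal hosts (low %PL) whose cable lies in
        # path-proximal surroundings qualify — material in remote
        # neighborhoods is distal in path terms whatever its radius.
        from .spatial_density import classify_voxels, clip_length_to_voxels, percent_pl_annotate

        ann = percent_pl_annotate(tree)
        pct = dict(zip(ann.node_ids.tolist(), ann.percent_pl.tolist()))
        # classify at a stricter threshold than the analysis uses so that
        # boundary voxels (whose class can flip under per-sample jitter) are
        # never touched by the reduction
        field_one = clip_length_to_voxels(tree)
        vclass_core = classify_voxels(
            [field_one], [ann], threshold=params.prune_class_threshold
        )
        want = "proximal" if zone == "proximal" else "distal"

        def _in_class(path: list[int], vclass: dict) -> bool:
            # every node and several points per edge must sit in a voxel of
            # the wanted class — a twig may poke into a neighboring voxel
            points = [np.asarray(tree.node(i).position) for i in path]
            probes = list(points)
            for a, b2 in zip(points[:-1], points[1:]):
                for t in (0.25, 0.5, 0.75):
                    probes.append(a + t * (b2 - a))
            for pt in probes:
                key = tuple(int(v) for v in np.floor(pt / 20.0))
                if vclass.get(key) != want:
                    return False
            return True

        removed = 0.0
        keep = {n.id for n in tree.nodes}
        all_sections = [
            p2
            for p2 in _terminal_sections_in_zone(tree, params.r_split, zone)
            if pct[p2[0]] < params.host_pl_max
        ]
        core = [p2 for p2 in all_sections if _in_class(p2, vclass_core)]
        # short twigs deep in the zone core first, longer dead-ends second;
        # material outside the core is never touched (class flips under
        # jitter would smear the effect into the distal partition)
        passes = [
            [p2 for p2 in core if len(p2) <= 3],
            [p2 for p2 in core if len(p2) > 3],
        ]
        for sections in passes:
            pass_units = [
                (set(path[1:]), _section_cable(tree, path)) for path in sections
            ]
            for idx in rng.permutation(len(pass_units)):
                ids, cable = pass_units[idx]
                if not ids <= keep:
                    continue
                if abs(removed + cable - target) >= abs(removed - target):
                    continue
                keep -= ids
                removed += cable
                if removed >= target:
                    break
            if removed >= 0.97 * target:
                break
        # exact remainder: uniformly shorten the kept core twigs — the
        # shortened segment is a subset of the original, so it stays inside
        # the same core voxels and the calibration becomes continuous
        shortened: dict[int, tuple[float, float, float]] = {}
        shortfall = target - removed
        if shortfall > 1e-9:
            root_pos = np.asarray(tree.root.position)
            candidates = []
            cable_avail = 0.0
            for tip in tree.tips():
                if tip not in keep:
                    continue
                host = tree.parent_of(tip)
                if host == -1 or host not in keep:
                    continue
                hp = np.asarray(tree.node(host).position)
                tp = np.asarray(tree.node(tip).position)
                mid_r = float(np.linalg.norm((hp + tp) / 2 - root_pos))
                if (mid_r < params.r_split) != (zone == "proximal"):
                    continue
                if not _in_class([host, tip], vclass_core):
                    continue
                candidates.append((host, tip, hp, tp))
                cable_avail += float(np.linalg.norm(tp - hp))
            if cable_avail > 0:
                frac = min(shortfall / cable_avail, 0.9)
                for host, tip, hp, tp in candidates:
                    np_pos = hp + (tp - hp) * (1.0 - frac)
                    shortened[tip] = tuple(float(x) for x in np_pos)
                removed += frac * cable_avail
        # final calibration stage: local smoothing of core through-paths.
        # Interior nodes move toward the midpoint of their neighbors,
        # removing tortuosity cable diffusely, in place, without topology
        # changes; iterated with re-measurement until the target is met
        if target - removed > 1e-9:
            root_pos = np.asarray(tree.root.position)
            pos_map = {
                n.id: np.asarray(shortened.get(n.id, n.position), dtype=float)
                for n in tree.nodes
                if n.id in keep
            }

            def zone_cable_now() -> float:
                out = 0.0
                for nid, p0 in pos_map.items():
                    pid = tree.parent_of(nid)
                    if pid == -1 or pid not in pos_map:
                        continue
                    p1 = pos_map[pid]
                    mid_r = float(np.linalg.norm((p0 + p1) / 2 - root_pos))
                    if (mid_r < params.r_split) == (zone == "proximal"):
                        out += float(np.linalg.norm(p0 - p1))
                return out

            zone_start = zone_cable_now() + removed
            windows = []
            for n in tree.nodes:
                nid = n.id
                if nid not in keep or nid == tree.root.id:
                    continue
                kids = [k for k in tree.children_of(nid) if k in keep]
                pid = tree.parent_of(nid)
                if len(kids) != 1 or pid == -1 or pid not in keep:
                    continue
                if _in_class([pid, nid, kids[0]], vclass_core):
                    windows.append((pid, nid, kids[0]))
            # recover most (not all) of the shortfall with bounded per-node
            # displacement: large node moves would carry cable across voxel
            # boundaries and smear the effect
            goal = 0.15 * (target - (zone_start - zone_cable_now()))
            for _ in range(3):
                shortfall = target - (zone_start - zone_cable_now()) - goal
                if shortfall <= 1.0 or not windows:
                    break
                slack = 0.0
                for pid, nid, cid in windows:
                    a, m, c2 = pos_map[pid], pos_map[nid], pos_map[cid]
                    slack += (
                        float(np.linalg.norm(m - a))
                        + float(np.linalg.norm(c2 - m))
                        - float(np.linalg.norm(c2 - a))
                    )
                if slack <= 1e-9:
                    break
                beta = min(shortfall / slack, 0.9)
                move = 1.0 - math.sqrt(max(1.0 - beta, 0.0))

                def _edges_in_core(a: np.ndarray, m: np.ndarray, c2: np.ndarray) -> bool:
                    # the moved edges must stay wholly inside core voxels, or
                    # cable would retract out of unclassified neighbors
                    for p0, p1 in ((a, m), (m, c2)):
                        for t in (0.0, 0.25, 0.5, 0.75, 1.0):
                            pt = p0 + t * (p1 - p0)
                            key = tuple(int(v) for v in np.floor(pt / 20.0))
                            if vclass_core.get(key) != want:
                                return False
                    return True

                for pid, nid, cid in windows:
                    mid = (pos_map[pid] + pos_map[cid]) / 2
                    step = move * (mid - pos_map[nid])
                    norm = float(np.linalg.norm(step))
                    if norm > 1.0:  # μm cap per iteration
                        step = step / norm
                    cand = pos_map[nid] + step
                    # the node must stay in its own voxel: crossing would
                    # perturb the pooled remoteness classification
                    same_voxel = tuple(np.floor(cand / 20.0)) == tuple(
                        np.floor(pos_map[nid] / 20.0)
                    )
                    if same_voxel and _edges_in_core(
                        pos_map[pid], cand, pos_map[cid]
                    ):
                        pos_map[nid] = cand
            shortened = {
                nid: tuple(float(x) for x in p)
                for nid, p in pos_map.items()
                if not np.array_equal(p, np.asarray(tree.node(nid).position))
            }
        nodes = [
            MorphNode(
                n.id, n.parent_id,
                shortened.get(n.id, n.position),
                n.radius, n.structure_label,
            )
            if n.id in shortened
            else n
            for n in tree.nodes
            if n.id in keep
        ]
        return MorphTree(
            nodes, name=tree.name, group=tree.group,
            sample_id=tree.sample_id, regparam_id=tree.regparam_id,
            validate=False,
        )
    # factor > 1: attach short terminal twigs at random nodes in the zone
    root = np.asarray(tree.root.position)
    in_zone = [
        n.id
        for n in tree.nodes
        if (np.linalg.norm(np.asarray(n.position) - root) < params.r_split)
        == (zone == "proximal")
    ]
    if not in_zone:
        return tree
    nodes = list(tree.nodes)
    next_id = max(n.id for n in nodes) + 1
    added = 0.0
    while added < target:
        host = tree.node(int(rng.choice(in_zone)))
        length = abs(rng.normal(params.twig_length_mean, 1.5)) + 0.5
        if abs(added + length - target) >= abs(added - target):
            break
        d = _unit(rng.standard_normal(3))
        pos = np.asarray(host.position) + length * d
        nodes.append(MorphNode(next_id, host.id, tuple(float(x) for x in pos), 0.4, 3))
        next_id += 1
        added += length
    return MorphTree(
        nodes, name=tree.name, group=tree.group,
        sample_id=tree.sample_id, regparam_id=tree.regparam_id,
    )


def _fringe_outgrowth(
    tree: MorphTree, target: float, params: MorphGenParams, rng: np.random.Generator
) -> MorphTree:
    """Extend outward-continuing twigs at distal terminals until ~``target``
    μm of new cable is added (compensatory outgrowth at the arbor fringe)."""
    if target <= 0:
        return tree
    root = np.asarray(tree.root.position)
    tip_ids = tree.tips()
    radii = {
        t: float(np.linalg.norm(np.asarray(tree.node(t).position) - root))
        for t in tip_ids
    }
    r_max = max(radii.values())
    # a single gently curving process from the outermost terminal, heading
    # radially outward: it leaves the arbor's envelope within one segment and
    # stays outside it, so the new cable occupies only space the rest of the
    # arbor does not
    anchor = max(tip_ids, key=lambda t: radii[t])
    pos = np.asarray(tree.node(anchor).position)
    parent = anchor
    nodes = list(tree.nodes)
    next_id = max(n.id for n in nodes) + 1
    added = 0.0
    seg_len = 1.5 * params.segment_length_mean
    out_dir = _unit(pos - root)
    while True:
        length = abs(rng.normal(seg_len, 2.0)) + 2.0
        if abs(added + length - target) >= abs(added - target):
            break
        out_dir = _unit(out_dir + 0.15 * rng.standard_normal(3))
        cand = pos + length * out_dir
        if np.linalg.norm(cand - root) < r_max + 10.0:
            # re-aim strictly outward rather than dipping back into the arbor
            out_dir = _unit(pos - root)
            cand = pos + length * out_dir
        pos = cand
        nodes.append(MorphNode(next_id, parent, tuple(float(x) for x in pos), 0.4, 3))
        parent = next_id
        next_id += 1
        added += length
    return MorphTree(
        nodes, name=tree.name, group=tree.group,
        sample_id=tree.sample_id, regparam_id=tree.regparam_id,
    )


def _rotation(rng: np.random.Generator, sd: float) -> np.ndarray:
    angle = rng.normal(0.0, sd)
    axis = _unit(rng.standard_normal(3))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _structural_variant(
    tree: MorphTree, params: MorphGenParams, rng: np.random.Generator, **labels
) -> MorphTree:
    """An individual-animal variant of the archetype: random terminal-branch
    pruning plus a small affine deformation and per-node jitter."""
    keep = {n.id for n in tree.nodes}
    critical = {tree.root.id} | set(tree.bifurcations())
    protected = _protected_ids(tree)
    for tip in tree.tips():
        if rng.random() >= params.sample_prune_probability:
            continue
        path = [tip]
        cur = tip
        while tree.parent_of(cur) != -1 and cur not in critical:
            cur = tree.parent_of(cur)
            path.append(cur)
        drop = set(path[:-1])  # keep the critical head
        # only short twigs vary between animals; large branches are stable
        if drop and len(drop) <= 2 and drop < keep and not (drop & protected):
            keep -= drop
    pruned = tree.extract(keep, tree.root.id, validate=False, **labels)
    R = _rotation(rng, params.sample_rotation_sd) * math.exp(
        rng.normal(0.0, params.sample_scale_sd)
    )
    t = rng.normal(0.0, params.sample_translation_sd, 3)
    moved = (
        pruned.positions() @ R.T
        + t
        + rng.normal(0.0, params.sample_node_jitter_sd, (len(pruned), 3))
    )
    nodes = [
        MorphNode(n.id, n.parent_id, (row[0], row[1], row[2]),
                  n.radius, n.structure_label)
        for n, row in zip(pruned.nodes, moved.tolist())
    ]
    return MorphTree(
        nodes, name=pruned.name, group=pruned.group,
        sample_id=pruned.sample_id, regparam_id=pruned.regparam_id,
        validate=False,
    )


def _rigid_jitter(
    tree: MorphTree, rng: np.random.Generator, trans_sd: float, rot_sd: float
) -> MorphTree:
    """Small random rigid transform (residual registration variability)."""
    angle = rng.normal(0.0, rot_sd)
    axis = _unit(rng.standard_normal(3))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
    t = rng.normal(0.0, trans_sd, 3)
    moved = tree.positions() @ R.T + t
    nodes = [
        MorphNode(n.id, n.parent_id, (row[0], row[1], row[2]),
                  n.radius, n.structure_label)
        for n, row in zip(tree.nodes, moved.tolist())
    ]
    return MorphTree(
        nodes, name=tree.name, group=tree.group,
        sample_id=tree.sample_id, regparam_id=tree.regparam_id,
        validate=False,
    )


def gen_morph_population(
    params: MorphGenParams, seed: int
) -> tuple[list[SubregionSet], dict]:
    """Generate both maturation groups with per-zone group effects.

    Returns one :class:`SubregionSet` per (group, sample, regparam) plus a
    ground-truth record (per-tree zone cable before/after the effect).
    Deterministic per (params, seed).
    """
    rng = np.random.default_rng(seed)
    population: list[SubregionSet] = []
    truth: dict = dict(params={**asdict(params)}, seed=seed, samples=[])
    prox_f, dist_f = params.group_effect
    for attempt in range(40):
        b, dorsal, ventral = _grow_tree(params, rng)
        if len(b.nodes) >= max(params.min_nodes, params.trunk_segments * 2 + 5):
            break
    else:
        if len(b.nodes) < params.trunk_segments * 2 + 5:
            raise RuntimeError("morphology generator produced empty trees")
    archetype = MorphTree(b.nodes, name="archetype")
    # the group effect is a property of the forager neuron itself, so it is
    # applied once at the archetype level: every F sample consistently lacks
    # (or carries) the same per-zone cable
    f_archetype = _apply_zone_factor(
        _apply_zone_factor(archetype, "proximal", prox_f, params, rng),
        "distal", dist_f, params, rng,
    )
    if params.conserve_total_cable:
        deficit = archetype.total_length() - f_archetype.total_length()
        f_archetype = _fringe_outgrowth(f_archetype, deficit, params, rng)
    for group in ("NE", "F"):
        for s in range(params.n_per_group):
            sample_id = f"{group}{s + 1}"
            source = archetype if group == "NE" else f_archetype
            pre_prox, pre_dist = _zone_cable(archetype, params.r_split)
            base = _structural_variant(
                source, params, rng,
                name=sample_id, group=group, sample_id=sample_id,
            )
            post_prox, post_dist = _zone_cable(base, params.r_split)
            truth["samples"].append(
                dict(
                    sample_id=sample_id, group=group,
                    proximal_cable_pre=pre_prox, distal_cable_pre=pre_dist,
                    proximal_cable=post_prox, distal_cable=post_dist,
                )
            )
            for r in range(params.n_regparam):
                reg_id = f"rp{r}"
                jittered = (
                    base.with_labels(regparam_id=reg_id)
                    if params.n_regparam == 1
                    else _rigid_jitter(
                        base.with_labels(regparam_id=reg_id),
                        rng,
                        params.regparam_translation_sd,
                        params.regparam_rotation_sd,
                    )
                )
                population.append(split_subregions(jittered, dorsal, ventral))
    return population, truth


def write_morph_population(
    population: list[SubregionSet], out_dir: str | Path, truth: dict | None = None
) -> Path:
    """Emit WA SWC files plus the manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("path,group,sample_id,regparam_id\n")
        for sub in population:
            wa = sub.WA
            fname = f"{wa.sample_id}_{wa.regparam_id}.swc"
            write_swc(wa, out_dir / fname)
            fh.write(f"{fname},{wa.group},{wa.sample_id},{wa.regparam_id}\n")
    if truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return manifest


# -- spike generation ----------------------------------------------------------


def _rate_boundaries(p: SpikeGenParams) -> list[tuple[float, float, float]]:
    """(start, stop, rate) segments covering the trial span; outside the four
    periods the spontaneous rate applies."""
    r = p.rates
    on0, on1 = p.onset, p.onset + ON_PHASIC_DURATION
    reb0 = p.offset + REBOUND_DELAY
    reb1 = reb0 + REBOUND_DURATION
    segs = [
        (p.trial_span[0], on0, r["spontaneous"]),
        (on0, on1, r["on_phasic"]),
        (on1, p.offset, r["inhibitory"]),
        (p.offset, reb0, r["spontaneous"]),
        (reb0, reb1, r["rebound"]),
        (reb1, p.trial_span[1], r["spontaneous"]),
    ]
    return [(a, b, rate) for a, b, rate in segs if b > a]


def _simulate_trial(p: SpikeGenParams, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant renewal process: within each constant-rate segment
    intervals are refractory + Exp(lambda*), with the hazard
    lambda* = lambda / (1 - lambda * refractory) chosen so the realized rate
    equals the nominal rate.  Each segment starts in equilibrium (the first
    event delay is drawn from the forward-recurrence distribution), so the
    expected count in a window of any duration is duration * rate — short
    windows carry no start-up bias."""
    spikes: list[float] = []
    last = -np.inf
    tau = p.refractory
    for a, bnd, lam in _rate_boundaries(p):
        if lam <= 0:
            continue
        if lam * tau >= 1.0:
            raise ValueError("rate too high for the given refractory period")
        hazard = lam / (1.0 - lam * tau)
        mean_isi = 1.0 / lam
        if last + tau > a:
            # a recent spike: continue the renewal conditional on dead time
            t = last + tau + rng.exponential(1.0 / hazard)
        else:
            # stationary start: forward recurrence time of the renewal process
            if rng.random() < tau / mean_isi:
                t = a + rng.uniform(0.0, tau)
            else:
                t = a + tau + rng.exponential(1.0 / hazard)
        while t < bnd:
            spikes.append(t)
            last = t
            t = last + tau + rng.exponential(1.0 / hazard)
    return np.asarray(spikes)


def _spike_template(sampling_rate: float, amplitude: float) -> np.ndarray:
    """Biphasic ~2.5 ms action-potential template."""
    t = np.arange(-0.0008, 0.0017, 1.0 / sampling_rate)
    depol = np.exp(-0.5 * (t / 0.00025) ** 2)
    ahp = -0.25 * np.exp(-0.5 * ((t - 0.0009) / 0.0006) ** 2)
    return amplitude * (depol + ahp)


def gen_spike_population(
    params: SpikeGenParams,
    seed: int,
    neuron_id: str = "syn0",
    group: str = "unknown",
) -> tuple[list[SpikeTrainTrial], list[VoltageTrace] | None, dict]:
    """Trials for one neuron; optional spike-templated voltage traces.

    Returns (trials, traces-or-None, ground truth).  Deterministic per
    (params, seed).
    """
    rng = np.random.default_rng(seed)
    trials, traces = [], [] if params.voltage else None
    for _ in range(params.n_trials):
        spikes = _simulate_trial(params, rng)
        trials.append(
            SpikeTrainTrial(
                spikes, stim_offset=params.offset, stim_onset=params.onset,
                neuron_id=neuron_id, group=group,
            )
        )
        if params.voltage:
            n = int(round((params.trial_span[1] - params.trial_span[0]) * STUDY_SAMPLING_RATE))
            v = params.baseline_mv + params.voltage_noise_sd * rng.standard_normal(n)
            tmpl = _spike_template(STUDY_SAMPLING_RATE, params.spike_amplitude)
            for s in spikes:
                i0 = int(round((s - params.trial_span[0]) * STUDY_SAMPLING_RATE)) - int(
                    0.0008 * STUDY_SAMPLING_RATE
                )
                j0, j1 = max(i0, 0), min(i0 + tmpl.size, n)
                if j1 > j0:
                    v[j0:j1] += tmpl[j0 - i0 : j1 - i0]
            traces.append(VoltageTrace(v, STUDY_SAMPLING_RATE, params.trial_span[0]))
    truth = dict(params={**asdict(params)}, seed=seed, rates=dict(params.rates))
    return trials, traces, truth


def gen_ephys_population(
    ne_params: SpikeGenParams | None = None,
    f_params: SpikeGenParams | None = None,
    n_neurons: int = 6,
    rate_cv: float = 0.12,
    seed: int = 0,
) -> tuple[dict[str, list[SpikeTrainTrial]], dict]:
    """Two groups of neurons with per-neuron lognormal rate heterogeneity.

    Defaults to the paper-like presets.  Returns ({neuron_id: trials}, truth).
    """
    rng = np.random.default_rng(seed)
    base = {
        "NE": ne_params or SpikeGenParams(rates=dict(PAPER_LIKE_NE_RATES)),
        "F": f_params or SpikeGenParams(rates=dict(PAPER_LIKE_F_RATES)),
    }
    out: dict[str, list[SpikeTrainTrial]] = {}
    truth: dict = dict(seed=seed, neurons=[])
    sigma = math.sqrt(math.log(1 + rate_cv**2))
    for group, p in base.items():
        for i in range(n_neurons):
            scale = float(rng.lognormal(-0.5 * sigma**2, sigma)) if rate_cv > 0 else 1.0
            rates = {k: v * scale for k, v in p.rates.items()}
            pi = SpikeGenParams(**{**asdict(p), "rates": rates})
            nid = f"{group}_n{i + 1}"
            trials, _, _ = gen_spike_population(
                pi, seed=int(rng.integers(0, 2**31 - 1)), neuron_id=nid, group=group
            )
            out[nid] = trials
            truth["neurons"].append(dict(neuron_id=nid, group=group, rates=rates))
    return out, truth


def write_spike_csv(
    trials_by_neuron: dict[str, list[SpikeTrainTrial]], path: str | Path
) -> Path:
    """Emit the spike-time CSV the ephys arm consumes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("neuron_id,trial_id,spike_time_s,onset_s,offset_s,group\n")
        for nid, trials in trials_by_neuron.items():
            for ti, tr in enumerate(trials):
                if tr.spike_times.size == 0:
                    # keep spike-free trials in the trial count
                    fh.write(f"{nid},{ti},,{tr.stim_onset},{tr.stim_offset},{tr.group}\n")
                for s in tr.spike_times:
                    fh.write(
                        f"{nid},{ti},{s:.6f},{tr.stim_onset},{tr.stim_offset},{tr.group}\n"
                    )
    return path
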