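"""Shell, voxel and proximal/distal dendritic-density statistics.

Works on co-registered morphologies.  Space is divided either into concentric
spherical shells of fixed thickness (a Sholl-style radial analysis) or into
non-overlapping cubic voxels; per morphology the percentage of total dendritic
length in each bin is computed (PDL_shell, PDL_voxel) by *analytic* clipping of
straight edges against sphere radii / grid planes, so bin totals conserve
cable exactly.

Group differences per bin are tested with ART two-way ANOVA (maturation x
registration-parameter set); a bin is flagged when the maturation main effect
survives Bonferroni correction across tested bins while the interaction with
the registration nuisance factor is non-significant.

For the proximal/distal analysis each tree node carries %PL, its relative
path-length remoteness:

    %PL = 100 * PL_root / (PL_root + PL_term_max)

where PL_root is the path length to the root and PL_term_max the maximum path
length to a downstream terminal.  A voxel is distal when the median %PL of the
nodes it contains (pooled across groups, registration sets and samples)
exceeds a threshold (default 90).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morph_io import MorphTree
from .stats_engine import FactorialResult, art_anova_2way

__all__ = [
    "ShellProfile",
    "VoxelField",
    "NormalizedChangeField",
    "PercentPLAnnotation",
    "clip_length_to_shells",
    "clip_length_to_voxels",
    "percent_pl_annotate",
    "classify_voxels",
    "normalized_change",
    "shell_group_test",
    "voxel_group_test",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 20.0  # μm, both shell thickness and voxel edge
DEFAULT_PL_THRESHOLD = 90.0


@dataclass
class ShellProfile:
    """Percent dendritic length per spherical shell for one morphology.

    Shell k spans radii [k*thickness, (k+1)*thickness) around ``center``.
    Values sum to 100.
    """

    sample_id: str
    group: str
    regparam_id: str
    subregion: str
    shell_thickness: float
    center: tuple[float, float, float]
    values: dict[int, float] = field(default_factory=dict)


@dataclass
class VoxelField:
    """Percent dendritic length per cubic voxel for one morphology.

    Voxel (i, j, k) spans the half-open cube
    [origin + size*(i,j,k), origin + size*(i+1,j+1,k+1)); absent keys are 0.
    """

    sample_id: str
    group: str
    regparam_id: str
    subregion: str
    voxel_size: float
    origin: tuple[float, float, float]
    values: dict[tuple[int, int, int], float] = field(default_factory=dict)


@dataclass
class NormalizedChangeField:
    """Per-voxel normalized group change (mean_F - mean_NE) / grand_mean."""

    values: dict[tuple[int, int, int], float]
    mean_f: dict[tuple[int, int, int], float]
    mean_n: dict[tuple[int, int, int], float]
    grand_mean: dict[tuple[int, int, int], float]


@dataclass
class PercentPLAnnotation:
    """Per-node path-length remoteness of one morphology."""

    node_ids: np.ndarray
    positions: np.ndarray  # (N, 3)
    pl_root: np.ndarray
    pl_term_max: np.ndarray
    percent_pl: np.ndarray


# -- clipping ------------------------------------------------------------------


def _edge_geometry(tree: MorphTree) -> tuple[np.ndarray, np.ndarray]:
    c, p, _, _ = tree.edge_arrays()
    return p, c  # start, end


def clip_length_to_shells(
    tree: MorphTree,
    center,
    thickness: float = DEFAULT_BIN_SIZE,
) -> ShellProfile:
    """Analytically clip every edge against concentric sphere radii.

    Each straight edge is intersected with the spheres of radius k*thickness;
    sub-lengths accumulate into the shell containing their midpoint, then
    convert to percent of total length.
    """
    total = tree.total_length()
    if total <= 0:
        raise ValueError("clip_length_to_shells requires nonzero total length")
    center = np.asarray(center, dtype=float)
    starts, ends = _edge_geometry(tree)
    acc: dict[int, float] = {}
    for p0, p1 in zip(starts, ends):
        a = p0 - center
        d = p1 - p0
        L = float(np.linalg.norm(d))
        if L == 0:
            continue
        aa = float(a @ a)
        ad = float(a @ d)
        dd = float(d @ d)
        r0 = math.sqrt(aa)
        r1 = float(np.linalg.norm(a + d))
        # closest approach may be interior
        t_star = -ad / dd
        r_min = min(r0, r1)
        if 0.0 < t_star < 1.0:
            r_min = min(r_min, math.sqrt(max(aa + 2 * t_star * ad + t_star**2 * dd, 0.0)))
        r_max = max(r0, r1)
        k_lo = int(math.ceil(r_min / thickness))
        k_hi = int(math.floor(r_max / thickness))
        ts = [0.0, 1.0]
        for k in range(max(k_lo, 1), k_hi + 1):
            R = k * thickness
            disc = ad * ad - dd * (aa - R * R)
            if disc <= 0:
                continue
            sq = math.sqrt(disc)
            for t in ((-ad - sq) / dd, (-ad + sq) / dd):
                if 0.0 < t < 1.0:
                    ts.append(t)
        ts.sort()
        for ta, tb in zip(ts[:-1], ts[1:]):
            if tb <= ta:
                continue
            tm = 0.5 * (ta + tb)
            rm = math.sqrt(max(aa + 2 * tm * ad + tm * tm * dd, 0.0))
            k = int(rm // thickness)
            acc[k] = acc.get(k, 0.0) + (tb - ta) * L
    values = {k: 100.0 * v / total for k, v in acc.items()}
    return ShellProfile(
        sample_id=tree.sample_id,
        group=tree.group,
        regparam_id=tree.regparam_id,
        subregion=tree.name,
        shell_thickness=thickness,
        center=tuple(center),
        values=values,
    )


def clip_length_to_voxels(
    tree: MorphTree,
    origin=(0.0, 0.0, 0.0),
    voxel_size: float = DEFAULT_BIN_SIZE,
) -> VoxelField:
    """Split every edge at each axis-aligned grid plane it crosses and
    accumulate sub-lengths into half-open voxels, as percent of total length.

    Points on a grid plane belong to the higher-index voxel.
    """
    total = tree.total_length()
    if total <= 0:
        raise ValueError("clip_length_to_voxels requires nonzero total length")
    origin = np.asarray(origin, dtype=float)
    starts, ends = _edge_geometry(tree)
    acc: dict[tuple[int, int, int], float] = {}
    if len(starts) == 0:
        return VoxelField(
            sample_id=tree.sample_id, group=tree.group,
            regparam_id=tree.regparam_id, subregion=tree.name,
            voxel_size=voxel_size, origin=tuple(origin), values={},
        )
    d = ends - starts
    lengths = np.linalg.norm(d, axis=1)
    # breakpoints: every axis-aligned grid plane crossed by each edge,
    # gathered fully vectorized as (edge index, parameter t) pairs
    edge_idx_parts = [np.arange(len(starts)), np.arange(len(starts))]
    t_parts = [np.zeros(len(starts)), np.ones(len(starts))]
    g0 = (starts - origin) / voxel_size
    g1 = (ends - origin) / voxel_size
    lo = np.minimum(g0, g1)
    hi = np.maximum(g0, g1)
    first = np.floor(lo).astype(int) + 1
    count = np.maximum(np.ceil(hi).astype(int) - first, 0)
    for ax in range(3):
        c = count[:, ax]
        if c.sum() == 0:
            continue
        e = np.repeat(np.arange(len(starts)), c)
        # plane indices first_e .. first_e + c_e - 1, flattened
        offs = np.concatenate([np.arange(n) for n in c if n > 0])
        m = np.repeat(first[:, ax], c) + offs
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (origin[ax] + m * voxel_size - starts[e, ax]) / d[e, ax]
        keepm = (t > 0.0) & (t < 1.0)
        edge_idx_parts.append(e[keepm])
        t_parts.append(t[keepm])
    e_all = np.concatenate(edge_idx_parts)
    t_all = np.concatenate(t_parts)
    order = np.lexsort((t_all, e_all))
    e_all, t_all = e_all[order], t_all[order]
    same_edge = e_all[1:] == e_all[:-1]
    ta, tb = t_all[:-1][same_edge], t_all[1:][same_edge]
    eseg = e_all[:-1][same_edge]
    seg_len = (tb - ta) * lengths[eseg]
    mids = starts[eseg] + 0.5 * (ta + tb)[:, None] * d[eseg]
    idx = np.floor((mids - origin) / voxel_size).astype(int)
    keys, inverse = np.unique(idx, axis=0, return_inverse=True)
    sums = np.bincount(inverse, weights=seg_len)
    acc = {tuple(k): float(v) for k, v in zip(keys, sums) if v > 0}
    values = {k: 100.0 * v / total for k, v in acc.items()}
    return VoxelField(
        sample_id=tree.sample_id,
        group=tree.group,
        regparam_id=tree.regparam_id,
        subregion=tree.name,
        voxel_size=voxel_size,
        origin=tuple(origin),
        values=values,
    )


# -- %PL and partitions --------------------------------------------------------


def percent_pl_annotate(tree: MorphTree) -> PercentPLAnnotation:
    """Annotate each node with %PL = 100 * PL_root / (PL_root + PL_term_max).

    One upward pass computes path length to the root, one downward pass the
    maximum path length to a downstream terminal.  The root gets 0, terminals
    100; a single-node tree gets 0.
    """
    order = tree.topological_order()
    pl_root: dict[int, float] = {}
    for nid in order:
        node = tree.node(nid)
        if node.parent_id == -1:
            pl_root[nid] = 0.0
        else:
            pl_root[nid] = pl_root[node.parent_id] + math.dist(
                node.position, tree.node(node.parent_id).position
            )
    pl_term: dict[int, float] = {}
    for nid in reversed(order):
        kids = tree.children_of(nid)
        if not kids:
            pl_term[nid] = 0.0
        else:
            pl_term[nid] = max(
                pl_term[k] + math.dist(tree.node(k).position, tree.node(nid).position)
                for k in kids
            )
    ids = np.array(order)
    root = np.array([pl_root[i] for i in order])
    term = np.array([pl_term[i] for i in order])
    denom = root + term
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * root / np.where(denom > 0, denom, 1.0), 0.0)
    return PercentPLAnnotation(
        node_ids=ids,
        positions=np.array([tree.node(i).position for i in order], dtype=float),
        pl_root=root,
        pl_term_max=term,
        percent_pl=pct,
    )


def classify_voxels(
    fields: list[VoxelField],
    annotations: list[PercentPLAnnotation],
    threshold: float = DEFAULT_PL_THRESHOLD,
) -> dict[tuple[int, int, int], str]:
    """Classify voxels as proximal/distal from pooled node %PL medians.

    Node %PL values of every annotated morphology (pooled across maturation
    levels, registration-parameter sets and samples) are assigned to the voxel
    containing the node; a voxel is ``distal`` iff the pooled median exceeds
    ``threshold``.  Voxels containing no nodes are absent from the map.
    """
    if not fields:
        raise ValueError("classify_voxels requires at least one VoxelField")
    origin = np.asarray(fields[0].origin)
    size = fields[0].voxel_size
    for f in fields[1:]:
        if tuple(f.origin) != tuple(origin) or f.voxel_size != size:
            raise ValueError("all VoxelFields must share origin and voxel size")
    pooled: dict[tuple[int, int, int], list[float]] = {}
    for ann in annotations:
        keys = np.floor((ann.positions - origin) / size).astype(int)
        for key, pct in zip(map(tuple, keys), ann.percent_pl):
            pooled.setdefault(key, []).append(float(pct))
    return {
        key: ("distal" if float(np.median(v)) > threshold else "proximal")
        for key, v in pooled.items()
    }


def normalized_change(fields: list[VoxelField]) -> NormalizedChangeField:
    """Per-voxel normalized change in PDL_voxel between maturation groups.

    For each voxel: (mean over F morphologies - mean over NE morphologies)
    divided by the mean over all morphologies; morphologies without cable in
    the voxel contribute 0.  Voxels with zero grand mean are omitted.
    """
    groups = {f.group for f in fields}
    if not {"NE", "F"} <= groups:
        raise ValueError("normalized_change requires both NE and F fields")
    keys = sorted({k for f in fields for k in f.values})
    f_fields = [f for f in fields if f.group == "F"]
    n_fields = [f for f in fields if f.group == "NE"]
    values, mf_d, mn_d, g_d = {}, {}, {}, {}
    for key in keys:
        mf = float(np.mean([f.values.get(key, 0.0) for f in f_fields]))
        mn = float(np.mean([f.values.get(key, 0.0) for f in n_fields]))
        grand = float(np.mean([f.values.get(key, 0.0) for f in fields]))
        mf_d[key], mn_d[key], g_d[key] = mf, mn, grand
        if grand > 0:
            values[key] = (mf - mn) / grand
    return NormalizedChangeField(values=values, mean_f=mf_d, mean_n=mn_d, grand_mean=g_d)


# -- factorial tests -----------------------------------------------------------


def _included_bins(per_morph: dict, bins, groups) -> list:
    """Bins with nonzero PDL in >= half the morphologies of each group."""
    out = []
    for b in bins:
        ok = True
        for g in ("NE", "F"):
            vals = [v.get(b, 0.0) for (grp, _, _), v in per_morph.items() if grp == g]
            if not vals or sum(v > 0 for v in vals) < 0.5 * len(vals):
                ok = False
                break
        if ok:
            out.append(b)
    return out


def _factorial_table(per_morph: dict, b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    resp, fa, fb = [], [], []
    for (grp, _sid, reg), v in per_morph.items():
        resp.append(v.get(b, 0.0))
        fa.append(grp)
        fb.append(reg)
    return np.asarray(resp), np.asarray(fa), np.asarray(fb)


def shell_group_test(profiles: list[ShellProfile], alpha: float = 0.05) -> pd.DataFrame:
    """Per-shell ART two-way ANOVA (maturation x registration-parameter set).

    A shell is flagged iff the maturation main effect is significant at
    alpha / (number of shells tested) (Bonferroni) AND the interaction with
    registration parameters is not significant at ``alpha``.  Shells lacking
    coverage (nonzero PDL_shell in fewer than half the morphologies of either
    group) are skipped and logged.

    Returns a frame with shell index, radius range, per-group mean/SD, the
    three p-values and the flag.
    """
    per_morph = {
        (p.group, p.sample_id, p.regparam_id): p.values for p in profiles
    }
    thickness = profiles[0].shell_thickness
    bins = sorted({k for p in profiles for k in p.values})
    tested = _included_bins(per_morph, bins, ("NE", "F"))
    skipped = [b for b in bins if b not in tested]
    if skipped:
        logger.info("shell_group_test: skipping shells without coverage: %s", skipped)
    results = {}
    for b in tested:
        resp, fa, fb = _factorial_table(per_morph, b)
        results[b] = art_anova_2way(resp, fa, fb)
    m = max(len(tested), 1)
    rows = []
    for b in bins:
        resp, fa, _ = _factorial_table(per_morph, b)
        ne, f = resp[fa == "NE"], resp[fa == "F"]
        rec = dict(
            shell=b,
            r_lo=b * thickness,
            r_hi=(b + 1) * thickness,
            ne_mean=float(ne.mean()),
            ne_sd=float(ne.std(ddof=1)) if ne.size > 1 else math.nan,
            f_mean=float(f.mean()),
            f_sd=float(f.std(ddof=1)) if f.size > 1 else math.nan,
            tested=b in results,
        )
        if b in results:
            r = results[b].apply_flag(alpha / m, alpha)
            rec.update(
                p_maturation=r.p_main_A,
                p_regparam=r.p_main_B,
                p_interaction=r.p_interaction,
                flag=r.flag_significant,
            )
        else:
            rec.update(
                p_maturation=math.nan, p_regparam=math.nan,
                p_interaction=math.nan, flag=False,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def voxel_group_test(
    fields: list[VoxelField],
    partition: dict[tuple[int, int, int], str] | None = None,
    alpha: float = 0.05,
    per_voxel: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-voxel flags plus partition-level ART tests.

    Per voxel: same criteria as the shell analysis with Bonferroni across
    tested voxels.  If a proximal/distal ``partition`` map is given, PDL_voxel
    values are additionally pooled across the tested voxels of each partition
    and submitted to a single ART two-way ANOVA per partition, reporting the
    change in pooled median PDL_voxel from NE to F.

    Returns (per-voxel frame, per-partition frame).
    """
    per_morph = {
        (f.group, f.sample_id, f.regparam_id): f.values for f in fields
    }
    bins = sorted({k for f in fields for k in f.values})
    tested = _included_bins(per_morph, bins, ("NE", "F"))
    skipped = len(bins) - len(tested)
    if skipped:
        logger.info("voxel_group_test: %d voxels skipped for lack of coverage", skipped)
    m = max(len(tested), 1)
    rows = []
    for b in tested if per_voxel else []:
        resp, fa, fb = _factorial_table(per_morph, b)
        r = art_anova_2way(resp, fa, fb).apply_flag(alpha / m, alpha)
        ne, f = resp[fa == "NE"], resp[fa == "F"]
        rows.append(
            dict(
                i=b[0], j=b[1], k=b[2],
                ne_mean=float(ne.mean()), f_mean=float(f.mean()),
                p_maturation=r.p_main_A, p_regparam=r.p_main_B,
                p_interaction=r.p_interaction, flag=r.flag_significant,
                partition=(partition or {}).get(b, "unclassified"),
            )
        )
    voxel_df = pd.DataFrame(rows)

    part_rows = []
    if partition is not None:
        sides_present = [
            s
            for s in ("proximal", "distal")
            if any(partition.get(b) == s for b in tested)
        ]
        m_part = max(len(sides_present), 1)
        for side in ("proximal", "distal"):
            vox = [b for b in tested if partition.get(b) == side]
            if not vox:
                logger.info("voxel_group_test: no tested voxels in %s partition", side)
                continue
            # the factorial response is one value per morphology — its total
            # PDL share over the partition's tested voxels — so the error term
            # is honest between-sample variation, not cross-voxel spread;
            # the reported change in median uses the pooled voxel values
            resp, fa, fb, pooled, pooled_g = [], [], [], [], []
            for (grp, _sid, reg), v in per_morph.items():
                vals = [v.get(b, 0.0) for b in vox]
                resp.append(float(np.sum(vals)))
                fa.append(grp)
                fb.append(reg)
                pooled.extend(vals)
                pooled_g.extend([grp] * len(vals))
            resp = np.asarray(resp)
            fa = np.asarray(fa)
            pooled = np.asarray(pooled)
            pooled_g = np.asarray(pooled_g)
            r = art_anova_2way(resp, fa, np.asarray(fb)).apply_flag(
                alpha / m_part, alpha
            )
            med_ne = float(np.median(pooled[pooled_g == "NE"]))
            med_f = float(np.median(pooled[pooled_g == "F"]))
            part_rows.append(
                dict(
                    partition=side,
                    n_voxels=len(vox),
                    ne_median=med_ne,
                    f_median=med_f,
                    change_in_median_pct=(
                        100.0 * (med_f - med_ne) / med_ne if med_ne != 0 else math.nan
                    ),
                    p_maturation=r.p_main_A,
                    p_regparam=r.p_main_B,
                    p_interaction=r.p_interaction,
                    flag=r.flag_significant,
                )
            )
    return voxel_df, pd.DataFrame(part_rows)
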