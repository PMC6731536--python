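"""Whole-cell scalar morphometrics and group comparison.

Nineteen metric and topological measures are computed per morphological
subregion (WA/MB/DB/VB) and compared between maturation groups (newly emerged
adult, NE, vs forager, F) with two-sided Mann-Whitney U tests at a 5% cutoff.
Group summaries report min/median/max per group and the change in median,
``100 * (median_F - median_NE) / median_NE``.

Measures that are undefined for a subregion (e.g. partition asymmetry of an
unbranched main branch) are reported as missing (NaN), not zero.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .morph_io import MorphTree, SubregionSet, SUBREGIONS
from .stats_engine import mann_whitney

__all__ = [
    "MEASURES",
    "bounding_extent",
    "total_dendritic_length",
    "total_dendritic_volume",
    "total_surface_area",
    "max_centrifugal_order",
    "centrifugal_orders",
    "average_partition_asymmetry",
    "tree_asymmetry",
    "hausdorff_fractal_dimension",
    "compute_all_measures",
    "change_in_median",
    "compare_groups_scalar",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


def bounding_extent(tree: MorphTree, axis: str) -> float:
    """Extent (max - min) of node coordinates along ``axis`` in μm.

    Segments are straight, so node extrema suffice.
    """
    if axis not in _AXIS:
        raise ValueError(f"axis must be one of {tuple(_AXIS)}, got {axis!r}")
    coords = tree.positions()[:, _AXIS[axis]]
    return float(coords.max() - coords.min())


def total_dendritic_length(tree: MorphTree) -> float:
    """Total cable: sum of Euclidean parent-child distances, μm."""
    return tree.total_length()


def total_dendritic_volume(tree: MorphTree) -> float:
    """Sum of conical-frustum edge volumes (pi*h/3)*(r1^2 + r1*r2 + r2^2), μm^3."""
    c, p, cr, pr = tree.edge_arrays()
    if len(c) == 0:
        return 0.0
    h = np.linalg.norm(c - p, axis=1)
    return float((math.pi * h / 3.0 * (cr**2 + cr * pr + pr**2)).sum())


def total_surface_area(tree: MorphTree) -> float:
    """Frustum lateral surface: pi*(r1+r2)*slant per edge, μm^2."""
    c, p, cr, pr = tree.edge_arrays()
    if len(c) == 0:
        return 0.0
    h = np.linalg.norm(c - p, axis=1)
    slant = np.sqrt(h**2 + (cr - pr) ** 2)
    return float((math.pi * (cr + pr) * slant).sum())


def centrifugal_orders(tree: MorphTree) -> dict[int, int]:
    """Per node: number of bifurcation nodes strictly on the root path."""
    orders: dict[int, int] = {}
    for nid in tree.topological_order():
        node = tree.node(nid)
        if node.parent_id == -1:
            orders[nid] = 0
        else:
            bump = 1 if len(tree.children_of(node.parent_id)) >= 2 else 0
            orders[nid] = orders[node.parent_id] + bump
    return orders


def max_centrifugal_order(tree: MorphTree) -> int:
    return max(centrifugal_orders(tree).values())


def _tip_counts(tree: MorphTree) -> dict[int, int]:
    counts: dict[int, int] = {}
    for nid in reversed(tree.topological_order()):
        kids = tree.children_of(nid)
        counts[nid] = 1 if not kids else sum(counts[k] for k in kids)
    return counts


def _binary_partitions(tree: MorphTree) -> list[tuple[int, int]]:
    """Tip-count pairs (l, r) per binary split; an n-furcation is decomposed
    into (n-1) binary splits in child order (tip counts are conserved)."""
    counts = _tip_counts(tree)
    parts = []
    for bid in tree.bifurcations():
        if bid == tree.root.id:
            # the root's split is the cropped primary-neurite bifurcation,
            # not a dendritic branch point
            continue
        kid_tips = [counts[k] for k in tree.children_of(bid)]
        while len(kid_tips) > 1:
            left = kid_tips.pop(0)
            parts.append((left, sum(kid_tips)))
    return parts


def average_partition_asymmetry(tree: MorphTree) -> float:
    """Mean over bifurcations of |l-r|/(l+r-2); NaN when no bifurcations.

    ``l, r`` are terminal-tip counts of the two subtrees; an (1,1) split
    contributes 0.
    """
    parts = _binary_partitions(tree)
    if not parts:
        return math.nan
    vals = [0.0 if l + r == 2 else abs(l - r) / (l + r - 2) for l, r in parts]
    return float(np.mean(vals))


def tree_asymmetry(tree: MorphTree) -> float:
    """Tip-count-weighted partition asymmetry (weights l+r-2)."""
    parts = _binary_partitions(tree)
    weights = [l + r - 2 for l, r in parts]
    if not parts or sum(weights) == 0:
        return math.nan if not parts else 0.0
    num = sum(abs(l - r) for l, r in parts)
    return float(num / sum(weights))


# -- branch sections (paths between critical nodes) ---------------------------


def _branch_sections(tree: MorphTree) -> list[list[int]]:
    """Paths (node-id lists) from each critical node (root/bifurcation) to the
    next critical node or tip."""
    critical = {tree.root.id} | set(tree.bifurcations())
    sections = []
    for start in sorted(critical):
        for child in tree.children_of(start):
            path = [start, child]
            cur = child
            while cur not in critical and tree.children_of(cur):
                cur = tree.children_of(cur)[0]
                path.append(cur)
            sections.append(path)
    return sections


def _section_length(tree: MorphTree, path: list[int]) -> float:
    pos = np.array([tree.node(i).position for i in path])
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def _path_lengths_from_root(tree: MorphTree) -> dict[int, float]:
    pl: dict[int, float] = {}
    for nid in tree.topological_order():
        node = tree.node(nid)
        if node.parent_id == -1:
            pl[nid] = 0.0
        else:
            parent = tree.node(node.parent_id)
            d = math.dist(node.position, parent.position)
            pl[nid] = pl[node.parent_id] + d
    return pl


# -- fractal dimension ---------------------------------------------------------


def _resample_points(tree: MorphTree, step: float) -> np.ndarray:
    """Points along all edges at spacing <= step (both endpoints included)."""
    c, p, _, _ = tree.edge_arrays()
    if len(c) == 0:
        return tree.positions()
    pts = [tree.positions()]
    for a, b in zip(p, c):
        d = np.linalg.norm(b - a)
        n = max(int(np.ceil(d / step)), 1)
        t = np.arange(1, n)[:, None] / n
        if len(t):
            pts.append(a + t * (b - a))
    return np.vstack(pts)


def _box_count(points: np.ndarray, s: float, n_offsets: int = 5) -> int:
    """Minimal cover by boxes of size s over a few diagonal grid offsets.

    Taking the minimum approximates the covering number and removes most of
    the grid-alignment inflation (a bare line of length L occupies ~L/s
    boxes whatever its orientation)."""
    lo = points.min(axis=0)
    ext = points.max(axis=0) - lo
    nbox = np.maximum(np.ceil(ext / s), 1).astype(int)
    best = None
    for k in range(n_offsets):
        off = s * k / n_offsets
        idx = np.minimum(np.maximum((points - lo + off) // s, 0), nbox).astype(int)
        n = np.unique(idx, axis=0).shape[0]
        best = n if best is None else min(best, n)
    return best


def hausdorff_fractal_dimension(
    tree: MorphTree,
    resample_step: float = 1.0,
    n_scales: int = 7,
    min_box: float = 2.0,
    min_count: int = 16,
) -> float:
    """Box-counting estimate of the fractal dimension.

    All edges are resampled at ``resample_step`` μm; occupied cubic boxes
    N(s) are counted over a geometric ladder s = diag/2^j (j = 1..n_scales),
    and the slope of log N vs log(1/s) is fit by least squares over the
    scaling window N(s) >= ``min_count`` (coarse scales carry mostly
    bounding-box edge effects) and s >= ``min_box`` μm.  NaN for degenerate
    (near-point) geometry or an insufficient scaling window.
    """
    points = _resample_points(tree, resample_step)
    # canonical (principal-axis) orientation: the estimate is then invariant
    # to rigid rotation of the reconstruction up to axis sign
    centered = points - points.mean(axis=0)
    if len(points) > 3:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        points = centered @ vt.T
        # canonical axis signs (positive third moment) so mirror-image
        # projections do not shift the box alignment
        m3 = (points**3).mean(axis=0)
        points = points * np.where(m3 < 0, -1.0, 1.0)
    diag = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    if diag < 10 * resample_step:
        return math.nan
    scales, counts = [], []
    for j in range(1, n_scales + 1):
        s = diag / 2**j
        if s < min_box:
            break
        n = _box_count(points, s)
        if n >= min_count:
            scales.append(s)
            counts.append(n)
    if len(scales) < 2:
        return math.nan
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(scales)), np.log(counts), 1)
    return float(slope)


# -- measure registry ----------------------------------------------------------


def _mean_segment_length(tree: MorphTree) -> float:
    secs = _branch_sections(tree)
    if not secs:
        return math.nan
    return float(np.mean([_section_length(tree, s) for s in secs]))


def _max_branch_length(tree: MorphTree) -> float:
    secs = _branch_sections(tree)
    if not secs:
        return math.nan
    return float(max(_section_length(tree, s) for s in secs))


def _average_contraction(tree: MorphTree) -> float:
    secs = _branch_sections(tree)
    ratios = []
    for s in secs:
        path = _section_length(tree, s)
        if path <= 0:
            continue
        chord = math.dist(tree.node(s[0]).position, tree.node(s[-1]).position)
        ratios.append(chord / path)
    return float(np.mean(ratios)) if ratios else math.nan

# The six Table-1-style measures plus a canonical L-Measure-style complement.
MEASURES: dict[str, callable] = {
    "width_x": lambda t: bounding_extent(t, "x"),
    "height_y": lambda t: bounding_extent(t, "y"),
    "depth_z": lambda t: bounding_extent(t, "z"),
    "total_dendritic_volume": total_dendritic_volume,
    "total_surface_area": total_surface_area,
    "n_nodes": lambda t: float(len(t)),
    "n_bifurcations": lambda t: float(len(t.bifurcations())),
    "n_tips": lambda t: float(len(t.tips())),
    "max_centrifugal_order": lambda t: float(max_centrifugal_order(t)),
    "mean_branch_order": lambda t: float(np.mean(list(centrifugal_orders(t).values()))),
    "average_partition_asymmetry": average_partition_asymmetry,
    "tree_asymmetry": tree_asymmetry,
    "max_path_length": lambda t: float(max(_path_lengths_from_root(t).values())),
    "max_euclidean_distance": lambda t: float(
        np.linalg.norm(t.positions() - np.asarray(t.root.position), axis=1).max()
    ),
    "mean_segment_length": _mean_segment_length,
    "max_branch_length": _max_branch_length,
    "mean_radius": lambda t: float(np.mean([n.radius for n in t])),
    "average_contraction": _average_contraction,
    "hausdorff_fractal_dimension": hausdorff_fractal_dimension,
}
# measures meaningless on trees without bifurcations
_NEEDS_BIFURCATION = {
    "average_partition_asymmetry",
    "tree_asymmetry",
}


def compute_all_measures(subregions: SubregionSet) -> pd.DataFrame:
    """Tidy table of every registered measure for each subregion.

    Columns: sample_id, group, subregion, measure, value.  Missing subregions
    (empty DB/VB) and undefined measures yield NaN values.
    """
    rows = []
    for subregion, tree in subregions.items():
        for measure, fn in MEASURES.items():
            if tree is None:
                value = math.nan
            else:
                value = fn(tree)
            rows.append(
                dict(
                    sample_id=subregions.sample_id,
                    group=subregions.group,
                    regparam_id=subregions.regparam_id,
                    subregion=subregion,
                    measure=measure,
                    value=value,
                )
            )
    return pd.DataFrame(rows)


def change_in_median(median_ne: float, median_f: float) -> float:
    """Percent change in median from NE to F: 100*(median_F - median_NE)/median_NE."""
    if median_ne == 0:
        raise ZeroDivisionError("change_in_median undefined for median_NE = 0")
    return 100.0 * (median_f - median_ne) / median_ne


def compare_groups_scalar(rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group summary per measure x subregion (Table-1-style).

    Input is the tidy frame from :func:`compute_all_measures` pooled over
    samples.  Output columns: measure, subregion, ne_min/median/max,
    f_min/median/max, change_in_median_pct, p_value, significant.  A measure
    missing for any sample in either group is summarized as N/A (all NaN).
    No multiplicity correction is applied (per-measure 5% cutoff).
    """
    out = []
    for (measure, subregion), grp in rows.groupby(["measure", "subregion"], sort=False):
        ne = grp.loc[grp.group == "NE", "value"].to_numpy(dtype=float)
        f = grp.loc[grp.group == "F", "value"].to_numpy(dtype=float)
        rec = dict(measure=measure, subregion=subregion)
        ne_ok = ne.size > 0 and not np.isnan(ne).any()
        f_ok = f.size > 0 and not np.isnan(f).any()
        if not (ne_ok and f_ok):
            for k in ("ne_min", "ne_median", "ne_max", "f_min", "f_median", "f_max",
                      "change_in_median_pct", "p_value"):
                rec[k] = math.nan
            rec["significant"] = False
            out.append(rec)
            continue
        rec.update(
            ne_min=ne.min(), ne_median=float(np.median(ne)), ne_max=ne.max(),
            f_min=f.min(), f_median=float(np.median(f)), f_max=f.max(),
        )
        med_ne = rec["ne_median"]
        rec["change_in_median_pct"] = (
            change_in_median(med_ne, rec["f_median"]) if med_ne != 0 else math.nan
        )
        res = mann_whitney(ne, f)
        rec["p_value"] = res.p_two_sided
        rec["significant"] = res.p_two_sided < alpha
        out.append(rec)
    return pd.DataFrame(out)
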