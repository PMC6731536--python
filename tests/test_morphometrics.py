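import math

import numpy as np
import pytest

from dlint1.morph_io import MorphNode, MorphTree, split_subregions
from dlint1.morphometrics import (
    MEASURES,
    average_partition_asymmetry,
    bounding_extent,
    change_in_median,
    compare_groups_scalar,
    compute_all_measures,
    hausdorff_fractal_dimension,
    max_centrifugal_order,
    total_dendritic_length,
    total_dendritic_volume,
)
from conftest import binary_tree, chain_tree


def _rotated(tree: MorphTree, R: np.ndarray, shift=(0.0, 0.0, 0.0)) -> MorphTree:
    return MorphTree(
        [
            MorphNode(
                n.id, n.parent_id,
                tuple(R @ np.asarray(n.position) + np.asarray(shift)),
                n.radius, n.structure_label,
            )
            for n in tree.nodes
        ]
    )


class TestExtentAndLength:
    def test_extent_examples(self):
        t = chain_tree([(0, 0, 0), (10, 1, 2), (25.5, -1, 4)])
        assert bounding_extent(t, "x") == pytest.approx(25.5)
        single = chain_tree([(3, 4, 5)])
        assert bounding_extent(single, "y") == 0.0

    def test_extent_matches_brute_force_scan(self, random_trees):
        for t in random_trees:
            pos = t.positions()
            for ax, name in enumerate("xyz"):
                assert bounding_extent(t, name) == pytest.approx(
                    max(p[ax] for p in pos) - min(p[ax] for p in pos)
                )

    def test_length_chain(self):
        t = chain_tree([(0, 0, 0), (10, 0, 0), (20, 0, 0)])
        assert total_dendritic_length(t) == pytest.approx(20.0)
        assert total_dendritic_length(chain_tree([(5, 5, 5)])) == 0.0

    def test_length_matches_pairwise_oracle(self, random_trees):
        for t in random_trees:
            expected = sum(
                math.dist(t.node(c).position, t.node(p).position)
                for c, p in t.edges()
            )
            assert total_dendritic_length(t) == pytest.approx(expected, rel=1e-12)


class TestVolume:
    def test_cylinder_and_cone(self):
        cyl = chain_tree([(0, 0, 0), (3, 0, 0)], radii=[1.0, 1.0])
        assert total_dendritic_volume(cyl) == pytest.approx(3 * math.pi)
        cone = chain_tree([(0, 0, 0), (3, 0, 0)], radii=[1.0, 0.0])
        assert total_dendritic_volume(cone) == pytest.approx(math.pi)

    def test_matches_numeric_integration(self, random_trees):
        # integrate pi*r(t)^2 along each edge with linearly varying radius
        for t in random_trees[:10]:
            expected = 0.0
            for c, p in t.edges():
                h = math.dist(t.node(c).position, t.node(p).position)
                r0, r1 = t.node(p).radius, t.node(c).radius
                s = np.linspace(0, 1, 2001)
                r = r0 + (r1 - r0) * s
                expected += float(np.trapezoid(math.pi * r**2, s) * h)
            assert total_dendritic_volume(t) == pytest.approx(expected, rel=1e-6)


class TestTopology:
    def test_chain_has_order_zero(self):
        assert max_centrifugal_order(chain_tree([(0, 0, 0), (1, 0, 0), (2, 0, 0)])) == 0

    def test_perfect_binary_tree_order(self):
        assert max_centrifugal_order(binary_tree(3)) == 3

    def test_order_matches_bfs_oracle(self, random_trees):
        for t in random_trees:
            # BFS that counts multi-child nodes along each root path
            best = 0
            stack = [(t.root.id, 0)]
            while stack:
                nid, order = stack.pop()
                kids = t.children_of(nid)
                bump = 1 if len(kids) >= 2 else 0
                best = max(best, order)
                stack.extend((k, order + bump) for k in kids)
            assert max_centrifugal_order(t) == best


class TestPartitionAsymmetry:
    def test_balanced_split_is_zero(self):
        # stem -> bifurcation with two tips: one (1,1) split
        t = chain_tree([(0, 0, 0), (5, 0, 0)])
        nodes = list(t.nodes)
        nodes.append(MorphNode(3, 2, (10.0, 3.0, 0.0), 1.0))
        nodes.append(MorphNode(4, 2, (10.0, -3.0, 0.0), 1.0))
        assert average_partition_asymmetry(MorphTree(nodes)) == 0.0

    def test_three_one_split(self):
        # stem -> bifurcation with a 3-tip subtree and a single tip
        nodes = [
            MorphNode(1, -1, (0, 0, 0), 1.0),
            MorphNode(2, 1, (1, 0, 0), 1.0),  # stem (bifurcates below)
            MorphNode(3, 2, (2, 1, 0), 1.0),  # side A: tip
            MorphNode(4, 2, (2, -1, 0), 1.0),  # side B: 3 tips below
            MorphNode(5, 4, (3, -1, 1), 1.0),
            MorphNode(6, 4, (3, -2, 0), 1.0),
            MorphNode(7, 6, (4, -2, 1), 1.0),
            MorphNode(8, 6, (4, -3, 0), 1.0),
        ]
        t = MorphTree(nodes)
        # splits: (1,3) at node 2 -> |1-3|/2 = 1; (1,2) at 4 -> 1; (1,1) at 6 -> 0
        assert average_partition_asymmetry(t) == pytest.approx((1.0 + 1.0 + 0.0) / 3)

    def test_no_bifurcation_is_missing(self):
        assert math.isnan(average_partition_asymmetry(chain_tree([(0, 0, 0), (1, 0, 0)])))

    def test_matches_enumeration_oracle(self, random_trees):
        for t in random_trees:
            tips = {}
            for nid in reversed(t.topological_order()):
                kids = t.children_of(nid)
                tips[nid] = 1 if not kids else sum(tips[k] for k in kids)
            vals = []
            for b in t.bifurcations():
                if b == t.root.id:
                    continue
                counts = [tips[k] for k in t.children_of(b)]
                while len(counts) > 1:
                    l = counts.pop(0)
                    r = sum(counts)
                    vals.append(0.0 if l + r == 2 else abs(l - r) / (l + r - 2))
            assert average_partition_asymmetry(t) == pytest.approx(np.mean(vals))


class TestFractalDimension:
    def test_straight_segment_is_one_dimensional(self):
        t = chain_tree([(i * 20.0, 0, 0) for i in range(11)])
        assert 0.95 <= hausdorff_fractal_dimension(t) <= 1.05

    def test_dense_grid_is_two_dimensional(self):
        # 20x20 crossbars over a 60x60 μm square
        ext, n = 60.0, 20
        nodes = [MorphNode(1, -1, (0, 0, 0), 0.5)]
        nid = 2
        sp = ext / (n - 1)
        for k in range(n):
            for start, end in (
                ((0.001, k * sp, 0), (ext, k * sp, 0)),
                ((k * sp, 0.001, 0), (k * sp, ext, 0)),
            ):
                nodes.append(MorphNode(nid, 1, start, 0.5))
                nodes.append(MorphNode(nid + 1, nid, end, 0.5))
                nid += 2
        t = MorphTree(nodes)
        assert 1.8 <= hausdorff_fractal_dimension(t) <= 2.05

    def test_degenerate_returns_missing(self):
        assert math.isnan(hausdorff_fractal_dimension(chain_tree([(0, 0, 0), (1, 0, 0)])))

    def test_rotation_invariance(self, random_trees, rng):
        from scipy.spatial.transform import Rotation

        for t in random_trees[:6]:
            D = hausdorff_fractal_dimension(t)
            R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
            D2 = hausdorff_fractal_dimension(_rotated(t, R))
            assert abs(D - D2) < 0.05


class TestInvariances:
    def test_rigid_motion_invariance_of_metrics(self, random_trees, rng):
        from scipy.spatial.transform import Rotation

        t = random_trees[0]
        R = Rotation.random(random_state=7).as_matrix()
        moved = _rotated(t, R, shift=(12.0, -5.0, 30.0))
        assert total_dendritic_length(moved) == pytest.approx(
            total_dendritic_length(t), rel=1e-9
        )
        assert total_dendritic_volume(moved) == pytest.approx(
            total_dendritic_volume(t), rel=1e-9
        )

    def test_scaling_laws(self, random_trees):
        t = random_trees[1]
        k = 2.0
        scaled = MorphTree(
            [
                MorphNode(
                    n.id, n.parent_id,
                    tuple(k * x for x in n.position), k * n.radius,
                )
                for n in t.nodes
            ]
        )
        assert total_dendritic_length(scaled) == pytest.approx(
            k * total_dendritic_length(t), rel=1e-9
        )
        assert total_dendritic_volume(scaled) == pytest.approx(
            k**3 * total_dendritic_volume(t), rel=1e-9
        )


class TestChangeInMedian:
    def test_identity_is_zero(self):
        assert change_in_median(7.7, 7.7) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            change_in_median(0.0, 1.0)

    def test_antisymmetry_under_group_swap(self):
        c = change_in_median(22.1, 34.1)
        c_swapped = change_in_median(34.1, 22.1)
        assert c_swapped == pytest.approx(-100 * c / (100 + c))


class TestMeasureTable:
    def test_registry_has_nineteen_measures(self):
        assert len(MEASURES) == 19

    def test_unbranched_mb_yields_missing_asymmetry(self):
        nodes = [MorphNode(1, -1, (0, 0, 0), 1.0)]
        nodes += [MorphNode(2, 1, (0, 10, 0), 1.0), MorphNode(3, 2, (0, 20, 0), 1.0)]
        nodes += [MorphNode(4, 1, (0, -10, 0), 1.0), MorphNode(5, 4, (0, -20, 0), 1.0)]
        t = MorphTree(nodes, sample_id="s1", group="NE")
        with pytest.warns(UserWarning):
            sub = split_subregions(t, 2, 4)
        rows = compute_all_measures(sub)
        mb = rows[(rows.subregion == "MB")].set_index("measure")["value"]
        assert math.isnan(mb["average_partition_asymmetry"])
        assert mb["width_x"] == 0.0
        assert mb["total_surface_area"] > 0.0
        assert len(rows) == 19 * 4

    def test_group_comparison_known_case(self):
        import pandas as pd

        rows = pd.DataFrame(
            [
                dict(sample_id=f"n{i}", group="NE", subregion="WA",
                     measure="width_x", value=v)
                for i, v in enumerate([1.0, 2.0, 3.0])
            ]
            + [
                dict(sample_id=f"f{i}", group="F", subregion="WA",
                     measure="width_x", value=v)
                for i, v in enumerate([4.0, 5.0, 6.0])
            ]
        )
        out = compare_groups_scalar(rows).iloc[0]
        assert out.change_in_median_pct == pytest.approx(150.0)
        assert out.p_value == pytest.approx(0.1)  # exact MW, U = 0, n = m = 3

    def test_identical_groups_not_significant(self):
        import pandas as pd

        rows = pd.DataFrame(
            [
                dict(sample_id=f"{g}{i}", group=g, subregion="WA",
                     measure="n_nodes", value=float(i))
                for g in ("NE", "F")
                for i in range(1, 7)
            ]
        )
        out = compare_groups_scalar(rows).iloc[0]
        assert out.change_in_median_pct == 0.0
        assert out.p_value > 0.9
        assert not out.significant
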