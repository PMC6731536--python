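import math

import numpy as np
import pytest

from dlint1.morph_io import MorphNode, MorphTree
from dlint1.spatial_density import (
    classify_voxels,
    clip_length_to_shells,
    clip_length_to_voxels,
    normalized_change,
    percent_pl_annotate,
    shell_group_test,
    voxel_group_test,
    VoxelField,
)
from conftest import chain_tree
from oracles import resample_shell_profile, resample_voxel_field


class TestShellClipping:
    def test_radial_segment_spans_three_shells(self):
        t = chain_tree([(0, 0, 0), (50, 0, 0)])
        prof = clip_length_to_shells(t, (0, 0, 0), 20.0)
        assert prof.values[0] == pytest.approx(40.0)
        assert prof.values[1] == pytest.approx(40.0)
        assert prof.values[2] == pytest.approx(20.0)

    def test_segment_inside_one_shell(self):
        t = chain_tree([(65, 0, 0), (70, 0, 0)])
        prof = clip_length_to_shells(t, (0, 0, 0), 20.0)
        assert prof.values == {3: pytest.approx(100.0)}

    def test_chord_through_shells(self):
        # chord at distance 15 from center: dips into shell 0 in the middle
        t = chain_tree([(-20, 15, 0), (20, 15, 0)])
        prof = clip_length_to_shells(t, (0, 0, 0), 20.0)
        half_chord = math.sqrt(20**2 - 15**2)
        inner = 2 * half_chord / 40 * 100
        assert prof.values[0] == pytest.approx(inner)
        assert prof.values[1] == pytest.approx(100 - inner)

    def test_sums_to_hundred(self, random_trees):
        for t in random_trees:
            prof = clip_length_to_shells(t, t.root.position, 20.0)
            assert sum(prof.values.values()) == pytest.approx(100.0, abs=1e-6)

    def test_matches_resampling_oracle(self, random_trees):
        for t in random_trees[:4]:
            prof = clip_length_to_shells(t, t.root.position, 20.0)
            oracle = resample_shell_profile(t, t.root.position, 20.0, step=0.02)
            for k in set(prof.values) | set(oracle):
                assert prof.values.get(k, 0.0) == pytest.approx(
                    oracle.get(k, 0.0), abs=0.1
                )

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            clip_length_to_shells(chain_tree([(1, 1, 1)]), (0, 0, 0), 20.0)


class TestVoxelClipping:
    def test_segment_inside_one_voxel(self):
        t = chain_tree([(2, 2, 2), (12, 2, 2)])
        f = clip_length_to_voxels(t, (0, 0, 0), 20.0)
        assert f.values == {(0, 0, 0): pytest.approx(100.0)}

    def test_segment_split_at_plane(self):
        t = chain_tree([(10, 10, 10), (30, 10, 10)])
        f = clip_length_to_voxels(t, (0, 0, 0), 20.0)
        assert f.values[(0, 0, 0)] == pytest.approx(50.0)
        assert f.values[(1, 0, 0)] == pytest.approx(50.0)

    def test_boundary_point_belongs_to_higher_voxel(self):
        t = chain_tree([(20, 0.5, 0.5), (25, 0.5, 0.5)])
        f = clip_length_to_voxels(t, (0, 0, 0), 20.0)
        assert list(f.values) == [(1, 0, 0)]

    def test_sums_to_hundred(self, random_trees):
        for t in random_trees:
            f = clip_length_to_voxels(t)
            assert sum(f.values.values()) == pytest.approx(100.0, abs=1e-6)

    def test_matches_resampling_oracle(self, random_trees):
        for t in random_trees[:4]:
            f = clip_length_to_voxels(t)
            oracle = resample_voxel_field(t, (0, 0, 0), 20.0, step=0.02)
            for k in set(f.values) | set(oracle):
                assert f.values.get(k, 0.0) == pytest.approx(
                    oracle.get(k, 0.0), abs=0.1
                )

    def test_orientation_independence(self):
        fwd = chain_tree([(10, 10, 10), (30, 10, 10), (30, 30, 10)])
        # reversed parentage: same geometry walked from the other end
        rev = chain_tree([(30, 30, 10), (30, 10, 10), (10, 10, 10)])
        f1 = clip_length_to_voxels(fwd)
        f2 = clip_length_to_voxels(rev)
        for k in set(f1.values) | set(f2.values):
            assert f1.values.get(k, 0.0) == pytest.approx(f2.values.get(k, 0.0))

    def test_refinement_reaggregates(self, random_trees):
        t = random_trees[0]
        coarse = clip_length_to_voxels(t, voxel_size=20.0)
        fine = clip_length_to_voxels(t, voxel_size=10.0)
        total = t.total_length()
        for key, pct in coarse.values.items():
            children = sum(
                fine.values.get((2 * key[0] + i, 2 * key[1] + j, 2 * key[2] + k), 0.0)
                for i in range(2) for j in range(2) for k in range(2)
            )
            assert children * total == pytest.approx(pct * total, abs=1e-6 * total)


class TestPercentPL:
    def test_root_terminal_and_interior(self):
        t = chain_tree([(0, 0, 0), (90, 0, 0), (100, 0, 0)])
        ann = percent_pl_annotate(t)
        by_id = dict(zip(ann.node_ids, ann.percent_pl))
        assert by_id[1] == 0.0
        assert by_id[3] == 100.0
        assert by_id[2] == pytest.approx(90.0)

    def test_scaling_invariance(self, random_trees):
        t = random_trees[0]
        scaled = MorphTree(
            [
                MorphNode(n.id, n.parent_id, tuple(3.0 * x for x in n.position), n.radius)
                for n in t.nodes
            ]
        )
        a = percent_pl_annotate(t)
        b = percent_pl_annotate(scaled)
        np.testing.assert_allclose(a.percent_pl, b.percent_pl, atol=1e-9)


class TestClassifyVoxels:
    def _population(self):
        trees = [
            chain_tree([(0, 0, 0), (90, 0, 0), (100, 0, 0)], sample_id=s, group=g)
            for s, g in (("a", "NE"), ("b", "F"))
        ]
        fields = [clip_length_to_voxels(t) for t in trees]
        anns = [percent_pl_annotate(t) for t in trees]
        return fields, anns

    def test_terminal_voxels_distal_root_voxels_proximal(self):
        fields, anns = self._population()
        part = classify_voxels(fields, anns, threshold=90.0)
        assert part[(0, 0, 0)] == "proximal"  # contains the root (%PL = 0)
        assert part[(5, 0, 0)] == "distal"  # contains only the terminal node

    def test_threshold_monotonicity(self, random_trees):
        fields = [clip_length_to_voxels(t) for t in random_trees[:6]]
        anns = [percent_pl_annotate(t) for t in random_trees[:6]]
        prev_distal = None
        for thr in (80.0, 90.0, 95.0):
            part = classify_voxels(fields, anns, threshold=thr)
            distal = {k for k, v in part.items() if v == "distal"}
            if prev_distal is not None:
                assert distal <= prev_distal
            prev_distal = distal

    def test_mismatched_grids_rejected(self):
        fields, anns = self._population()
        fields[1].voxel_size = 10.0
        with pytest.raises(ValueError, match="share origin"):
            classify_voxels(fields, anns)


class TestNormalizedChange:
    @staticmethod
    def _field(group, sample, values):
        return VoxelField(
            sample_id=sample, group=group, regparam_id="rp0", subregion="WA",
            voxel_size=20.0, origin=(0, 0, 0), values=values,
        )

    def test_equal_means_give_zero(self):
        fields = [
            self._field("NE", "a", {(0, 0, 0): 2.0}),
            self._field("F", "b", {(0, 0, 0): 2.0}),
        ]
        assert normalized_change(fields).values[(0, 0, 0)] == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        fields = [
            self._field("NE", "a", {(0, 0, 0): 1.0}),
            self._field("F", "b", {(0, 0, 0): 3.0}),
        ]
        assert normalized_change(fields).values[(0, 0, 0)] == pytest.approx(1.0)

    def test_matches_flat_averaging_oracle(self, rng):
        for _ in range(20):
            keys = [(i, 0, 0) for i in range(4)]
            fields = []
            table = []
            for g in ("NE", "F"):
                for s in range(3):
                    for rp in range(2):
                        vals = {k: float(rng.uniform(0, 5)) for k in keys}
                        fields.append(
                            VoxelField(
                                sample_id=f"{g}{s}", group=g, regparam_id=f"rp{rp}",
                                subregion="WA", voxel_size=20.0, origin=(0, 0, 0),
                                values=vals,
                            )
                        )
                        table.extend((g, k, v) for k, v in vals.items())
            out = normalized_change(fields)
            for k in keys:
                f_vals = [v for g, kk, v in table if g == "F" and kk == k]
                n_vals = [v for g, kk, v in table if g == "NE" and kk == k]
                grand = np.mean(f_vals + n_vals)
                expected = (np.mean(f_vals) - np.mean(n_vals)) / grand
                assert out.values[k] == pytest.approx(expected, abs=1e-12)

    def test_requires_both_groups(self):
        with pytest.raises(ValueError):
            normalized_change([self._field("NE", "a", {(0, 0, 0): 1.0})])


def _shell_population(rng, shift_shell=None, delta=0.0, n=6, n_rp=3):
    """ShellProfiles over 8 shells with optional group shift in one shell."""
    from dlint1.spatial_density import ShellProfile

    profiles = []
    base = np.array([5.0, 15.0, 25.0, 20.0, 15.0, 10.0, 7.0, 3.0])
    for g in ("NE", "F"):
        for s in range(n):
            for rp in range(n_rp):
                # raw per-shell responses (no compositional renormalization:
                # the shift must stay confined to the target shell)
                vals = base + rng.normal(0, 1.0, base.size)
                if g == "F" and shift_shell is not None:
                    vals[shift_shell] += delta
                vals = np.clip(vals, 0.01, None)
                profiles.append(
                    ShellProfile(
                        sample_id=f"{g}{s}", group=g, regparam_id=f"rp{rp}",
                        subregion="WA", shell_thickness=20.0, center=(0, 0, 0),
                        values=dict(enumerate(vals)),
                    )
                )
    return profiles


class TestShellGroupTest:
    def test_pure_shift_flags_only_target_shell(self, rng):
        hits = others = 0
        n_sim = 10
        for _ in range(n_sim):
            profiles = _shell_population(rng, shift_shell=5, delta=6.0, n_rp=9)
            out = shell_group_test(profiles)
            flagged = set(out.loc[out.flag, "shell"])
            hits += 5 in flagged
            others += len(flagged - {5})
        assert hits >= 8
        assert others <= n_sim  # stray flags are rare

    def test_identical_groups_no_flags(self, rng):
        profiles = _shell_population(rng)
        out = shell_group_test(profiles)
        assert not out.flag.any()

    def test_permuted_labels_control_type_one(self, rng):
        false_flags = 0
        n_sim = 20
        for _ in range(n_sim):
            profiles = _shell_population(rng)
            labels = [p.group for p in profiles]
            rng.shuffle(labels)
            for p, g in zip(profiles, labels):
                p.group = g
            try:
                out = shell_group_test(profiles)
            except ValueError:
                continue
            false_flags += int(out.flag.sum())
        assert false_flags <= max(2, 0.05 * 8 * n_sim)


class TestVoxelGroupTest:
    def test_degenerate_single_voxel_skipped(self, caplog):
        fields = [
            VoxelField(
                sample_id=s, group=g, regparam_id=f"rp{rp}", subregion="WA",
                voxel_size=20.0, origin=(0, 0, 0),
                values={(0, 0, 0): 100.0} if g == "NE" else {(1, 0, 0): 100.0},
            )
            for g, s in (("NE", "a"), ("NE", "b"), ("F", "c"), ("F", "d"))
            for rp in range(2)
        ]
        import logging

        with caplog.at_level(logging.INFO, logger="dlint1.spatial_density"):
            vox, parts = voxel_group_test(fields, None)
        assert vox.empty
        assert "skipped" in caplog.text
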