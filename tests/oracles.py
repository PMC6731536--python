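"""Independent brute-force oracles used by unit and acceptance tests."""

import numpy as np


def resample_shell_profile(tree, center, thickness, step=0.01):
    """Shell percentages by dense edge resampling (midpoint binning)."""
    center = np.asarray(center, dtype=float)
    acc = {}
    total = 0.0
    c, p, _, _ = tree.edge_arrays()
    for a, b in zip(p, c):
        L = float(np.linalg.norm(b - a))
        if L == 0:
            continue
        n = max(int(np.ceil(L / step)), 1)
        mids = a + (np.arange(n)[:, None] + 0.5) / n * (b - a)
        r = np.linalg.norm(mids - center, axis=1)
        ks, counts = np.unique((r // thickness).astype(int), return_counts=True)
        for k, cnt in zip(ks, counts):
            acc[int(k)] = acc.get(int(k), 0.0) + cnt * L / n
        total += L
    return {k: 100.0 * v / total for k, v in acc.items()}


def resample_voxel_field(tree, origin, size, step=0.01):
    """Voxel percentages by dense edge resampling (midpoint binning)."""
    origin = np.asarray(origin, dtype=float)
    acc = {}
    total = 0.0
    c, p, _, _ = tree.edge_arrays()
    for a, b in zip(p, c):
        L = float(np.linalg.norm(b - a))
        if L == 0:
            continue
        n = max(int(np.ceil(L / step)), 1)
        mids = a + (np.arange(n)[:, None] + 0.5) / n * (b - a)
        idx = np.floor((mids - origin) / size).astype(int)
        keys, counts = np.unique(idx, axis=0, return_counts=True)
        for k, cnt in zip(map(tuple, keys), counts):
            acc[k] = acc.get(k, 0.0) + cnt * L / n
        total += L
    return {k: 100.0 * v / total for k, v in acc.items()}
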