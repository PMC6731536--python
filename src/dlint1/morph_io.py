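"""Reading, validating, writing and subdividing SWC neuron reconstructions.

SWC is the standard 7-column plain-text format for neuron morphologies:
``id type x y z radius parent_id`` per line, with ``#`` comments and a single
root whose parent id is -1.  Coordinates are micrometres and are assumed to be
already co-registered to a common frame; no transform is applied on read.

A reconstruction is subdivided into the four analysis subregions used for the
DL-Int-1 interneuron:

* **MB** (main branch): the two daughter paths of the primary neurite, from the
  root up to and including their first bifurcation nodes,
* **DB** / **VB** (dorsal / ventral branch): the arborizations distal to the
  first bifurcation on the respective daughter,
* **WA** (whole arborization): MB + DB + VB.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "MorphNode",
    "MorphTree",
    "SubregionSet",
    "SwcParseError",
    "SwcStructureError",
    "read_swc",
    "write_swc",
    "split_subregions",
    "read_manifest",
]

SUBREGIONS = ("WA", "MB", "DB", "VB")
GROUPS = ("NE", "F", "unknown")


class SwcParseError(ValueError):
    """A malformed SWC line (wrong field count or non-numeric field)."""


class SwcStructureError(ValueError):
    """Topologically invalid tree (orphan parent, multiple roots, cycle)."""


@dataclass(frozen=True)
class MorphNode:
    """One SWC sample point: position + radius + parent link."""

    id: int
    parent_id: int
    position: tuple[float, float, float]
    radius: float
    structure_label: int = 0

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise SwcStructureError(f"node id must be positive, got {self.id}")
        if self.radius < 0:
            raise SwcStructureError(
                f"node {self.id}: radius must be non-negative, got {self.radius}"
            )


class MorphTree:
    """A rooted tree of 3D points with radii; the unit of all morphometry.

    Parameters
    ----------
    nodes
        Sequence of :class:`MorphNode`; need not be in topological order.
    name, group, sample_id, regparam_id
        Provenance labels.  ``group`` is one of ``NE`` (newly emerged adult),
        ``F`` (forager) or ``unknown``; ``regparam_id`` identifies the
        registration-parameter set the coordinates were produced with.
    """

    def __init__(
        self,
        nodes: Sequence[MorphNode],
        name: str = "",
        group: str = "unknown",
        sample_id: str = "",
        regparam_id: str = "",
        validate: bool = True,
    ) -> None:
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
        self.nodes: list[MorphNode] = list(nodes)
        self.name = name
        self.group = group
        self.sample_id = sample_id
        self.regparam_id = regparam_id
        self._build()
        if validate:
            self._validate()

    # -- structure -----------------------------------------------------------

    def _build(self) -> None:
        if not self.nodes:
            raise SwcStructureError("tree has no nodes")
        self._by_id = {n.id: n for n in self.nodes}
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SwcStructureError(
                f"tree must have exactly one root (parent_id -1), found {len(roots)}"
            )
        self._root = roots[0]
        children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id == -1:
                continue
            if n.parent_id not in self._by_id:
                raise SwcStructureError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
            children[n.parent_id].append(n.id)
        self._children = children

    def _validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SwcStructureError(f"duplicate node ids: {dup}")
        # connectivity (and implicitly acyclicity: N-1 edges reaching all nodes)
        seen: set[int] = set()
        stack = [self._root.id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise SwcStructureError(f"cycle detected at node {i}")
            seen.add(i)
            stack.extend(self._children[i])
        if len(seen) != len(self.nodes):
            missing = sorted(set(ids) - seen)
            raise SwcStructureError(f"nodes unreachable from root: {missing}")
        for n in self.nodes:
            if n.parent_id != -1:
                if n.position == self._by_id[n.parent_id].position:
                    warnings.warn(
                        f"node {n.id} coincides with its parent (zero-length edge)",
                        stacklevel=3,
                    )

    # -- accessors -----------------------------------------------------------

    @property
    def root(self) -> MorphNode:
        return self._root

    def node(self, node_id: int) -> MorphNode:
        return self._by_id[node_id]

    def children_of(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def parent_of(self, node_id: int) -> int:
        return self._by_id[node_id].parent_id

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[MorphNode]:
        return iter(self.nodes)

    def positions(self) -> np.ndarray:
        """(N, 3) array of node coordinates in file order, μm."""
        return np.array([n.position for n in self.nodes], dtype=float)

    def edges(self) -> list[tuple[int, int]]:
        """(child_id, parent_id) pairs; one per non-root node."""
        return [(n.id, n.parent_id) for n in self.nodes if n.parent_id != -1]

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized edge geometry: child xyz, parent xyz, child r, parent r."""
        cs, ps, cr, pr = [], [], [], []
        for n in self.nodes:
            if n.parent_id == -1:
                continue
            p = self._by_id[n.parent_id]
            cs.append(n.position)
            ps.append(p.position)
            cr.append(n.radius)
            pr.append(p.radius)
        if not cs:
            z = np.zeros((0, 3))
            return z, z, np.zeros(0), np.zeros(0)
        return (
            np.asarray(cs, dtype=float),
            np.asarray(ps, dtype=float),
            np.asarray(cr, dtype=float),
            np.asarray(pr, dtype=float),
        )

    def edge_lengths(self) -> np.ndarray:
        c, p, _, _ = self.edge_arrays()
        return np.linalg.norm(c - p, axis=1)

    def total_length(self) -> float:
        """Total cable (sum of straight parent-child distances), μm."""
        return float(self.edge_lengths().sum())

    def topological_order(self) -> list[int]:
        """Node ids, parents before children."""
        order = []
        stack = [self._root.id]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self._children[i]))
        return order

    def tips(self) -> list[int]:
        return [n.id for n in self.nodes if not self._children[n.id]]

    def bifurcations(self) -> list[int]:
        """Ids of nodes with 2+ children (multifurcations included)."""
        return [n.id for n in self.nodes if len(self._children[n.id]) >= 2]

    def subtree_ids(self, node_id: int) -> set[int]:
        out: set[int] = set()
        stack = [node_id]
        while stack:
            i = stack.pop()
            out.add(i)
            stack.extend(self._children[i])
        return out

    def extract(self, node_ids: set[int], root_id: int, **labels) -> "MorphTree":
        """Subtree on ``node_ids`` rooted at ``root_id`` (its parent link cut)."""
        nodes = []
        for n in self.nodes:
            if n.id not in node_ids:
                continue
            if n.id == root_id:
                nodes.append(
                    MorphNode(n.id, -1, n.position, n.radius, n.structure_label)
                )
            else:
                nodes.append(n)
        meta = dict(
            name=self.name,
            group=self.group,
            sample_id=self.sample_id,
            regparam_id=self.regparam_id,
        )
        meta.update(labels)
        return MorphTree(nodes, **meta)

    def with_labels(self, **labels) -> "MorphTree":
        meta = dict(
            name=self.name,
            group=self.group,
            sample_id=self.sample_id,
            regparam_id=self.regparam_id,
        )
        meta.update(labels)
        return MorphTree(self.nodes, **meta)


@dataclass
class SubregionSet:
    """The four morphological subregions of one reconstruction.

    ``DB`` and ``VB`` may be ``None`` when the corresponding daughter path has
    no bifurcation (the whole daughter then lives in MB).  ``SPN`` (soma and
    primary neurite) is carried if supplied but excluded from all analyses.
    """

    WA: MorphTree
    MB: MorphTree
    DB: MorphTree | None
    VB: MorphTree | None
    SPN: MorphTree | None = None
    provenance: str = ""

    def get(self, subregion: str) -> MorphTree | None:
        if subregion not in SUBREGIONS:
            raise KeyError(f"unknown subregion {subregion!r}")
        return getattr(self, subregion)

    def items(self) -> Iterator[tuple[str, MorphTree | None]]:
        for s in SUBREGIONS:
            yield s, getattr(self, s)

    @property
    def sample_id(self) -> str:
        return self.WA.sample_id

    @property
    def group(self) -> str:
        return self.WA.group

    @property
    def regparam_id(self) -> str:
        return self.WA.regparam_id


# -- SWC file I/O -------------------------------------------------------------


def read_swc(path: str | Path, **labels) -> MorphTree:
    """Parse an SWC file into a validated :class:`MorphTree`.

    ``#`` comment lines and blank lines are skipped; any column whitespace is
    accepted.  Extra keyword arguments (``group``, ``sample_id``, ...) become
    tree labels.

    Raises
    ------
    SwcParseError
        On a malformed line, naming the line number.
    SwcStructureError
        On orphan parent references, multiple roots, duplicate ids or cycles.
    """
    path = Path(path)
    nodes: list[MorphNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SwcParseError(
                    f"{path.name}:{lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                nid = int(fields[0])
                label = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise SwcParseError(f"{path.name}:{lineno}: {exc}") from None
            nodes.append(MorphNode(nid, parent, (x, y, z), r, label))
    labels.setdefault("name", path.stem)
    return MorphTree(nodes, **labels)


def write_swc(tree: MorphTree, path: str | Path) -> None:
    """Write standard 7-column SWC, parents before children, ids re-indexed 1..N."""
    order = tree.topological_order()
    newid = {old: i + 1 for i, old in enumerate(order)}
    with open(path, "w") as fh:
        fh.write(f"# {tree.name}\n")
        for old in order:
            n = tree.node(old)
            parent = -1 if n.parent_id == -1 else newid[n.parent_id]
            x, y, z = n.position
            fh.write(
                f"{newid[old]} {n.structure_label} {x:.6f} {y:.6f} {z:.6f} "
                f"{n.radius:.6f} {parent}\n"
            )


# -- subregion splitting -------------------------------------------------------


def _first_bifurcation_on_path(tree: MorphTree, start_id: int) -> tuple[list[int], int | None]:
    """Follow single-child links from ``start_id``; return (path ids incl. both
    ends, id of first node with >=2 children or None if the path terminates)."""
    path = [start_id]
    cur = start_id
    while True:
        kids = tree.children_of(cur)
        if len(kids) >= 2:
            return path, cur
        if not kids:
            return path, None
        cur = kids[0]
        path.append(cur)


def split_subregions(
    tree: MorphTree, dorsal_child_id: int, ventral_child_id: int
) -> SubregionSet:
    """Split a whole arborization into MB / DB / VB (+ WA).

    ``dorsal_child_id`` and ``ventral_child_id`` are the two children of the
    tree root (the first bifurcation of the primary neurite).  MB consists of
    the two daughter paths up to and including their first bifurcation nodes;
    DB and VB are the subtrees distal to those bifurcations.  A daughter path
    with no bifurcation contributes entirely to MB and yields an empty branch
    (a warning is emitted).
    """
    root_children = set(tree.children_of(tree.root.id))
    for cid, side in ((dorsal_child_id, "dorsal"), (ventral_child_id, "ventral")):
        if cid not in root_children:
            raise ValueError(
                f"{side} child id {cid} is not a child of the root "
                f"(root children: {sorted(root_children)})"
            )
    if dorsal_child_id == ventral_child_id:
        raise ValueError("dorsal and ventral child ids must differ")

    mb_ids: set[int] = {tree.root.id}
    branches: dict[str, MorphTree | None] = {}
    for side, cid in (("DB", dorsal_child_id), ("VB", ventral_child_id)):
        path, bif = _first_bifurcation_on_path(tree, cid)
        mb_ids.update(path)
        if bif is None:
            warnings.warn(
                f"{side}: daughter path from node {cid} has no bifurcation; "
                "branch is empty and the whole path belongs to MB",
                stacklevel=2,
            )
            branches[side] = None
        else:
            sub_ids = tree.subtree_ids(bif)
            branches[side] = tree.extract(sub_ids, bif)

    mb = tree.extract(mb_ids, tree.root.id)
    return SubregionSet(
        WA=tree, MB=mb, DB=branches["DB"], VB=branches["VB"],
        provenance=f"split of {tree.name}",
    )


# -- manifest ------------------------------------------------------------------

MANIFEST_COLUMNS = ("path", "group", "sample_id", "regparam_id")


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read a morphology manifest CSV (``path,group,sample_id,regparam_id``).

    Relative SWC paths are resolved against the manifest's directory.
    """
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
        for rec in reader:
            swc = Path(rec["path"])
            if not swc.is_absolute():
                swc = path.parent / swc
            rows.append(
                dict(
                    path=str(swc),
                    group=rec["group"],
                    sample_id=rec["sample_id"],
                    regparam_id=rec["regparam_id"],
                )
            )
    return rows


def load_manifest_trees(path: str | Path) -> list[MorphTree]:
    """Read every SWC listed in a manifest, attaching its labels."""
    return [
        read_swc(
            rec["path"],
            group=rec["group"],
            sample_id=rec["sample_id"],
            regparam_id=rec["regparam_id"],
        )
        for rec in read_manifest(path)
    ]
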