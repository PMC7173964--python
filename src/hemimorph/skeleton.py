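"""Neuron skeletons: SWC I/O, segment decomposition, serial pruning, cable length.

A skeleton is a rooted tree of 3-D nodes with coordinates in micrometres.
The main trajectory of a neuron is obtained by serially pruning terminal
branches shorter than increasing length thresholds (10, 25, 50 um by
default); the total cable length of what remains is the backbone-length
statistic used in the hemilineage comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SkeletonNode",
    "NeuronSkeleton",
    "SkeletonSegment",
    "SwcParseError",
    "SkeletonStructureError",
    "read_swc",
    "write_swc",
    "locate_root_by_intensity",
    "decompose_segments",
    "prune_terminal_branches",
    "main_trajectory_length",
    "total_cable_length",
    "coefficient_of_variation",
    "DEFAULT_PRUNE_THRESHOLDS",
]

DEFAULT_PRUNE_THRESHOLDS = (10.0, 25.0, 50.0)


class SwcParseError(ValueError):
    """Malformed SWC content; carries the offending line number."""


class SkeletonStructureError(ValueError):
    """The node table does not describe a single rooted tree."""


@dataclass
class SkeletonNode:
    id: int
    parent_id: Optional[int]
    position: np.ndarray  # (3,), um
    radius: float = 1.0
    intensity: Optional[float] = None
    swc_type: int = 0  # read from SWC, ignored by the analysis

    def copy(self) -> "SkeletonNode":
        return replace(self, position=self.position.copy())


class NeuronSkeleton:
    """A rooted tree of :class:`SkeletonNode` with free-form metadata.

    Invariants checked on construction: node ids unique, every parent id
    refers to an existing node, exactly one root, and the graph is a
    connected tree (acyclicity follows from the single-parent structure).
    """

    def __init__(self, nodes: Sequence[SkeletonNode], metadata: Optional[dict] = None):
        self.nodes: list[SkeletonNode] = list(nodes)
        self.metadata: dict = dict(metadata or {})
        self._index: dict[int, SkeletonNode] = {}
        self._children: dict[int, list[int]] = {}
        self._root_id: Optional[int] = None
        self._rebuild()

    # -- structure bookkeeping -------------------------------------------------

    def _rebuild(self) -> None:
        self._index = {}
        self._children = {}
        roots = []
        for n in self.nodes:
            if n.id in self._index:
                raise SkeletonStructureError(f"duplicate node id {n.id}")
            self._index[n.id] = n
            self._children.setdefault(n.id, [])
        for n in self.nodes:
            if n.parent_id is None:
                roots.append(n.id)
            else:
                if n.parent_id not in self._index:
                    raise SkeletonStructureError(
                        f"node {n.id} references missing parent {n.parent_id}"
                    )
                self._children[n.parent_id].append(n.id)
        if len(roots) != 1:
            raise SkeletonStructureError(
                f"expected exactly one root, found {len(roots)}: {roots[:10]}"
            )
        self._root_id = roots[0]
        # connectivity: walk down from the root; single-parent + connected => tree
        seen = set()
        stack = [self._root_id]
        while stack:
            cur = stack.pop()
            seen.add(cur)
            stack.extend(self._children[cur])
        if len(seen) != len(self.nodes):
            orphans = sorted(set(self._index) - seen)
            raise SkeletonStructureError(
                f"{len(orphans)} nodes unreachable from root (e.g. {orphans[:10]}); "
                "the parent table contains a cycle or disconnected component"
            )

    @property
    def root_id(self) -> int:
        assert self._root_id is not None
        return self._root_id

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> SkeletonNode:
        return self._index[node_id]

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def leaves(self) -> list[int]:
        """Non-root nodes without children."""
        return [
            n.id for n in self.nodes if not self._children[n.id] and n.id != self._root_id
        ]

    def branch_points(self) -> list[int]:
        """Nodes with two or more children (the root included)."""
        return [n.id for n in self.nodes if len(self._children[n.id]) >= 2]

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float)

    def edge_length(self, child_id: int) -> float:
        n = self._index[child_id]
        if n.parent_id is None:
            return 0.0
        return float(np.linalg.norm(n.position - self._index[n.parent_id].position))

    def edges(self) -> Iterable[tuple[int, int]]:
        for n in self.nodes:
            if n.parent_id is not None:
                yield (n.parent_id, n.id)

    def copy(self) -> "NeuronSkeleton":
        return NeuronSkeleton([n.copy() for n in self.nodes], dict(self.metadata))

    def drop_nodes(self, node_ids: Iterable[int]) -> "NeuronSkeleton":
        dead = set(node_ids)
        return NeuronSkeleton(
            [n.copy() for n in self.nodes if n.id not in dead], dict(self.metadata)
        )

    def reroot(self, new_root: int) -> None:
        """Reorient parent pointers so that ``new_root`` becomes the root.

        The undirected edge set and all edge lengths are unchanged.
        """
        if new_root not in self._index:
            raise KeyError(f"unknown node id {new_root}")
        # path from new_root up to the old root
        path = [new_root]
        while self._index[path[-1]].parent_id is not None:
            path.append(self._index[path[-1]].parent_id)
        # reverse parent pointers along that path
        for child, parent in zip(path, path[1:]):
            self._index[parent].parent_id = child
        self._index[new_root].parent_id = None
        self._rebuild()


@dataclass
class SkeletonSegment:
    """A maximal unbranched run between consecutive critical points.

    ``node_path`` is ordered proximal (critical point: root or branch point)
    to distal (leaf or branch point).  An unbranched skeleton yields a single
    root-to-leaf segment, nominally terminal, which pruning exempts (a
    neuron is never deleted wholesale).
    """

    node_path: list[int]
    length: float
    kind: str  # "terminal" | "internal"


def total_cable_length(skeleton: NeuronSkeleton) -> float:
    """Sum of Euclidean parent-child edge lengths, um."""
    return float(sum(skeleton.edge_length(c) for _, c in skeleton.edges()))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> NeuronSkeleton:
    """Read a whitespace-delimited SWC file (7 columns, ``#`` comments).

    Columns: id, type, x, y, z, radius, parent (parent ``-1`` marks the
    root).  An optional 8th column is read as a per-node intensity (arbitrary
    units), written back by :func:`write_swc`.  Coordinates are treated as
    micrometres.
    """
    path = Path(path)
    nodes: list[SkeletonNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (7, 8):
                raise SwcParseError(
                    f"{path.name}:{lineno}: expected 7 (or 8) columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                swc_type = int(parts[1])
                pos = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                radius = float(parts[5])
                parent = int(parts[6])
                intensity = float(parts[7]) if len(parts) == 8 else None
            except ValueError as exc:
                raise SwcParseError(f"{path.name}:{lineno}: {exc}") from exc
            nodes.append(
                SkeletonNode(
                    id=nid,
                    parent_id=None if parent == -1 else parent,
                    position=pos,
                    radius=radius,
                    intensity=intensity,
                    swc_type=swc_type,
                )
            )
    if not nodes:
        raise SwcParseError(f"{path.name}: no nodes")
    skel = NeuronSkeleton(nodes, metadata={"source": str(path)})
    return skel


def write_swc(skeleton: NeuronSkeleton, path: str | Path) -> None:
    """Write standard 7-column SWC (plus an intensity column when present)."""
    has_intensity = any(n.intensity is not None for n in skeleton.nodes)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent" + (" intensity" if has_intensity else "") + "\n")
        for n in skeleton.nodes:
            parent = -1 if n.parent_id is None else n.parent_id
            row = (
                f"{n.id} {n.swc_type} {n.position[0]:.6g} {n.position[1]:.6g} "
                f"{n.position[2]:.6g} {n.radius:.6g} {parent}"
            )
            if has_intensity:
                row += f" {0.0 if n.intensity is None else n.intensity:.6g}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def locate_root_by_intensity(skeleton: NeuronSkeleton) -> int:
    """Re-root the skeleton at its highest-intensity node (the soma proxy).

    The cell body is taken as the node with the maximal intensity value; ties
    break to the lowest node id.  Returns the new root id.  Skeletons without
    intensity data must be rooted explicitly via :meth:`NeuronSkeleton.reroot`.
    """
    candidates = [n for n in skeleton.nodes if n.intensity is not None]
    if not candidates:
        raise ValueError(
            "no intensity data on any node; supply an explicit root via reroot()"
        )
    best = min(candidates, key=lambda n: (-n.intensity, n.id))
    skeleton.reroot(best.id)
    return best.id


# ---------------------------------------------------------------------------
# Segments and pruning
# ---------------------------------------------------------------------------

def decompose_segments(skeleton: NeuronSkeleton) -> list[SkeletonSegment]:
    """Split the skeleton into unbranched segments between critical points.

    Critical points are the root, branch points (>= 2 children) and leaves.
    Segments partition the edge set exactly once.  ``kind`` is ``terminal``
    iff the distal end is a leaf.  A single-node skeleton yields ``[]``.
    """
    if len(skeleton) <= 1:
        return []
    branch = set(skeleton.branch_points())
    critical = branch | {skeleton.root_id}
    segments: list[SkeletonSegment] = []
    # walk upward from every distal critical point (leaf or branch point)
    for n in skeleton.nodes:
        nid = n.id
        is_leaf = not skeleton.children(nid) and nid != skeleton.root_id
        if not (is_leaf or nid in branch) or nid == skeleton.root_id:
            continue
        path = [nid]
        cur = skeleton.node(nid).parent_id
        length = skeleton.edge_length(nid)
        while cur is not None and cur not in critical:
            path.append(cur)
            length += skeleton.edge_length(cur)
            cur = skeleton.node(cur).parent_id
        if cur is not None:
            path.append(cur)
        path.reverse()  # proximal -> distal
        segments.append(
            SkeletonSegment(
                node_path=path,
                length=float(length),
                kind="terminal" if is_leaf else "internal",
            )
        )
    return segments


def prune_terminal_branches(
    skeleton: NeuronSkeleton,
    threshold: float,
    fixpoint: bool = True,
) -> NeuronSkeleton:
    """Remove terminal branches shorter than ``threshold`` (um).

    Iterates to a fixpoint: within one iteration all currently-short terminal
    segments (leaf to nearest critical point) are removed simultaneously;
    degree-2 pass-through points created by the removal are absorbed into
    their containing segment on the next iteration's re-decomposition.  A
    skeleton with no branch point is returned unchanged, so a neuron can
    never be pruned away entirely.  ``fixpoint=False`` performs a single
    sweep (one simultaneous removal round) instead.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    current = skeleton.copy()
    if threshold == 0:
        return current
    while True:
        if not current.branch_points():
            return current
        short = [
            seg
            for seg in decompose_segments(current)
            if seg.kind == "terminal" and seg.length < threshold
        ]
        if not short:
            return current
        dead: set[int] = set()
        for seg in short:
            # drop everything distal of the proximal critical point
            dead.update(seg.node_path[1:])
        current = current.drop_nodes(dead)
        if not fixpoint:
            return current


def main_trajectory_length(
    skeleton: NeuronSkeleton,
    prune_thresholds: Sequence[float] = DEFAULT_PRUNE_THRESHOLDS,
    fixpoint: bool = True,
) -> float:
    """Serial-pruning backbone length, um.

    Prunes terminal branches at each threshold in ascending order (10, 25,
    50 um by default) and returns the total cable length of the remaining
    main trajectory.
    """
    thresholds = list(prune_thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("prune thresholds must be strictly increasing")
    current = skeleton
    for t in thresholds:
        current = prune_terminal_branches(current, t, fixpoint=fixpoint)
    return total_cable_length(current)


def coefficient_of_variation(lengths: Sequence[float]) -> float:
    """Sample standard deviation over mean; requires n >= 2 and mean > 0."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least two values, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    return float(arr.std(ddof=1) / mean)
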