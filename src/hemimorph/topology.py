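"""Rule-based neuron topology classification.

Brain-intrinsic neurons are classified from the geometry of their arbor
domains relative to the sagittal midline plane:

* ``S`` (Single): one unilateral arborization domain;
* ``P`` (Projection): several domains, all in one hemisphere;
* ``C`` (Central): a single domain covering the midline;
* ``M`` (Midline): midline-covering plus non-midline arborization;
* ``T`` (Transverse) / ``H`` (Horizontal): midline-crossing neurons without
  vs. with bilaterally symmetric innervation;
* ``D`` (External): brain input/output neurons (e.g. descending neurons)
  whose arbors leave the brain volume.

Arbor domains are a geometric surrogate for what an anatomist would outline
by eye: single-linkage clusters of terminal and branch points, with small
clusters discarded.  The decision order D -> C -> M -> T/H -> S/P resolves
rule overlaps deterministically (a crossing neuron that also covers the
midline is Midline, not Transverse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .nomenclature import TypeName
from .skeleton import NeuronSkeleton

__all__ = [
    "BrainModel",
    "ArborDomain",
    "TopologyParams",
    "ClassificationError",
    "detect_arbor_domains",
    "crosses_midline",
    "bilateral_symmetry",
    "classify_topology",
    "count_topology_classes",
]

TOPOLOGY_CLASSES = ("S", "P", "C", "M", "T", "H", "D")


class ClassificationError(ValueError):
    pass


@dataclass
class BrainModel:
    """Coordinate frame: sagittal midline plane and brain bounding box (um)."""

    x_mid: float
    midline_tolerance: float = 5.0
    bounds_min: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0]))
    bounds_max: np.ndarray = field(
        default_factory=lambda: np.array([600.0, 400.0, 250.0])
    )

    def __post_init__(self) -> None:
        self.bounds_min = np.asarray(self.bounds_min, dtype=float)
        self.bounds_max = np.asarray(self.bounds_max, dtype=float)
        if self.midline_tolerance <= 0:
            raise ValueError("midline tolerance must be positive")
        if not (self.bounds_min[0] <= self.x_mid <= self.bounds_max[0]):
            raise ValueError("midline plane must lie inside the bounding volume")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the midline plane (positive on the +x side)."""
        return np.atleast_2d(points)[:, 0] - self.x_mid

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.all((pts >= self.bounds_min) & (pts <= self.bounds_max), axis=1)

    def mirror(self, points: np.ndarray) -> np.ndarray:
        out = np.array(np.atleast_2d(points), dtype=float, copy=True)
        out[:, 0] = 2.0 * self.x_mid - out[:, 0]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "x_mid": self.x_mid,
                    "midline_tolerance": self.midline_tolerance,
                    "bounds_min": self.bounds_min.tolist(),
                    "bounds_max": self.bounds_max.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BrainModel":
        d = json.loads(Path(path).read_text())
        return cls(
            x_mid=d["x_mid"],
            midline_tolerance=d["midline_tolerance"],
            bounds_min=np.array(d["bounds_min"]),
            bounds_max=np.array(d["bounds_max"]),
        )


@dataclass
class ArborDomain:
    points: np.ndarray  # member terminal/branch positions
    centroid: np.ndarray
    side: str  # "left" | "right" | "straddling"
    radius: float  # max member distance to centroid


@dataclass
class TopologyParams:
    link_radius: float = 20.0  # single-linkage cut distance, um
    min_points: int = 5  # smallest cluster kept as a domain
    match_radius: float = 30.0  # mirrored-centroid match distance, um


def _domain_side(signed: np.ndarray, tol: float) -> str:
    if np.any(np.abs(signed) <= tol) or (np.any(signed > tol) and np.any(signed < -tol)):
        return "straddling"
    return "right" if signed[0] > 0 else "left"


def detect_arbor_domains(
    skeleton: NeuronSkeleton,
    brain: BrainModel,
    link_radius: float = 20.0,
    min_points: int = 5,
) -> list[ArborDomain]:
    """Single-linkage clustering of leaf and branch-point positions.

    Clusters with fewer than ``min_points`` members are discarded (isolated
    pass-through points are not arborizations).  Each domain's side is taken
    from the signed distances of its members to the midline: straddling if
    members fall on both sides or any lies within the midline tolerance.
    """
    ids = skeleton.leaves() + skeleton.branch_points()
    if not ids:
        return []
    points = np.array([skeleton.node(i).position for i in ids], dtype=float)
    if len(points) == 1:
        assignments = np.array([1])
    else:
        z = linkage(pdist(points), method="single")
        assignments = fcluster(z, t=link_radius, criterion="distance")
    domains = []
    for label in np.unique(assignments):
        member = points[assignments == label]
        if len(member) < min_points:
            continue
        centroid = member.mean(axis=0)
        signed = brain.signed_distance(member)
        domains.append(
            ArborDomain(
                points=member,
                centroid=centroid,
                side=_domain_side(signed, brain.midline_tolerance),
                radius=float(np.max(np.linalg.norm(member - centroid, axis=1))),
            )
        )
    # deterministic order: by centroid coordinates
    domains.sort(key=lambda d: tuple(d.centroid))
    return domains


def crosses_midline(skeleton: NeuronSkeleton, brain: BrainModel) -> bool:
    """True iff the skeleton reaches beyond tolerance on both sides of the midline.

    Because the skeleton is connected, nodes beyond the +/- tolerance bands
    on both sides imply a path through the midline plane.  (A per-edge test
    would be resolution-dependent: finely sampled skeletons have no single
    edge long enough to span both bands.)
    """
    tol = brain.midline_tolerance
    signed = brain.signed_distance(skeleton.positions())
    return bool(np.any(signed > tol) and np.any(signed < -tol))


def bilateral_symmetry(
    domains: Sequence[ArborDomain],
    brain: BrainModel,
    match_radius: float = 30.0,
) -> bool:
    """Bilaterally symmetric innervation of the lateral arbor domains.

    True iff every non-straddling domain on one side has a partner on the
    other side whose mirrored centroid lies within ``match_radius``, with at
    least one such matched pair.
    """
    left = [d.centroid for d in domains if d.side == "left"]
    right = [d.centroid for d in domains if d.side == "right"]
    if not left or not right:
        return False

    def matched(src: list[np.ndarray], dst: list[np.ndarray]) -> bool:
        dst_arr = np.array(dst)
        for c in src:
            mirrored = brain.mirror(c[None, :])[0]
            if np.min(np.linalg.norm(dst_arr - mirrored, axis=1)) > match_radius:
                return False
        return True

    return matched(left, right) and matched(right, left)


def classify_topology(
    skeleton: NeuronSkeleton,
    brain: BrainModel,
    params: Optional[TopologyParams] = None,
) -> str:
    """Assign one of the S/P/C/M/T/H/D topology classes.

    Decision order: D if any leaf lies outside the brain volume; else C if
    the single domain covers the midline; else M if midline-covering and
    lateral domains coexist; else, for midline-crossing neurons, H when the
    lateral innervation is bilaterally symmetric and T otherwise; else S for
    one domain and P for several (all within one hemisphere).
    """
    params = params or TopologyParams()
    leaf_pos = np.array(
        [skeleton.node(i).position for i in skeleton.leaves()] or np.empty((0, 3))
    )
    exits = len(leaf_pos) > 0 and not bool(np.all(brain.contains(leaf_pos)))
    if exits:
        return "D"
    domains = detect_arbor_domains(
        skeleton, brain, link_radius=params.link_radius, min_points=params.min_points
    )
    if not domains:
        raise ClassificationError("no arborization detected")
    straddling = [d for d in domains if d.side == "straddling"]
    lateral = [d for d in domains if d.side != "straddling"]
    if len(domains) == 1 and straddling:
        return "C"
    if straddling and lateral:
        return "M"
    if crosses_midline(skeleton, brain):
        return "H" if bilateral_symmetry(domains, brain, params.match_radius) else "T"
    return "S" if len(domains) == 1 else "P"


def count_topology_classes(types: Sequence[TypeName]) -> int:
    """Number of distinct topology-class letters in a hemilineage's types."""
    if not types:
        raise ValueError("empty type list")
    return len({t.class_letter for t in types})
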