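"""Synthetic lineages with known ground truth.

Generates brains, hemilineage morphology templates, single-neuron skeletons
and clone-induction records that emulate the structure of a twin-spot clonal
mapping study, so that every pipeline stage can be exercised against planted
truth:

* each hemilineage owns a *primary trajectory* (a lane through the brain
  shared by all its types) with type-specific terminal arbors hung off it —
  the hemilineage-shared-backbone / type-specific-elaboration structure;
* dual lineages carry A (Notch-on) and B (Notch-off) hemilineages; lone
  hemilineages have a single viable side (the other side lost to programmed
  cell death, modelled as per-type survival probability);
* each type has a planted topology class realised geometrically (arbor
  domain placement relative to the midline), a planted birth window on the
  2-hr induction schedule, and a planted main-trajectory length;
* a designated pair of lineages is *duplicated*: their A hemilineages share
  one morphology template exactly (up to jitter), planting the
  cross-hemilineage similarity that the NBLAST grouping should recover.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .birth_order import CloneRecord, InductionSchedule, SchedulePoint
from .nomenclature import parse_type_name
from .skeleton import NeuronSkeleton, SkeletonNode
from .topology import BrainModel

__all__ = [
    "TypeSpec",
    "LineageSpec",
    "TypeMorphology",
    "MorphologyTemplate",
    "Scenario",
    "generate_brain_model",
    "synthesize_skeleton",
    "sample_clone_records",
    "demo_scenario",
    "study_scenario",
    "write_scenario",
]

ARBOR_Y_OFFSET = -25.0  # arbor centroids sit this far from the trajectory lane
ARBOR_RADIUS = 14.0
ARBOR_TIPS = 12
TRAJECTORY_STEP = 5.0  # um between trajectory nodes
BRANCH_LEN_MEDIAN = 5.0  # log-normal median of arbor branch lengths, um
BRANCH_LEN_SIGMA = 0.35
ARBOR_PATH_BUDGET = 14.0  # max root-to-tip path length inside an arbor, um
MIN_TAIL = 55.0  # shortest surviving terminal tail (> final prune threshold)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class TypeSpec:
    """One planted neuron type."""

    name: str  # rendered type name, e.g. "CREa1A_P01"
    birth_window: tuple[int, int]  # schedule indices, inclusive
    topology_class: str
    group: str  # morphological group label
    survival: float = 1.0
    target_length: float = 380.0  # planted main-trajectory length, um

    @property
    def hemilineage(self) -> str:
        return parse_type_name(self.name).hemilineage


@dataclass
class LineageSpec:
    name: str
    dual: bool
    types: list[TypeSpec]
    duplication_partner: Optional[str] = None

    def hemilineages(self) -> list[str]:
        seen: list[str] = []
        for t in self.types:
            h = t.hemilineage
            if h not in seen:
                seen.append(h)
        return seen

    def types_of(self, hemilineage: str) -> list[TypeSpec]:
        return [t for t in self.types if t.hemilineage == hemilineage]


@dataclass
class TypeMorphology:
    """Geometric recipe for one type: backbone polyline plus grown arbors.

    Arbor tree shapes are part of the type's template (grown once, at
    template-building time) so that planted-duplicate types are identical up
    to per-skeleton jitter, the way twin series of indistinguishable neuron
    types are.  ``arbors`` holds (positions, parents) per arbor; parents
    index within the arbor, -1 marking the arbor root.
    """

    trajectory: np.ndarray  # (P, 3) polyline from the soma, um
    arbor_centroids: list[np.ndarray]
    arbors: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    arbor_radius: float = ARBOR_RADIUS
    arbor_tips: int = ARBOR_TIPS


@dataclass
class MorphologyTemplate:
    """Per-hemilineage morphology: soma, lane, and per-type recipes."""

    hemilineage: str
    soma: np.ndarray
    per_type: dict[str, TypeMorphology] = field(default_factory=dict)
    jitter: float = 1.0  # positional noise applied per synthesized skeleton, um


# ---------------------------------------------------------------------------
# Brain
# ---------------------------------------------------------------------------

def generate_brain_model(seed: int) -> BrainModel:
    """A brain bounding box with a centred sagittal midline plane."""
    rng = np.random.default_rng(seed)
    width = float(rng.uniform(580.0, 620.0))
    return BrainModel(
        x_mid=width / 2.0,
        midline_tolerance=5.0,
        bounds_min=np.zeros(3),
        bounds_max=np.array([width, 400.0, 250.0]),
    )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _tail_waypoints(
    end: np.ndarray, length: float, brain: BrainModel, toward_x: float
) -> list[np.ndarray]:
    """Extend the backbone by ``length`` um inside the box without branching.

    Legs: up in y, then along x toward ``toward_x``, then down in y; each leg
    is truncated at the box margin.  The tail stays within the hemisphere it
    starts in (it never approaches the midline closer than its start).
    """
    margin = 10.0
    pts: list[np.ndarray] = []
    cur = end.copy()
    remaining = length
    legs = [
        (1, brain.bounds_max[1] - margin),  # +y
        (0, toward_x),  # x, toward the given bound
        (1, brain.bounds_min[1] + margin),  # -y
        (2, brain.bounds_max[2] - margin),  # +z
    ]
    for axis, bound in legs:
        if remaining <= 0:
            break
        room = abs(bound - cur[axis])
        step = min(remaining, room)
        if step <= 0:
            continue
        cur = cur.copy()
        cur[axis] += np.sign(bound - cur[axis]) * step
        pts.append(cur.copy())
        remaining -= step
    return pts


def _type_geometry(
    cls: str,
    soma: np.ndarray,
    brain: BrainModel,
    rng: np.random.Generator,
    target_length: float,
) -> TypeMorphology:
    """Lay out backbone waypoints and arbor centroids realising a class."""
    x0, y, z = soma
    xm = brain.x_mid
    ao = ARBOR_Y_OFFSET

    def pt(x: float) -> np.ndarray:
        return np.array([x, y, z])

    def arbor(x: float) -> np.ndarray:
        return np.array([x, y + ao, z])

    exit_leg: list[np.ndarray] = []
    if cls == "S":
        x_e = xm - 110.0 + rng.uniform(-20, 20)
        waypoints, arbors = [pt(x_e)], [arbor(x_e - 10)]
    elif cls == "P":
        x_e = xm - 60.0 + rng.uniform(-15, 15)
        xs = [x0 + 60.0, (x0 + 60.0 + x_e) / 2.0, x_e - 10.0]
        waypoints, arbors = [pt(x_e)], [arbor(x) for x in xs]
    elif cls == "C":
        waypoints, arbors = [pt(xm - 20.0)], [arbor(xm)]
    elif cls == "M":
        waypoints = [pt(xm - 30.0)]
        arbors = [arbor(x0 + 110.0), arbor(xm)]
    elif cls == "T":
        x_e = xm + 120.0 + rng.uniform(-10, 10)
        waypoints, arbors = [pt(x_e)], [arbor(xm + 100.0)]
    elif cls == "H":
        x_e = xm + 120.0 + rng.uniform(-10, 10)
        off = 120.0 + rng.uniform(-10, 10)
        waypoints, arbors = [pt(x_e)], [arbor(xm - off), arbor(xm + off)]
    elif cls == "D":
        x_e = x0 + 110.0
        waypoints, arbors = [pt(x_e)], [arbor(x0 + 100.0)]
        # descending: leave the brain volume through the floor
        exit_leg = [np.array([x_e, y, brain.bounds_min[2] - 40.0])]
    else:
        raise ValueError(f"unknown topology class {cls!r}")

    poly = [soma.copy()] + waypoints
    base_len = _polyline_length(np.array(poly)) + sum(
        np.linalg.norm(b - a)
        for a, b in zip([poly[-1]] + exit_leg, exit_leg)
    )
    tail = max(MIN_TAIL, target_length - base_len)
    if cls == "D":
        # lengthen the exit leg instead of adding an in-brain tail
        exit_leg[-1][2] -= tail - MIN_TAIL
        poly += exit_leg
    else:
        end = poly[-1]
        toward = x0 + 10.0 if end[0] < xm else brain.bounds_max[0] - 20.0
        poly += _tail_waypoints(end, tail, brain, toward_x=toward)
    grown = [_grow_arbor(c, ARBOR_RADIUS, ARBOR_TIPS, rng) for c in arbors]
    return TypeMorphology(
        trajectory=np.array(poly), arbor_centroids=arbors, arbors=grown
    )


def _resample(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    stations = np.arange(0.0, cum[-1], step)
    stations = np.append(stations, cum[-1])
    out = np.empty((len(stations), 3))
    for axis in range(3):
        out[:, axis] = np.interp(stations, cum, points[:, axis])
    return out


def _grow_arbor(
    centroid: np.ndarray,
    radius: float,
    n_tips: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random binary tree confined to a ball; returns positions and parents.

    Node 0 is the arbor root (at the centroid); branch lengths are log-normal
    with median ``BRANCH_LEN_MEDIAN``, clipped so no root-to-tip path exceeds
    ``ARBOR_PATH_BUDGET``.  The bound keeps the whole arbor (plus its
    connector to the backbone) shorter than the final 50-um prune threshold,
    so serial pruning removes terminal arbors cleanly and the planted
    main-trajectory length is realised by the backbone alone.  Returned
    parents index into the positions array.
    """
    positions = [centroid.copy()]
    parents = [-1]
    used = [0.0]  # path length from the arbor root
    active = [0]
    n_total = 1
    while active and n_total < 2 * n_tips - 1:
        i = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            length = float(
                np.clip(
                    rng.lognormal(np.log(BRANCH_LEN_MEDIAN), BRANCH_LEN_SIGMA), 2.0, 7.0
                )
            )
            length = min(length, ARBOR_PATH_BUDGET - used[i])
            if length < 1.0:
                continue
            for _attempt in range(8):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                candidate = positions[i] + direction * length
                if np.linalg.norm(candidate - centroid) <= radius:
                    break
            else:  # pull back toward the centroid
                candidate = positions[i] + (centroid - positions[i]) * 0.5
            positions.append(candidate)
            parents.append(i)
            used.append(used[i] + length)
            if used[-1] < ARBOR_PATH_BUDGET - 1.0:
                active.append(len(positions) - 1)
            n_total += 1
    return np.array(positions), np.array(parents)


# ---------------------------------------------------------------------------
# Skeleton synthesis
# ---------------------------------------------------------------------------

def synthesize_skeleton(
    template: MorphologyTemplate,
    type_name: str,
    seed: int,
    brain: Optional[BrainModel] = None,
) -> NeuronSkeleton:
    """Build one neuron skeleton from its hemilineage template.

    The shared primary trajectory is resampled and jittered; type-specific
    arbors are grown at their placed domains and attached to the nearest
    backbone node.  Node intensity is maximal at the soma (node ids start at
    1, soma first), so intensity-based rooting recovers the true root.
    Deterministic given ``seed``.
    """
    if type_name not in template.per_type:
        raise KeyError(f"type {type_name!r} not in template for {template.hemilineage}")
    morph = template.per_type[type_name]
    rng = np.random.default_rng(seed)

    backbone = _resample(morph.trajectory, TRAJECTORY_STEP)
    jitter = rng.normal(scale=template.jitter, size=backbone.shape)
    jitter[0] = 0.0  # soma stays put
    backbone = backbone + jitter

    nodes: list[SkeletonNode] = []
    for i, pos in enumerate(backbone):
        nodes.append(
            SkeletonNode(
                id=i + 1,
                parent_id=None if i == 0 else i,
                position=pos.copy(),
                intensity=100.0 if i == 0 else float(rng.uniform(1.0, 10.0)),
            )
        )
    next_id = len(nodes) + 1
    for centroid, (positions, parents) in zip(morph.arbor_centroids, morph.arbors):
        attach_idx = int(np.argmin(np.linalg.norm(backbone - centroid, axis=1)))
        attach_id = attach_idx + 1
        positions = positions + rng.normal(scale=template.jitter, size=positions.shape)
        base = next_id
        for j, (pos, par) in enumerate(zip(positions, parents)):
            nodes.append(
                SkeletonNode(
                    id=base + j,
                    parent_id=attach_id if par < 0 else base + par,
                    position=pos,
                    intensity=float(rng.uniform(1.0, 10.0)),
                )
            )
        next_id = base + len(positions)

    skel = NeuronSkeleton(nodes, metadata={"type_name": type_name})
    tn = parse_type_name(type_name)
    skel.metadata.update(
        {
            "lineage": tn.lineage,
            "hemilineage": tn.hemilineage,
            "notch_state": tn.notch_suffix or "lone",
            "true_class": tn.class_letter,
        }
    )
    return skel


# ---------------------------------------------------------------------------
# Clone records
# ---------------------------------------------------------------------------

def sample_clone_records(
    lineages: Sequence[LineageSpec],
    schedule: InductionSchedule,
    n_brains: int,
    seed: int,
    recovery_prob: float = 0.3,
) -> list[CloneRecord]:
    """Simulate twin-spot clone recovery over a series of brains.

    Each simulated brain receives one induction time drawn uniformly from
    the schedule; every type whose birth window covers that time yields a
    single-cell clone with probability ``recovery_prob * survival``.
    Deterministic given ``seed``.
    """
    if n_brains < 1:
        raise ValueError("n_brains must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[CloneRecord] = []
    for b in range(n_brains):
        t_idx = int(rng.integers(len(schedule)))
        point = schedule.points[t_idx]
        for lin in lineages:
            for ts in lin.types:
                if not (ts.birth_window[0] <= t_idx <= ts.birth_window[1]):
                    continue
                if rng.random() >= recovery_prob * ts.survival:
                    continue
                records.append(
                    CloneRecord(
                        lineage=lin.name,
                        hemilineage=ts.hemilineage,
                        neuron_type=ts.name,
                        induction_time=point,
                        clone_class="single-cell",
                        brain_id=f"b{b:05d}",
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A full planted experiment: brain, lineage specs, morphology templates."""

    brain: BrainModel
    lineages: list[LineageSpec]
    templates: dict[str, MorphologyTemplate]
    schedule: InductionSchedule
    seed: int

    def all_types(self) -> list[TypeSpec]:
        return [t for lin in self.lineages for t in lin.types]

    def true_classes(self) -> dict[str, str]:
        return {t.name: t.topology_class for t in self.all_types()}

    def true_birth_order(self, hemilineage: str) -> list[str]:
        types = [
            t
            for lin in self.lineages
            for t in lin.types_of(hemilineage)
            if t.survival > 0
        ]
        types.sort(key=lambda t: (t.birth_window[0], t.name))
        return [t.name for t in types]

    def hemilineages(self) -> list[str]:
        return [h for lin in self.lineages for h in lin.hemilineages()]

    def group_assignment(self) -> dict[str, str]:
        return {t.name: f"{t.hemilineage}:{t.group}" for t in self.all_types()}

    def skeletons(self) -> dict[str, NeuronSkeleton]:
        """One skeleton per planted type, with stable per-type child seeds."""
        out = {}
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(self.all_types()))
        for child, ts in zip(children, self.all_types()):
            template = self.templates[ts.hemilineage]
            out[ts.name] = synthesize_skeleton(
                template, ts.name, seed=child.generate_state(1)[0] % (2**31), brain=self.brain
            )
        return out

    def clone_records(
        self, n_brains: int, seed: Optional[int] = None, recovery_prob: float = 0.3
    ) -> list[CloneRecord]:
        return sample_clone_records(
            self.lineages,
            self.schedule,
            n_brains,
            seed=self.seed + 1 if seed is None else seed,
            recovery_prob=recovery_prob,
        )


def _build_types(
    hemilineage: str,
    classes: Sequence[str],
    rng: np.random.Generator,
    schedule_len: int,
    length_mean: float,
    length_spread: float,
    group_of: Optional[Sequence[str]] = None,
) -> list[TypeSpec]:
    """Serially numbered types with staggered birth windows and lengths."""
    base = int(rng.integers(0, 8))
    serial_counter: dict[str, int] = {}
    out = []
    for i, cls in enumerate(classes):
        serial_counter[cls] = serial_counter.get(cls, 0) + 1
        name = f"{hemilineage}_{cls}{serial_counter[cls]:02d}"
        start = min(base + i * 7 + int(rng.integers(0, 2)), schedule_len - 5)
        target = float(length_mean + rng.uniform(-length_spread, length_spread))
        out.append(
            TypeSpec(
                name=name,
                birth_window=(start, start + 3),
                topology_class=cls,
                group=group_of[i] if group_of else cls,
                target_length=target,
            )
        )
    return out


def _lane_positions(n: int, brain: BrainModel) -> list[tuple[float, float]]:
    """(y, z) lanes for hemilineage trajectories, pairwise well separated."""
    ys = np.arange(70.0, 360.0, 40.0)  # 8 lanes in y
    zs = np.array([50.0, 100.0, 150.0, 200.0])
    lanes = [(float(y), float(z)) for z in zs for y in ys]
    if n > len(lanes):
        raise ValueError(f"too many hemilineages for the lane grid: {n}")
    return lanes[:n]


_DUAL_CLASSES = {
    "SMPp&v1": (["P", "S", "P", "S", "P"], ["T", "H", "M", "H", "T", "M"]),
    "CREa1": (["P", "P", "P", "P", "P"], ["H", "T", "M", "H", "P", "M"]),
    "CREa2": (["P", "P", "P", "P", "P"], ["S", "P", "S", "P", "M", "P"]),
    "AOTUv1": (["P", "P", "P", "S", "P"], ["P", "H", "M", "T", "H", "M"]),
    "AOTUv3": (["H", "H", "H", "H", "H"], ["P", "P", "M", "P", "M", "T"]),
    "AOTUv4": (["P", "P", "P", "P", "S"], ["P", "H", "T", "H", "M", "H"]),
    "LALv1": (["P", "P", "P", "P", "P"], ["P", "H", "M", "S", "T", "H"]),
}

_LONE_CLASSES = {
    "SMPad1": ["P", "P", "S", "P", "P", "S"],
    "SLPpm3": ["P", "S", "P", "P", "S", "P"],
    "WEDd1": ["D", "D", "P", "P", "S", "P"],
    "VLPa2": ["P", "P", "P", "P", "P", "P"],
    "VESa1": ["P", "H", "S", "P", "H", "M"],
    "VESa2": ["P", "P", "H", "S", "P", "P"],
    "ALv1": ["P", "P", "P", "P", "P", "P"],
    "FLAa1": ["S", "S", "P", "S", "S", "P"],
    "FLAa2": ["P", "P", "S", "P", "P", "S"],
    "FLAa3": ["P", "P", "P", "P", "P", "P"],
    "WEDa1": ["H", "H", "T", "H", "H", "T"],
}

# lineages whose B side carries a planted mean-length excess over the A side
_LONG_B_LINEAGES = ("CREa1", "SMPp&v1")


def _build_templates(
    lineages: Sequence[LineageSpec],
    brain: BrainModel,
    rng: np.random.Generator,
    duplicated: Sequence[tuple[str, str]],
) -> dict[str, MorphologyTemplate]:
    hemis = [h for lin in lineages for h in lin.hemilineages()]
    # duplicated partners share a lane and a template: drop the copy from
    # the lane allocation, then alias afterwards
    copies = {b: a for a, b in duplicated}
    lane_owners = [h for h in hemis if h not in copies]
    lanes = _lane_positions(len(lane_owners), brain)
    templates: dict[str, MorphologyTemplate] = {}
    spec_of = {t.name: t for lin in lineages for t in lin.types}
    x_soma = brain.bounds_min[0] + 40.0
    for h, (y, z) in zip(lane_owners, lanes):
        soma = np.array([x_soma, y, z])
        tpl = MorphologyTemplate(hemilineage=h, soma=soma)
        for lin in lineages:
            for ts in lin.types_of(h):
                tpl.per_type[ts.name] = _type_geometry(
                    ts.topology_class, soma, brain, rng, ts.target_length
                )
        templates[h] = tpl
    for copy_h, source_h in copies.items():
        src = templates[source_h]
        tpl = MorphologyTemplate(hemilineage=copy_h, soma=src.soma.copy())
        source_types = sorted(src.per_type)
        copy_types = sorted(
            t.name for lin in lineages for t in lin.types_of(copy_h)
        )
        if len(copy_types) != len(source_types):
            raise ValueError(
                f"duplicated hemilineages {source_h}/{copy_h} need matching type counts"
            )
        for src_name, dst_name in zip(source_types, copy_types):
            m = src.per_type[src_name]
            tpl.per_type[dst_name] = TypeMorphology(
                trajectory=m.trajectory.copy(),
                arbor_centroids=[c.copy() for c in m.arbor_centroids],
                arbors=[(p.copy(), q.copy()) for p, q in m.arbors],
                arbor_radius=m.arbor_radius,
                arbor_tips=m.arbor_tips,
            )
        templates[copy_h] = tpl
    return templates


def _assemble(
    seed: int,
    dual_classes: dict[str, tuple[list[str], list[str]]],
    lone_classes: dict[str, list[str]],
    duplicated: Sequence[tuple[str, str]],
    long_b: Sequence[str],
) -> Scenario:
    rng = np.random.default_rng(seed)
    brain = generate_brain_model(seed)
    schedule = InductionSchedule()
    lineages: list[LineageSpec] = []
    for name, (a_classes, b_classes) in dual_classes.items():
        types = _build_types(
            name + "A", a_classes, rng, len(schedule), length_mean=450.0, length_spread=15.0
        )
        b_mean, b_spread = (700.0, 100.0) if name in long_b else (450.0, 150.0)
        types += _build_types(
            name + "B", b_classes, rng, len(schedule), length_mean=b_mean, length_spread=b_spread
        )
        partner = None
        for a, b in duplicated:
            if name + "A" == a:
                partner = b[:-1]
            elif name + "A" == b:
                partner = a[:-1]
        lineages.append(
            LineageSpec(name=name, dual=True, types=types, duplication_partner=partner)
        )
    for name, classes in lone_classes.items():
        types = _build_types(
            name, classes, rng, len(schedule), length_mean=450.0, length_spread=60.0
        )
        lineages.append(LineageSpec(name=name, dual=False, types=types))
    templates = _build_templates(lineages, brain, rng, duplicated)
    return Scenario(
        brain=brain,
        lineages=lineages,
        templates=templates,
        schedule=schedule,
        seed=seed,
    )


def study_scenario(seed: int = 0) -> Scenario:
    """The full planted scenario mirroring the mapped-lineage study design.

    18 lineages / 25 hemilineages: 7 dual (two viable hemilineages) and 11
    lone.  Planted structure: the CREa1A/CREa2A pair is duplicated (shared
    template); B hemilineages carry more topology classes and a larger
    spread of main-trajectory lengths than their A siblings; CREa1 and
    SMPp&v1 additionally carry a B-side mean-length excess.  Type counts are
    scaled down from the mapped lineages (5-6 per hemilineage) to keep
    simulation fast.
    """
    return _assemble(
        seed,
        _DUAL_CLASSES,
        _LONE_CLASSES,
        duplicated=[("CREa1A", "CREa2A")],
        long_b=_LONG_B_LINEAGES,
    )


def demo_scenario(seed: int = 0) -> Scenario:
    """A small three-lineage scenario for quick tests.

    One duplicated pair (CREa1A/CREa2A) and one dual lineage whose B side
    has extra topology classes, including the rarer C and D classes.
    """
    dual = {
        "CREa1": (["P", "P", "S"], ["H", "T", "M"]),
        "CREa2": (["P", "P", "S"], ["P", "S", "P"]),
        "SMPp&v1": (["P", "P"], ["C", "D", "T", "H"]),
    }
    return _assemble(
        seed, dual, {}, duplicated=[("CREa1A", "CREa2A")], long_b=_LONG_B_LINEAGES
    )


def write_scenario(
    scenario: Scenario,
    out_dir: str | Path,
    n_brains: int = 2000,
) -> None:
    """Write SWC files, clones.csv and ground_truth.json for a scenario."""
    from .birth_order import write_clone_records
    from .skeleton import write_swc

    out = Path(out_dir)
    (out / "swc").mkdir(parents=True, exist_ok=True)
    for name, skel in scenario.skeletons().items():
        safe = name.replace("&", "+").replace("/", "-")
        write_swc(skel, out / "swc" / f"{safe}.swc")
    write_clone_records(scenario.clone_records(n_brains), out / "clones.csv")
    truth = {
        "classes": scenario.true_classes(),
        "birth_order": {
            h: scenario.true_birth_order(h) for h in scenario.hemilineages()
        },
        "duplicated": [
            [lin.name + "A", lin.duplication_partner + "A"]
            for lin in scenario.lineages
            if lin.duplication_partner and lin.name < lin.duplication_partner
        ],
        "target_lengths": {t.name: t.target_length for t in scenario.all_types()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    scenario.brain.to_json(out / "brain.json")
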