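"""End-to-end analysis conveniences built on the stage modules.

These functions chain the single-purpose operations into the tables a study
would report: per-neuron length measurements, topology classification
reports, similarity pair/group extraction from a score matrix, and the
hemilineage-level statistics over dual lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import nblast
from .nomenclature import parse_type_name
from .skeleton import (
    DEFAULT_PRUNE_THRESHOLDS,
    NeuronSkeleton,
    main_trajectory_length,
    total_cable_length,
)
from .stats import (
    LineagePair,
    TestResult,
    class_count_paired_test,
    cv_paired_test,
    lineage_length_test,
)
from .topology import BrainModel, TopologyParams, classify_topology, crosses_midline, detect_arbor_domains

__all__ = [
    "measure_lengths",
    "classification_report",
    "SimilarityAnalysis",
    "similarity_analysis",
    "lineage_pairs_from",
    "hemilineage_stats_report",
]


def measure_lengths(
    skeletons: Mapping[str, NeuronSkeleton],
    prune_thresholds: Sequence[float] = DEFAULT_PRUNE_THRESHOLDS,
) -> pd.DataFrame:
    """Total and main-trajectory cable length per neuron type.

    Columns: type_name, lineage, hemilineage, notch_state, total_cable_um,
    main_trajectory_um.
    """
    rows = []
    for name, skel in skeletons.items():
        tn = parse_type_name(name)
        rows.append(
            {
                "type_name": name,
                "lineage": tn.lineage,
                "hemilineage": tn.hemilineage,
                "notch_state": tn.notch_suffix or "lone",
                "total_cable_um": total_cable_length(skel),
                "main_trajectory_um": main_trajectory_length(skel, prune_thresholds),
            }
        )
    return pd.DataFrame(rows)


def classification_report(
    skeletons: Mapping[str, NeuronSkeleton],
    brain: BrainModel,
    params: Optional[TopologyParams] = None,
) -> pd.DataFrame:
    """Topology classification per neuron.

    Columns: type_name, n_domains, crosses_midline, symmetric, class.
    ``symmetric`` reports whether lateral domains mirror across the midline.
    """
    from .topology import bilateral_symmetry

    params = params or TopologyParams()
    rows = []
    for name, skel in skeletons.items():
        domains = detect_arbor_domains(
            skel, brain, link_radius=params.link_radius, min_points=params.min_points
        )
        rows.append(
            {
                "type_name": name,
                "n_domains": len(domains),
                "crosses_midline": crosses_midline(skel, brain),
                "symmetric": bilateral_symmetry(domains, brain, params.match_radius),
                "class": classify_topology(skel, brain, params),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SimilarityAnalysis:
    """Result bundle of the score-matrix pair/group extraction."""

    matrix: nblast.SimilarityMatrix
    pairs: list[tuple[str, str]]  # above cutoff, unordered
    non_sibling_pairs: list[tuple[str, str]]  # cross-hemilineage only
    groups: list[nblast.SimilarityGroup]

    @property
    def n_grouped_types(self) -> int:
        return sum(len(g) for g in self.groups)


def similarity_analysis(
    matrix: nblast.SimilarityMatrix,
    cutoff: float = 0.3,
) -> SimilarityAnalysis:
    """Pairs above cutoff -> sibling filter -> connected-component groups."""
    pairs = nblast.select_pairs(matrix, cutoff)
    non_sibling = nblast.filter_non_sibling(pairs)
    groups = nblast.consolidate_groups(non_sibling)
    return SimilarityAnalysis(
        matrix=matrix, pairs=pairs, non_sibling_pairs=non_sibling, groups=groups
    )


def lineage_pairs_from(
    lengths: pd.DataFrame,
    classes: Optional[pd.DataFrame] = None,
    length_column: str = "main_trajectory_um",
) -> list[LineagePair]:
    """Assemble A/B measurement pairs for every dual-hemilineage lineage.

    ``lengths`` is a :func:`measure_lengths`-style table; ``classes`` an
    optional :func:`classification_report`-style table used for
    topology-class counts (parsed from type names when absent).
    """
    class_of = {}
    if classes is not None:
        class_of = dict(zip(classes["type_name"], classes["class"]))
    pairs = []
    for lineage, sub in lengths.groupby("lineage", sort=True):
        a = sub[sub["notch_state"] == "A"]
        b = sub[sub["notch_state"] == "B"]
        if a.empty or b.empty:
            continue

        def n_classes(frame: pd.DataFrame) -> int:
            letters = {
                class_of.get(t, parse_type_name(t).class_letter)
                for t in frame["type_name"]
            }
            return len(letters)

        pairs.append(
            LineagePair(
                lineage=lineage,
                A_lengths=list(a[length_column]),
                B_lengths=list(b[length_column]),
                A_classes=n_classes(a),
                B_classes=n_classes(b),
            )
        )
    return pairs


def hemilineage_stats_report(
    pairs: Sequence[LineagePair],
    alpha_lineage: float = 0.01,
    length_test_method: str = "welch",
) -> dict:
    """Per-lineage length tests plus the paired CV and class-count tests."""
    per_lineage = {
        p.lineage: lineage_length_test(p, alpha=alpha_lineage, method=length_test_method)
        for p in pairs
    }
    return {
        "per_lineage_length": per_lineage,
        "significant_lineages": sorted(
            name for name, res in per_lineage.items() if res.significant
        ),
        "cv_paired": cv_paired_test(pairs),
        "class_count_paired": class_count_paired_test(pairs),
    }
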