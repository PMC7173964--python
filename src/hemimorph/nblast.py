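"""NBLAST-style point-cloud similarity scoring and similarity groups.

Neurons are compared as *dotprops*: point clouds resampled at regular
spacing along the skeleton, each point carrying a unit tangent vector from a
local PCA of its k nearest neighbours.  A raw score accumulates, over every
query point, a function of the distance to the nearest target point and the
absolute tangent dot product.  The default scoring function is the analytic
surrogate ``f(d, a) = exp(-d / sigma) * a`` with sigma = 3 um, which keeps
the published score's monotonicity (decreasing in distance, increasing in
tangent alignment); a tabulated score matrix can be supplied instead.

Normalized mean scores (self-score 1, symmetric) feed pair selection at a
cutoff, removal of intra-hemilineage (sibling) pairs, and consolidation of
the surviving pair graph into connected-component similarity groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .nomenclature import hemilineage_key
from .skeleton import NeuronSkeleton, decompose_segments

__all__ = [
    "DotProps",
    "ExponentialScore",
    "TabulatedScore",
    "SimilarityMatrix",
    "SimilarityGroup",
    "to_dotprops",
    "raw_score",
    "mean_normalized_score",
    "all_to_all",
    "select_pairs",
    "filter_non_sibling",
    "consolidate_groups",
    "hemilineage_heatmap",
]

logger = logging.getLogger(__name__)


@dataclass
class DotProps:
    """Resampled point cloud with unit tangents."""

    points: np.ndarray  # (N, 3), um
    tangents: np.ndarray  # (N, 3), unit vectors (sign arbitrary)
    k_neighbors: int
    spacing: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if len(self.points) < 1:
            raise ValueError("dotprops needs at least one point")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tangents must be unit vectors")

    def __len__(self) -> int:
        return len(self.points)


class ExponentialScore:
    """Analytic scoring function ``f(d, a) = exp(-d / sigma) * a``."""

    def __init__(self, sigma: float = 3.0):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = sigma

    def __call__(self, dist: np.ndarray, absdot: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(dist, dtype=float) / self.sigma) * np.asarray(
            absdot, dtype=float
        )


class TabulatedScore:
    """Scoring function from a table over distance x |dot product| bins.

    Out-of-range arguments clip to the nearest bin, mirroring how published
    NBLAST score matrices are applied.
    """

    def __init__(
        self,
        dist_edges: Sequence[float],
        dot_edges: Sequence[float],
        values: np.ndarray,
    ):
        self.dist_edges = np.asarray(dist_edges, dtype=float)
        self.dot_edges = np.asarray(dot_edges, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.dist_edges) - 1, len(self.dot_edges) - 1):
            raise ValueError("value table shape does not match bin edges")

    def __call__(self, dist: np.ndarray, absdot: np.ndarray) -> np.ndarray:
        di = np.clip(
            np.searchsorted(self.dist_edges, dist, side="right") - 1,
            0,
            len(self.dist_edges) - 2,
        )
        ai = np.clip(
            np.searchsorted(self.dot_edges, absdot, side="right") - 1,
            0,
            len(self.dot_edges) - 2,
        )
        return self.values[di, ai]


ScoringFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]
DEFAULT_SCORE: ScoringFunction = ExponentialScore(sigma=3.0)


# ---------------------------------------------------------------------------
# Dotprops construction
# ---------------------------------------------------------------------------

def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at ``spacing`` arc length; endpoints retained."""
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total == 0:
        return points[:1]
    stations = np.arange(0.0, total, spacing)
    if total - stations[-1] > 1e-9:
        stations = np.append(stations, total)
    out = np.empty((len(stations), 3))
    for axis in range(3):
        out[:, axis] = np.interp(stations, cum, points[:, axis])
    return out


def to_dotprops(skeleton: NeuronSkeleton, spacing: float = 1.0, k: int = 5) -> DotProps:
    """Resample a skeleton into a dotprops cloud with local-PCA tangents.

    Each unbranched segment is resampled at ``spacing`` um along its arc
    length; every point's tangent is the dominant principal direction of its
    ``k`` nearest neighbours (tangent sign is arbitrary; scoring uses the
    absolute dot product).
    """
    if spacing <= 0 or k < 1:
        raise ValueError("spacing must be positive and k >= 1")
    segments = decompose_segments(skeleton)
    if segments:
        pieces = []
        for seg in segments:
            poly = np.array([skeleton.node(i).position for i in seg.node_path])
            pieces.append(_resample_polyline(poly, spacing))
        points = np.vstack(pieces)
    else:  # single-node skeleton
        points = skeleton.positions()
    if len(points) < k:
        raise ValueError(
            f"only {len(points)} resampled points but k={k}; use a smaller k "
            "or finer spacing"
        )
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k)
    if k == 1:
        idx = idx[:, None]
    tangents = np.empty_like(points)
    for i, nbrs in enumerate(idx):
        local = points[nbrs] - points[nbrs].mean(axis=0)
        # dominant eigenvector of the local covariance
        _, vecs = np.linalg.eigh(local.T @ local)
        tangents[i] = vecs[:, -1]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return DotProps(points=points, tangents=tangents, k_neighbors=k, spacing=spacing)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def raw_score(
    query: DotProps, target: DotProps, f: ScoringFunction = DEFAULT_SCORE
) -> float:
    """Asymmetric raw similarity: sum over query points of ``f(d, |dot|)``.

    ``d`` is the Euclidean distance from each query point to its nearest
    target point; ``|dot|`` the absolute tangent dot product of that pair.
    """
    tree = cKDTree(target.points)
    dist, idx = tree.query(query.points)
    absdot = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    return float(np.sum(f(dist, absdot)))


def mean_normalized_score(
    a: DotProps, b: DotProps, f: ScoringFunction = DEFAULT_SCORE
) -> float:
    """Symmetric normalized score: ``(raw(a,b)/raw(a,a) + raw(b,a)/raw(b,b))/2``.

    Identical clouds score exactly 1.
    """
    self_a = raw_score(a, a, f)
    self_b = raw_score(b, b, f)
    if self_a <= 0 or self_b <= 0:
        raise ValueError("zero self-score: scoring function must have f(0, 1) > 0")
    return 0.5 * (raw_score(a, b, f) / self_a + raw_score(b, a, f) / self_b)


# ---------------------------------------------------------------------------
# Similarity matrix
# ---------------------------------------------------------------------------

class SimilarityMatrix:
    """Labelled square matrix of similarity scores.

    Thin wrapper over a :class:`pandas.DataFrame` carrying ``normalized``
    (diagonal = 1) and ``symmetrized`` flags.
    """

    def __init__(self, frame: pd.DataFrame, normalized: bool, symmetrized: bool):
        if frame.shape[0] != frame.shape[1]:
            raise ValueError(f"matrix must be square, got {frame.shape}")
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column labels must match")
        if len(set(frame.index)) != len(frame.index):
            raise ValueError("duplicate labels")
        self.frame = frame.astype(float)
        self.normalized = normalized
        self.symmetrized = symmetrized

    @property
    def labels(self) -> list[str]:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def score(self, a: str, b: str) -> float:
        return float(self.frame.at[a, b])

    def symmetrize(self) -> "SimilarityMatrix":
        """Average with the transpose (no-op when already symmetric)."""
        if self.symmetrized:
            return self
        logger.info("symmetrizing asymmetric score matrix by averaging with transpose")
        sym = (self.frame + self.frame.T) / 2.0
        return SimilarityMatrix(sym, self.normalized, True)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SimilarityMatrix":
        """Tolerant reader: comma or tab delimited, first row/column labels.

        Auto-detects whether the matrix is normalized (diagonal ~ 1) and
        symmetric, and logs the verdict.
        """
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
        frame.index = frame.index.astype(str).str.strip()
        frame.columns = frame.columns.astype(str).str.strip()
        values = frame.to_numpy(dtype=float)
        normalized = bool(np.allclose(np.diag(values), 1.0, atol=1e-6))
        symmetrized = bool(np.allclose(values, values.T, atol=1e-9))
        logger.info(
            "read %dx%d score matrix from %s (normalized=%s, symmetric=%s)",
            *frame.shape, path, normalized, symmetrized,
        )
        return cls(frame, normalized=normalized, symmetrized=symmetrized)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path)


@dataclass(frozen=True)
class SimilarityGroup:
    id: int
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def all_to_all(
    neurons: Sequence[tuple[str, DotProps]],
    f: ScoringFunction = DEFAULT_SCORE,
) -> SimilarityMatrix:
    """All-to-all normalized, symmetrized score matrix (diagonal exactly 1)."""
    labels = [lab for lab, _ in neurons]
    if len(labels) < 2:
        raise ValueError("need at least two labelled neurons")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    clouds = [dp for _, dp in neurons]
    n = len(clouds)
    self_scores = np.array([raw_score(dp, dp, f) for dp in clouds])
    if np.any(self_scores <= 0):
        raise ValueError("zero self-score: scoring function must have f(0, 1) > 0")
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.5 * (
                raw_score(clouds[i], clouds[j], f) / self_scores[i]
                + raw_score(clouds[j], clouds[i], f) / self_scores[j]
            )
            values[i, j] = values[j, i] = s
    frame = pd.DataFrame(values, index=labels, columns=labels)
    return SimilarityMatrix(frame, normalized=True, symmetrized=True)


# ---------------------------------------------------------------------------
# Pairs and groups
# ---------------------------------------------------------------------------

def select_pairs(
    matrix: SimilarityMatrix, cutoff: float = 0.3
) -> list[tuple[str, str]]:
    """All unordered label pairs with score strictly greater than ``cutoff``.

    The matrix is symmetrized by averaging first if needed; the diagonal is
    excluded.  Pairs are returned in matrix label order (deterministic).
    """
    m = matrix.symmetrize()
    labels = m.labels
    values = m.values
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if values[i, j] > cutoff:
                pairs.append((labels[i], labels[j]))
    return pairs


def filter_non_sibling(
    pairs: Iterable[tuple[str, str]],
    name_parser: Callable[[str], str] = hemilineage_key,
) -> list[tuple[str, str]]:
    """Drop intra-hemilineage (sibling) pairs.

    ``name_parser`` maps a label to its hemilineage key (lineage plus A/B
    suffix for dual lineages, bare lineage for lone hemilineages); pairs
    whose members share a key are removed.
    """
    kept = []
    for a, b in pairs:
        try:
            ka = name_parser(a)
        except Exception as exc:
            raise ValueError(f"cannot derive hemilineage for label {a!r}: {exc}") from exc
        try:
            kb = name_parser(b)
        except Exception as exc:
            raise ValueError(f"cannot derive hemilineage for label {b!r}: {exc}") from exc
        if ka != kb:
            kept.append((a, b))
    return kept


def consolidate_groups(pairs: Iterable[tuple[str, str]]) -> list[SimilarityGroup]:
    """Connected components of the pair graph as similarity groups.

    Groups are sorted by size descending, then by lexicographically smallest
    member; labels in no pair do not appear.
    """
    graph = nx.Graph()
    graph.add_edges_from(pairs)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), min(c)),
    )
    return [SimilarityGroup(id=i + 1, members=c) for i, c in enumerate(components)]


def hemilineage_heatmap(
    matrix: SimilarityMatrix,
    hemilineage: str,
    type_order: Sequence[str],
    name_parser: Callable[[str], str] = hemilineage_key,
) -> pd.DataFrame:
    """Intra-hemilineage score sub-matrix with rows/columns in ``type_order``.

    Sorting ``type_order`` by birth order exposes temporal patterns of
    relatedness (progressive vs cyclic) as banding in the heatmap.
    """
    known = set(matrix.labels)
    for label in type_order:
        if label not in known:
            raise KeyError(f"label {label!r} not in matrix")
        if name_parser(label) != hemilineage:
            raise ValueError(f"label {label!r} is not in hemilineage {hemilineage!r}")
    return matrix.frame.loc[list(type_order), list(type_order)]
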