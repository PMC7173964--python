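import numpy as np
import pytest

from hemimorph import NeuronSkeleton, SkeletonNode, demo_scenario


def make_path(xs, ys=None, zs=None, intensities=None):
    """Unbranched skeleton along given coordinates (ids 1..n)."""
    n = len(xs)
    ys = ys or [0.0] * n
    zs = zs or [0.0] * n
    nodes = []
    for i in range(n):
        nodes.append(
            SkeletonNode(
                id=i + 1,
                parent_id=None if i == 0 else i,
                position=np.array([xs[i], ys[i], zs[i]], float),
                intensity=None if intensities is None else intensities[i],
            )
        )
    return NeuronSkeleton(nodes)


def attach_branch(skeleton, at_id, offsets, start_id):
    """Append a chain of nodes branching off ``at_id`` by successive offsets."""
    nodes = [n.copy() for n in skeleton.nodes]
    pos = skeleton.node(at_id).position.copy()
    parent = at_id
    nid = start_id
    for off in offsets:
        pos = pos + np.asarray(off, float)
        nodes.append(SkeletonNode(id=nid, parent_id=parent, position=pos.copy()))
        parent = nid
        nid += 1
    return NeuronSkeleton(nodes)


def random_tree(rng, n_nodes, step=8.0, with_intensity=False):
    """Random rooted tree with geometric edge lengths around ``step`` um."""
    nodes = [
        SkeletonNode(
            id=1,
            parent_id=None,
            position=np.zeros(3),
            intensity=float(rng.uniform(1, 100)) if with_intensity else None,
            radius=float(rng.uniform(0.5, 2.0)),
        )
    ]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = nodes[parent - 1].position + direction * rng.uniform(0.3, 2.0) * step
        nodes.append(
            SkeletonNode(
                id=i,
                parent_id=parent,
                position=pos,
                intensity=float(rng.uniform(1, 100)) if with_intensity else None,
                radius=float(rng.uniform(0.5, 2.0)),
            )
        )
    return NeuronSkeleton(nodes)


@pytest.fixture(scope="session")
def demo():
    return demo_scenario(1)


@pytest.fixture(scope="session")
def demo_skeletons(demo):
    return demo.skeletons()
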