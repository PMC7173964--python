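"""Serial pruning of a neuron skeleton down to its main trajectory.

Builds a toy neuron (100-um trunk with a 30-um and a 60-um side branch) and
prunes terminal branches shorter than 10, then 25, then 50 um.  The
surviving cable length is the main-trajectory length — the backbone
statistic used to compare hemilineages.
"""

import numpy as np

from hemimorph import (
    NeuronSkeleton,
    SkeletonNode,
    main_trajectory_length,
    prune_terminal_branches,
    total_cable_length,
)


def node(nid, parent, x, y=0.0):
    return SkeletonNode(id=nid, parent_id=parent, position=np.array([x, y, 0.0]))


nodes = [node(1, None, 0)] + [node(i + 1, i, i * 10.0) for i in range(1, 11)]
nodes += [node(20, 6, 50, 15), node(21, 20, 50, 30)]   # 30-um branch at x=50
nodes += [node(30, 9, 80, 30), node(31, 30, 80, 60)]   # 60-um branch at x=80
skel = NeuronSkeleton(nodes)

print(f"total cable:        {total_cable_length(skel):6.1f} um")
for threshold in (10, 25, 50):
    skel = prune_terminal_branches(skel, threshold)
    print(f"after <{threshold:>2} um prune: {total_cable_length(skel):6.1f} um")

nodes2 = [node(1, None, 0)] + [node(i + 1, i, i * 10.0) for i in range(1, 11)]
nodes2 += [node(20, 6, 50, 15), node(21, 20, 50, 30)]
nodes2 += [node(30, 9, 80, 30), node(31, 30, 80, 60)]
print(f"main_trajectory_length: {main_trajectory_length(NeuronSkeleton(nodes2)):.1f} um")
# 190 -> 190 -> 170 -> 140: the 20-um distal tail goes at 25 um (merging the
# 60-um branch into the trunk), the 30-um branch goes at 50 um.
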