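"""Analysis helpers: branch persistence, well recovery, merge order.

A conformation tree built on a landscape with well-separated wells should
show one long-lived branch per well, and branches of wells separated by
lower barriers should merge at smaller ε.  The helpers here quantify that:

* **branch persistence** follows each leaf upward using the elder rule —
  at a merge node the largest child subtree continues the branch, the
  others die there — so a branch's persistence is the ε distance from its
  birth to the merge that absorbs it.  Short-lived leaves (e.g. a handful
  of fringe points that join the main cluster one level later) are not
  counted as maximal-depth branches.
* **well recovery** maps long-lived branches to wells by majority vote of
  the generating-well assignment and reports purity.
* **merge order** replays the expected single-linkage merge events of the
  landscape (:func:`welltree.landscape.expected_merge_order`) against the
  ε at which the corresponding branches actually became density-connected
  in the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .landscape import WellSpec, expected_merge_order
from .tree import ConformationTree, TreeNode

__all__ = [
    "branch_persistence",
    "maximal_depth_branches",
    "WellRecovery",
    "well_recovery",
]


def branch_persistence(tree: ConformationTree) -> dict[int, float]:
    """ε lifetime of each leaf's branch under the elder rule.

    Returns leaf id → persistence (``inf`` for the branch that survives to
    the top of the tree).  At every ancestor with several children the
    branch continues only through the child with the most members (ties:
    lowest node id).
    """
    out: dict[int, float] = {}
    for leaf in tree.leaves():
        current: TreeNode = leaf
        death: float | None = None
        while current.parent is not None:
            parent = tree.node(current.parent)
            siblings = [tree.node(c) for c in parent.children]
            if len(siblings) > 1:
                elder = max(siblings, key=lambda s: (s.n_members, -s.id))
                if elder.id != current.id:
                    death = parent.eps_first
                    break
            current = parent
        out[leaf.id] = (
            np.inf if death is None else death - leaf.eps_first
        )
    return out


def maximal_depth_branches(
    tree: ConformationTree, min_levels: int = 2
) -> list[TreeNode]:
    """Leaves whose branch persists at least ``min_levels`` ε increments.

    These are the tree's maximal-depth branches: the densest clusters that
    remain separate long enough to count as distinct wells, as opposed to
    transient fringe fragments that merge away after a level or two.
    """
    persistence = branch_persistence(tree)
    threshold = min_levels * tree.schedule.delta_eps
    return [
        leaf for leaf in tree.leaves()
        if persistence[leaf.id] >= threshold
    ]


@dataclass(frozen=True)
class WellRecovery:
    """How faithfully a tree recovers a known well structure."""

    n_wells: int
    n_branches: int                       # maximal-depth branches found
    branch_wells: tuple[int, ...]         # majority well per branch
    purities: tuple[float, ...]           # majority fraction per branch
    one_branch_per_well: bool
    merge_eps: tuple[float, ...]          # tree ε of each expected merge event
    merge_order_matches: bool

    @property
    def min_purity(self) -> float:
        return min(self.purities) if self.purities else 0.0


def _path_eps(tree: ConformationTree, leaf: TreeNode) -> dict[int, float]:
    """Node id → birth ε for every node on the leaf's path to the top."""
    path = {}
    current = leaf
    while True:
        path[current.id] = current.eps_first
        if current.parent is None:
            return path
        current = tree.node(current.parent)


def well_recovery(
    tree: ConformationTree,
    well_assignment: np.ndarray,
    spec: WellSpec,
    min_levels: int = 2,
) -> WellRecovery:
    """Score branch count, purity and merge order against the landscape.

    ``well_assignment`` is the per-frame generating-well index from the
    sampler.  Merge order is compared event by event against
    :func:`expected_merge_order`: the tree ε of each expected event must be
    non-decreasing along the expected sequence, strictly increasing where
    the expected gaps are strictly ordered (ties accept either order).
    """
    wa = np.asarray(well_assignment, dtype=int)
    branches = maximal_depth_branches(tree, min_levels=min_levels)
    branch_wells: list[int] = []
    purities: list[float] = []
    for leaf in sorted(branches, key=lambda n: n.id):
        members = np.fromiter(leaf.members, dtype=int)
        counts = np.bincount(wa[members], minlength=spec.n_wells)
        branch_wells.append(int(np.argmax(counts)))
        purities.append(float(counts.max() / counts.sum()))
    one_per_well = (
        len(branches) == spec.n_wells
        and sorted(branch_wells) == list(range(spec.n_wells))
    )

    expected = expected_merge_order(spec)
    merge_eps: list[float] = []
    order_ok = one_per_well
    if one_per_well and expected:
        leaf_of_well = {
            w: leaf for w, leaf in zip(
                branch_wells, sorted(branches, key=lambda n: n.id)
            )
        }
        paths = {w: _path_eps(tree, leaf) for w, leaf in leaf_of_well.items()}

        def lca_eps(i: int, j: int) -> float:
            shared = set(paths[i]) & set(paths[j])
            if not shared:
                raise InvalidArgumentError(
                    f"wells {i} and {j} never merge (incomplete tree?)"
                )
            return min(paths[i][s] for s in shared)

        for group_a, group_b, _gap in expected:
            merge_eps.append(
                min(lca_eps(i, j) for i in group_a for j in group_b)
            )
        for idx in range(1, len(expected)):
            prev_gap, gap = expected[idx - 1][2], expected[idx][2]
            if merge_eps[idx] < merge_eps[idx - 1]:
                order_ok = False
            elif gap > prev_gap + 1e-12 and not (
                merge_eps[idx] >= merge_eps[idx - 1]
            ):
                order_ok = False
    return WellRecovery(
        n_wells=spec.n_wells,
        n_branches=len(branches),
        branch_wells=tuple(branch_wells),
        purities=tuple(purities),
        one_branch_per_well=one_per_well,
        merge_eps=tuple(merge_eps),
        merge_order_matches=order_ok,
    )
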