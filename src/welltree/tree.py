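"""Adaptive density-clustering trees over conformational point clouds.

The core algorithm: run DBSCAN on the projected frames at a radius ε, then
repeatedly increase ε by Δε and re-run.  Because the minimum density a
cluster must exceed is ``minpts / V_d(ε)`` (with ``V_d`` the volume of a
d-ball), growing ε lowers the density bar, so dense clusters found at
small ε — the deep energy wells visited by a simulation — become nested
inside progressively more diffuse clusters, until a single cluster holds
every frame: the root.  The nesting across ε levels is assembled into a
:class:`ConformationTree` whose leaves are the densest wells and whose
internal nodes record at which ε formerly separate basins became
density-connected: wells separated by low barriers merge at small ε,
deeply separated wells only near the root.

DBSCAN here is the textbook algorithm under the L2 norm with two
deterministic conventions, both documented because the method's output is
required to be reproducible bit-for-bit:

* a point's ε-neighborhood includes the point itself, so a core point has
  ``>= minpts`` points (self included) within ε;
* a border point reachable from several clusters joins the cluster of its
  lowest-index core neighbor; new clusters are numbered in order of their
  lowest-index core point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    NodeNotFoundError,
    TreeValidationError,
)
from .pca import ProjectedEnsemble

__all__ = [
    "NOISE",
    "EpsilonSchedule",
    "ClusterLevel",
    "TreeNode",
    "ConformationTree",
    "TreeReport",
    "hypersphere_volume",
    "min_density",
    "dbscan",
    "build_tree",
    "validate_tree",
    "SCHEDULE_PRESETS",
]

NOISE = -1

#: ε-schedules used in published analyses of an ABC-transporter ensemble,
#: one per (starting conformation, atom selection) pair; all use minpts=4
#: in a 10-dimensional PC subspace.
SCHEDULE_PRESETS: dict[str, dict[str, float | int]] = {
    "peroxisome_open_all_ca": {"eps_init": 0.83, "delta_eps": 0.01, "minpts": 4},
    "peroxisome_open_atp_pocket_ca": {
        "eps_init": 0.135, "delta_eps": 0.001, "minpts": 4,
    },
    "cytosol_open_all_ca": {"eps_init": 3.7, "delta_eps": 0.05, "minpts": 4},
    "cytosol_open_vlcfa_pocket_ca": {
        "eps_init": 0.3, "delta_eps": 0.001, "minpts": 4,
    },
}


@dataclass(frozen=True)
class EpsilonSchedule:
    """Parameters of the adaptive ε sweep.

    ``eps_init`` is the starting radius, ``delta_eps`` the per-iteration
    increment (level L runs at ``eps_init + L * delta_eps``), ``minpts``
    the DBSCAN core threshold (self included) and ``max_levels`` a safety
    cap on the number of iterations.
    """

    eps_init: float
    delta_eps: float
    minpts: int = 4
    max_levels: int = 10_000

    def __post_init__(self) -> None:
        if self.eps_init <= 0:
            raise InvalidArgumentError("eps_init must be positive")
        if self.delta_eps <= 0:
            raise InvalidArgumentError("delta_eps must be positive")
        if self.minpts < 1:
            raise InvalidArgumentError("minpts must be >= 1")
        if self.max_levels < 1:
            raise InvalidArgumentError("max_levels must be >= 1")

    def eps_at(self, level: int) -> float:
        return self.eps_init + level * self.delta_eps


@dataclass(frozen=True)
class ClusterLevel:
    """One DBSCAN pass: radius, per-frame cluster id (or NOISE), count."""

    eps: float
    assignment: np.ndarray
    n_clusters: int


@dataclass
class TreeNode:
    id: int
    eps_first: float
    eps_last: float
    members: frozenset[int]
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ConformationTree:
    """Nested density clusters across the ε sweep.

    ``complete`` is True when the sweep reached a single all-frame cluster
    (the root); otherwise the structure is a forest of the nodes still
    active when ``max_levels`` was exhausted (``root_id is None``,
    ``top_ids`` lists the forest tops).
    """

    nodes: dict[int, TreeNode]
    root_id: int | None
    complete: bool
    n_frames: int
    schedule: EpsilonSchedule
    levels_run: int
    top_ids: tuple[int, ...] = ()

    def node(self, node_id: int) -> TreeNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise NodeNotFoundError(f"no node with id {node_id}") from None

    def leaves(self) -> list[TreeNode]:
        """Childless nodes — the maximal-depth (densest) branches."""
        return [n for n in self.nodes.values() if not n.children]

    def __len__(self) -> int:
        return len(self.nodes)


def hypersphere_volume(radius: float, dim: int) -> float:
    """Volume of a d-ball: ``V_d(R) = π^(d/2) R^d / Γ(d/2 + 1)``."""
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    if dim < 1:
        raise InvalidArgumentError("dim must be >= 1")
    return float(
        np.exp(0.5 * dim * np.log(np.pi) + dim * np.log(radius)
               - gammaln(0.5 * dim + 1))
    )


def min_density(minpts: int, radius: float, dim: int) -> float:
    """Density bar a cluster must exceed: ``minpts / V_d(radius)``.

    In 10 dimensions with minpts=4 this is ``480 / (π⁵ R¹⁰)``, since
    ``V_10(R) = π⁵ R¹⁰ / 120``.
    """
    if minpts < 1:
        raise InvalidArgumentError("minpts must be >= 1")
    return minpts / hypersphere_volume(radius, dim)


def _as_points(points: ProjectedEnsemble | np.ndarray) -> np.ndarray:
    if isinstance(points, ProjectedEnsemble):
        return points.points
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 1)
    return pts


def dbscan(
    points: ProjectedEnsemble | np.ndarray, eps: float, minpts: int
) -> ClusterLevel:
    """Density-based clustering under the L2 norm (deterministic order).

    Core points have >= ``minpts`` points (self included) within ``eps``;
    clusters are maximal density-connected sets of core points plus their
    border points; unreachable points are labelled :data:`NOISE`.
    """
    if eps <= 0:
        raise InvalidArgumentError("eps must be positive")
    if minpts < 1:
        raise InvalidArgumentError("minpts must be >= 1")
    x = _as_points(points)
    n = x.shape[0]
    if n == 0:
        return ClusterLevel(eps=eps, assignment=np.empty(0, dtype=int),
                            n_clusters=0)
    tree = cKDTree(x)
    neighborhoods = tree.query_ball_point(x, r=eps)
    core = np.fromiter(
        (len(nb) >= minpts for nb in neighborhoods), dtype=bool, count=n
    )
    labels = np.full(n, NOISE, dtype=int)
    cid = 0
    for i in range(n):  # ascending frame index: deterministic numbering
        if not core[i] or labels[i] != NOISE:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for nb in neighborhoods[j]:
                if core[nb] and labels[nb] == NOISE:
                    labels[nb] = cid
                    stack.append(nb)
        cid += 1
    # Border points: lowest-index core neighbor decides the cluster.
    for i in range(n):
        if core[i]:
            continue
        core_nb = [j for j in neighborhoods[i] if core[j]]
        if core_nb:
            labels[i] = labels[min(core_nb)]
    return ClusterLevel(eps=eps, assignment=labels, n_clusters=cid)


def build_tree(
    points: ProjectedEnsemble | np.ndarray, schedule: EpsilonSchedule
) -> ConformationTree:
    """Assemble the ε-sweep cluster hierarchy into a conformation tree.

    DBSCAN runs at ε_L = eps_init + L·Δε for L = 0, 1, 2, … until one
    cluster contains every frame (the root) or ``max_levels`` is reached
    (flagged-incomplete forest).  Each cluster becomes a node; a node whose
    member set is unchanged on the next level is extended (its
    ``[eps_first, eps_last]`` interval grows) instead of duplicated.
    Parent links attach each node to the next-level cluster holding the
    majority of its members (ties: the candidate containing the lowest
    frame index).  Frames that were noise at denser levels enter the tree
    at the first level that clusters them.
    """
    x = _as_points(points)
    n = x.shape[0]
    if n < schedule.minpts:
        raise InsufficientDataError(
            f"need at least minpts={schedule.minpts} frames, got {n}"
        )
    nodes: dict[int, TreeNode] = {}
    active: dict[int, TreeNode] = {}
    next_id = 0
    complete = False
    levels_run = 0
    for level_idx in range(schedule.max_levels):
        eps = schedule.eps_at(level_idx)
        level = dbscan(x, eps, schedule.minpts)
        levels_run = level_idx + 1
        clusters = {
            cid: np.flatnonzero(level.assignment == cid)
            for cid in range(level.n_clusters)
        }
        # parent cluster for each active node: majority overlap
        attach: dict[int, list[int]] = {cid: [] for cid in clusters}
        for nid, node in active.items():
            member_arr = np.fromiter(node.members, dtype=int)
            labs = level.assignment[member_arr]
            labs = labs[labs != NOISE]
            counts = np.bincount(labs, minlength=level.n_clusters)
            best = int(np.argmax(counts))
            tied = np.flatnonzero(counts == counts[best])
            if len(tied) > 1:
                best = int(min(tied, key=lambda c: clusters[c].min()))
            attach[best].append(nid)
        new_active: dict[int, TreeNode] = {}
        for cid in sorted(clusters, key=lambda c: clusters[c].min()):
            members = frozenset(map(int, clusters[cid]))
            kids = attach[cid]
            if len(kids) == 1 and nodes[kids[0]].members == members:
                node = nodes[kids[0]]
                node.eps_last = eps
            else:
                node = TreeNode(
                    id=next_id, eps_first=eps, eps_last=eps, members=members
                )
                next_id += 1
                for kid in sorted(kids):
                    nodes[kid].parent = node.id
                    node.children.append(kid)
                nodes[node.id] = node
            new_active[node.id] = node
        active = new_active
        if level.n_clusters == 1 and len(clusters[0]) == n:
            complete = True
            break
    top_ids = tuple(sorted(active))
    return ConformationTree(
        nodes=nodes,
        root_id=top_ids[0] if complete else None,
        complete=complete,
        n_frames=n,
        schedule=schedule,
        levels_run=levels_run,
        top_ids=top_ids,
    )


@dataclass(frozen=True)
class TreeReport:
    """Outcome of :func:`validate_tree`."""

    n_nodes: int
    n_leaves: int
    single_root: bool
    containment_fraction: float  # min over non-top nodes of |m ∩ parent| / |m|
    exact_nesting: bool


def validate_tree(tree: ConformationTree, strict: bool = True) -> TreeReport:
    """Check tree invariants and report parent-containment quality.

    Invariants: a complete tree has exactly one parentless node (the root)
    whose members are all frames clustered at the final level; every
    non-top node's member set is a subset of its parent's; children of a
    common parent born at the same ε level are pairwise disjoint.  With
    ``strict`` (default) a violation raises :class:`TreeValidationError`
    naming the node; otherwise it is only reflected in the report.
    """
    problems: list[str] = []
    tops = [n for n in tree.nodes.values() if n.parent is None]
    single_root = len(tops) == 1
    if tree.complete:
        if not single_root:
            problems.append(
                f"complete tree has {len(tops)} parentless nodes: "
                f"{sorted(n.id for n in tops)}"
            )
        elif tree.root_id is not None and len(
            tree.node(tree.root_id).members
        ) != tree.n_frames:
            problems.append(f"root node {tree.root_id} does not hold all frames")
    min_frac = 1.0
    for node in tree.nodes.values():
        if node.parent is None:
            continue
        parent = tree.node(node.parent)
        if node.n_members:
            frac = len(node.members & parent.members) / node.n_members
            min_frac = min(min_frac, frac)
            if frac < 1.0:
                problems.append(
                    f"node {node.id} is not nested in its parent {parent.id} "
                    f"(containment {frac:.4f})"
                )
    for node in tree.nodes.values():
        kids = [tree.node(c) for c in node.children]
        by_birth: dict[float, list[TreeNode]] = {}
        for kid in kids:
            by_birth.setdefault(kid.eps_first, []).append(kid)
        for birth, sibs in by_birth.items():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    if sibs[i].members & sibs[j].members:
                        problems.append(
                            f"siblings {sibs[i].id} and {sibs[j].id} born at "
                            f"eps={birth:g} overlap"
                        )
    if strict and problems:
        raise TreeValidationError("; ".join(problems))
    return TreeReport(
        n_nodes=len(tree.nodes),
        n_leaves=len(tree.leaves()),
        single_root=single_root,
        containment_fraction=min_frac,
        exact_nesting=min_frac == 1.0 and not problems,
    )
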