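"""Serialisation of conformation trees: Newick, DOT, node tables.

Newick internal/leaf labels are ``n<id>``; the branch length of a child is
its ε-span, i.e. the ε distance from the child's birth level to its
parent's birth level (how long the child persisted as a separate density
cluster before merging).  The DOT export optionally carries per-node fill
colors from an annotation pass.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InvalidArgumentError
from .tree import ConformationTree, EpsilonSchedule, TreeNode

__all__ = [
    "to_newick",
    "to_dot",
    "write_node_table",
    "read_node_table",
]


def to_newick(tree: ConformationTree) -> str:
    """Render a complete tree as a Newick string with node-id labels."""
    if not tree.complete or tree.root_id is None:
        raise InvalidArgumentError(
            "cannot serialise an incomplete forest as Newick; "
            "increase max_levels or the epsilon schedule"
        )

    def render(node_id: int) -> str:
        node = tree.node(node_id)
        label = f"n{node.id}"
        if not node.children:
            return label
        parts = []
        for child_id in node.children:
            child = tree.node(child_id)
            span = node.eps_first - child.eps_first
            parts.append(f"{render(child_id)}:{span:.6g}")
        return f"({','.join(parts)}){label}"

    return render(tree.root_id) + ";"


def to_dot(
    tree: ConformationTree,
    fillcolors: dict[int, str] | None = None,
) -> str:
    """Render the tree (or incomplete forest) as a Graphviz digraph."""
    lines = ["digraph conformation_tree {", "  node [shape=box];"]
    for node in sorted(tree.nodes.values(), key=lambda n: n.id):
        attrs = [
            f'label="n{node.id}\\n{node.n_members} frames\\n'
            f'eps {node.eps_first:g}..{node.eps_last:g}"'
        ]
        if fillcolors and node.id in fillcolors:
            attrs.append(f'style=filled fillcolor="{fillcolors[node.id]}"')
        lines.append(f"  n{node.id} [{' '.join(attrs)}];")
    for node in sorted(tree.nodes.values(), key=lambda n: n.id):
        for child in node.children:
            lines.append(f"  n{node.id} -> n{child};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_node_table(tree: ConformationTree, path: str | Path) -> None:
    """Write nodes as TSV: id, parent (-1 for top), ε interval, members."""
    rows = []
    for node in sorted(tree.nodes.values(), key=lambda n: n.id):
        rows.append(
            {
                "node_id": node.id,
                "parent_id": -1 if node.parent is None else node.parent,
                "eps_first": node.eps_first,
                "eps_last": node.eps_last,
                "n_members": node.n_members,
                "members": " ".join(map(str, sorted(node.members))),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_node_table(
    path: str | Path, schedule: EpsilonSchedule | None = None
) -> ConformationTree:
    """Rebuild a ConformationTree from a node table written by this module."""
    df = pd.read_csv(path, sep="\t", dtype={"members": str})
    nodes: dict[int, TreeNode] = {}
    for row in df.itertuples(index=False):
        members = frozenset(
            int(m) for m in str(row.members).split() if m
        )
        nodes[int(row.node_id)] = TreeNode(
            id=int(row.node_id),
            eps_first=float(row.eps_first),
            eps_last=float(row.eps_last),
            members=members,
            parent=None if int(row.parent_id) < 0 else int(row.parent_id),
        )
    for node in nodes.values():
        if node.parent is not None:
            nodes[node.parent].children.append(node.id)
    for node in nodes.values():
        node.children.sort()
    tops = tuple(sorted(n.id for n in nodes.values() if n.parent is None))
    all_frames: set[int] = set()
    for node in nodes.values():
        all_frames |= node.members
    complete = len(tops) == 1 and nodes[tops[0]].members == frozenset(all_frames)
    return ConformationTree(
        nodes=nodes,
        root_id=tops[0] if complete else None,
        complete=complete,
        n_frames=len(all_frames),
        schedule=schedule
        or EpsilonSchedule(eps_init=1.0, delta_eps=1.0, minpts=1),
        levels_run=0,
        top_ids=tops,
    )
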