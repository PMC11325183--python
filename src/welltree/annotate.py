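"""Projecting per-frame metadata onto conformation trees.

A tree node is a cluster of frames; annotating the tree with a categorical
label (mutation, disease-progression form, …) means counting, per node and
label value, the member frames carrying that value and turning the count
into a logarithmic color intensity

    I = log10(count in node) / log10(total of that value),

so a node holding every conformation of a type renders at full intensity
and intensity decays logarithmically with the count.  Nodes holding fewer
than ``min_display`` conformations of a value (default 5) render white
(intensity 0) for that value.  Values are assigned colors from a
cyan/magenta/yellow palette and a node's display color is the additive mix
of its per-value intensities, so branches shared by several types show
blended hues.

Numeric covariates (e.g. a biomarker ratio) are discretised — by terciles
over the frames' values by default, or at explicit cut points — and then
annotated like a categorical label.

Representative structures: a node's representative is its member frame of
latest simulation time (ties: lowest frame index); representatives of two
branches are compared by RMSD, by default after optimal superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBreaksError,
    InvalidArgumentError,
    MissingLabelError,
)
from .geometry import rmsd
from .tree import ConformationTree

__all__ = [
    "DEFAULT_PALETTE",
    "NodeAnnotation",
    "Representative",
    "node_intensity",
    "annotate_tree",
    "annotate_numeric",
    "select_representative",
    "rmsd",
    "write_annotations",
]

#: Additive-mixing palette; the first three entries follow the
#: cyan/magenta/yellow convention for three-way label overlaps.
DEFAULT_PALETTE: tuple[tuple[float, float, float], ...] = (
    (0.0, 1.0, 1.0),  # cyan
    (1.0, 0.0, 1.0),  # magenta
    (1.0, 1.0, 0.0),  # yellow
    (1.0, 0.5, 0.0),  # orange
    (0.2, 0.4, 1.0),  # blue
    (0.1, 0.8, 0.2),  # green
)


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-node label summary: counts, intensities and a mixed color."""

    node_id: int
    counts: Mapping[str, int]
    intensities: Mapping[str, float]
    color: str  # '#rrggbb' additive mix of per-value colors


@dataclass(frozen=True)
class Representative:
    """The frame chosen to stand for a node's cluster."""

    node_id: int
    frame_index: int
    rule: str = "latest-time"


def node_intensity(
    count_in_node: int, total_of_type: int, min_display: int = 5
) -> float:
    """Logarithmic color intensity of a label value in a node.

    ``I = log10(count) / log10(total)`` clamped to [0, 1]; counts below
    ``min_display`` render white (0).  ``total_of_type`` must be >= 2 for
    the logarithm to be meaningful.
    """
    if total_of_type < 2:
        raise InvalidArgumentError("total_of_type must be >= 2")
    if not 0 <= count_in_node <= total_of_type:
        raise InvalidArgumentError(
            "count_in_node must be within [0, total_of_type]"
        )
    if count_in_node == total_of_type:
        return 1.0  # full-count limit outranks the display floor
    if count_in_node < min_display or count_in_node < 1:
        return 0.0
    return float(
        np.clip(np.log10(count_in_node) / np.log10(total_of_type), 0.0, 1.0)
    )


def _mix_color(
    intensities: Mapping[str, float],
    palette: Mapping[str, tuple[float, float, float]],
) -> str:
    rgb = np.zeros(3)
    for value, inten in intensities.items():
        rgb += inten * np.asarray(palette[value], dtype=float)
    rgb = np.clip(rgb, 0.0, 1.0)
    return "#{:02x}{:02x}{:02x}".format(*(int(round(c * 255)) for c in rgb))


def _palette_for(
    values: Sequence[str],
    palette: Mapping[str, tuple[float, float, float]] | None,
) -> dict[str, tuple[float, float, float]]:
    if palette is not None:
        missing = [v for v in values if v not in palette]
        if missing:
            raise InvalidArgumentError(f"palette lacks colors for {missing}")
        return dict(palette)
    return {
        v: DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
        for i, v in enumerate(values)
    }


def annotate_tree(
    tree: ConformationTree,
    labels: pd.DataFrame,
    label_name: str,
    palette: Mapping[str, tuple[float, float, float]] | None = None,
    min_display: int = 5,
) -> dict[int, NodeAnnotation]:
    """Count label values per node and derive logarithmic intensities.

    ``labels`` must contain ``frame_index`` and the ``label_name`` column,
    with a row for every frame that appears in the tree.  Intensities are
    normalised per label value against that value's global total, so the
    root (which holds every frame) is at full intensity for every value.
    """
    if label_name not in labels.columns:
        raise MissingLabelError(f"label table has no column {label_name!r}")
    per_frame = labels.set_index("frame_index")[label_name]
    if per_frame.index.has_duplicates:
        raise InvalidArgumentError("label table has duplicate frame_index rows")
    tree_frames: set[int] = set()
    for node in tree.nodes.values():
        tree_frames |= node.members
    missing = tree_frames - set(per_frame.index)
    if missing:
        raise MissingLabelError(
            f"frames missing from label table: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    per_frame = per_frame.astype(str)
    values = sorted(per_frame.unique())
    totals = per_frame.value_counts().to_dict()
    for v, tot in totals.items():
        if tot < 2:
            raise InvalidArgumentError(
                f"label value {v!r} occurs only {tot} time(s); intensity "
                "normalisation needs totals >= 2"
            )
    pal = _palette_for(values, palette)
    out: dict[int, NodeAnnotation] = {}
    for node in tree.nodes.values():
        member_values = per_frame.loc[sorted(node.members)]
        counts = {v: 0 for v in values}
        counts.update(member_values.value_counts().to_dict())
        intensities = {
            v: node_intensity(counts[v], totals[v], min_display) for v in values
        }
        out[node.id] = NodeAnnotation(
            node_id=node.id,
            counts=counts,
            intensities=intensities,
            color=_mix_color(intensities, pal),
        )
    return out


def annotate_numeric(
    tree: ConformationTree,
    labels: pd.DataFrame,
    covariate: str,
    breaks: str | Sequence[float] = "terciles",
    palette: Mapping[str, tuple[float, float, float]] | None = None,
    min_display: int = 5,
) -> dict[int, NodeAnnotation]:
    """Discretise a numeric covariate and annotate the tree with the bins.

    ``breaks="terciles"`` cuts at the empirical 1/3 and 2/3 quantiles of
    the covariate over all labelled frames (bins ``T1 <= T2 <= T3``);
    alternatively pass explicit interior cut points.  A covariate whose
    quantiles collapse (e.g. constant) raises
    :class:`DegenerateBreaksError`.
    """
    if covariate not in labels.columns:
        raise MissingLabelError(f"label table has no column {covariate!r}")
    vals = pd.to_numeric(labels[covariate], errors="raise").to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise InvalidArgumentError(f"covariate {covariate!r} has missing values")
    if isinstance(breaks, str):
        if breaks != "terciles":
            raise InvalidArgumentError(f"unknown break rule {breaks!r}")
        cuts = np.quantile(vals, [1 / 3, 2 / 3])
    else:
        cuts = np.asarray(list(breaks), dtype=float)
    if len(cuts) < 1 or np.any(np.diff(cuts) <= 0) or (
        cuts[0] <= vals.min() and cuts[-1] >= vals.max()
    ):
        raise DegenerateBreaksError(
            f"break points {cuts} do not split the covariate range "
            f"[{vals.min():g}, {vals.max():g}]"
        )
    bin_names = [f"T{i + 1}" for i in range(len(cuts) + 1)]
    binned = pd.cut(
        vals,
        bins=[-np.inf, *cuts, np.inf],
        labels=bin_names,
        include_lowest=True,
    ).astype(str)
    derived = labels[["frame_index"]].copy()
    derived[f"{covariate}_bin"] = binned
    return annotate_tree(
        tree, derived, f"{covariate}_bin", palette=palette,
        min_display=min_display,
    )


def select_representative(
    tree: ConformationTree,
    node_id: int,
    frame_time: np.ndarray,
) -> Representative:
    """Member frame of latest simulation time (ties: lowest frame index)."""
    node = tree.node(node_id)
    if not node.members:
        raise InvalidArgumentError(f"node {node_id} has no members")
    members = np.fromiter(sorted(node.members), dtype=int)
    times = np.asarray(frame_time, dtype=float)[members]
    best = members[int(np.argmax(times))]  # argmax takes the first maximum
    return Representative(node_id=node_id, frame_index=int(best))


def write_annotations(
    annotations: Mapping[int, NodeAnnotation], path: str | Path
) -> None:
    """Write annotations as TSV: node_id, label_value, count, intensity, hex."""
    rows = []
    for node_id in sorted(annotations):
        ann = annotations[node_id]
        for value in sorted(ann.counts):
            rows.append(
                {
                    "node_id": node_id,
                    "label_value": value,
                    "count": ann.counts[value],
                    "intensity": ann.intensities[value],
                    "hexcolor": ann.color,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
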