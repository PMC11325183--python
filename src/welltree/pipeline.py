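"""End-to-end orchestration: load → superpose → PCA → tree → annotate.

The pipeline is deterministic for a fixed configuration and seed: every
output file (projection, model, node table, Newick, DOT, annotations,
representatives, manifest) is byte-identical across repeated runs.  The
manifest records the package version, the full parameter set, the seed and
SHA-256 checksums of all inputs, so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    annotate_tree,
    select_representative,
    write_annotations,
    rmsd,
)
from .ensemble import load_ensemble, load_labels, superpose_frames
from .errors import ConfigError, WellTreeError
from .export import to_dot, to_newick, write_node_table
from .landscape import WellSpec, sample_gaussian_wells, write_sample_set
from .pca import fit_pca, project, save_projection
from .tree import EpsilonSchedule, build_tree, validate_tree

logger = logging.getLogger("welltree")

__all__ = ["RunConfig", "run_pipeline", "simulate_fixture"]


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips losslessly through JSON."""

    input_coords: str
    eps_init: float
    delta_eps: float
    outdir: str
    input_format: str = "matrix"          # "matrix" | "pdb"
    atom_names: tuple[str, ...] | None = None   # e.g. ("CA",) for carbon-α
    reference_frame: int = 0
    n_components: int = 10
    minpts: int = 4
    max_levels: int = 10_000
    label_file: str | None = None
    label_name: str | None = None
    min_display: int = 5
    seed: int = 0
    superpose: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if payload.get("atom_names") is not None:
            payload["atom_names"] = tuple(payload["atom_names"])
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate(config: RunConfig) -> None:
    if not Path(config.input_coords).exists():
        raise ConfigError(f"input file not found: {config.input_coords}")
    if config.label_name and not config.label_file:
        raise ConfigError("annotation requested (label_name) without label_file")
    if config.label_file and not Path(config.label_file).exists():
        raise ConfigError(f"label file not found: {config.label_file}")
    if config.n_components < 1:
        raise ConfigError("n_components must be >= 1")
    try:
        EpsilonSchedule(
            eps_init=config.eps_init,
            delta_eps=config.delta_eps,
            minpts=config.minpts,
            max_levels=config.max_levels,
        )
    except WellTreeError as exc:
        raise ConfigError(f"invalid epsilon schedule: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full analysis; returns a name → path map of outputs.

    All configuration is validated before any compute.  Stage order:
    load → superpose → fit PCA → project → build tree → validate →
    annotate (if a label is configured) → representatives (+ pairwise
    leaf-representative RMSD).
    """
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest: dict = {
        "welltree_version": __version__,
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {config.input_coords: _sha256(Path(config.input_coords))},
        "stages": {},
    }
    if config.label_file:
        manifest["inputs"][config.label_file] = _sha256(Path(config.label_file))

    ens = load_ensemble(
        config.input_coords,
        format=config.input_format,
        atom_names=config.atom_names,
    )
    logger.info("loaded %d frames x %d atoms", ens.n_frames, ens.n_atoms)
    manifest["stages"]["load"] = {
        "n_frames": ens.n_frames, "n_atoms": ens.n_atoms,
    }

    if config.superpose:
        ens = superpose_frames(ens, reference=config.reference_frame)
        logger.info("superposed onto frame %d", config.reference_frame)
    manifest["stages"]["superpose"] = {
        "applied": config.superpose, "reference": config.reference_frame,
    }

    k = min(config.n_components, ens.n_frames - 1, 3 * ens.n_atoms)
    model = fit_pca(ens, k=k)
    proj = project(model, ens)
    ratio = float(model.eigenvalues.sum() / model.total_variance)
    logger.info("PCA: %d components explain %.3f of variance", k, ratio)
    manifest["stages"]["pca"] = {"k": k, "explained_ratio": ratio}
    model.to_json(outdir / "pca_model.json")
    save_projection(proj, outdir / "projection.tsv")
    outputs["pca_model"] = str(outdir / "pca_model.json")
    outputs["projection"] = str(outdir / "projection.tsv")

    schedule = EpsilonSchedule(
        eps_init=config.eps_init,
        delta_eps=config.delta_eps,
        minpts=config.minpts,
        max_levels=config.max_levels,
    )
    tree = build_tree(proj, schedule)
    report = validate_tree(tree, strict=False)
    logger.info(
        "tree: %d nodes, %d leaves, %d levels, complete=%s",
        report.n_nodes, report.n_leaves, tree.levels_run, tree.complete,
    )
    manifest["stages"]["tree"] = {
        "n_nodes": report.n_nodes,
        "n_leaves": report.n_leaves,
        "levels_run": tree.levels_run,
        "complete": tree.complete,
        "containment_fraction": report.containment_fraction,
    }
    write_node_table(tree, outdir / "tree_nodes.tsv")
    outputs["tree_nodes"] = str(outdir / "tree_nodes.tsv")
    if tree.complete:
        (outdir / "tree.nwk").write_text(to_newick(tree) + "\n")
        outputs["newick"] = str(outdir / "tree.nwk")

    annotations = None
    if config.label_name:
        labels = load_labels(config.label_file)
        annotations = annotate_tree(
            tree, labels, config.label_name, min_display=config.min_display
        )
        write_annotations(annotations, outdir / "annotations.tsv")
        outputs["annotations"] = str(outdir / "annotations.tsv")
        manifest["stages"]["annotate"] = {
            "label": config.label_name, "n_nodes": len(annotations),
        }
    colors = (
        {nid: ann.color for nid, ann in annotations.items()}
        if annotations else None
    )
    (outdir / "tree.dot").write_text(to_dot(tree, fillcolors=colors))
    outputs["dot"] = str(outdir / "tree.dot")

    leaves = sorted(tree.leaves(), key=lambda n: n.id)
    reps = [
        select_representative(tree, leaf.id, ens.frame_time) for leaf in leaves
    ]
    rep_rows = []
    for rep in reps:
        coords = ens.coordinates[rep.frame_index].ravel()
        rep_rows.append(
            {
                "node_id": rep.node_id,
                "frame_index": rep.frame_index,
                "time": ens.frame_time[rep.frame_index],
                **{f"x{i}": c for i, c in enumerate(coords)},
            }
        )
    pd.DataFrame(rep_rows).to_csv(
        outdir / "representatives.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    outputs["representatives"] = str(outdir / "representatives.tsv")
    rmsd_rows = []
    for i, ra in enumerate(reps):
        for rb in reps[i + 1:]:
            rmsd_rows.append(
                {
                    "node_a": ra.node_id,
                    "node_b": rb.node_id,
                    "rmsd_nm": rmsd(
                        ens.coordinates[ra.frame_index],
                        ens.coordinates[rb.frame_index],
                        superpose=True,
                    ),
                }
            )
    pd.DataFrame(
        rmsd_rows, columns=["node_a", "node_b", "rmsd_nm"]
    ).to_csv(outdir / "representative_rmsd.tsv", sep="\t", index=False,
             float_format="%.10g")
    outputs["representative_rmsd"] = str(outdir / "representative_rmsd.tsv")
    manifest["stages"]["representatives"] = {"n": len(reps)}

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = str(manifest_path)
    return outputs


def simulate_fixture(
    spec_path: str | Path,
    n: int,
    seed: int,
    out_prefix: str | Path,
) -> dict[str, str]:
    """Sample a landscape spec to TSV fixture files (coords + labels)."""
    try:
        spec = WellSpec.from_json(spec_path)
    except (OSError, KeyError, json.JSONDecodeError, WellTreeError) as exc:
        raise ConfigError(f"invalid well spec {spec_path}: {exc}") from exc
    samples = sample_gaussian_wells(spec, n, seed)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    coords = Path(f"{prefix}_coords.tsv")
    labels = Path(f"{prefix}_labels.tsv")
    write_sample_set(samples, spec, coords, labels)
    logger.info("wrote %d samples to %s / %s", samples.n, coords, labels)
    return {"coords": str(coords), "labels": str(labels)}
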