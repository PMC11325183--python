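"""Conformational ensembles: loading, concatenation, superposition.

A :class:`ConformationEnsemble` is a stack of frames — ``(n_frames,
n_atoms, 3)`` coordinates in nm — with per-frame time stamps and a source
(simulation) identifier, typically the carbon-α subset of a trajectory.
Two on-disk formats are supported:

* plain coordinate matrices (TSV/CSV, one frame per row, 3N columns,
  optional header, ``#`` comments), the package's round-trip format;
* multi-model PDB (``MODEL``/``ENDMDL`` records, read via Biopython),
  with an optional atom-name filter such as ``{"CA"}``; PDB Å are
  converted to nm on load.

Label tables are plain pandas DataFrames read/written as TSV with mandatory
columns ``frame_index`` (0-based) and ``simulation_id`` plus arbitrary
categorical or numeric label columns.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError, ShapeError
from .geometry import kabsch_superpose

__all__ = [
    "ConformationEnsemble",
    "load_ensemble",
    "save_ensemble",
    "load_labels",
    "save_labels",
    "concatenate",
    "superpose_frames",
]

PDB_TO_NM = 0.1  # PDB coordinates are Å; the package works in nm


@dataclass
class ConformationEnsemble:
    """Frames × atoms × 3 coordinates (nm) with per-frame metadata."""

    coordinates: np.ndarray
    frame_time: np.ndarray
    source_id: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ShapeError("coordinates must have shape (n_frames, n_atoms, 3)")
        n = coords.shape[0]
        t = np.asarray(self.frame_time, dtype=float).ravel()
        s = np.asarray(self.source_id, dtype=object).ravel()
        if t.shape[0] != n or s.shape[0] != n:
            raise ShapeError("frame_time and source_id must have one entry per frame")
        for sid in pd.unique(s):
            ts = t[s == sid]
            if np.any(np.diff(ts) < 0):
                raise InvalidArgumentError(
                    f"frame_time must be non-decreasing within source {sid!r}"
                )
        self.coordinates = coords
        self.frame_time = t
        self.source_id = s

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def flat(self) -> np.ndarray:
        """Frames as a (n_frames, 3N) matrix view."""
        return self.coordinates.reshape(self.n_frames, -1)


def _default_meta(n: int, source: str = "traj") -> tuple[np.ndarray, np.ndarray]:
    return np.arange(n, dtype=float), np.full(n, source, dtype=object)


def _load_matrix(path: Path) -> np.ndarray:
    delimiter = "," if path.suffix.lower() == ".csv" else None
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        return np.empty((0, 0))
    # Optional single header line of column names.
    first_fields = lines[0].replace(",", " ").split()
    try:
        [float(f) for f in first_fields]
    except ValueError:
        lines = lines[1:]
    try:
        mat = np.loadtxt(io.StringIO("\n".join(lines)), delimiter=delimiter,
                         ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed coordinate matrix: {exc}") from exc
    return mat


def _load_pdb(path: Path, atom_names: set[str] | None) -> np.ndarray:
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("ens", str(path))
    frames: list[np.ndarray] = []
    for model in structure:
        xyz = [
            atom.coord
            for chain in model
            for residue in chain
            for atom in residue
            if atom_names is None or atom.get_name() in atom_names
        ]
        if not xyz:
            raise FormatError(f"{path}: a model has no atoms after filtering")
        frames.append(np.asarray(xyz, dtype=float) * PDB_TO_NM)
    if not frames:
        raise FormatError(f"{path}: no models found")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        raise FormatError(
            f"{path}: inconsistent atom counts across models: {sorted(counts)}"
        )
    return np.stack(frames)


def load_ensemble(
    path: str | Path,
    format: str = "matrix",
    atom_names: Iterable[str] | None = None,
    source: str | None = None,
) -> ConformationEnsemble:
    """Load an ensemble from a coordinate matrix or a multi-model PDB.

    Parameters
    ----------
    format:
        ``"matrix"`` (TSV/CSV, one frame per row, 3N columns) or ``"pdb"``
        (multi-model PDB; coordinates converted Å → nm).
    atom_names:
        For PDB input, keep only atoms with these names (e.g. ``{"CA"}``
        for carbon-α).  Ignored for matrix input.
    source:
        Simulation id recorded on every frame (default: the file stem).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "matrix":
        mat = _load_matrix(path)
        if mat.size and mat.shape[1] % 3 != 0:
            raise FormatError(
                f"{path}: column count {mat.shape[1]} is not a multiple of 3"
            )
        coords = mat.reshape(mat.shape[0], -1, 3)
    elif format == "pdb":
        coords = _load_pdb(path, set(atom_names) if atom_names else None)
    else:
        raise InvalidArgumentError(f"unknown format {format!r}")
    t, s = _default_meta(coords.shape[0], source or path.stem)
    return ConformationEnsemble(coordinates=coords, frame_time=t, source_id=s)


def save_ensemble(ensemble: ConformationEnsemble, path: str | Path) -> None:
    """Write the ensemble as a TSV coordinate matrix (one frame per row)."""
    np.savetxt(path, ensemble.flat(), delimiter="\t", fmt="%.10g")


def load_labels(path: str | Path) -> pd.DataFrame:
    """Read a TSV label table; requires frame_index and simulation_id columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("frame_index", "simulation_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: label table lacks column {col!r}")
    return df


def save_labels(labels: pd.DataFrame, path: str | Path) -> None:
    """Write a label table as TSV, declaring categorical vocabularies."""
    with open(path, "w") as fh:
        fh.write("# frame_index is 0-based\n")
        for col in labels.columns:
            if col in ("frame_index",):
                continue
            if labels[col].dtype == object:
                vocab = ",".join(sorted(map(str, labels[col].unique())))
                fh.write(f"# vocabulary {col}: {vocab}\n")
        labels.to_csv(fh, sep="\t", index=False)


def concatenate(
    ensembles: Sequence[ConformationEnsemble],
    ids: Sequence[str],
) -> tuple[ConformationEnsemble, pd.DataFrame]:
    """Concatenate trajectories, tagging frames for later demultiplexing.

    Frames keep their input order; the returned label table has one row per
    frame (columns ``frame_index``, ``simulation_id``) so that projections
    and trees built on the joint ensemble can be split by simulation again.
    """
    if not ensembles:
        raise InvalidArgumentError("need at least one ensemble")
    if len(ids) != len(ensembles) or len(set(ids)) != len(ids):
        raise InvalidArgumentError("ids must be unique, one per ensemble")
    counts = {e.n_atoms for e in ensembles}
    if len(counts) > 1:
        raise ShapeError(f"atom-count mismatch across ensembles: {sorted(counts)}")
    coords = np.concatenate([e.coordinates for e in ensembles], axis=0)
    times = np.concatenate([e.frame_time for e in ensembles])
    sources = np.concatenate(
        [np.full(e.n_frames, i, dtype=object) for e, i in zip(ensembles, ids)]
    )
    joint = ConformationEnsemble(coords, times, sources)
    table = pd.DataFrame(
        {"frame_index": np.arange(joint.n_frames), "simulation_id": sources}
    )
    return joint, table


def superpose_frames(
    ensemble: ConformationEnsemble, reference: int = 0
) -> ConformationEnsemble:
    """Rigid-body align every frame onto a reference frame (Kabsch).

    Each frame is translated and rotated to minimise its RMSD to the
    reference; the reference frame itself is unchanged up to numerical
    noise.  Returns a new ensemble.
    """
    n = ensemble.n_frames
    if not -n <= reference < n:
        raise InvalidArgumentError(f"reference frame {reference} out of range")
    ref = ensemble.coordinates[reference]
    out = np.empty_like(ensemble.coordinates)
    for i in range(n):
        out[i] = kabsch_superpose(ensemble.coordinates[i], ref)
    return ConformationEnsemble(
        coordinates=out,
        frame_time=ensemble.frame_time.copy(),
        source_id=ensemble.source_id.copy(),
    )
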