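"""Trajectory PCA (essential dynamics) and subspace projection.

The positional covariance over frames of a superposed ensemble is
eigendecomposed; the top-k eigenvectors span the essential subspace into
which frames (of this or any other ensemble with the same atom count) are
projected.  Conventions:

* covariance uses 1/n normalisation (frames are the full sample), so the
  per-component variance of the fitting ensemble's projection equals the
  eigenvalue exactly;
* each component's largest-magnitude entry is made positive, fixing the
  sign ambiguity deterministically;
* no mass weighting (uniform atoms, as for carbon-α-only selections);
* k defaults to 10 components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ConformationEnsemble
from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    ShapeError,
)

__all__ = [
    "PCAModel",
    "ProjectedEnsemble",
    "fit_pca",
    "project",
    "explained_ratio",
    "save_projection",
    "load_projection",
]

DEFAULT_COMPONENTS = 10


@dataclass(frozen=True)
class PCAModel:
    """Mean, top-k orthonormal components and spectrum of a trajectory PCA.

    ``eigenvalues`` are the retained k variances (nm², descending);
    ``total_variance`` is the trace of the full covariance, so
    ``eigenvalues.sum() / total_variance`` is the explained ratio.
    """

    mean: np.ndarray          # (3N,)
    components: np.ndarray    # (k, 3N), row-orthonormal
    eigenvalues: np.ndarray   # (k,), descending, >= 0
    total_variance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(
            self, "components", np.asarray(self.components, dtype=float)
        )
        object.__setattr__(
            self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float)
        )
        if self.components.ndim != 2 or self.components.shape[1] != self.mean.shape[0]:
            raise ShapeError("components must be (k, 3N) matching the mean")
        if self.eigenvalues.shape[0] != self.components.shape[0]:
            raise ShapeError("one eigenvalue per component required")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise InvalidArgumentError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-10):
            raise InvalidArgumentError("eigenvalues must be non-negative")

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "total_variance": self.total_variance,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        p = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(p["mean"]),
            components=np.asarray(p["components"]),
            eigenvalues=np.asarray(p["eigenvalues"]),
            total_variance=float(p["total_variance"]),
        )


@dataclass(frozen=True)
class ProjectedEnsemble:
    """Frames as points in the k-dimensional PC subspace (nm)."""

    points: np.ndarray       # (n_frames, k)
    frame_time: np.ndarray
    source_id: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise ShapeError("points must be a 2-D array")
        if len(self.frame_time) != pts.shape[0] or len(self.source_id) != pts.shape[0]:
            raise ShapeError("metadata length must match the frame count")
        object.__setattr__(self, "points", pts)
        object.__setattr__(
            self, "frame_time", np.asarray(self.frame_time, dtype=float)
        )
        object.__setattr__(
            self, "source_id", np.asarray(self.source_id, dtype=object)
        )

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def k(self) -> int:
        return self.points.shape[1]


def fit_pca(ensemble: ConformationEnsemble, k: int = DEFAULT_COMPONENTS) -> PCAModel:
    """Eigendecompose the coordinate covariance of a superposed ensemble.

    ``k`` must satisfy ``1 <= k <= min(n_frames - 1, 3 * n_atoms)``.
    Deterministic: the component sign is fixed by making each component's
    largest-magnitude entry positive.
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("PCA needs at least 2 frames")
    x = ensemble.flat()
    n, p = x.shape
    if not 1 <= k <= min(n - 1, p):
        raise InvalidArgumentError(
            f"k={k} out of range [1, {min(n - 1, p)}]"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / n
    total = float(eigenvalues.sum())
    comps = vt[:k]
    # deterministic sign: largest-|entry| coordinate of each component > 0
    idx = np.argmax(np.abs(comps), axis=1)
    signs = np.sign(comps[np.arange(k), idx])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    return PCAModel(
        mean=mean,
        components=comps,
        eigenvalues=eigenvalues[:k],
        total_variance=total,
    )


def project(model: PCAModel, ensemble: ConformationEnsemble) -> ProjectedEnsemble:
    """Project an ensemble into the model's PC subspace.

    The ensemble need not be the fitting one — e.g. a wild-type-only
    trajectory can be projected into a subspace fitted on the concatenated
    mutant + wild-type ensemble — but atom counts must match.
    """
    x = ensemble.flat()
    if x.shape[1] != model.mean.shape[0]:
        raise ShapeError(
            f"ensemble dimensionality {x.shape[1]} != model {model.mean.shape[0]}"
        )
    pts = (x - model.mean) @ model.components.T
    return ProjectedEnsemble(
        points=pts,
        frame_time=ensemble.frame_time.copy(),
        source_id=ensemble.source_id.copy(),
    )


def explained_ratio(model: PCAModel, k: int) -> float:
    """Fraction of total variance captured by the top-k components."""
    if not 1 <= k <= model.k:
        raise InvalidArgumentError(
            f"k={k} exceeds the recorded spectrum of length {model.k}"
        )
    if model.total_variance <= 0:
        raise InvalidArgumentError("total variance is zero (constant ensemble)")
    return float(model.eigenvalues[:k].sum() / model.total_variance)


def save_projection(proj: ProjectedEnsemble, path: str | Path) -> None:
    """Write a projection as TSV: frame_index, source_id, time, pc1..pck."""
    df = pd.DataFrame(
        proj.points, columns=[f"pc{i + 1}" for i in range(proj.k)]
    )
    df.insert(0, "time", proj.frame_time)
    df.insert(0, "source_id", proj.source_id)
    df.insert(0, "frame_index", np.arange(proj.n_frames))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_projection(path: str | Path) -> ProjectedEnsemble:
    df = pd.read_csv(path, sep="\t", comment="#")
    pc_cols = [c for c in df.columns if c.startswith("pc")]
    if not pc_cols:
        raise InvalidArgumentError(f"{path}: no pc columns found")
    return ProjectedEnsemble(
        points=df[pc_cols].to_numpy(dtype=float),
        frame_time=df["time"].to_numpy(dtype=float)
        if "time" in df else np.arange(len(df), dtype=float),
        source_id=df["simulation_id"].to_numpy()
        if "simulation_id" in df
        else df.get("source_id", pd.Series(["traj"] * len(df))).to_numpy(),
    )
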