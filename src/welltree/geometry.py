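"""Rigid-body superposition (Kabsch) and RMSD between coordinate sets.

All coordinates are ``(n_atoms, 3)`` arrays in nm.  The optimal rotation is
obtained from :func:`scipy.spatial.transform.Rotation.align_vectors`, which
implements the Kabsch least-squares solution restricted to proper rotations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateSuperpositionError, ShapeError

__all__ = ["kabsch_superpose", "rmsd"]


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise ShapeError("coordinates must be (n_atoms, 3) arrays")
    if a.shape[0] != b.shape[0]:
        raise ShapeError(
            f"atom-count mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] < 1:
        raise ShapeError("need at least one atom")
    return a, b


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid-body transform `mobile` onto `target`, least-squares optimal.

    Returns the transformed copy of ``mobile``; neither input is modified.
    Raises :class:`DegenerateSuperpositionError` when the target has fewer
    than 3 non-collinear atoms (rotation under-determined).
    """
    mobile, target = _check_pair(mobile, target)
    tc = target.mean(axis=0)
    mc = mobile.mean(axis=0)
    t0 = target - tc
    if target.shape[0] < 3 or np.linalg.matrix_rank(t0, tol=1e-10) < 2:
        raise DegenerateSuperpositionError(
            "superposition requires >= 3 non-collinear atoms"
        )
    rot, _ = Rotation.align_vectors(t0, mobile - mc)
    return rot.apply(mobile - mc) + tc


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, superpose: bool = True) -> float:
    """Root mean square deviation between matched atoms, in nm.

    With ``superpose=True`` (default) the optimal rigid-body alignment is
    removed first, so pure rotations/translations give RMSD 0.
    """
    a, b = _check_pair(coords_a, coords_b)
    if superpose:
        # The minimised RMSD is well defined even when the rotation is not
        # unique (collinear or < 3 atoms), so no degeneracy check here.
        bc = b.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rot, _ = Rotation.align_vectors(b - bc, a - a.mean(axis=0))
        a = rot.apply(a - a.mean(axis=0)) + bc
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
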