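"""Shared fixtures: small synthetic ensembles, trees and a PDB writer."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import welltree as wt


def format_pdb(models: list[np.ndarray], atom_names: list[str]) -> str:
    """Render frames (Å coordinates) as minimal multi-model PDB text."""
    lines = []
    for m, coords in enumerate(models, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (name, (x, y, z)) in enumerate(zip(atom_names, coords), start=1):
            field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {i:5d} {field} ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{name[0]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def two_well_spec() -> wt.WellSpec:
    return wt.WellSpec(
        centers=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
        widths=np.array([1.0, 1.0]),
        weights=np.array([0.5, 0.5]),
        labels=("left", "right"),
    )


@pytest.fixture(scope="session")
def two_well_samples(two_well_spec) -> wt.SampleSet:
    return wt.sample_gaussian_wells(two_well_spec, 500, seed=11)


@pytest.fixture(scope="session")
def fixture_schedule() -> wt.EpsilonSchedule:
    # eps_init = 2x well width keeps each well one initial cluster;
    # delta = width/4 resolves merge order on the fixtures.
    return wt.EpsilonSchedule(eps_init=2.0, delta_eps=0.25, minpts=4)


@pytest.fixture(scope="session")
def two_well_tree(two_well_samples, fixture_schedule) -> wt.ConformationTree:
    return wt.build_tree(two_well_samples.points, fixture_schedule)


@pytest.fixture(scope="session")
def two_well_labels(two_well_spec, two_well_samples) -> pd.DataFrame:
    rng = np.random.default_rng(5)
    n = two_well_samples.n
    return pd.DataFrame(
        {
            "frame_index": np.arange(n),
            "simulation_id": "synthetic",
            "well_label": [
                two_well_spec.labels[w]
                for w in two_well_samples.well_assignment
            ],
            "biomarker": rng.uniform(0.0, 1.0, size=n),
        }
    )


@pytest.fixture
def random_ensemble() -> wt.ConformationEnsemble:
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(12, 10, 3))
    return wt.ConformationEnsemble(
        coordinates=coords,
        frame_time=np.arange(12, dtype=float),
        source_id=np.full(12, "sim", dtype=object),
    )
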