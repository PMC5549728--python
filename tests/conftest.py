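"""Shared fixtures: tiny hand-built structures and fast toy configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from habind.model_io import InMemoryTrajectory, StructureModel


def make_model(coords, resids=None, resnames=None, chains=None, names=None,
               elements=None, roles=None, box=None) -> StructureModel:
    """Build a StructureModel from plain arrays with sensible defaults."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    resids = list(resids) if resids is not None else list(range(1, n + 1))
    resnames = list(resnames) if resnames is not None else ["ALA"] * n
    chains = list(chains) if chains is not None else ["A"] * n
    names = list(names) if names is not None else ["CA"] * n
    elements = list(elements) if elements is not None else ["C"] * n
    atoms = pd.DataFrame({"name": names, "element": elements, "resid": resids,
                          "resname": resnames, "chain": chains})
    return StructureModel(atoms=atoms, coords=coords, box=box,
                          roles=roles or {"A": "protein"})


def make_traj(model: StructureModel, frames, times=None, box=None
              ) -> InMemoryTrajectory:
    frames = np.asarray(frames, dtype=float)
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return InMemoryTrajectory(model, frames, times, box=box)


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 3-atom PDB with known Angstrom coordinates."""
    lines = [
        "ATOM      1  N   ALA A   1      10.000  20.000  30.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1      11.500  20.000  30.000  1.00  0.00           C",
        "ATOM      3  O   HOH B   2       0.000   5.000  -3.000  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def fast_toy():
    """Small, quick toy-system config (32-bead chain)."""
    from habind.synthetic import ToySystemConfig

    return ToySystemConfig(n_mono=32)
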