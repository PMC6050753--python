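"""Shared fixtures: programmatically built models, tables and toy specs."""

from __future__ import annotations

import numpy as np
import pytest
import biotite.structure as struc

from fabscatter.models import AtomicModel
from fabscatter.formfactor import FormFactorTable, build_form_factor_table


def make_point_model(
    coords,
    elements=None,
    res_names=None,
    atom_names=None,
    chain_ids=None,
    res_ids=None,
    label="test",
) -> AtomicModel:
    """Build a model from raw arrays; one residue per atom unless res_ids given."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.asarray(chain_ids if chain_ids is not None else ["A"] * n)
    arr.res_id = np.asarray(res_ids if res_ids is not None else np.arange(1, n + 1))
    arr.res_name = np.asarray(res_names if res_names is not None else ["GLY"] * n)
    arr.atom_name = np.asarray(atom_names if atom_names is not None else ["CA"] * n)
    arr.element = np.asarray(elements if elements is not None else ["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("atom_id", np.arange(1, n + 1))
    return AtomicModel(arr, label=label, coords=coords)


class UnitFormFactorTable(FormFactorTable):
    """A table with f identically 1 for every species: isolates the Debye
    geometry from the form-factor physics in closed-form checks."""

    def _direct(self, species, q):
        q = np.asarray(q, dtype=float)
        out = np.ones(q.shape)
        return float(out) if out.ndim == 0 else out


def unit_table(level="atomic", species=("C",)) -> UnitFormFactorTable:
    grid = np.linspace(0.0, 1.0, 11)
    return UnitFormFactorTable(
        level=level,
        species=list(species),
        q_grid=grid,
        values=np.ones((len(species), grid.size)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_protein_model(rng):
    """50 atoms with realistic element mix in a ~25 A blob."""
    elements = rng.choice(["C", "N", "O", "S"], size=50, p=[0.6, 0.15, 0.2, 0.05])
    coords = rng.normal(scale=8.0, size=(50, 3))
    return make_point_model(coords, elements=elements, atom_names=["X"] * 50)


@pytest.fixture
def atomic_table(random_protein_model):
    return build_form_factor_table(random_protein_model, level="atomic")
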