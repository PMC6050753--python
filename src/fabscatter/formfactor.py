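"""Atomic and residue-level X-ray form factors f(q) for the Debye sum.

Vacuum atomic form factors use the Cromer-Mann 4-Gaussian parameterization
(coefficients shipped as package data, ``data/elements.tsv``):

    f(q) = sum_k a_k exp(-b_k s^2) + c,   s = q / 4pi

At q = 0 this reduces to the element's electron count.  The optional
excluded-solvent correction subtracts the scattering of the bulk solvent
displaced by the atom,

    f_corr(q) = f(q) - rho_s V exp(-q^2 V^(2/3) / 4pi),

with bulk electron density rho_s = 0.334 e/A^3 and tabulated per-element
displaced volumes V.  No hydration-shell term is modeled.

Residue-level form factors are composition sums over the residue's atoms
(in-chain composition: one water removed per peptide bond, hydrogens
included), the coarse level used for residue-pair intensity decompositions
where inter-residue distances are taken between C-alpha positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np

from .models import AtomicModel

__all__ = [
    "FormFactorTable",
    "atomic_form_factor",
    "residue_form_factor",
    "build_form_factor_table",
    "known_elements",
    "known_residues",
    "SOLVENT_DENSITY",
]

SOLVENT_DENSITY = 0.334  # bulk water electron density, e/A^3


def _load_elements() -> dict[str, dict]:
    table: dict[str, dict] = {}
    text = resources.files("fabscatter.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        sym = parts[0].upper()
        nums = [float(x) for x in parts[1:]]
        table[sym] = {
            "z": int(nums[0]),
            "a": np.array(nums[1:5]),
            "b": np.array(nums[5:9]),
            "c": nums[9],
            "v": nums[10],
        }
    return table


def _load_residues() -> dict[str, dict[str, int]]:
    table: dict[str, dict[str, int]] = {}
    text = resources.files("fabscatter.data").joinpath("residues.tsv").read_text()
    elements = None
    for line in text.splitlines():
        if line.startswith("# residue"):
            elements = line.lstrip("# ").split()[1:]
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        counts = {el: int(n) for el, n in zip(elements, parts[1:]) if int(n) > 0}
        table[parts[0].upper()] = counts
    return table


_ELEMENTS = _load_elements()
_RESIDUES = _load_residues()


def known_elements() -> list[str]:
    return sorted(_ELEMENTS)


def known_residues() -> list[str]:
    return sorted(_RESIDUES)


def atomic_form_factor(
    element: str, q: float | np.ndarray, corrected: bool = False
) -> float | np.ndarray:
    """Vacuum (or excluded-volume-corrected) atomic form factor, electrons."""
    key = element.upper().strip()
    if key not in _ELEMENTS:
        raise KeyError(
            f"unknown element {element!r}; known species: {', '.join(known_elements())}"
        )
    rec = _ELEMENTS[key]
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    s2 = (q / (4.0 * np.pi)) ** 2
    f = np.sum(rec["a"][:, None] * np.exp(-rec["b"][:, None] * s2.ravel()), axis=0)
    f = f.reshape(q.shape) + rec["c"]
    if corrected:
        v = rec["v"]
        f = f - SOLVENT_DENSITY * v * np.exp(-(q**2) * v ** (2.0 / 3.0) / (4.0 * np.pi))
    return float(f) if f.ndim == 0 else f


def residue_form_factor(
    residue_name: str,
    q: float | np.ndarray,
    corrected: bool = False,
) -> float | np.ndarray:
    """Residue form factor: sum of atomic form factors over the in-chain
    composition of a standard amino acid (hydrogens included)."""
    key = residue_name.upper().strip()
    if key not in _RESIDUES:
        raise KeyError(
            f"unknown residue {residue_name!r}; known species: {', '.join(known_residues())}"
        )
    q = np.asarray(q, dtype=float)
    total = np.zeros(q.shape)
    for el, n in _RESIDUES[key].items():
        total = total + n * np.atleast_1d(atomic_form_factor(el, q, corrected)).reshape(q.shape)
    return float(total) if total.ndim == 0 else total


def residue_electron_count(residue_name: str) -> int:
    """Total electron count of a residue's in-chain composition."""
    key = residue_name.upper().strip()
    if key not in _RESIDUES:
        raise KeyError(f"unknown residue {residue_name!r}")
    return sum(_ELEMENTS[el]["z"] * n for el, n in _RESIDUES[key].items())


@dataclass
class FormFactorTable:
    """Form factors for a fixed species set on a fixed q-grid.

    ``values[i, j]`` is the form factor of ``species[i]`` at ``q_grid[j]``
    in electrons.  ``lookup`` evaluates at arbitrary q, either by direct
    re-evaluation (default, exact) or by linear interpolation on the grid
    (``mode="grid"``), the precomputed-table style of coarse residue-level
    pipelines.
    """

    level: Literal["atomic", "residue"]
    species: list[str]
    q_grid: np.ndarray
    values: np.ndarray
    solvent_corrected: bool = False
    parameterization: str = "Cromer-Mann 4-Gaussian (Intl. Tables C, 6.1.1.4)"

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), self.q_grid.size):
            raise ValueError("values must be (n_species, n_q)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite form-factor values")

    def _direct(self, species: str, q):
        if self.level == "atomic":
            return atomic_form_factor(species, q, self.solvent_corrected)
        return residue_form_factor(species, q, self.solvent_corrected)

    def lookup(
        self, species: str, q: float | np.ndarray, mode: Literal["direct", "grid"] = "direct"
    ) -> float | np.ndarray:
        key = species.upper().strip()
        if key not in self.species:
            raise KeyError(f"species {species!r} not in table ({', '.join(self.species)})")
        if mode == "direct":
            return self._direct(key, q)
        row = self.values[self.species.index(key)]
        return np.interp(np.asarray(q, dtype=float), self.q_grid, row)

    def site_factors(self, model: AtomicModel, q: float | np.ndarray) -> np.ndarray:
        """Per-site form factors for ``model`` at q: one row per atom
        (atomic level) or per residue (residue level)."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if self.level == "atomic":
            keys = [e.upper() for e in model.elements]
        else:
            ridx = model.residue_index
            starts = np.flatnonzero(np.r_[True, np.diff(ridx) != 0])
            keys = [model.residue_names[s].upper() for s in starts]
        out = np.empty((len(keys), q.size))
        cache: dict[str, np.ndarray] = {}
        for i, k in enumerate(keys):
            if k not in cache:
                cache[k] = np.atleast_1d(self._direct(k, q))
            out[i] = cache[k]
        return out


def build_form_factor_table(
    model: AtomicModel,
    level: Literal["atomic", "residue"] = "residue",
    q_grid: np.ndarray | None = None,
    corrected: bool = False,
) -> FormFactorTable:
    """Build a table covering exactly the species present in ``model``."""
    if q_grid is None:
        q_grid = np.arange(0.0, 0.5001, 0.01)
    q_grid = np.asarray(q_grid, dtype=float)
    if level == "atomic":
        species = sorted({e.upper() for e in model.elements})
        missing = [s for s in species if s not in _ELEMENTS]
        if missing:
            raise KeyError(f"unresolvable element(s) in model: {', '.join(missing)}")
        values = np.vstack([atomic_form_factor(s, q_grid, corrected) for s in species])
    elif level == "residue":
        species = sorted({r.upper() for r in model.residue_names})
        missing = [s for s in species if s not in _RESIDUES]
        if missing:
            raise KeyError(f"unresolvable residue(s) in model: {', '.join(missing)}")
        values = np.vstack([residue_form_factor(s, q_grid, corrected) for s in species])
    else:
        raise ValueError(f"unknown level {level!r}")
    return FormFactorTable(
        level=level,
        species=species,
        q_grid=q_grid,
        values=values,
        solvent_corrected=corrected,
    )
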