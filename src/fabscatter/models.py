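"""Core in-memory containers: atomic models, ensembles, and scattering curves.

Atomic structures are stored as :class:`biotite.structure.AtomArray` objects
wrapped in a thin :class:`AtomicModel`, which adds a deterministic 0-based
residue enumeration (file order, chain gaps do not renumber) and convenience
selectors.  Ensembles share a single topology with an ``(F, N, 3)`` coordinate
block, mirroring how MD frames relate to their reference structure.

Units are fixed package-wide: coordinates in Angstrom, momentum transfer q in
inverse Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

__all__ = ["Atom", "AtomicModel", "Ensemble", "SAXSCurve"]


@dataclass(frozen=True)
class Atom:
    """A single atom record (a convenience view, not the storage format)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class AtomicModel:
    """One conformation: an ordered collection of atoms with coordinates in A.

    Parameters
    ----------
    array : biotite.structure.AtomArray
        Backing storage; annotation categories ``chain_id``, ``res_id``,
        ``ins_code``, ``res_name``, ``atom_name``, ``element`` are used.
    label : str
        Free-form identifier (frame index, PDB id, ...).
    """

    def __init__(self, array: struc.AtomArray, label: str = "", coords: np.ndarray | None = None):
        if array.array_length() < 1:
            raise ValueError("AtomicModel requires at least one atom")
        # biotite stores coordinates as float32; geometry and scattering are
        # computed in float64, so a double-precision copy is authoritative
        if coords is None:
            coords = np.asarray(array.coord, dtype=np.float64)
        else:
            coords = np.asarray(coords, dtype=np.float64)
            if coords.shape != (array.array_length(), 3):
                raise ValueError("coords shape does not match atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in model")
        self.array = array
        self._coords = coords
        self.label = label
        self._residue_index: np.ndarray | None = None

    # -- basic views -------------------------------------------------------
    def __len__(self) -> int:
        return self.array.array_length()

    @property
    def n_atoms(self) -> int:
        return self.array.array_length()

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float64 coordinates in Angstrom."""
        return self._coords

    @property
    def elements(self) -> np.ndarray:
        return self.array.element

    @property
    def residue_names(self) -> np.ndarray:
        return self.array.res_name

    @property
    def chain_ids(self) -> np.ndarray:
        return self.array.chain_id

    @property
    def residue_seqs(self) -> np.ndarray:
        return self.array.res_id

    @property
    def residue_index(self) -> np.ndarray:
        """Per-atom 0-based residue enumeration in file order.

        A new residue starts whenever ``(chain_id, res_id, ins_code)``
        changes between consecutive atoms; numbering gaps within a chain do
        not introduce extra indices.
        """
        if self._residue_index is None:
            arr = self.array
            ins = (
                arr.ins_code
                if "ins_code" in arr.get_annotation_categories()
                else np.full(len(self), "", dtype="U1")
            )
            keys = list(zip(arr.chain_id, arr.res_id, ins))
            idx = np.zeros(len(self), dtype=int)
            for i in range(1, len(self)):
                idx[i] = idx[i - 1] + (keys[i] != keys[i - 1])
            self._residue_index = idx
        return self._residue_index

    @property
    def n_residues(self) -> int:
        return int(self.residue_index[-1]) + 1

    def atoms(self) -> list[Atom]:
        """Materialize per-atom records (slow path, for inspection only)."""
        arr = self.array
        cats = arr.get_annotation_categories()
        serial = arr.atom_id if "atom_id" in cats else np.arange(1, len(self) + 1)
        occ = arr.occupancy if "occupancy" in cats else np.ones(len(self))
        alt = arr.altloc_id if "altloc_id" in cats else np.full(len(self), "")
        ins = arr.ins_code if "ins_code" in cats else np.full(len(self), "")
        return [
            Atom(
                serial=int(serial[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_name=str(arr.res_name[i]),
                residue_seq=int(arr.res_id[i]),
                insertion_code=str(ins[i]),
                chain_id=str(arr.chain_id[i]),
                position=self._coords[i],
                occupancy=float(occ[i]),
                altloc=str(alt[i]),
            )
            for i in range(len(self))
        ]

    # -- selections --------------------------------------------------------
    def ca_mask(self) -> np.ndarray:
        return (self.array.atom_name == "CA") & (self.array.element != "CA")

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "AtomicModel":
        """Copy of this model with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"coordinate block {coords.shape} does not match {self.n_atoms} atoms"
            )
        arr = self.array.copy()
        arr.coord = coords.astype(np.float32)
        return AtomicModel(arr, label=self.label if label is None else label, coords=coords)

    def __getitem__(self, mask) -> "AtomicModel":
        return AtomicModel(self.array[mask], label=self.label, coords=self._coords[mask])


@dataclass
class Ensemble:
    """An ordered stack of conformations sharing one topology (MD frames)."""

    topology: AtomicModel
    coordinates: np.ndarray  # (F, N, 3), Angstrom
    frame_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (F, N, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coordinates.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not self.frame_labels:
            self.frame_labels = [str(i) for i in range(self.n_frames)]
        if len(self.frame_labels) != self.n_frames:
            raise ValueError("frame_labels length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> AtomicModel:
        """Extract frame ``i`` as a standalone model."""
        return self.topology.with_coords(self.coordinates[i], label=self.frame_labels[i])

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


@dataclass
class SAXSCurve:
    """A scattering curve I(q) on a strictly ascending q-grid (1/A).

    ``sigma`` is present for experimental curves (per-point uncertainties,
    all positive) and ``None`` for theoretical ones.  Intensities may be any
    finite real: buffer-subtracted experimental data can dip below zero.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if np.any(self.q < 0):
            raise ValueError("q values must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("non-finite values in curve")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q length")
            if np.any(self.sigma <= 0):
                bad = int(np.argmax(self.sigma <= 0))
                raise ValueError(f"sigma must be positive (row {bad}: {self.sigma[bad]})")

    def __len__(self) -> int:
        return self.q.size

    def truncated(self, q_max: float) -> "SAXSCurve":
        """Restrict the curve to q <= q_max."""
        m = self.q <= q_max
        return SAXSCurve(
            self.q[m],
            self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            label=self.label,
        )
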