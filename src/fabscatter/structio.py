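"""File I/O: PDB structures, experimental SAXS curves, and fit output.

PDB parsing/writing is delegated to :mod:`biotite.structure.io.pdb`
(wwPDB v3.3 fixed columns); DCD trajectories with a PDB topology are read
through :mod:`biotite.structure.io.dcd` when available.  SAXS curves are
plain whitespace-delimited 2- or 3-column text with ``#`` comments.

All coordinates are Angstrom and all q values 1/A; curves recorded in 1/nm
must be converted upstream (factor 0.1; the CLI exposes ``--q-units``).
"""

from __future__ import annotations

import os
from typing import Literal

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .models import AtomicModel, Ensemble, SAXSCurve

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_dcd_ensemble",
    "read_saxs_curve",
    "write_saxs_curve",
    "write_fit",
    "read_fit",
]


def _altloc_mask(array: struc.AtomArray) -> np.ndarray:
    # Keep the highest-occupancy conformer per (chain, res, name); ties break
    # on altloc letter order so the result is deterministic.
    keep = np.ones(array.array_length(), dtype=bool)
    cats = array.get_annotation_categories()
    if "altloc_id" not in cats:
        return keep
    alt = array.altloc_id
    occ = array.occupancy if "occupancy" in cats else np.ones(len(alt))
    ins = array.ins_code if "ins_code" in cats else np.full(len(alt), "")
    groups: dict[tuple, list[int]] = {}
    for i in range(array.array_length()):
        if alt[i] in (".", "", " "):
            continue
        key = (array.chain_id[i], int(array.res_id[i]), str(ins[i]), array.atom_name[i])
        groups.setdefault(key, []).append(i)
    for idxs in groups.values():
        if len(idxs) == 1:
            continue
        best = min(idxs, key=lambda i: (-occ[i], alt[i]))
        for i in idxs:
            if i != best:
                keep[i] = False
    return keep


def read_pdb(
    path: str | os.PathLike,
    model_policy: Literal["first", "all"] = "first",
) -> AtomicModel | Ensemble:
    """Read a PDB file into a model (``first``) or an ensemble (``all``).

    MODEL/ENDMDL blocks become ensemble frames under ``model_policy="all"``.
    Alternate locations are reduced to a single conformer (highest occupancy,
    ties by altloc letter).  Hydrogens, waters and het groups are retained;
    exclude them downstream if desired.
    """
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # biotite reports the offending line
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no coordinate records found")
    label = os.path.splitext(os.path.basename(str(path)))[0]
    if model_policy == "first":
        array = pdb.get_structure(model=1, extra_fields=["occupancy", "atom_id"], altloc="all")
        array = array[_altloc_mask(array)]
        if array.array_length() == 0:
            raise ValueError(f"{path}: zero atoms after parsing")
        return AtomicModel(array, label=label)
    if model_policy == "all":
        stack = pdb.get_structure(extra_fields=["occupancy", "atom_id"], altloc="all")
        keep = _altloc_mask(stack[0])  # altloc reduction is topology-wide
        topology = AtomicModel(stack[0][keep], label=label)
        labels = [f"{label}:{i + 1}" for i in range(n_models)]
        return Ensemble(
            topology=topology,
            coordinates=stack.coord[:, keep, :],
            frame_labels=labels,
        )
    raise ValueError(f"unknown model_policy {model_policy!r}")


def write_pdb(path: str | os.PathLike, obj: AtomicModel | Ensemble) -> None:
    """Write a model (single) or ensemble (multi-model) PDB file."""
    pdb = PDBFile()
    if isinstance(obj, AtomicModel):
        pdb.set_structure(obj.array)
    else:
        stack = struc.from_template(obj.topology.array, obj.coordinates)
        pdb.set_structure(stack)
    pdb.write(str(path))


def read_dcd_ensemble(topology_path: str | os.PathLike, dcd_path: str | os.PathLike) -> Ensemble:
    """Read a binary DCD trajectory against a PDB topology."""
    from biotite.structure.io.dcd import DCDFile

    top = read_pdb(topology_path, model_policy="first")
    dcd = DCDFile.read(str(dcd_path))
    coords = dcd.get_coord()
    if coords.shape[1] != top.n_atoms:
        raise ValueError(
            f"trajectory has {coords.shape[1]} atoms, topology {top.n_atoms}"
        )
    labels = [f"{top.label}:{i}" for i in range(coords.shape[0])]
    return Ensemble(topology=top, coordinates=np.asarray(coords, float), frame_labels=labels)


def read_saxs_curve(path: str | os.PathLike, q_scale: float = 1.0) -> SAXSCurve:
    """Read a 2- or 3-column (q, I[, sigma]) whitespace-delimited text file.

    Comment lines (``#``) and non-numeric header lines are tolerated.  Rows
    are sorted into ascending q; duplicate or non-positive-sigma rows raise.
    ``q_scale`` rescales the q column (0.1 converts 1/nm data to 1/A).
    """
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue  # header line
            if len(vals) < 2:
                continue
            vals = vals[:3]
            if ncols is None:
                ncols = len(vals)
            if len(vals) != ncols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            if vals[0] < 0 or not np.isfinite(vals[0]):
                continue  # q outside [0, inf) rejected
            if ncols == 3 and vals[2] <= 0:
                raise ValueError(f"{path}:{lineno}: sigma must be positive, got {vals[2]}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    data = np.array(rows, dtype=float)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) <= 0):
        dup = int(np.argmax(np.diff(data[:, 0]) <= 0))
        raise ValueError(f"{path}: duplicate q value near q={data[dup, 0]}")
    sigma = data[:, 2] if data.shape[1] == 3 else None
    label = os.path.splitext(os.path.basename(str(path)))[0]
    return SAXSCurve(data[:, 0] * q_scale, data[:, 1], sigma, label=label)


def write_saxs_curve(path: str | os.PathLike, curve: SAXSCurve) -> None:
    """Write a curve as 2- or 3-column text."""
    cols = [curve.q, curve.intensity]
    header = "q(1/A) I(q)"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += " sigma"
    np.savetxt(str(path), np.column_stack(cols), fmt="%.6e", header=header)


def write_fit(result, path: str | os.PathLike) -> None:
    """Write a fit as 4-column text: q, I_exp, sigma, scaled model.

    The model column is the fitted curve ``c * I_mod + delta`` so the file
    re-plots directly against the experimental columns; the header records
    chi^2, c, delta and the residual convention (log10 I_exp - log10 I_fit).
    """
    if result.n_points == 0:
        raise ValueError("cannot write an empty fit")
    header = (
        f"fit of {result.theory_label} to {result.experiment_label}\n"
        f"chi2={result.chi2:.6g} scale={result.scale:.6g} "
        f"constant={result.constant:.6g} n={result.n_points} "
        f"q_max={result.q_max_used:.6g} category={result.category}\n"
        "q(1/A) I_exp sigma I_fit(=c*I_mod+delta)"
    )
    data = np.column_stack([result.q, result.i_exp, result.sigma, result.i_fit])
    np.savetxt(str(path), data, fmt="%.6e", header=header)


def read_fit(path: str | os.PathLike) -> np.ndarray:
    """Read back a 4-column fit file as an (N, 4) array."""
    data = np.loadtxt(str(path))
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns, found {data.shape[1]}")
    return data
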