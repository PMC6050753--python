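"""F(ab) elbow-angle geometry.

An antibody F(ab) pairs a light chain (VL-CL) with a heavy chain (VH-CH1).
Each module — variable (VL/VH) and constant (CL/CH1) — is related by an
approximate two-fold ("pseudo-dyad") rotation that maps the light-chain
domain onto its heavy-chain partner.  The elbow angle is the angle between
the two pseudo-dyad axes, describing the hinge between the variable and
constant modules; reported values for lambda light chains span roughly
117-227 degrees, so the angle is disambiguated onto (0, 360).

The axes are extracted from the rotation part of the least-squares
superposition of VL C-alpha atoms onto VH (and CL onto CH1).  Residues are
paired by rank within each domain after truncation to equal length; a
custom pairing can be supplied for sequence-aligned use.  The sign of the
determinant det[v_axis, c_axis, h] with h the unit vector from the constant
module centroid to the variable module centroid decides whether the angle
is alpha or 360 - alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import _kabsch
from .models import AtomicModel, Ensemble

__all__ = ["DomainSplit", "ElbowResult", "elbow_angle", "elbow_series"]

# example split residues for a lambda-light-chain F(ab) with sequential
# domain numbering (variable domain = residues strictly below the split);
# the conventional heavy/light V-C boundaries used by structural elbow tools
EXAMPLE_LAMBDA_SPLIT = {"heavy_split": 113, "light_split": 107}


@dataclass(frozen=True)
class DomainSplit:
    """Chain ids and V/C boundary residues of a F(ab).

    Residues with ``res_id < split`` belong to the variable domain of the
    chain; the rest form the constant domain.  Splits are author residue
    numbers and must be chosen for the structure at hand (domain boundaries
    depend on the numbering scheme).
    """

    heavy_chain: str
    light_chain: str
    heavy_split: int
    light_split: int


@dataclass
class ElbowResult:
    """Elbow angle with the two pseudo-dyad axes that define it."""

    angle: float  # degrees in (0, 360)
    variable_axis: np.ndarray  # unit vector
    constant_axis: np.ndarray  # unit vector
    variable_rotation_deg: float  # rotation angle of the VL->VH superposition
    constant_rotation_deg: float
    split: DomainSplit
    warnings: list[str] = field(default_factory=list)


def _domain_ca(model: AtomicModel, chain: str, lo: float, hi: float) -> np.ndarray:
    mask = (
        model.ca_mask()
        & (model.chain_ids == chain)
        & (model.residue_seqs >= lo)
        & (model.residue_seqs < hi)
    )
    coords = model.coords[mask]
    if coords.shape[0] < 20:
        raise ValueError(
            f"domain chain {chain} residues [{lo}, {hi}) resolves to "
            f"{coords.shape[0]} C-alpha atoms, need >= 20"
        )
    return coords


def _dyad_axis(light: np.ndarray, heavy: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotation axis and angle (deg) of the superposition of the light-chain
    domain onto its heavy-chain partner, paired by rank."""
    n = min(len(light), len(heavy))
    rot, _, _ = _kabsch(light[:n], heavy[:n])
    rotvec = Rotation.from_matrix(rot).as_rotvec()
    theta = np.linalg.norm(rotvec)
    if theta == 0:
        raise ValueError("identity superposition: pseudo-dyad axis undefined")
    return rotvec / theta, float(np.degrees(theta))


def elbow_angle(model: AtomicModel, split: DomainSplit) -> ElbowResult:
    """Elbow angle of one conformation under the given domain split."""
    vl = _domain_ca(model, split.light_chain, -np.inf, split.light_split)
    cl = _domain_ca(model, split.light_chain, split.light_split, np.inf)
    vh = _domain_ca(model, split.heavy_chain, -np.inf, split.heavy_split)
    ch1 = _domain_ca(model, split.heavy_chain, split.heavy_split, np.inf)

    v_axis, v_rot = _dyad_axis(vl, vh)
    c_axis, c_rot = _dyad_axis(cl, ch1)

    warnings: list[str] = []
    for name, rot in (("variable", v_rot), ("constant", c_rot)):
        if rot < 90.0:
            warnings.append(
                f"{name}-module superposition rotation is only {rot:.1f} deg; "
                "pseudo-dyad axis may be ill-defined"
            )

    alpha = float(np.degrees(np.arccos(np.clip(v_axis @ c_axis, -1.0, 1.0))))
    var_centroid = np.vstack([vl, vh]).mean(axis=0)
    const_centroid = np.vstack([cl, ch1]).mean(axis=0)
    h = var_centroid - const_centroid
    norm = np.linalg.norm(h)
    if norm > 0:
        h = h / norm
    handedness = float(np.linalg.det(np.column_stack([v_axis, c_axis, h])))
    angle = alpha if handedness >= 0 else 360.0 - alpha
    return ElbowResult(
        angle=angle,
        variable_axis=v_axis,
        constant_axis=c_axis,
        variable_rotation_deg=v_rot,
        constant_rotation_deg=c_rot,
        split=split,
        warnings=warnings,
    )


def elbow_series(ensemble: Ensemble, split: DomainSplit) -> np.ndarray:
    """Per-frame elbow angles (degrees) over an ensemble."""
    return np.array([elbow_angle(frame, split).angle for frame in ensemble])
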