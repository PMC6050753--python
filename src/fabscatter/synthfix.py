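"""Synthetic structures, ensembles, and noisy experimental-style curves.

The hinge toy emulates the two features of a F(ab) ensemble that the
analysis must disentangle:

* a *global* motion — a variable module (two pseudo-domains related by a
  175-degree pseudo-dyad) hinging against a fixed constant module (its own
  pseudo-dyad pair), so that the inter-dyad elbow angle sweeps a chosen
  range across frames; and
* a *local* motion — a short contiguous loop of residues in one constant
  pseudo-domain toggling between a "bent" and an "extended" conformation,
  independent of the hinge.

Domains are helical-lattice C-alpha point clouds (non-degenerate inertia
tensors, so superpositions and axis extraction are well conditioned), and
pseudo-residues are glycine-labelled so residue-level form factors resolve.
The generator is constructed so that the elbow angle computed from the
pseudo-dyad axes equals the requested angle, giving ground truth for
geometry, PCA, clustering and chi-square recovery tests.

Noisy "experimental" curves are Debye profiles perturbed with Gaussian
noise sigma(q) = a*I(q) + b (counting-statistics-like relative noise with a
small floor), with the same sigma stored in the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import pdist

from .debye import debye_profile
from .elbow import DomainSplit
from .formfactor import FormFactorTable
from .models import AtomicModel, Ensemble, SAXSCurve

__all__ = [
    "LoopSpec",
    "HingeToySpec",
    "NoiseSpec",
    "make_hinge_model",
    "make_hinge_toy",
    "toy_domain_split",
    "frame_parameters",
    "synth_experiment",
]

_DYAD_DEG = 175.0  # pseudo-two-fold rotation relating paired domains
_DOMAIN_OFFSET = 8.5  # lateral offset of each domain from its module axis, A
_MODULE_DISTANCE = 30.0  # constant-module pivot to variable-module centroid, A
_CONST_CENTER = np.array([0.0, 0.0, -28.0])
_PIVOT = np.array([0.0, 0.0, -3.0])


@dataclass(frozen=True)
class LoopSpec:
    """A contiguous mobile surface loop in the heavy-chain constant domain.

    Residues ``res_lo..res_hi`` (inclusive, heavy-chain numbering) are
    displaced radially outward by ``amplitude`` Angstrom in the "extended"
    state; the "bent" state is the undisplaced lattice.
    """

    res_lo: int
    res_hi: int
    amplitude: float = 6.0
    chain: str = "H"


@dataclass(frozen=True)
class HingeToySpec:
    """Parameters of the hinged two-module toy ensemble.

    Defaults give a 50-frame sweep of elbow angles over 130-175 degrees
    with a 10-residue mobile loop toggling at random between its two
    states — hinge (global) and loop (local) variation are independent, the
    confound the difference-matrix analysis is designed to resolve.
    """

    n_residues_per_domain: int = 60
    hinge_angle_range: tuple[float, float] = (130.0, 175.0)
    frames: int = 50
    seed: int = 0
    mode: str = "sweep"  # "sweep" (linspace) or "random" (uniform draws)
    loop: LoopSpec | None = None
    loop_states: tuple[bool, ...] | None = None  # per-frame; random if None
    jitter: float = 0.0  # per-atom Gaussian positional noise, A

    def resolved_loop(self) -> LoopSpec:
        if self.loop is not None:
            return self.loop
        n = self.n_residues_per_domain
        # a 10-residue window in the middle of the heavy constant domain
        lo = n + max(1, n // 4)
        return LoopSpec(res_lo=lo, res_hi=lo + 9, amplitude=6.0, chain="H")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise model sigma(q) = rel_sigma * I(q) + floor_frac * max I."""

    rel_sigma: float = 0.01
    floor_frac: float = 1e-4
    seed: int = 0


def _helix_cloud(n: int, radius: float = 7.0, rise: float = 1.5, twist_deg: float = 100.0) -> np.ndarray:
    """Helical lattice of n points with axis along z, centered at the origin."""
    k = np.arange(n)
    ang = np.radians(twist_deg) * k
    pts = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * (k - (n - 1) / 2.0)]
    )
    return pts


def _orient(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Rotate a z-axis-aligned cloud so its axis lies along ``axis``."""
    z = np.array([0.0, 0.0, 1.0])
    axis = axis / np.linalg.norm(axis)
    cross = np.cross(z, axis)
    s = np.linalg.norm(cross)
    c = float(z @ axis)
    if s < 1e-12:
        if c > 0:
            return points.copy()
        return points @ Rotation.from_rotvec([np.pi, 0, 0]).as_matrix().T
    rotvec = cross / s * np.arctan2(s, c)
    return points @ Rotation.from_rotvec(rotvec).as_matrix().T


def _rotate_about(points: np.ndarray, axis: np.ndarray, deg: float, center: np.ndarray) -> np.ndarray:
    rot = Rotation.from_rotvec(np.radians(deg) * axis / np.linalg.norm(axis)).as_matrix()
    return (points - center) @ rot.T + center


def _variable_axis(elbow_deg: float) -> np.ndarray:
    """Unit dyad axis of the variable module for a target elbow angle.

    The constant dyad is +z.  For target angle e the variable axis makes the
    polar angle gamma = e (or 360 - e beyond 180) with z, twisted 45 degrees
    out of the bending plane; the twist sign sets the handedness so that the
    disambiguated elbow angle equals e on either side of 180.
    """
    if not 0.0 < elbow_deg < 360.0:
        raise ValueError("elbow angle must lie in (0, 360)")
    if elbow_deg <= 180.0:
        gamma, tau = np.radians(elbow_deg), np.radians(45.0)
    else:
        gamma, tau = np.radians(360.0 - elbow_deg), np.radians(-45.0)
    return np.array(
        [np.sin(gamma) * np.cos(tau), np.sin(gamma) * np.sin(tau), np.cos(gamma)]
    )


def make_hinge_model(
    spec: HingeToySpec,
    elbow_deg: float,
    loop_extended: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Coordinates (N, 3) of one toy conformation.

    Atom order: heavy chain (variable then constant domain), then light
    chain (variable then constant), one C-alpha per pseudo-residue.
    """
    n = spec.n_residues_per_domain
    cloud = _helix_cloud(n)

    # constant module: dyad axis +z through _CONST_CENTER
    c_axis = np.array([0.0, 0.0, 1.0])
    ch1 = _orient(cloud, c_axis) + _CONST_CENTER + _DOMAIN_OFFSET * np.array([1.0, 0.0, 0.0])
    cl = _rotate_about(ch1, c_axis, _DYAD_DEG, _CONST_CENTER)

    # variable module: dyad axis v through its centroid m; the centroid bends
    # in the x-z plane (half-angle) so the handedness reference is non-degenerate
    v_axis = _variable_axis(elbow_deg)
    gamma = np.radians(elbow_deg if elbow_deg <= 180.0 else 360.0 - elbow_deg)
    bend = np.array([np.sin(gamma / 2.0), 0.0, np.cos(gamma / 2.0)])
    m = _PIVOT + _MODULE_DISTANCE * bend
    w = np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ v_axis) * v_axis
    w = w / np.linalg.norm(w)
    vh = _orient(cloud, v_axis) + m + _DOMAIN_OFFSET * w
    vl = _rotate_about(vh, v_axis, _DYAD_DEG, m)

    coords = np.vstack([vh, ch1, vl, cl])
    if loop_extended:
        loop = spec.resolved_loop()
        # heavy chain residues res_lo..res_hi live in rows (res-1) of [vh; ch1]
        rows = np.arange(loop.res_lo - 1, loop.res_hi)
        center = ch1.mean(axis=0)
        for r in rows:
            radial = coords[r] - center
            radial[2] = 0.0  # displace perpendicular to the module axis
            nrm = np.linalg.norm(radial)
            if nrm > 0:
                coords[r] = coords[r] + loop.amplitude * radial / nrm
    if spec.jitter > 0 and rng is not None:
        coords = coords + rng.normal(scale=spec.jitter, size=coords.shape)
    return coords


def _toy_topology(spec: HingeToySpec) -> AtomicModel:
    n = spec.n_residues_per_domain
    total = 4 * n
    arr = struc.AtomArray(total)
    arr.coord = np.zeros((total, 3))
    arr.chain_id = np.array(["H"] * (2 * n) + ["L"] * (2 * n))
    arr.res_id = np.array(list(range(1, 2 * n + 1)) * 2)
    arr.res_name = np.array(["GLY"] * total)
    arr.atom_name = np.array(["CA"] * total)
    arr.element = np.array(["C"] * total)
    arr.hetero = np.zeros(total, dtype=bool)
    arr.set_annotation("occupancy", np.ones(total))
    arr.set_annotation("atom_id", np.arange(1, total + 1))
    return AtomicModel(arr, label="hinge-toy")


def toy_domain_split(spec: HingeToySpec) -> DomainSplit:
    """The domain split matching the toy's residue numbering."""
    n = spec.n_residues_per_domain
    return DomainSplit(heavy_chain="H", light_chain="L", heavy_split=n + 1, light_split=n + 1)


def make_hinge_toy(spec: HingeToySpec) -> Ensemble:
    """Generate the toy ensemble.  Deterministic under ``spec.seed``.

    Frame labels encode the ground truth as ``elbow=<deg>;loop=<ext|bent>``;
    :func:`frame_parameters` parses them back.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.hinge_angle_range
    if not lo < hi:
        raise ValueError("hinge_angle_range must be a non-empty (low, high) interval")
    if spec.mode == "sweep":
        angles = np.linspace(lo, hi, spec.frames)
    elif spec.mode == "random":
        angles = rng.uniform(lo, hi, spec.frames)
    else:
        raise ValueError(f"unknown mode {spec.mode!r}")
    if spec.loop_states is not None:
        if len(spec.loop_states) != spec.frames:
            raise ValueError("loop_states length must equal frames")
        states = np.asarray(spec.loop_states, dtype=bool)
    else:
        states = rng.random(spec.frames) < 0.5
    topo = _toy_topology(spec)
    coords = np.empty((spec.frames, topo.n_atoms, 3))
    labels = []
    for i in range(spec.frames):
        xyz = make_hinge_model(spec, angles[i], bool(states[i]), rng)
        attempts = 0
        while pdist(xyz).min() < 1.0:  # steric clash: retry with jitter
            attempts += 1
            if attempts > 100:
                raise RuntimeError(
                    f"frame {i}: no clash-free conformation in 100 attempts"
                )
            xyz = make_hinge_model(spec, angles[i], bool(states[i]), rng)
            xyz = xyz + rng.normal(scale=0.05, size=xyz.shape)
        coords[i] = xyz
        labels.append(f"elbow={angles[i]:.6f};loop={'ext' if states[i] else 'bent'}")
    return Ensemble(topology=topo, coordinates=coords, frame_labels=labels)


def frame_parameters(ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Recover (elbow angles, loop-extended flags) from toy frame labels."""
    angles, states = [], []
    for lab in ensemble.frame_labels:
        fields = dict(part.split("=") for part in lab.split(";"))
        angles.append(float(fields["elbow"]))
        states.append(fields["loop"] == "ext")
    return np.array(angles), np.array(states, dtype=bool)


def synth_experiment(
    model: AtomicModel,
    table: FormFactorTable,
    q_grid: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
) -> SAXSCurve:
    """Noisy experimental-style curve generated from a model.

    The Debye profile is perturbed with zero-mean Gaussian noise of standard
    deviation sigma(q) = rel_sigma * I(q) + floor_frac * max I, and the same
    sigma is stored as the curve's uncertainty.  With both noise parameters
    zero the curve equals the profile exactly (a tiny positive sigma is
    stored to keep the uncertainty contract valid).
    """
    profile = debye_profile(model, table, q_grid)
    intensity = profile.intensity
    sigma = noise.rel_sigma * np.abs(intensity) + noise.floor_frac * np.abs(intensity).max()
    if np.all(sigma == 0):
        return SAXSCurve(
            profile.q,
            intensity.copy(),
            np.full_like(intensity, max(np.abs(intensity).max(), 1.0) * 1e-12),
            label=f"synth({model.label})",
        )
    rng = np.random.default_rng(noise.seed)
    noisy = intensity + rng.normal(scale=sigma)
    return SAXSCurve(profile.q, noisy, sigma, label=f"synth({model.label})")
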