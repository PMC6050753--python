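"""Ensemble analysis: superposition, C-alpha PCA, clustering, autocorrelation.

The workflow mirrors how MD snapshot ensembles are reduced for comparison
with solution scattering: rigid-body motion is removed by least-squares
superposition on a stable selection (e.g. the C-alpha atoms of the constant
domains of a F(ab)), a 3N-dimensional covariance matrix of the analyzed
C-alpha coordinates is diagonalized into principal components, frames are
projected onto the leading components, and hierarchical agglomerative
clustering on pairwise best-fit RMSD (termination threshold epsilon, default
2 A) condenses the ensemble into representative frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .models import AtomicModel, Ensemble

__all__ = [
    "Selection",
    "PCAResult",
    "ClusterSet",
    "superpose",
    "superpose_coords",
    "pca",
    "project",
    "interpolate_pc",
    "cluster",
    "pairwise_rmsd_matrix",
    "autocorrelation",
]


@dataclass(frozen=True)
class Selection:
    """A predicate over atoms: chain ids, residue-number ranges, atom names.

    ``None`` fields match everything.  Residue ranges are inclusive
    ``(low, high)`` pairs on the author residue numbering (``res_id``).
    The default atom-name set is C-alpha only, the selection level at which
    superposition and PCA operate.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = frozenset({"CA"})

    @classmethod
    def make(cls, chains=None, residue_ranges=None, atom_names=("CA",)) -> "Selection":
        return cls(
            chains=None if chains is None else frozenset(chains),
            residue_ranges=None if residue_ranges is None else tuple(
                (int(lo), int(hi)) for lo, hi in residue_ranges
            ),
            atom_names=None if atom_names is None else frozenset(atom_names),
        )

    def mask(self, model: AtomicModel) -> np.ndarray:
        m = np.ones(model.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(model.chain_ids, list(self.chains))
        if self.residue_ranges is not None:
            in_range = np.zeros(model.n_atoms, dtype=bool)
            for lo, hi in self.residue_ranges:
                in_range |= (model.residue_seqs >= lo) & (model.residue_seqs <= hi)
            m &= in_range
        if self.atom_names is not None:
            m &= np.isin(model.array.atom_name, list(self.atom_names))
        return m

    def indices(self, model: AtomicModel, minimum: int = 1) -> np.ndarray:
        idx = np.flatnonzero(self.mask(model))
        if idx.size < minimum:
            raise ValueError(
                f"selection resolves to {idx.size} atoms, need at least {minimum}"
            )
        return idx


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids such that (x - cm) @ R.T + cr maps
    mobile onto reference in the least-squares sense."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, cr


def superpose_coords(
    mobile: np.ndarray,
    reference: np.ndarray,
    sel_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Rigid-body superpose ``mobile`` onto ``reference`` (both (N, 3)).

    The optimal transform is computed on ``sel_indices`` (all atoms when
    None) and applied to every atom; returns the transformed coordinates and
    the RMSD over the selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(len(mobile)) if sel_indices is None else np.asarray(sel_indices)
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    sub_m, sub_r = mobile[idx], reference[idx]
    # collinearity check: rank of centered selection
    centered = sub_m - sub_m.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        import warnings

        warnings.warn("degenerate (collinear) selection; superposition may be ill-conditioned")
    rot, cm, cr = _kabsch(sub_m, sub_r)
    moved = (mobile - cm) @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved[idx] - reference[idx]) ** 2, axis=1))))
    return moved, rmsd


def superpose(
    mobile: AtomicModel,
    reference: AtomicModel,
    selection: Selection | None = None,
) -> tuple[AtomicModel, float]:
    """Superpose a model onto a reference on ``selection`` (default: all CA)."""
    sel = selection or Selection()
    idx_m = sel.indices(mobile, minimum=3)
    idx_r = sel.indices(reference, minimum=3)
    if idx_m.size != idx_r.size:
        raise ValueError(
            f"selection resolves to {idx_m.size} atoms in mobile but "
            f"{idx_r.size} in reference"
        )
    if not np.array_equal(idx_m, idx_r):
        raise ValueError("selection does not resolve to the same atoms in both models")
    moved, rmsd = superpose_coords(mobile.coords, reference.coords, idx_m)
    return mobile.with_coords(moved), rmsd


@dataclass
class PCAResult:
    """Eigen-decomposition of the C-alpha coordinate covariance.

    ``mean_coords`` is the 3M-vector of the aligned ensemble mean over the
    analyzed atoms; ``eigenvectors`` has one orthonormal 3M-row per
    component (descending eigenvalue, A^2); ``projections`` are per-frame
    scores.  ``mean_full``/``analyze_indices`` retain enough context to
    embed synthetic structures back into full coordinates.
    """

    mean_coords: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (K, 3M)
    projections: np.ndarray  # (F, K)
    variance_fraction: np.ndarray
    align_selection: Selection
    analyze_selection: Selection
    mean_full: np.ndarray = None  # (N, 3) full-atom aligned mean
    align_reference: np.ndarray = None  # (N, 3) reference of the final alignment pass
    analyze_indices: np.ndarray = None
    align_indices: np.ndarray = None
    topology: AtomicModel = None
    total_variance: float = 0.0

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _align_frames(
    coords: np.ndarray, align_idx: np.ndarray, mean_iterations: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Align all frames to frame 0 on the alignment selection, then realign
    to the ensemble mean (``mean_iterations`` passes, default one).

    Returns the aligned frames and the reference used in the final
    alignment pass (frame 0 when ``mean_iterations`` is 0); new structures
    projected later must be aligned to that same reference.
    """
    aligned = np.empty_like(coords)
    aligned[0] = coords[0]
    reference = coords[0]
    for i in range(1, len(coords)):
        aligned[i], _ = superpose_coords(coords[i], reference, align_idx)
    for _ in range(mean_iterations):
        reference = aligned.mean(axis=0)
        for i in range(len(coords)):
            aligned[i], _ = superpose_coords(aligned[i], reference, align_idx)
    return aligned, reference


def pca(
    ensemble: Ensemble,
    align_selection: Selection | None = None,
    analyze_selection: Selection | None = None,
    n_components: int | None = None,
    mean_iterations: int = 1,
) -> PCAResult:
    """Principal component analysis of C-alpha coordinate variation.

    Frames are superposed on ``align_selection`` (first to frame 1, then one
    realignment pass to the ensemble mean), the covariance of the
    ``analyze_selection`` coordinates is diagonalized, and eigenvector signs
    are fixed by making each vector's largest-magnitude component positive.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA requires at least 2 frames")
    align_sel = align_selection or Selection()
    analyze_sel = analyze_selection or Selection()
    top = ensemble.topology
    align_idx = align_sel.indices(top, minimum=3)
    analyze_idx = analyze_sel.indices(top, minimum=1)
    aligned, align_ref = _align_frames(ensemble.coordinates, align_idx, mean_iterations)
    mean_full = aligned.mean(axis=0)
    x = aligned[:, analyze_idx, :].reshape(ensemble.n_frames, -1)  # (F, 3M)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (ensemble.n_frames - 1)
    dim = cov.shape[0]
    k = dim if n_components is None else int(n_components)
    if k > dim:
        raise ValueError(f"n_components={k} exceeds 3M={dim}")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    total = float(evals.sum())
    evals_k = evals[:k].copy()
    evecs_k = evecs[:, :k].T.copy()  # (K, 3M)
    for row in evecs_k:  # deterministic sign: largest |component| positive
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    projections = xc @ evecs_k.T
    return PCAResult(
        mean_coords=mean,
        eigenvalues=evals_k,
        eigenvectors=evecs_k,
        projections=projections,
        variance_fraction=evals_k / total if total > 0 else np.zeros(k),
        align_selection=align_sel,
        analyze_selection=analyze_sel,
        mean_full=mean_full,
        align_reference=align_ref,
        analyze_indices=analyze_idx,
        align_indices=align_idx,
        topology=top,
        total_variance=total,
    )


def project(result: PCAResult, obj: AtomicModel | Ensemble) -> np.ndarray:
    """Project structures onto the principal components.

    The structure is first superposed onto the PCA's aligned mean using the
    alignment selection; scores are (x - mean) . v_k.  Returns (K,) for a
    model, (F, K) for an ensemble.
    """
    if isinstance(obj, AtomicModel):
        coords = obj.coords[None, :, :]
        single = True
    else:
        coords = obj.coordinates
        single = False
    if coords.shape[1] != result.mean_full.shape[0]:
        raise ValueError(
            f"structure has {coords.shape[1]} atoms, PCA topology has "
            f"{result.mean_full.shape[0]}"
        )
    scores = np.empty((coords.shape[0], result.n_components))
    for i in range(coords.shape[0]):
        moved, _ = superpose_coords(coords[i], result.align_reference, result.align_indices)
        x = moved[result.analyze_indices].reshape(-1)
        scores[i] = result.eigenvectors @ (x - result.mean_coords)
    return scores[0] if single else scores


def interpolate_pc(
    result: PCAResult, component: int, amplitudes: np.ndarray | list[float]
) -> Ensemble:
    """Synthetic motion along one PC: frames mean + a * v_k per amplitude.

    Non-analyzed atoms stay at the aligned mean; the output is suitable for
    multi-model PDB export to visualize the captured motion.
    """
    if not 1 <= component <= result.n_components:
        raise ValueError(f"component must be in [1, {result.n_components}]")
    vec = result.eigenvectors[component - 1]
    amplitudes = np.asarray(amplitudes, dtype=float)
    frames = np.repeat(result.mean_full[None, :, :], len(amplitudes), axis=0)
    for i, a in enumerate(amplitudes):
        disp = (result.mean_coords + a * vec).reshape(-1, 3)
        frames[i, result.analyze_indices, :] = disp
    labels = [f"PC{component}:{a:+.3f}" for a in amplitudes]
    return Ensemble(topology=result.topology, coordinates=frames, frame_labels=labels)


def pairwise_rmsd_matrix(ensemble: Ensemble, selection: Selection | None = None) -> np.ndarray:
    """Symmetric (F, F) matrix of pairwise best-fit RMSD on the selection."""
    sel = selection or Selection()
    idx = sel.indices(ensemble.topology, minimum=3)
    f = ensemble.n_frames
    sub = ensemble.coordinates[:, idx, :]
    dmat = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            _, rmsd = superpose_coords(sub[j], sub[i], None)
            dmat[i, j] = dmat[j, i] = rmsd
    return dmat


@dataclass
class ClusterSet:
    """Frame clustering: per-frame labels, one representative per cluster.

    Cluster ids are 0-based and ordered by first frame appearance; the
    representative is the member frame with minimum mean RMSD to its
    co-members (the physical-frame surrogate for the cluster center).
    """

    labels: np.ndarray
    representatives: list[int]
    epsilon: float
    linkage: str
    metric_selection: Selection
    rmsd_matrix: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def cluster(
    ensemble: Ensemble,
    epsilon: float = 2.0,
    metric_selection: Selection | None = None,
    linkage: str = "average",
) -> ClusterSet:
    """Hierarchical agglomerative clustering of frames by best-fit RMSD.

    Merging stops when the minimum inter-cluster linkage distance exceeds
    ``epsilon`` (A); ``linkage`` is any scipy hierarchy method (default
    average).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    sel = metric_selection or Selection()
    dmat = pairwise_rmsd_matrix(ensemble, sel)
    f = ensemble.n_frames
    if f == 1:
        labels = np.zeros(1, dtype=int)
    else:
        z = sch.linkage(squareform(dmat, checks=False), method=linkage)
        raw = sch.fcluster(z, t=epsilon, criterion="distance")
        # renumber by first appearance for determinism
        labels = np.empty(f, dtype=int)
        mapping: dict[int, int] = {}
        for i, r in enumerate(raw):
            if r not in mapping:
                mapping[r] = len(mapping)
            labels[i] = mapping[r]
    reps: list[int] = []
    for cid in range(labels.max() + 1):
        members = np.flatnonzero(labels == cid)
        if members.size == 1:
            reps.append(int(members[0]))
            continue
        sub = dmat[np.ix_(members, members)]
        mean_rmsd = sub.sum(axis=1) / (members.size - 1)
        reps.append(int(members[np.argmin(mean_rmsd)]))  # argmin: lowest index on ties
    return ClusterSet(
        labels=labels,
        representatives=reps,
        epsilon=epsilon,
        linkage=linkage,
        metric_selection=sel,
        rmsd_matrix=dmat,
    )


def autocorrelation(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Normalized autocorrelation of a scalar series.

    Mean-removed, variance-normalized estimator with per-lag (n - k)
    normalization:

        c_k = [1/(n-k) sum_t (x_t - m)(x_{t+k} - m)] / [1/n sum_t (x_t - m)^2]

    so c_0 = 1 exactly and a strictly alternating series has c_1 = -1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least 2 values")
    x = x - x.mean()
    var = np.mean(x**2)
    if var == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    n = x.size
    max_lag = n - 1 if max_lag is None else min(int(max_lag), n - 1)
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = np.mean(x[: n - k] * x[k:]) / var
    return acf
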