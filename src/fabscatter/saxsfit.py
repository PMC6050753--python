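"""Scoring theoretical SAXS curves against experimental data.

The agreement statistic is the reduced chi-square

    chi2 = 1/(N-1) * sum_j [ (I_exp(q_j) - delta - c * I_mod(q_j)) / sigma_j ]^2

minimized analytically over the scale factor c (and, optionally, the
constant offset delta, which absorbs small buffer-subtraction errors).  The
theoretical curve is linearly interpolated onto the experimental q-grid;
extrapolation is forbidden.  Fitting is restricted to q <= q_max with a
default of 0.2 1/A, the truncation beyond which single-conformer fits of
flexible proteins typically develop systematic residuals.

chi2 values are classified into the four agreement categories used when
annotating ensemble analyses: good (chi2 < 3), fair (3 <= chi2 < 6),
poor (6 <= chi2 < 9), very_poor (chi2 >= 9).

Also provided: Guinier radius of gyration from the low-q expansion
ln I = ln I0 - q^2 Rg^2 / 3, and model-based Rg/Dmax from coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .models import AtomicModel, SAXSCurve

__all__ = [
    "FitResult",
    "ShapeStats",
    "fit_scale",
    "chi2_category",
    "guinier_rg",
    "model_shape",
    "CHI2_THRESHOLDS",
]

# category upper bounds (half-open intervals, in order)
CHI2_THRESHOLDS = {"good": 3.0, "fair": 6.0, "poor": 9.0}


def chi2_category(chi2: float, thresholds: dict[str, float] | None = None) -> str:
    """Classify a chi2 value into good / fair / poor / very_poor."""
    if chi2 < 0:
        raise ValueError(f"chi2 must be non-negative, got {chi2}")
    t = CHI2_THRESHOLDS if thresholds is None else thresholds
    if chi2 < t["good"]:
        return "good"
    if chi2 < t["fair"]:
        return "fair"
    if chi2 < t["poor"]:
        return "poor"
    return "very_poor"


@dataclass
class FitResult:
    """Outcome of fitting a theoretical curve to an experimental one.

    ``i_fit`` is the fitted model ``c * I_mod + delta`` on the experimental
    grid; ``residuals`` are log10(I_exp) - log10(I_fit) (NaN where either
    intensity is non-positive).
    """

    chi2: float
    scale: float
    constant: float
    q_max_used: float
    n_points: int
    q: np.ndarray
    i_exp: np.ndarray
    sigma: np.ndarray
    i_mod: np.ndarray
    category: str = ""
    theory_label: str = ""
    experiment_label: str = ""
    residuals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.category:
            self.category = chi2_category(self.chi2)
        if self.residuals is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.log10(self.i_exp) - np.log10(self.i_fit)
            r[~np.isfinite(r)] = np.nan
            self.residuals = r

    @property
    def i_fit(self) -> np.ndarray:
        return self.scale * self.i_mod + self.constant


def fit_scale(
    theory: SAXSCurve,
    experiment: SAXSCurve,
    q_max: float = 0.2,
    fit_constant: bool = False,
) -> FitResult:
    """Fit ``c * I_mod (+ delta)`` to the experimental curve for q <= q_max.

    The minimization is exact weighted linear least squares; with
    ``fit_constant`` disabled delta is fixed at 0.
    """
    if experiment.sigma is None:
        raise ValueError("experimental curve must carry uncertainties")
    mask = experiment.q <= q_max
    q = experiment.q[mask]
    if q.size < 2:
        raise ValueError(f"fewer than 2 experimental points below q_max={q_max}")
    if q.min() < theory.q.min() - 1e-12 or q.max() > theory.q.max() + 1e-12:
        raise ValueError(
            "theory grid does not cover the experimental grid "
            f"([{theory.q.min():g}, {theory.q.max():g}] vs [{q.min():g}, {q.max():g}]); "
            "extrapolation is not performed"
        )
    i_exp = experiment.intensity[mask]
    sigma = experiment.sigma[mask]
    i_mod = np.interp(q, theory.q, theory.intensity)
    if np.all(i_mod == 0):
        raise ValueError("degenerate fit: model curve is identically zero")
    w = 1.0 / sigma**2
    if fit_constant:
        # weighted LS for I_exp ~ c * I_mod + delta
        design = np.column_stack([i_mod, np.ones_like(i_mod)])
        wd = design * w[:, None]
        ata = design.T @ wd
        atb = wd.T @ i_exp
        try:
            c, delta = np.linalg.solve(ata, atb)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate fit: singular normal equations") from exc
    else:
        denom = np.sum(w * i_mod**2)
        if denom == 0:
            raise ValueError("degenerate fit: model curve is identically zero")
        c = np.sum(w * i_exp * i_mod) / denom
        delta = 0.0
    resid = (i_exp - delta - c * i_mod) / sigma
    chi2 = float(np.sum(resid**2) / (q.size - 1))
    return FitResult(
        chi2=chi2,
        scale=float(c),
        constant=float(delta),
        q_max_used=float(q_max),
        n_points=int(q.size),
        q=q,
        i_exp=i_exp,
        sigma=sigma,
        i_mod=i_mod,
        theory_label=theory.label,
        experiment_label=experiment.label,
    )


@dataclass
class ShapeStats:
    """Radius of gyration and maximum dimension, Angstrom.

    ``dmax`` is None for Guinier-derived stats: the maximum dimension is not
    observable from the Guinier region alone.
    """

    rg: float
    dmax: float | None
    source: Literal["model", "guinier"]

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValueError("Rg must be positive")
        if self.dmax is not None and self.dmax <= 0:
            raise ValueError("Dmax must be positive")


def guinier_rg(
    experiment: SAXSCurve,
    qmax_rg_product: float = 1.3,
    max_iter: int = 50,
) -> ShapeStats:
    """Guinier Rg from a weighted linear fit of ln I vs q^2.

    The fit window is the largest low-q stretch satisfying
    q * Rg <= qmax_rg_product, iterated to self-consistency starting from
    the smallest admissible window.
    """
    q = experiment.q
    intensity = experiment.intensity
    positive = intensity > 0
    min_pts = 5

    def window_fit(n: int) -> tuple[float, float]:
        sel = np.flatnonzero(positive[:n])
        if sel.size < min_pts:
            raise ValueError("fewer than 5 usable points in the Guinier window")
        x = q[sel] ** 2
        y = np.log(intensity[sel])
        if experiment.sigma is not None:
            w = (intensity[sel] / experiment.sigma[sel]) ** 2  # var of ln I
        else:
            w = np.ones_like(x)
        wm = np.sum(w)
        xb = np.sum(w * x) / wm
        yb = np.sum(w * y) / wm
        sxx = np.sum(w * (x - xb) ** 2)
        slope = np.sum(w * (x - xb) * (y - yb)) / sxx
        return slope, yb - slope * xb

    n = min_pts
    rg = None
    for _ in range(max_iter):
        slope, _ = window_fit(n)
        if slope >= 0:
            raise ValueError("no Guinier decay: non-negative slope of ln I vs q^2")
        rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(q, qmax_rg_product / rg, side="right"))
        n_new = max(n_new, min_pts)
        if n_new == n:
            break
        n = min(n_new, q.size)
    assert rg is not None
    return ShapeStats(rg=rg, dmax=None, source="guinier")


def model_shape(
    model: AtomicModel,
    weighting: Literal["electrons", "uniform"] = "electrons",
) -> ShapeStats:
    """Rg and Dmax directly from coordinates.

    Rg uses electron-count or uniform weights; Dmax is the exact maximum
    pairwise distance (computed on the convex hull for large models).
    """
    if model.n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    xyz = model.coords
    if weighting == "electrons":
        from .formfactor import _ELEMENTS

        w = np.array([_ELEMENTS[e.upper()]["z"] if e.upper() in _ELEMENTS else 6.0
                      for e in model.elements], dtype=float)
    else:
        w = np.ones(model.n_atoms)
    center = np.average(xyz, axis=0, weights=w)
    rg = float(np.sqrt(np.average(np.sum((xyz - center) ** 2, axis=1), weights=w)))
    if model.n_atoms > 2000:
        try:
            pts = xyz[ConvexHull(xyz).vertices]
        except Exception:
            pts = xyz
    else:
        pts = xyz
    dmax = float(pdist(pts).max())
    return ShapeStats(rg=rg, dmax=dmax, source="model")
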