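"""Dose-response surface models D(tau, I0).

Three model families predict the control-subtracted cell-death fraction as a
function of laser duration tau (minutes) and intensity I0 (mW/cm^2):

``lowess``
    2-D locally weighted linear regression.  Neighbourhoods are defined by
    Euclidean distance after standardising tau and I0 to unit variance; each
    prediction is a tricube-weighted local linear fit over a span fraction of
    nearest training points, with robust bisquare re-weighting to damp
    outliers.
``thinplate``
    Exact thin-plate-spline interpolation of the training points (smoothing
    penalty zero), so fitted values at training locations reproduce the
    training data.
``poly2``
    The degree-2 analytical surface
    ``D = a1*I0^2 + a2*I0 + a3*tau^2 + a4*tau + a5*tau*I0 + a6``
    fitted by ordinary least squares.

Raw model output is clipped to [0, 1] at prediction time; death rates are
probabilities.  Goodness of fit is reported as the mean and SD of signed
residuals in percentage points plus R^2 on the fraction scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, QhullError

Family = Literal["lowess", "thinplate", "poly2"]

#: Reference degree-2 coefficients (a1..a6) for the AuNP-mTHPC dose-response
#: surfaces, fitted to the 12-condition training grid of each modality.  They
#: serve both as published-model references and as default ground truth for
#: the synthetic-data generator.
PDT_REFERENCE_COEFFS: tuple[float, ...] = (-0.001, 0.04, -0.014, 0.17, 0.002, -0.392)
PTT_REFERENCE_COEFFS: tuple[float, ...] = (-0.0003, 0.02, -0.0006, 0.018, 0.003, -0.14)


@dataclass(frozen=True)
class TreatmentCondition:
    """A single-laser treatment setting.

    Parameters
    ----------
    modality : {"PDT", "PTT"}
        Photodynamic (650 nm) or photothermal (532 nm) activation of the
        nanocomplex.
    intensity : float
        Laser radiation intensity I0 in mW/cm^2, > 0.
    duration : float
        Radiation duration tau in minutes, > 0.
    """

    modality: str
    intensity: float
    duration: float

    def __post_init__(self) -> None:
        if self.modality not in ("PDT", "PTT"):
            raise ValueError(f"modality must be 'PDT' or 'PTT', got {self.modality!r}")
        if not (self.intensity > 0 and np.isfinite(self.intensity)):
            raise ValueError(f"intensity must be finite and > 0, got {self.intensity}")
        if not (self.duration > 0 and np.isfinite(self.duration)):
            raise ValueError(f"duration must be finite and > 0, got {self.duration}")


@dataclass(frozen=True)
class FitDiagnostics:
    """Residual summary of a fitted surface against observed death rates.

    ``residual_mean`` and ``residual_sd`` summarise signed residuals
    (predicted - observed) in percentage points; ``r_squared`` is
    1 - SS_res/SS_tot on the fraction scale (``None`` when the observed
    values have zero variance).
    """

    residual_mean: float
    residual_sd: float
    r_squared: float | None


def _as_points(points: Sequence) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (tau, intensity, death)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("points must be finite")
    if np.any((arr[:, 2] < 0) | (arr[:, 2] > 1)):
        raise ValueError("death fractions must lie in [0, 1]")
    return arr


def _average_duplicates(arr: np.ndarray) -> np.ndarray:
    """Average D over replicated (tau, I0) locations, preserving first-seen order."""
    keys: dict[tuple[float, float], list[float]] = {}
    for tau, i0, d in arr:
        keys.setdefault((tau, i0), []).append(d)
    return np.array([[t, i, float(np.mean(ds))] for (t, i), ds in keys.items()])


class ResponseSurface:
    """Fitted predictor of death fraction D(tau, I0); base class of the three families."""

    family: Family

    def __init__(self, training_points: np.ndarray):
        self.training_points = np.asarray(training_points, dtype=float)
        self._hull: Delaunay | None = None
        self._hull_failed = False

    # subclasses implement the raw (unclipped) evaluator
    def _evaluate(self, tau: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_raw(self, tau, intensity) -> np.ndarray | float:
        """Raw model output, not clipped to [0, 1]."""
        t = np.atleast_1d(np.asarray(tau, dtype=float))
        i = np.atleast_1d(np.asarray(intensity, dtype=float))
        t, i = np.broadcast_arrays(t, i)
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(i)):
            raise ValueError("tau and intensity must be finite")
        if np.any(t < 0) or np.any(i < 0):
            raise ValueError("tau and intensity must be >= 0")
        out = self._evaluate(t.ravel(), i.ravel()).reshape(t.shape)
        if np.isscalar(tau) and np.isscalar(intensity):
            return float(out.ravel()[0])
        return out

    def predict(self, tau, intensity) -> np.ndarray | float:
        """Predicted death fraction, clipped to [0, 1]."""
        raw = self.predict_raw(tau, intensity)
        if np.isscalar(raw):
            return float(min(1.0, max(0.0, raw)))
        return np.clip(raw, 0.0, 1.0)

    def in_training_hull(self, tau, intensity) -> np.ndarray | bool:
        """True where (tau, I0) lies inside the convex hull of the training locations.

        Predictions outside the hull are extrapolations and should be treated
        with caution; this flag is attached to CLI/report output.
        """
        if self._hull is None and not self._hull_failed:
            try:
                self._hull = Delaunay(self.training_points[:, :2])
            except (QhullError, ValueError):
                self._hull_failed = True
        pts = np.column_stack(
            [np.atleast_1d(np.asarray(tau, float)).ravel(),
             np.atleast_1d(np.asarray(intensity, float)).ravel()]
        )
        if self._hull is None:
            inside = np.zeros(len(pts), dtype=bool)
        else:
            inside = self._hull.find_simplex(pts) >= 0
        if np.isscalar(tau) and np.isscalar(intensity):
            return bool(inside[0])
        return inside

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "training_points": self.training_points.tolist(),
        }


class Poly2Surface(ResponseSurface):
    """Degree-2 analytical surface with six coefficients a1..a6.

    Basis order: (I0^2, I0, tau^2, tau, tau*I0, 1).
    """

    family: Family = "poly2"

    def __init__(self, coeffs: Sequence[float], training_points: np.ndarray | None = None):
        coeffs = tuple(float(c) for c in coeffs)
        if len(coeffs) != 6:
            raise ValueError("poly2 surface requires exactly 6 coefficients")
        self.coeffs = coeffs
        if training_points is None:
            training_points = np.empty((0, 3))
        super().__init__(training_points)

    @staticmethod
    def design_matrix(tau: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, float)
        i0 = np.asarray(intensity, float)
        return np.column_stack([i0**2, i0, tau**2, tau, tau * i0, np.ones_like(tau)])

    def _evaluate(self, tau: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        return self.design_matrix(tau, intensity) @ np.asarray(self.coeffs)

    def stationary_point(self) -> tuple[float, float]:
        """(tau, I0) where the quadratic's gradient vanishes.

        Solves the 2x2 linear system dD/dI0 = dD/dtau = 0; raises if the
        Hessian is singular (no isolated stationary point).
        """
        a1, _a2, a3, _a4, a5, _a6 = self.coeffs
        hess = np.array([[2 * a3, a5], [a5, 2 * a1]])  # rows: d/dtau, d/dI0
        rhs = -np.array([self.coeffs[3], self.coeffs[1]])
        tau, i0 = np.linalg.solve(hess, rhs)
        return float(tau), float(i0)

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["coeffs"] = list(self.coeffs)
        return d


class ThinPlateSurface(ResponseSurface):
    """Exact thin-plate-spline interpolant (zero smoothing).

    Training values are reproduced exactly (to numerical precision) at the
    training locations; between points the surface follows the minimum
    bending-energy thin-plate shape.
    """

    family: Family = "thinplate"

    def __init__(self, training_points: np.ndarray):
        pts = _average_duplicates(_as_points(training_points))
        if len(pts) < 3:
            raise ValueError("thinplate requires >= 3 distinct (tau, intensity) locations")
        super().__init__(pts)
        self._rbf = RBFInterpolator(
            pts[:, :2], pts[:, 2], kernel="thin_plate_spline", smoothing=0.0
        )

    def _evaluate(self, tau: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        return self._rbf(np.column_stack([tau, intensity]))


class LowessSurface(ResponseSurface):
    """2-D locally weighted linear regression with robust re-weighting.

    Parameters
    ----------
    training_points : (n, 3) array
        Rows of (tau, intensity, death fraction).
    span : float
        Fraction of training points in each local neighbourhood (default
        0.28, the sliding-window span used for the reference fits); at least
        3 points are always used.
    robust_iters : int
        Number of bisquare re-weighting passes computed on training
        residuals (default 2).
    """

    family: Family = "lowess"

    def __init__(self, training_points: np.ndarray, span: float = 0.28, robust_iters: int = 2):
        pts = _as_points(training_points)
        if not 0 < span <= 1:
            raise ValueError("span must be in (0, 1]")
        n = len(pts)
        k = max(3, int(np.ceil(span * n)))
        if k > n:
            raise ValueError(f"span*n gives {k} neighbours but only {n} points supplied")
        super().__init__(pts)
        self.span = float(span)
        self.robust_iters = int(robust_iters)
        self._k = k
        # standardise (tau, I0) so the distance metric is scale-free
        xy = pts[:, :2]
        self._center = xy.mean(axis=0)
        scale = xy.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        self._scale = scale
        self._xy_std = (xy - self._center) / self._scale
        self._d = pts[:, 2]
        self._robust_w = np.ones(n)
        for _ in range(self.robust_iters):
            fitted = self._evaluate(pts[:, 0], pts[:, 1])
            resid = self._d - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            u = resid / (6.0 * s)
            self._robust_w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)

    def _local_fit(self, x_std: np.ndarray) -> float:
        dist = np.linalg.norm(self._xy_std - x_std, axis=1)
        order = np.argsort(dist, kind="stable")[: self._k]
        dmax = dist[order[-1]]
        if dmax == 0:
            w = np.ones(self._k)
        else:
            u = np.minimum(dist[order] / dmax, 1.0)
            w = (1 - u**3) ** 3
        w = w * self._robust_w[order]
        if w.sum() <= 0:
            w = np.ones(self._k)
        X = np.column_stack([np.ones(self._k), self._xy_std[order] - x_std])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], self._d[order] * sw, rcond=None)
        return float(beta[0])

    def _evaluate(self, tau: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        xy = (np.column_stack([tau, intensity]) - self._center) / self._scale
        return np.array([self._local_fit(x) for x in xy])

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["span"] = self.span
        d["robust_iters"] = self.robust_iters
        return d


def fit_surface(points: Sequence, family: Family, **options) -> ResponseSurface:
    """Fit a dose-response surface to (tau, intensity, death fraction) points.

    Parameters
    ----------
    points : sequence of (tau, intensity, death) triples
        Replicates at the same (tau, intensity) location are permitted; they
        are pre-averaged for the ``thinplate`` family (which requires single
        values per location).
    family : {"lowess", "thinplate", "poly2"}
    **options
        ``span`` and ``robust_iters`` for lowess.

    Raises
    ------
    ValueError
        On rank-deficient designs (poly2), too few points, or an unknown
        family.
    """
    pts = _as_points(points)
    if family == "poly2":
        if len({(t, i) for t, i, _ in pts}) < 6:
            raise ValueError("poly2 requires >= 6 distinct (tau, intensity) locations")
        X = Poly2Surface.design_matrix(pts[:, 0], pts[:, 1])
        if np.linalg.matrix_rank(X) < 6:
            raise ValueError(
                "rank-deficient design: the (tau, intensity) locations do not "
                "identify all 6 polynomial coefficients"
            )
        coeffs, *_ = np.linalg.lstsq(X, pts[:, 2], rcond=None)
        return Poly2Surface(coeffs, training_points=pts)
    if family == "thinplate":
        return ThinPlateSurface(pts)
    if family == "lowess":
        return LowessSurface(pts, **{k: v for k, v in options.items() if k in ("span", "robust_iters")})
    raise ValueError(f"unknown family {family!r}")


def diagnostics(surface: ResponseSurface, points: Sequence) -> FitDiagnostics:
    """Residual mean/SD (percentage points) and R^2 of a surface on observed points."""
    pts = _as_points(points)
    if len(pts) == 0:
        raise ValueError("points must be non-empty")
    pred = np.asarray(surface.predict(pts[:, 0], pts[:, 1]))
    resid = pred - pts[:, 2]
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((pts[:, 2] - pts[:, 2].mean()) ** 2))
    if ss_tot == 0:
        import warnings

        warnings.warn("observed death rates have zero variance; R^2 undefined")
        r2 = None
    else:
        r2 = 1.0 - ss_res / ss_tot
    return FitDiagnostics(
        residual_mean=float(resid.mean() * 100.0),
        residual_sd=float(resid.std(ddof=0) * 100.0),
        r_squared=r2,
    )


def reference_surfaces() -> tuple[Poly2Surface, Poly2Surface]:
    """The published degree-2 reference surfaces for PDT and PTT (in that order)."""
    return Poly2Surface(PDT_REFERENCE_COEFFS), Poly2Surface(PTT_REFERENCE_COEFFS)


def save_surface(surface: ResponseSurface, path) -> None:
    """Serialise a surface to JSON.

    poly2 coefficients round-trip bit-identically; lowess and thinplate store
    their training points and options and are re-fitted deterministically on
    load.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(surface.to_dict(), fh, indent=1)


def surface_from_dict(doc: dict) -> ResponseSurface:
    family = doc["family"]
    pts = np.asarray(doc.get("training_points", []), dtype=float)
    if family == "poly2":
        return Poly2Surface(doc["coeffs"], training_points=pts if pts.size else None)
    if family == "thinplate":
        return ThinPlateSurface(pts)
    if family == "lowess":
        return LowessSurface(pts, span=doc.get("span", 0.28), robust_iters=doc.get("robust_iters", 2))
    raise ValueError(f"unknown family {family!r}")


def load_surface(path) -> ResponseSurface:
    """Load a surface serialised by :func:`save_surface`."""
    with open(path, encoding="utf-8") as fh:
        return surface_from_dict(json.load(fh))
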