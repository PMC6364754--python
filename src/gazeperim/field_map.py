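"""Probability-of-seeing field mapping by ordinary kriging.

Corrected binary responses (hit = 1, miss = 0) at scattered retinal sites are
interpolated into a continuous probability-of-seeing (PoS) surface with
ordinary kriging: the best linear unbiased predictor under a stationary
semivariogram model.  The estimator follows scikit-learn conventions
(``fit(X, y)`` / ``predict(X)``), so it composes with sklearn tooling, and a
convenience layer turns a set of corrected trials into a lattice surface plus
its summary statistic, the Mean Hit Rate.

Notes on the model
------------------
* ``sill`` is the *partial* (structured) sill; the nugget is added on top.
  When ``sill=None`` it is set to the sample variance of the responses.
* A nugget > 0 smooths (the prediction no longer honors each datum exactly);
  nugget = 0 gives exact interpolation at the observation sites.
* Kriging is not range-respecting, so predictions are clamped to [0, 1].
* The surface is only defined inside the convex hull of the observation
  sites; cells outside carry no value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, lu_factor, lu_solve
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .correction import CorrectedTrial
from .errors import KrigingError
from .grid import GridLocation

_VARIOGRAM_MODELS = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class VariogramConfig:
    """Semivariogram family and parameters (degrees / variance units).

    Defaults: exponential model with a 6 deg range (one grid spacing), sill
    tied to the sample variance of the responses, and a small nugget for the
    binomial sampling noise of 4-rep binary data.
    """

    model: str = "exponential"
    range_deg: float = 6.0
    sill: float | None = None
    nugget: float = 0.05

    def __post_init__(self):
        if self.model not in _VARIOGRAM_MODELS:
            raise KrigingError(f"unknown variogram model {self.model!r}")
        if self.range_deg <= 0 or self.nugget < 0:
            raise KrigingError("need range_deg > 0 and nugget >= 0")
        if self.sill is not None and self.sill <= 0:
            raise KrigingError("sill must be positive when given")


def semivariogram(h, model: str, range_deg: float, sill: float, nugget: float):
    """gamma(h) for h >= 0, with gamma(0) = 0 (the nugget is a jump at 0+)."""
    h = np.asarray(h, dtype=float)
    a = range_deg
    if model == "exponential":
        structured = sill * (1.0 - np.exp(-h / a))
    elif model == "gaussian":
        structured = sill * (1.0 - np.exp(-((h / a) ** 2)))
    elif model == "spherical":
        hr = np.minimum(h / a, 1.0)
        structured = sill * (1.5 * hr - 0.5 * hr ** 3)
    else:  # pragma: no cover - guarded by VariogramConfig
        raise KrigingError(f"unknown variogram model {model!r}")
    return np.where(h > 0, nugget + structured, 0.0)


def _merge_colocated(X: np.ndarray, y: np.ndarray, radius: float):
    """Average responses at sites closer than ``radius`` (transitive groups)."""
    if radius <= 0 or len(X) < 2:
        return X, y
    pairs = cKDTree(X).query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return X, y
    parent = np.arange(len(X))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(len(X))])
    Xm, ym = [], []
    for r in np.unique(roots):
        sel = roots == r
        Xm.append(X[sel].mean(axis=0))
        ym.append(y[sel].mean())
    return np.asarray(Xm), np.asarray(ym)


class OrdinaryKrigingPoS(BaseEstimator):
    """Ordinary kriging of binary detection responses on the visual field.

    Parameters
    ----------
    model, range_deg, sill, nugget :
        Semivariogram family and parameters; see :class:`VariogramConfig`.
    merge_radius_deg :
        Observation sites closer than this are merged to their mean response
        before solving (0.25 deg by default), which keeps the kriging system
        well conditioned when co-located binary responses disagree.

    Attributes
    ----------
    sites_ : (n, 2) merged observation coordinates (degrees).
    values_ : (n,) merged responses in [0, 1].
    sill_ : the partial sill actually used.
    hull_ : Delaunay triangulation of the sites (support region), or None
        when the sites are degenerate (collinear).
    """

    def __init__(self, model: str = "exponential", range_deg: float = 6.0,
                 sill: float | None = None, nugget: float = 0.05,
                 merge_radius_deg: float = 0.25):
        self.model = model
        self.range_deg = range_deg
        self.sill = sill
        self.nugget = nugget
        self.merge_radius_deg = merge_radius_deg

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        VariogramConfig(self.model, self.range_deg, self.sill, self.nugget)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise KrigingError(f"X must be (n, 2) site coordinates, got {X.shape}")
        if len(X) != len(y):
            raise KrigingError("X and y length mismatch")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise KrigingError("non-finite site or response values")
        if np.any((y < 0) | (y > 1)):
            raise KrigingError("responses must lie in [0, 1]")

        Xm, ym = _merge_colocated(X, y, self.merge_radius_deg)
        if len(Xm) < 2:
            raise KrigingError("need at least 2 distinct sites after merging")
        self.sites_ = Xm
        self.values_ = ym
        self.constant_ = None

        variance = float(np.var(ym))
        if variance < 1e-12:
            # Constant field: kriging degenerates; predict the constant.
            self.constant_ = float(ym[0])
            self.sill_ = None
            self._lu = None
        else:
            self.sill_ = float(self.sill) if self.sill is not None else variance
            n = len(Xm)
            h = cdist(Xm, Xm)
            A = np.empty((n + 1, n + 1))
            A[:n, :n] = semivariogram(h, self.model, self.range_deg,
                                      self.sill_, self.nugget)
            A[n, :n] = 1.0
            A[:n, n] = 1.0
            A[n, n] = 0.0
            try:
                self._lu = lu_factor(A)
            except LinAlgError as exc:  # pragma: no cover - hard to trigger post-merge
                raise KrigingError(
                    f"singular kriging system for sites {Xm.tolist()}") from exc
            diag = np.abs(np.diag(self._lu[0]))
            if not np.all(np.isfinite(self._lu[0])) or diag.min() < 1e-12 * diag.max():
                raise KrigingError(f"singular kriging system for sites {Xm.tolist()}")

        try:
            self.hull_ = Delaunay(Xm) if len(Xm) >= 3 else None
        except QhullError:
            self.hull_ = None
        return self

    def predict(self, X):
        """Kriged probability of seeing at arbitrary points, clamped to [0, 1]."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.constant_ is not None:
            return np.full(len(X), self.constant_)
        n = len(self.sites_)
        B = np.empty((n + 1, len(X)))
        h = cdist(self.sites_, X)
        # Filtered kriging: the nugget is measurement-error variance, so the
        # right-hand side uses gamma -> nugget as h -> 0 (continuous), which
        # predicts the noise-free field.  With nugget = 0 this reduces to
        # exact interpolation at the observation sites.
        B[:n] = np.where(h > 0,
                         semivariogram(h, self.model, self.range_deg,
                                       self.sill_, self.nugget),
                         self.nugget)
        B[n] = 1.0
        w = lu_solve(self._lu, B)[:n]
        return np.clip(self.values_ @ w, 0.0, 1.0)

    # -- support / surface -------------------------------------------------
    def in_support(self, X) -> np.ndarray:
        """True where points lie inside the convex hull of the sites."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.hull_ is None:
            return np.zeros(len(X), dtype=bool)
        return self.hull_.find_simplex(X) >= 0

    def surface(self, resolution_deg: float = 0.5,
                extent: tuple[float, float, float, float] | None = None) -> "PoSSurface":
        """Render the fitted field to a masked lattice (see :class:`PoSSurface`)."""
        self._check_fitted()
        if resolution_deg <= 0:
            raise KrigingError("resolution_deg must be positive")
        if extent is None:
            (xmin, ymin), (xmax, ymax) = self.sites_.min(0), self.sites_.max(0)
        else:
            xmin, xmax, ymin, ymax = extent
        xs = np.arange(np.floor(xmin / resolution_deg),
                       np.ceil(xmax / resolution_deg) + 1) * resolution_deg
        ys = np.arange(np.floor(ymin / resolution_deg),
                       np.ceil(ymax / resolution_deg) + 1) * resolution_deg
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        mask = self.in_support(pts)
        values = np.full(len(pts), np.nan)
        if mask.any():
            values[mask] = self.predict(pts[mask])
        return PoSSurface(x_deg=xs, y_deg=ys,
                          values=values.reshape(gy.shape),
                          support_mask=mask.reshape(gy.shape),
                          model=self)

    def _check_fitted(self):
        if not hasattr(self, "sites_"):
            raise KrigingError("estimator is not fitted")


@dataclass
class PoSSurface:
    """Probability-of-seeing lattice over retinal degrees.

    ``values`` is (ny, nx) with NaN outside the support (the convex hull of
    the observation sites).  The fitted kriging ``model`` rides along so that
    summary statistics evaluate the field at exact coordinates rather than
    nearest lattice cells.
    """

    x_deg: np.ndarray
    y_deg: np.ndarray
    values: np.ndarray
    support_mask: np.ndarray
    model: OrdinaryKrigingPoS | None = None

    def evaluate(self, points) -> np.ndarray:
        """Exact field values at arbitrary points (NaN outside support)."""
        if self.model is None:
            raise KrigingError("surface carries no fitted model; refit from trials")
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(points), np.nan)
        inside = self.model.in_support(points)
        if inside.any():
            out[inside] = self.model.predict(points[inside])
        return out


def fit_pos_surface(trials: Sequence[CorrectedTrial],
                    vg: VariogramConfig | None = None,
                    resolution_deg: float = 0.5,
                    include_fallback: bool = False) -> PoSSurface:
    """Fit the PoS surface from corrected trials.

    Fallback-corrected trials (no usable gaze near the reference time) are
    excluded by default since their locations are only nominal.
    """
    vg = vg or VariogramConfig()
    used = [t for t in trials if include_fallback or not t.fallback_used]
    if len(used) < 10:
        raise KrigingError(f"need >= 10 usable corrected trials, got {len(used)}")
    X = np.array([[t.true_retinal.x_deg, t.true_retinal.y_deg] for t in used])
    y = np.array([t.response for t in used])
    if len(np.unique(X[:, 0])) < 2 or len(np.unique(X[:, 1])) < 2:
        raise KrigingError("sites must span >= 2 distinct positions per axis")
    model = OrdinaryKrigingPoS(model=vg.model, range_deg=vg.range_deg,
                               sill=vg.sill, nugget=vg.nugget)
    model.fit(X, y)
    return model.surface(resolution_deg=resolution_deg)


def mean_hit_rate(surface: PoSSurface,
                  reference: Sequence[GridLocation | tuple[float, float]]
                  ) -> tuple[float, int]:
    """Unweighted mean of the PoS field at reference locations inside support.

    Evaluates the kriged field at the exact reference coordinates (typically
    the 24-2 lattice) and averages over those inside the support; returns
    ``(mean_hit_rate, n_included)``.
    """
    pts = np.array([(p.x_deg, p.y_deg) if isinstance(p, GridLocation) else tuple(p)
                    for p in reference], dtype=float)
    vals = surface.evaluate(pts)
    included = np.isfinite(vals)
    if not included.any():
        raise KrigingError("no reference locations inside the surface support")
    return float(vals[included].mean()), int(included.sum())
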