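"""Monotone response surface e(d, n) for 2D tuning of translation.

Translational efficiency of an engineered mRNA rises with the distance d
(nt) of the first protein-binding motif from the 5' terminus and falls with
the number n of tandem motif copies.  This module fits a monotone surface to
(d, n, e) observations and inverts it to design constructs that hit a target
efficiency.

Two model forms are available:

* ``saturating_exponential`` (default):
  ``e(d, n) = floor(n) + (e_max - floor(n)) * (1 - exp(-(d - d0)/lambda))``
  with a shared distance scale ``lambda`` and plateau ``e_max`` and a
  per-copy-number floor; the simplest rise-to-plateau form matching the
  observed distance series.
* ``isotonic_grid``: a least-squares fit on the observation grid under the
  two monotonicity constraints (non-decreasing in d, non-increasing in n),
  interpolated bilinearly between grid points.

Queries beyond the largest fitted distance clamp to the plateau; copy
numbers outside the fitted range clamp to the nearest fitted n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

#: distance classes used by the construct library (nt from the 5' terminus)
LIBRARY_DISTANCES = (18, 67, 120, 164, 320)
#: feasible copy numbers for the tandem-motif cassette
LIBRARY_COPIES = (1, 2, 3, 4)
#: smallest achievable distance class; the parametric rise starts here
MIN_DISTANCE = 18.0

#: packaged anchor observations (d, n, e, sd): the measured efficiencies of
#: the K-loop 2D library entries and the kink-turn distance-series endpoints
#: used throughout this package's reproductions.
KL_ANCHORS: tuple[tuple[float, int, float, float], ...] = (
    (18.0, 3, 0.039, 0.013),
    (67.0, 3, 0.15, 0.015),
    (120.0, 1, 0.67, 0.059),
)
KT_ANCHORS: tuple[tuple[float, int, float, float], ...] = (
    (18.0, 1, 0.017, 0.0015),
    (164.0, 1, 0.24, 0.02),
    (320.0, 1, 0.24, 0.02),
)


@dataclass
class ResponseSurface:
    """A fitted monotone map (d, n) -> e for one motif."""

    motif: str = "Kl"
    model_form: str = "saturating_exponential"
    # parametric form
    e_max: float = math.nan
    lam: float = math.nan
    d0: float = MIN_DISTANCE
    floors: dict[int, float] = field(default_factory=dict)  # per-n floor
    # isotonic form
    grid_d: np.ndarray | None = None
    grid_n: np.ndarray | None = None
    grid_e: np.ndarray | None = None  # shape (len(grid_d), len(grid_n))
    fit_residuals: list[float] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        if self.model_form == "saturating_exponential":
            return bool(self.floors) and math.isfinite(self.e_max)
        return self.grid_e is not None

    # ------------------------------------------------------------------

    def predict(self, d: float, n: int) -> float:
        """Monotone prediction of e at distance d (nt) and n copies."""
        if not self.fitted:
            raise ValueError("response surface has not been fitted")
        if d <= 0:
            raise ValueError("distance d must be positive")
        if n < 1:
            raise ValueError("copy number n must be >= 1")
        if self.model_form == "saturating_exponential":
            d_max = max(self.fit_dmax, self.d0)
            d_eff = min(max(float(d), self.d0), d_max)
            floor = self._floor_at(n)
            rise = 1.0 - math.exp(-(d_eff - self.d0) / self.lam)
            return float(floor + (self.e_max - floor) * rise)
        return self._predict_grid(float(d), n)

    @property
    def fit_dmax(self) -> float:
        return getattr(self, "_fit_dmax", max(LIBRARY_DISTANCES))

    def _floor_at(self, n: int) -> float:
        ns = sorted(self.floors)
        if n in self.floors:
            return self.floors[n]
        if n <= ns[0]:
            return self.floors[ns[0]]
        if n >= ns[-1]:
            return self.floors[ns[-1]]
        # linear interpolation between fitted copy numbers (floors are
        # isotonic non-increasing, so interpolation preserves monotonicity)
        lo = max(v for v in ns if v < n)
        hi = min(v for v in ns if v > n)
        w = (n - lo) / (hi - lo)
        return (1 - w) * self.floors[lo] + w * self.floors[hi]

    def _predict_grid(self, d: float, n: int) -> float:
        gd, gn, ge = self.grid_d, self.grid_n, self.grid_e
        d = min(max(d, gd[0]), gd[-1])
        nf = min(max(float(n), gn[0]), gn[-1])
        i = int(np.searchsorted(gd, d, side="right") - 1)
        j = int(np.searchsorted(gn, nf, side="right") - 1)
        i = min(i, len(gd) - 2) if len(gd) > 1 else 0
        j = min(j, len(gn) - 2) if len(gn) > 1 else 0
        if len(gd) == 1 and len(gn) == 1:
            return float(ge[0, 0])
        if len(gd) == 1:
            t = (nf - gn[j]) / (gn[j + 1] - gn[j])
            return float((1 - t) * ge[0, j] + t * ge[0, j + 1])
        if len(gn) == 1:
            s = (d - gd[i]) / (gd[i + 1] - gd[i])
            return float((1 - s) * ge[i, 0] + s * ge[i + 1, 0])
        s = (d - gd[i]) / (gd[i + 1] - gd[i])
        t = (nf - gn[j]) / (gn[j + 1] - gn[j])
        return float((1 - s) * (1 - t) * ge[i, j] + s * (1 - t) * ge[i + 1, j]
                     + (1 - s) * t * ge[i, j + 1] + s * t * ge[i + 1, j + 1])


def _dedupe(observations: Sequence[tuple[float, int, float, float]]
            ) -> tuple[list[tuple[float, int, float, float]], list[str]]:
    """Average duplicate (d, n) observations; weights combine as 1/sd^2."""
    grouped: dict[tuple[float, int], list[tuple[float, float]]] = {}
    for d, n, e, sd in observations:
        if d <= 0:
            raise ValueError(f"non-positive distance {d}")
        if n < 1:
            raise ValueError(f"non-positive copy number {n}")
        grouped.setdefault((float(d), int(n)), []).append((e, sd))
    deduped, warnings = [], []
    for (d, n), vals in grouped.items():
        if len(vals) == 1:
            e, sd = vals[0]
        else:
            w = np.array([1.0 / s ** 2 if s and s > 0 else 1.0
                          for _e, s in vals])
            es = np.array([e for e, _s in vals])
            e = float(np.average(es, weights=w))
            sd = float(np.sqrt(1.0 / w.sum()))
            if es.max() - es.min() > 1e-12:
                warnings.append(
                    f"inconsistent duplicate observations at (d={d:g}, n={n}) "
                    f"averaged to e={e:.4g}"
                )
        deduped.append((d, n, e, sd))
    return deduped, warnings


def fit_surface(observations: Sequence[tuple[float, int, float, float]],
                motif: str = "Kl",
                model_form: str = "saturating_exponential") -> ResponseSurface:
    """Fit a monotone surface to (d, n, e, sd) observations.

    Weighted least squares with 1/sd^2 weights (unweighted when SDs are
    absent or zero).  A single observation yields a constant surface at that
    value.  Duplicate (d, n) points are averaged, with a warning recorded in
    the surface's ``warnings`` attribute.
    """
    if model_form not in ("saturating_exponential", "isotonic_grid"):
        raise ValueError(f"unknown model form {model_form!r}")
    obs, warnings = _dedupe(observations)
    if not obs:
        raise ValueError("no observations to fit")

    if model_form == "isotonic_grid":
        surface = _fit_isotonic(obs, motif)
    elif len(obs) == 1:
        d, n, e, _sd = obs[0]
        surface = ResponseSurface(motif=motif, e_max=e, lam=1.0,
                                  floors={n: e})
        surface._fit_dmax = d
        surface.fit_residuals = [0.0]
    else:
        surface = _fit_parametric(obs, motif)
    surface.warnings = warnings
    return surface


def _fit_parametric(obs: list[tuple[float, int, float, float]],
                    motif: str) -> ResponseSurface:
    d = np.array([o[0] for o in obs])
    n = np.array([o[1] for o in obs])
    e = np.array([o[2] for o in obs])
    sd = np.array([o[3] for o in obs])
    w = np.where(sd > 0, 1.0 / sd, 1.0) if np.all(sd > 0) else np.ones_like(e)
    ns = sorted(set(int(v) for v in n))
    d0 = min(MIN_DISTANCE, float(d.min()))

    e_cap = max(2.0 * e.max(), 1.0)

    def unpack(theta):
        e_max, lam = theta[0], theta[1]
        floors = dict(zip(ns, theta[2:]))
        return e_max, lam, floors

    def resid(theta):
        e_max, lam, floors = unpack(theta)
        pred = np.array([
            floors[int(nv)] + (e_max - floors[int(nv)])
            * (1.0 - math.exp(-(dv - d0) / lam))
            for dv, nv in zip(d, n)
        ])
        return w * (pred - e)

    x0 = [min(max(float(e.max()) * 1.2, 1e-3), e_cap), 60.0]
    x0 += [min(float(e[n == nv].min()), x0[0]) for nv in ns]
    lower = [1e-4, 1.0] + [0.0] * len(ns)
    upper = [e_cap, 2000.0] + [e_cap] * len(ns)
    x0 = np.clip(x0, lower, upper)
    fit = optimize.least_squares(resid, x0, bounds=(lower, upper))
    e_max, lam, floors = unpack(fit.x)

    # enforce monotonicity in n: floors non-increasing with copy number and
    # bounded by the plateau (isotonic projection, preserving order of ns)
    vals = np.minimum([floors[nv] for nv in ns], e_max)
    for i in range(1, len(vals)):  # running minimum over increasing n
        vals[i] = min(vals[i], vals[i - 1])
    floors = dict(zip(ns, (float(v) for v in vals)))

    surface = ResponseSurface(motif=motif, e_max=float(e_max),
                              lam=float(lam), d0=d0, floors=floors)
    surface._fit_dmax = float(d.max())
    surface.fit_residuals = [float(r) for r in resid(fit.x)]
    return surface


def _fit_isotonic(obs: list[tuple[float, int, float, float]],
                  motif: str) -> ResponseSurface:
    """Least-squares grid values under both monotonicity constraints."""
    gd = np.array(sorted({o[0] for o in obs}))
    gn = np.array(sorted({o[1] for o in obs}), dtype=float)
    shape = (len(gd), len(gn))
    target = np.full(shape, np.nan)
    weight = np.zeros(shape)
    for d, n, e, sd in obs:
        i, j = int(np.searchsorted(gd, d)), int(np.searchsorted(gn, n))
        target[i, j] = e
        weight[i, j] = 1.0 / sd ** 2 if sd > 0 else 1.0

    # initial fill of empty cells by nearest observed value
    filled = target.copy()
    if np.isnan(filled).any():
        obs_idx = np.argwhere(~np.isnan(target))
        for idx in np.argwhere(np.isnan(target)):
            k = obs_idx[np.abs(obs_idx - idx).sum(axis=1).argmin()]
            filled[tuple(idx)] = target[tuple(k)]

    mask = ~np.isnan(target)

    def objective(x):
        g = x.reshape(shape)
        return float(((g[mask] - target[mask]) ** 2 * weight[mask]).sum())

    constraints = []
    idx = np.arange(np.prod(shape)).reshape(shape)
    for j in range(shape[1]):
        for i in range(shape[0] - 1):  # non-decreasing in d
            a, b = idx[i, j], idx[i + 1, j]
            constraints.append({"type": "ineq",
                                "fun": (lambda x, a=a, b=b: x[b] - x[a])})
    for i in range(shape[0]):
        for j in range(shape[1] - 1):  # non-increasing in n
            a, b = idx[i, j], idx[i, j + 1]
            constraints.append({"type": "ineq",
                                "fun": (lambda x, a=a, b=b: x[a] - x[b])})

    res = optimize.minimize(objective, filled.ravel(), method="SLSQP",
                            constraints=constraints,
                            options={"maxiter": 500, "ftol": 1e-12})
    grid = res.x.reshape(shape)
    # numerical cleanup: project tiny constraint violations away
    for j in range(shape[1]):
        grid[:, j] = np.maximum.accumulate(grid[:, j])
    for i in range(shape[0]):
        grid[i, :] = np.minimum.accumulate(grid[i, :])

    surface = ResponseSurface(motif=motif, model_form="isotonic_grid",
                              grid_d=gd, grid_n=gn, grid_e=grid)
    surface.fit_residuals = [float(v) for v in (grid[mask] - target[mask])]
    return surface


def predict_efficiency(surface: ResponseSurface, d: float, n: int) -> float:
    """Predict e at distance d (nt, >0) and copy number n (>=1)."""
    return surface.predict(d, n)


@dataclass(frozen=True)
class DesignCandidate:
    motif: str
    distance_nt: float
    copies: int
    predicted_e: float


@dataclass
class DesignResult:
    """Ranked feasible designs for a target efficiency.

    Empty ``candidates`` means the target is infeasible within tolerance;
    ``nearest`` then holds the closest achievable design.
    """

    target: float
    tolerance: float
    candidates: list[DesignCandidate]
    nearest: DesignCandidate | None = None


def design_for_target(surface: ResponseSurface, e_target: float,
                      tolerance: float,
                      extra_distances: Sequence[float] = (),
                      copies: Sequence[int] = LIBRARY_COPIES) -> DesignResult:
    """Invert the surface: find (motif, d, n) designs near a target e.

    The design grid is the library distance classes (plus any user-supplied
    distances) crossed with the feasible copy numbers.  Candidates with
    |predicted - target| <= tolerance are ranked by closeness; if none
    qualify, the nearest achievable design is reported instead.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    grid_d = sorted(set(LIBRARY_DISTANCES) | set(extra_distances))
    scored = []
    for d in grid_d:
        for n in copies:
            pred = surface.predict(d, n)
            scored.append((abs(pred - e_target),
                           DesignCandidate(surface.motif, float(d), int(n),
                                           pred)))
    scored.sort(key=lambda t: (t[0], t[1].distance_nt, t[1].copies))
    candidates = [c for gap, c in scored if gap <= tolerance]
    nearest = scored[0][1] if not candidates else None
    return DesignResult(target=e_target, tolerance=tolerance,
                        candidates=candidates, nearest=nearest)
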