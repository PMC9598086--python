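"""3D second-order summary statistics (K, G, F, pair correlation), their
square-root transforms, and Monte Carlo CSR envelopes.

Estimators follow the translation edge correction for K and the pair
correlation, and border / Kaplan-Meier corrections for the distance-based
G and F functions. Normalization uses n(n-1)/|W|^2 for the squared
intensity, which is unbiased for binomial (fixed-n) patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EstimatorError, ValidationError

FUNCTIONS = ("K", "F", "G", "pcf")


@dataclass(frozen=True)
class Box3Window:
    """Axis-aligned box observation window, mm."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        if np.any(hi <= lo):
            raise ValidationError("window needs positive extent on all axes")

    @classmethod
    def unit(cls) -> "Box3Window":
        return cls((0.0, 0.0, 0.0), (1.0, 1.0, 1.0))

    @classmethod
    def from_points(cls, points: np.ndarray, pad: float = 1.0) -> "Box3Window":
        pts = np.asarray(points, float).reshape(-1, 3)
        return cls(tuple(pts.min(axis=0) - pad), tuple(pts.max(axis=0) + pad))

    @property
    def sides(self) -> np.ndarray:
        return np.asarray(self.hi, float) - np.asarray(self.lo, float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.sides))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 3)
        return np.all((pts >= self.lo) & (pts <= self.hi), axis=1)

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 3)
        return np.minimum(pts - self.lo, np.asarray(self.hi) - pts).min(axis=1)


@dataclass
class FunctionEstimate:
    function: str  # K | F | G | pcf
    r: np.ndarray
    estimate: np.ndarray
    theoretical: np.ndarray
    correction: str
    n_points: int
    sqrt_applied: bool = False


@dataclass
class EnvelopeResult:
    observed: FunctionEstimate
    lo: np.ndarray
    hi: np.ndarray
    nsim: int
    rank: int
    seed: int | None = None
    simulated: np.ndarray | None = field(default=None, repr=False)


def default_r_grid(window: Box3Window, n: int = 128, *, exclude_zero: bool = False) -> np.ndarray:
    """128 radii from 0 to one quarter of the shortest window side."""
    rmax = window.sides.min() / 4.0
    grid = np.linspace(0.0, rmax, n + 1)
    return grid[1:] if exclude_zero else grid[: n]


def _check_points(points: np.ndarray, window: Box3Window, min_n: int) -> np.ndarray:
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < min_n:
        raise EstimatorError(f"needs >= {min_n} points, got {len(pts)}")
    if len(pts) and not window.contains(pts).all():
        raise EstimatorError("point outside the observation window")
    return pts


def _pair_dist_weights(pts: np.ndarray, window: Box3Window) -> tuple[np.ndarray, np.ndarray]:
    """Unordered-pair distances, doubled translation weights e_ij (both
    ordered pairs folded into one entry)."""
    diff = np.abs(pts[:, None, :] - pts[None, :, :])
    d = np.sqrt((diff ** 2).sum(axis=2))
    denom = np.prod(window.sides - diff, axis=2)
    iu = np.triu_indices(len(pts), k=1)
    e = window.volume / denom[iu]
    return d[iu], 2.0 * e


def k3est(
    points: np.ndarray,
    window: Box3Window,
    r_grid: np.ndarray | None = None,
) -> FunctionEstimate:
    """Ripley K in 3D with translation edge correction."""
    pts = _check_points(points, window, 2)
    if r_grid is None:
        r_grid = default_r_grid(window)
    r_grid = np.asarray(r_grid, float)
    n = len(pts)
    d, w = _pair_dist_weights(pts, window)
    order = np.argsort(d)
    d_sorted, cumw = d[order], np.cumsum(w[order])
    idx = np.searchsorted(d_sorted, r_grid, side="right")
    khat = np.where(idx > 0, np.concatenate([[0.0], cumw])[idx], 0.0)
    khat *= window.volume / (n * (n - 1))
    return FunctionEstimate(
        function="K",
        r=r_grid,
        estimate=khat,
        theoretical=(4.0 / 3.0) * np.pi * r_grid ** 3,
        correction="translation",
        n_points=n,
    )


def _km_curve(r_grid: np.ndarray, dist: np.ndarray, bdist: np.ndarray) -> np.ndarray:
    """Kaplan-Meier estimate of P(D <= r) with censoring at the boundary
    distance (product-limit over observed events)."""
    times = np.minimum(dist, bdist)
    events = dist <= bdist
    order = np.argsort(times)
    times, events = times[order], events[order]
    n = len(times)
    at_risk = n - np.arange(n)
    factors = np.where(events, 1.0 - 1.0 / at_risk, 1.0)
    surv = np.cumprod(factors)
    idx = np.searchsorted(times, r_grid, side="right")
    s = np.where(idx > 0, np.concatenate([[1.0], surv])[idx], 1.0)
    return 1.0 - s


def _border_curve(r_grid: np.ndarray, dist: np.ndarray, bdist: np.ndarray) -> np.ndarray:
    est = np.full(len(r_grid), np.nan)
    for k, r in enumerate(r_grid):
        eligible = bdist > r
        denom = int(eligible.sum())
        if denom:  # denominator 0 -> missing, not 0
            est[k] = (dist[eligible] <= r).sum() / denom
    # reduced-sample ratios can dip; report the running max (still in [0, 1])
    valid = ~np.isnan(est)
    if valid.any():
        est[valid] = np.maximum.accumulate(est[valid])
    return est


def g3est(
    points: np.ndarray,
    window: Box3Window,
    r_grid: np.ndarray | None = None,
    correction: str = "border",
) -> FunctionEstimate:
    """Nearest-neighbour distance distribution G with border or
    Kaplan-Meier edge correction."""
    pts = _check_points(points, window, 2)
    if r_grid is None:
        r_grid = default_r_grid(window)
    r_grid = np.asarray(r_grid, float)
    if correction not in ("border", "km"):
        raise ValidationError("correction must be 'border' or 'km'")
    tree = cKDTree(pts)
    nn_dist = tree.query(pts, k=2)[0][:, 1]
    bdist = window.boundary_distance(pts)
    curve = (_border_curve if correction == "border" else _km_curve)(
        r_grid, nn_dist, bdist
    )
    lam = len(pts) / window.volume
    return FunctionEstimate(
        function="G",
        r=r_grid,
        estimate=curve,
        theoretical=1.0 - np.exp(-lam * (4.0 / 3.0) * np.pi * r_grid ** 3),
        correction=correction,
        n_points=len(pts),
    )


def f3est(
    points: np.ndarray,
    window: Box3Window,
    r_grid: np.ndarray | None = None,
    grid_spacing: float | None = None,
    correction: str = "border",
) -> FunctionEstimate:
    """Empty-space function F from a regular lattice of test locations."""
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) and not window.contains(pts).all():
        raise EstimatorError("point outside the observation window")
    if r_grid is None:
        r_grid = default_r_grid(window)
    r_grid = np.asarray(r_grid, float)
    if grid_spacing is None:
        grid_spacing = window.sides.min() / 32.0
    axes = [
        np.arange(lo + grid_spacing / 2.0, hi, grid_spacing)
        for lo, hi in zip(window.lo, window.hi)
    ]
    test = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(pts):
        dist = cKDTree(pts).query(test)[0]
    else:
        dist = np.full(len(test), np.inf)
    bdist = window.boundary_distance(test)
    curve = (_border_curve if correction == "border" else _km_curve)(r_grid, dist, bdist)
    if len(pts) == 0:
        curve = np.where(np.isnan(curve), 0.0, curve)
    lam = len(pts) / window.volume
    return FunctionEstimate(
        function="F",
        r=r_grid,
        estimate=curve,
        theoretical=1.0 - np.exp(-lam * (4.0 / 3.0) * np.pi * r_grid ** 3),
        correction=correction,
        n_points=len(pts),
    )


def epanechnikov(t: np.ndarray, h: float) -> np.ndarray:
    """Epanechnikov kernel with half-width h; integrates to 1."""
    u = np.asarray(t, float) / h
    return np.where(np.abs(u) <= 1.0, 0.75 / h * (1.0 - u ** 2), 0.0)


def stoyan_bandwidth(n: int, volume: float) -> float:
    """Stoyan's rule of thumb h = 0.26 / intensity^(1/3)."""
    return 0.26 * (n / volume) ** (-1.0 / 3.0)


def pcf3est(
    points: np.ndarray,
    window: Box3Window,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> FunctionEstimate:
    """Pair correlation function with Epanechnikov kernel and translation
    edge correction."""
    pts = _check_points(points, window, 2)
    if r_grid is None:
        r_grid = default_r_grid(window, exclude_zero=True)
    r_grid = np.asarray(r_grid, float)
    if np.any(r_grid <= 0.0):
        raise EstimatorError("pcf r grid must exclude 0")
    n = len(pts)
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(n, window.volume)
    d, w = _pair_dist_weights(pts, window)
    kern = epanechnikov(r_grid[:, None] - d[None, :], bandwidth)
    ghat = (kern * w[None, :]).sum(axis=1)
    ghat *= window.volume / (n * (n - 1)) / (4.0 * np.pi * r_grid ** 2)
    return FunctionEstimate(
        function="pcf",
        r=r_grid,
        estimate=ghat,
        theoretical=np.ones_like(r_grid),
        correction="translation",
        n_points=n,
    )


def sqrt_version(fe: FunctionEstimate) -> FunctionEstimate:
    """Element-wise square root of a K/F/G estimate (variance stabilizing)."""
    if fe.function not in ("K", "F", "G"):
        raise ValidationError(f"sqrt version undefined for {fe.function}")
    if fe.sqrt_applied:
        raise ValidationError("sqrt already applied")
    return replace(
        fe,
        estimate=np.sqrt(fe.estimate),
        theoretical=np.sqrt(fe.theoretical),
        sqrt_applied=True,
    )


_ESTIMATORS: dict[str, Callable] = {
    "K": k3est,
    "G": g3est,
    "F": f3est,
    "pcf": pcf3est,
}


def estimate_function(
    function: str,
    points: np.ndarray,
    window: Box3Window,
    r_grid: np.ndarray | None = None,
    **kwargs,
) -> FunctionEstimate:
    if function not in _ESTIMATORS:
        raise ValidationError(f"unknown function {function!r}; valid: {FUNCTIONS}")
    return _ESTIMATORS[function](points, window, r_grid, **kwargs)


def csr_envelope(
    points: np.ndarray,
    window: Box3Window,
    function: str = "K",
    nsim: int = 500,
    rank: int = 1,
    seed: int | None = None,
    r_grid: np.ndarray | None = None,
    apply_sqrt: bool = False,
    keep_simulations: bool = False,
    **kwargs,
) -> EnvelopeResult:
    """Pointwise rank envelopes from ``nsim`` binomial CSR simulations
    conditioned on the observed point count."""
    if nsim < 3:
        raise ValidationError("nsim must be >= 3")
    if not (1 <= rank <= nsim // 2):
        raise ValidationError("rank must satisfy 1 <= rank <= nsim/2")
    pts = np.asarray(points, float).reshape(-1, 3)
    if r_grid is None:
        r_grid = default_r_grid(window, exclude_zero=(function == "pcf"))
    observed = estimate_function(function, pts, window, r_grid, **kwargs)
    if apply_sqrt:
        observed = sqrt_version(observed)
    rng = np.random.default_rng(seed)
    n = len(pts)
    lo_hi = np.empty((nsim, len(r_grid)))
    for s in range(nsim):
        sim = rng.uniform(window.lo, window.hi, size=(n, 3))
        fe = estimate_function(function, sim, window, r_grid, **kwargs)
        lo_hi[s] = np.sqrt(fe.estimate) if apply_sqrt else fe.estimate
    sims_sorted = np.sort(lo_hi, axis=0)
    return EnvelopeResult(
        observed=observed,
        lo=sims_sorted[rank - 1],
        hi=sims_sorted[nsim - rank],
        nsim=nsim,
        rank=rank,
        seed=seed,
        simulated=lo_hi if keep_simulations else None,
    )
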