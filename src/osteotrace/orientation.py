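"""Circular statistics for tooth-score orientations relative to the bone's
principal longitudinal axis.

Orientations are axial (defined modulo 180 degrees), so every moment is
computed on doubled angles; descriptive statistics follow Fisher's
standardized circular definitions. The Rayleigh uniformity test uses the
classical series tail approximation, two-sample comparison is a randomized
Mardia-Watson-Wheeler test on uniform scores, and the false positive risk
converts a p-value through the -e*p*ln(p) minimum-Bayes-factor bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import rankdata

from .core import BoneTemplate, MarkRecord
from .errors import DegenerateCloudError, ValidationError


@dataclass
class OrientationSample:
    angles: np.ndarray  # degrees, axial, in [0, 180)
    element: str = ""
    side: str = ""
    context: str = ""

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) and (
            self.angles.min() < 0.0 or self.angles.max() >= 180.0
        ):
            raise ValidationError("axial angles must lie in [0, 180)")

    @property
    def n(self) -> int:
        return len(self.angles)


@dataclass
class CircularSummary:
    n: int
    rbar: float
    variance: float
    dispersion: float
    skewness: float
    kurtosis: float
    central_deg: tuple[float, float]  # pair 180 degrees apart
    central_rad: tuple[float, float]


@dataclass
class TestResult:
    method: str  # rayleigh | mww | fpr
    statistic: float
    p: float
    n_rand: int | None = None
    seed: int | None = None
    details: dict[str, Any] = field(default_factory=dict)


def principal_axis(
    template: BoneTemplate | np.ndarray, axis_ratio_min: float = 1.5
) -> np.ndarray:
    """Unit eigenvector of the point covariance with the largest eigenvalue,
    with a deterministic sign convention."""
    pts = template.points if isinstance(template, BoneTemplate) else np.asarray(template, float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 0 or evals[0] / evals[1] < axis_ratio_min:
        raise DegenerateCloudError("no dominant axis")
    axis = evecs[:, 0]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def score_angle(
    score: MarkRecord, axis: np.ndarray, normal: np.ndarray | None = None
) -> float:
    """Axial angle (degrees) between the score's endpoint vector and the
    axis, invariant to endpoint order and to joint rotation.

    Without a surface normal the unsigned 3D angle arccos(|d . a|) in
    [0, 90] is returned. With a normal the angle is signed within the local
    tangent plane, giving the full axial range [0, 180)."""
    if score.endpoints is None:
        raise ValidationError("punctual mark has no orientation")
    d = score.endpoints[1] - score.endpoints[0]
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    if normal is None:
        cosang = abs(d @ a) / np.linalg.norm(d)
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    u = a - (a @ n) * n  # axis projected into the tangent plane
    if np.linalg.norm(u) < 1e-9:
        cosang = abs(d @ a) / np.linalg.norm(d)
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    du, dv = d @ u, d @ v
    if du < 0 or (du == 0 and dv < 0):  # canonical axial direction
        du, dv = -du, -dv
    return float(np.degrees(np.arctan2(dv, du)) % 180.0)


def circular_summary(sample: OrientationSample) -> CircularSummary:
    """Descriptive circular moments of an axial sample (angle doubling)."""
    if sample.n < 2:
        raise ValidationError("need n >= 2")
    theta = 2.0 * np.deg2rad(sample.angles)
    c1, s1 = np.cos(theta).mean(), np.sin(theta).mean()
    rbar = float(np.hypot(c1, s1))
    mu = float(np.arctan2(s1, c1))
    c2, s2 = np.cos(2.0 * theta).mean(), np.sin(2.0 * theta).mean()
    rho2 = float(np.hypot(c2, s2))
    mu2 = float(np.arctan2(s2, c2))
    variance = 1.0 - rbar
    if variance < 1e-12:
        dispersion = skewness = kurtosis = float("nan")
    else:
        dispersion = (1.0 - rho2) / (2.0 * rbar ** 2)
        skewness = rho2 * np.sin(mu2 - 2.0 * mu) / variance ** 1.5
        kurtosis = (rho2 * np.cos(mu2 - 2.0 * mu) - rbar ** 4) / variance ** 2
    half_deg = np.degrees(mu) / 2.0  # in (-90, 90]
    central_deg = (half_deg, half_deg - 180.0)
    central_rad = (np.deg2rad(central_deg[0]), np.deg2rad(central_deg[1]))
    return CircularSummary(
        n=sample.n,
        rbar=rbar,
        variance=float(variance),
        dispersion=float(dispersion),
        skewness=float(skewness),
        kurtosis=float(kurtosis),
        central_deg=(float(central_deg[0]), float(central_deg[1])),
        central_rad=(float(central_rad[0]), float(central_rad[1])),
    )


def rayleigh_p(rbar: float, n: int) -> float:
    """Series tail approximation of the Rayleigh uniformity p-value.

    p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)],
    Z = n rbar^2. Falls back to exp(-Z) when the bracketed factor is not
    positive (the series breaks down); result clipped to [0, 1].
    """
    z = n * rbar * rbar
    bracket = (
        1.0
        + (2.0 * z - z ** 2) / (4.0 * n)
        - (24.0 * z - 132.0 * z ** 2 + 76.0 * z ** 3 - 9.0 * z ** 4) / (288.0 * n ** 2)
    )
    p = np.exp(-z) * bracket if bracket > 0.0 else np.exp(-z)
    return float(min(max(p, 0.0), 1.0))


def rayleigh_test(
    sample: OrientationSample | None = None,
    rbar: float | None = None,
    n: int | None = None,
) -> TestResult:
    """Rayleigh uniformity test on doubled axial angles, or directly on a
    supplied (rbar, n) pair; statistic reported is rbar."""
    if sample is not None:
        if sample.n < 4:
            raise ValidationError("need n >= 4")
        theta = 2.0 * np.deg2rad(sample.angles)
        rbar = float(np.hypot(np.cos(theta).mean(), np.sin(theta).mean()))
        n = sample.n
    if rbar is None or n is None:
        raise ValidationError("supply a sample or both rbar and n")
    if not (0.0 <= rbar <= 1.0):
        raise ValidationError("rbar must lie in [0, 1]")
    if n < 4:
        raise ValidationError("need n >= 4")
    return TestResult(
        method="rayleigh",
        statistic=float(rbar),
        p=rayleigh_p(rbar, n),
        details={"Z": n * rbar * rbar, "n": n},
    )


def _mww_statistic(cos_b: np.ndarray, sin_b: np.ndarray, in_a: np.ndarray) -> float:
    na = int(in_a.sum())
    nb = len(cos_b) - na
    ca, sa = cos_b[in_a].sum(), sin_b[in_a].sum()
    cb, sb = cos_b.sum() - ca, sin_b.sum() - sa
    return 2.0 * ((ca ** 2 + sa ** 2) / na + (cb ** 2 + sb ** 2) / nb)


def mww_test(
    a: OrientationSample,
    b: OrientationSample,
    n_rand: int = 9999,
    seed: int | None = None,
) -> TestResult:
    """Randomized Mardia-Watson-Wheeler test on uniform scores.

    Pooled angles are rank-mapped to beta = 2*pi*rank/N; the statistic
    W = 2 * sum_groups (C_g^2 + S_g^2)/n_g is compared against n_rand label
    shuffles with plus-one correction. Ties get midranks with a warning.
    """
    if a.n < 4 or b.n < 4:
        raise ValidationError("each sample needs n >= 4")
    pooled = np.concatenate([a.angles, b.angles])
    n_total = len(pooled)
    ranks = rankdata(pooled, method="average")
    if len(np.unique(pooled)) < n_total:
        warnings.warn("ties present; using midranks")
    beta = 2.0 * np.pi * ranks / n_total
    cos_b, sin_b = np.cos(beta), np.sin(beta)
    in_a = np.zeros(n_total, dtype=bool)
    in_a[: a.n] = True
    w_obs = _mww_statistic(cos_b, sin_b, in_a)

    rng = np.random.default_rng(seed)
    # vectorized label shuffles: the first a.n entries of each permuted order
    order = np.argsort(rng.random((n_rand, n_total)), axis=1)
    sel = order[:, : a.n]
    ca, sa = cos_b[sel].sum(axis=1), sin_b[sel].sum(axis=1)
    cb, sb = cos_b.sum() - ca, sin_b.sum() - sa
    w_perm = 2.0 * ((ca ** 2 + sa ** 2) / a.n + (cb ** 2 + sb ** 2) / b.n)
    p = (1.0 + (w_perm >= w_obs - 1e-12).sum()) / (n_rand + 1.0)
    return TestResult(
        method="mww",
        statistic=float(w_obs),
        p=float(p),
        n_rand=n_rand,
        seed=seed,
        details={"n_a": a.n, "n_b": b.n},
    )


def false_positive_risk(p: float, prior_h1: float = 0.5) -> TestResult:
    """Minimum-Bayes-factor bound on the false positive risk.

    BF = -e * p * ln(p), valid on 0 < p < 1/e;
    FPR = (1 - prior) * BF / ((1 - prior) * BF + prior).
    """
    if not (0.0 < p < 1.0):
        raise ValidationError("p must lie in (0, 1)")
    if not (0.0 < prior_h1 < 1.0):
        raise ValidationError("prior must lie in (0, 1)")
    if p >= 1.0 / np.e:
        return TestResult(
            method="fpr", statistic=float("nan"), p=p,
            details={"note": "bound not informative for p >= 1/e"},
        )
    bf = -np.e * p * np.log(p)
    fpr = (1.0 - prior_h1) * bf / ((1.0 - prior_h1) * bf + prior_h1)
    return TestResult(
        method="fpr", statistic=float(fpr), p=p,
        details={"bayes_factor": float(bf), "prior_h1": prior_h1},
    )


def rose_histogram(sample: OrientationSample, n_sectors: int = 36) -> np.ndarray:
    """Sector counts over [0, 360) with each axial angle duplicated at
    theta and theta + 180; counts sum to 2n."""
    if sample.n < 1:
        raise ValidationError("need n >= 1")
    if n_sectors < 2 or n_sectors % 2:
        raise ValidationError("n_sectors must be an even integer >= 2")
    width = 360.0 / n_sectors
    counts = np.zeros(n_sectors, dtype=np.int64)
    for theta in sample.angles:
        for t in (theta, theta + 180.0):
            counts[int(t // width) % n_sectors] += 1
    return counts


def radial_normal(
    midpoint: np.ndarray, axis: np.ndarray, centroid: np.ndarray
) -> np.ndarray | None:
    """Outward surface normal approximated by the component of the midpoint
    offset perpendicular to the long axis (exact for tubular shafts)."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    rad = np.asarray(midpoint, float) - np.asarray(centroid, float)
    rad = rad - (rad @ a) * a
    norm = np.linalg.norm(rad)
    if norm < 1e-9:
        return None
    return rad / norm


def scores_to_sample(
    scores: list[MarkRecord],
    template: BoneTemplate,
    *,
    element: str = "",
    side: str = "",
    context: str = "",
) -> OrientationSample:
    """Angles of linear marks against the template's principal axis, signed
    within the local tangent plane (radial-normal approximation)."""
    axis = principal_axis(template)
    centroid = template.points.mean(axis=0)
    angles = [
        score_angle(s, axis, radial_normal(s.position, axis, centroid))
        for s in scores
        if s.endpoints is not None
    ]
    return OrientationSample(
        angles=np.asarray(angles), element=element, side=side, context=context
    )
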