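"""Triangular death-probability distributions.

Death probabilities are modelled as triangular distributions Δ(min; max; mode)
on [0, 1], defined by their minimum, maximum and most likely value (mode).
The mean is (min + max + mode) / 3.  Comorbidity-specific distributions are
derived from a baseline distribution by applying a relative death risk (an
odds or hazard ratio treated as a multiplicative factor on the mean).

The overlap fraction of two densities — the integral of their pointwise
minimum — quantifies how much the death-probability distributions of two
patient groups share support.  Both densities integrate to one, so the value
is the shared-area fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "TriangularParams",
    "RiskScaling",
    "InvalidTriangleError",
    "InfeasibleScalingError",
    "triangular_mean",
    "triangular_pdf",
    "triangular_cdf",
    "triangular_ppf",
    "sample_triangular",
    "overlap_fraction",
    "scale_by_relative_risk",
]


class InvalidTriangleError(ValueError):
    """Raised when (minimum, maximum, mode) do not define a valid triangle on [0, 1]."""


class InfeasibleScalingError(ValueError):
    """Raised when a relative risk cannot be applied without leaving [0, 1]."""


@dataclass(frozen=True)
class TriangularParams:
    """Parameters of a triangular distribution Δ(min; max; mode) on [0, 1].

    The field order mirrors the Δ(min; max; mode) notation: minimum first,
    then maximum, then mode.  A degenerate triangle with minimum == maximum
    is a point mass and is allowed.
    """

    minimum: float
    maximum: float
    mode: float

    def __post_init__(self) -> None:
        a, b, c = self.minimum, self.maximum, self.mode
        if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(c)):
            raise InvalidTriangleError(f"non-finite triangle parameters {(a, b, c)}")
        if not (0.0 <= a <= c <= b <= 1.0):
            raise InvalidTriangleError(
                f"need 0 <= minimum <= mode <= maximum <= 1, got "
                f"(min={a}, max={b}, mode={c})"
            )

    @property
    def mean(self) -> float:
        return (self.minimum + self.maximum + self.mode) / 3.0

    @property
    def is_degenerate(self) -> bool:
        return self.minimum == self.maximum

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.minimum, self.maximum, self.mode)


@dataclass(frozen=True)
class RiskScaling:
    """How a relative death risk maps the baseline triangle to a comorbid one.

    method 'translate' shifts all three vertices by mean*(rr - 1), which
    preserves the shape and scales the mean exactly.  'translate_widen'
    additionally moves the minimum down and the maximum up by ``widen``
    (symmetric, so the mean is unchanged).  'explicit' ignores the derivation
    and uses a user-supplied triple (the relative risk is kept for reporting).
    """

    relative_risk: float
    method: str = "translate"
    explicit: Optional[TriangularParams] = None
    widen: float = 0.0

    _METHODS = ("translate", "translate_widen", "explicit")

    def __post_init__(self) -> None:
        if not self.relative_risk > 0:
            raise ValueError(f"relative_risk must be > 0, got {self.relative_risk}")
        if self.method not in self._METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        if self.method == "explicit" and self.explicit is None:
            raise ValueError("method 'explicit' requires an explicit TriangularParams")
        if self.widen < 0:
            raise ValueError("widen must be >= 0")


def triangular_mean(params: TriangularParams) -> float:
    """Mean (min + max + mode) / 3 of a triangular distribution."""
    return params.mean


def triangular_pdf(x, params: TriangularParams) -> np.ndarray:
    """Density of Δ(min; max; mode), vectorized over x.

    A point mass (minimum == maximum) has no density; all zeros are returned.
    """
    a, b, c = params.minimum, params.maximum, params.mode
    x = np.asarray(x, dtype=float)
    f = np.zeros_like(x)
    if a == b:
        return f
    if c > a and (b - a) * (c - a) > 0.0:
        rising = (x >= a) & (x <= c)
        f[rising] = 2.0 * (x[rising] - a) / ((b - a) * (c - a))
    if b > c and (b - a) * (b - c) > 0.0:
        falling = (x > c) & (x <= b)
        f[falling] = 2.0 * (b - x[falling]) / ((b - a) * (b - c))
    return f


def triangular_cdf(x, params: TriangularParams) -> np.ndarray:
    a, b, c = params.minimum, params.maximum, params.mode
    x = np.asarray(x, dtype=float)
    if a == b:
        return (x >= a).astype(float)
    F = np.zeros_like(x)
    if c > a:
        rising = (x > a) & (x <= c)
        F[rising] = (x[rising] - a) ** 2 / ((b - a) * (c - a))
    if b > c:
        falling = (x > c) & (x < b)
        F[falling] = 1.0 - (b - x[falling]) ** 2 / ((b - a) * (b - c))
    if a < c:
        F[x == c] = (c - a) / (b - a)
    F[x >= b] = 1.0
    return F


def triangular_ppf(u, params: TriangularParams) -> np.ndarray:
    """Inverse CDF; maps one uniform draw on [0, 1) to one triangular draw.

    Implemented in closed form so that exactly one uniform is consumed per
    draw (the patient-level draw-order contract relies on this) and so that
    degenerate point masses are handled.
    """
    a, b, c = params.minimum, params.maximum, params.mode
    u = np.asarray(u, dtype=float)
    if a == b:
        return np.full_like(u, a)
    fc = (c - a) / (b - a)
    low = u < fc
    x = np.empty_like(u)
    x[low] = a + np.sqrt(u[low] * (b - a) * (c - a))
    x[~low] = b - np.sqrt((1.0 - u[~low]) * (b - a) * (b - c))
    return x


def triangular_ppf_arrays(u: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized inverse CDF with per-element (min, max, mode) arrays."""
    u = np.asarray(u, dtype=float)
    width = b - a
    degenerate = width <= 0.0
    safe_width = np.where(degenerate, 1.0, width)
    fc = np.where(degenerate, 1.0, (c - a) / safe_width)
    low = u < fc
    x = np.where(
        low,
        a + np.sqrt(np.maximum(u, 0.0) * width * (c - a)),
        b - np.sqrt(np.maximum(1.0 - u, 0.0) * width * (b - c)),
    )
    return np.where(degenerate, a, x)


def sample_triangular(
    params: TriangularParams, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` death probabilities from Δ(min; max; mode).

    Reproducible: the same seeded generator yields the same sequence.  Each
    draw consumes exactly one uniform.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    return triangular_ppf(rng.random(count), params)


def _linear_pieces(params: TriangularParams) -> list[tuple[float, float, float, float]]:
    """The density as line segments (x0, x1, slope, intercept), f(x) = slope*x + intercept."""
    a, b, c = params.minimum, params.maximum, params.mode
    pieces = []
    # products can underflow to 0 for denormal-width pieces; treat as empty
    if c > a and (b - a) * (c - a) > 0.0:
        m = 2.0 / ((b - a) * (c - a))
        pieces.append((a, c, m, -m * a))
    if b > c and (b - a) * (b - c) > 0.0:
        m = -2.0 / ((b - a) * (b - c))
        pieces.append((c, b, m, -m * b))
    return pieces


def overlap_fraction(p1: TriangularParams, p2: TriangularParams) -> float:
    """Shared-area fraction of two triangular densities.

    Computed exactly: the pointwise minimum of two piecewise-linear unit-area
    densities is itself piecewise linear once every vertex and every pairwise
    segment intersection is a breakpoint, so the trapezoid rule over those
    breakpoints integrates it without error.

    Point masses are treated as limits: two identical point masses overlap
    fully; a point mass against anything else shares zero area.
    """
    if p1.is_degenerate or p2.is_degenerate:
        return 1.0 if p1.as_tuple() == p2.as_tuple() else 0.0

    lo = max(p1.minimum, p2.minimum)
    hi = min(p1.maximum, p2.maximum)
    if hi <= lo:
        return 0.0

    points = {lo, hi}
    for v in (p1.mode, p2.mode, p1.minimum, p2.minimum, p1.maximum, p2.maximum):
        if lo < v < hi:
            points.add(v)
    for x0, x1, m1, q1 in _linear_pieces(p1):
        for y0, y1, m2, q2 in _linear_pieces(p2):
            if m1 == m2:
                continue
            xc = (q2 - q1) / (m1 - m2)
            if max(x0, y0, lo) < xc < min(x1, y1, hi):
                points.add(xc)

    xs = np.array(sorted(points))
    f1 = triangular_pdf(xs, p1)
    f2 = triangular_pdf(xs, p2)
    g = np.minimum(f1, f2)
    area = float(np.trapezoid(g, xs))
    return min(max(area, 0.0), 1.0)


def scale_by_relative_risk(
    base: TriangularParams, scaling: RiskScaling
) -> TriangularParams:
    """Derive a comorbidity-specific triangle from the baseline.

    The returned triangle's mean equals relative_risk * mean(base) (methods
    'translate' and 'translate_widen'), or is the supplied explicit triple.
    If translation pushes a vertex outside [0, 1] the support is clamped and
    the excess is redistributed equally over the two remaining vertices so
    the target mean is preserved; if no valid triangle can achieve the target
    mean an :class:`InfeasibleScalingError` is raised.
    """
    if scaling.method == "explicit":
        assert scaling.explicit is not None
        return scaling.explicit

    target = scaling.relative_risk * base.mean
    if target > 1.0 + 1e-12:
        raise InfeasibleScalingError(
            f"target mean {target:.4f} = {scaling.relative_risk} * {base.mean:.4f} exceeds 1"
        )
    shift = base.mean * (scaling.relative_risk - 1.0)
    a = base.minimum + shift
    b = base.maximum + shift
    c = base.mode + shift
    if scaling.method == "translate_widen":
        a -= scaling.widen
        b += scaling.widen

    # Clamp to [0, 1], redistributing the clipped mass to keep the mean exact.
    if b > 1.0:
        excess = b - 1.0
        b = 1.0
        a += excess / 2.0
        c += excess / 2.0
    if a < 0.0:
        excess = -a
        a = 0.0
        b -= excess / 2.0
        c -= excess / 2.0

    try:
        result = TriangularParams(minimum=a, maximum=b, mode=c)
    except InvalidTriangleError as err:
        raise InfeasibleScalingError(
            f"relative risk {scaling.relative_risk} on {base.as_tuple()} "
            f"yields no valid triangle: {err}"
        ) from err
    if abs(result.mean - target) > 1e-9:
        raise InfeasibleScalingError(
            f"clamping could not preserve target mean {target:.6f} "
            f"(achieved {result.mean:.6f})"
        )
    return result
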