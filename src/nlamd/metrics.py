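"""Pairwise (dis)similarity metrics and ternary/quaternary multi-metrics on 3D points.

Pairwise metrics act on the Cartesian coordinate triples of two atoms and
carry the stable codes ``M1``..``M8`` and ``M10``..``M16``.  ``M1``..``M7``
are the Minkowski family at exponents p = 0.25, 0.5, 1, 1.5, 2, 2.5, 3 and
``M8`` is the Chebyshev (p -> infinity) limit.  The remaining codes are
coordinate-dependent similarity measures (Canberra, Bray-Curtis, Clark,
Soergel, Bhattacharyya, Wave-Edges, angular separation); they operate on the
raw coordinates and are therefore *not* invariant under rigid motion.

Multi-metrics (codes ``M19``..``M30``) score atom triples and quadruples:
perimeter, triangle area (Heron), sides summation, bond angle, simplex
volume and dihedral angle.  Perimeter, area and sides summation accept any
pairwise metric as their base "distance"; angles and volumes are purely
Cartesian constructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricSpec",
    "MultiMetricSpec",
    "pairwise_distance",
    "distance_matrix",
    "ternary_measure",
    "quaternary_measure",
    "MINKOWSKI_P",
]

#: Default Minkowski exponent for codes M1..M7, in the documented order.
MINKOWSKI_P = {
    "M1": 0.25,
    "M2": 0.5,
    "M3": 1.0,
    "M4": 1.5,
    "M5": 2.0,
    "M6": 2.5,
    "M7": 3.0,
}

_PAIR_CODES = frozenset(MINKOWSKI_P) | {
    "M8", "M10", "M11", "M12", "M13", "M14", "M15", "M16",
}

_ALLOWED_P = (0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class MetricSpec:
    """A pairwise metric: code plus the Minkowski exponent where relevant.

    Parameters
    ----------
    code:
        One of ``M1``..``M8``, ``M10``..``M16``.
    p:
        Minkowski exponent; only meaningful for ``M1``..``M7``.  Defaults to
        the code's canonical exponent (M1 -> 0.25 ... M7 -> 3).
    soergel_with_1_over_n:
        If True, apply the 1/n prefactor to the Soergel sum (M13).  The
        default omits it, matching the magnitudes of published example
        matrices.
    nonneg_policy:
        For Bhattacharyya (M14), ``"strict"`` raises on negative
        coordinates; ``"shift"`` translates both points so components are
        non-negative before the square roots.
    """

    code: str
    p: float | None = None
    soergel_with_1_over_n: bool = False
    nonneg_policy: str = "strict"

    def __post_init__(self):
        if self.code not in _PAIR_CODES:
            raise ValueError(f"unknown pairwise metric code {self.code!r}")
        if self.code in MINKOWSKI_P:
            p = self.p if self.p is not None else MINKOWSKI_P[self.code]
            if p not in _ALLOWED_P:
                raise ValueError(f"Minkowski exponent must be one of {_ALLOWED_P}, got {p}")
            object.__setattr__(self, "p", float(p))
        elif self.p is not None:
            raise ValueError(f"p is only valid for M1..M7, not {self.code}")

    @property
    def tag(self) -> str:
        return self.code


_TERNARY_ONLY = {"M21", "M22", "M27", "M28"}
_QUATERNARY_ONLY = {"M23", "M24", "M29", "M30"}
_EITHER_ARITY = {"M19", "M20", "M25", "M26"}
_MULTI_CODES = _TERNARY_ONLY | _QUATERNARY_ONLY | _EITHER_ARITY
_NEEDS_BASE = {"M19", "M20", "M21", "M22", "M25", "M26"}


@dataclass(frozen=True)
class MultiMetricSpec:
    """A ternary/quaternary measure: code plus the base pairwise metric.

    Codes: M19/M20 perimeter, M21/M22 triangle area, M23/M24 volume,
    M25/M26 sides summation, M27/M28 bond angle, M29/M30 dihedral angle.
    ``base_metric`` feeds the side lengths of perimeter/area/sides-summation
    and is ignored by the purely Cartesian angle/volume measures.
    """

    code: str
    base_metric: MetricSpec | None = field(default=None)

    def __post_init__(self):
        if self.code not in _MULTI_CODES:
            raise ValueError(f"unknown multi-metric code {self.code!r}")
        if self.code in _NEEDS_BASE and self.base_metric is None:
            object.__setattr__(self, "base_metric", MetricSpec("M5"))  # Euclidean

    @property
    def kind(self) -> str:
        return {
            "M19": "perimeter", "M20": "perimeter",
            "M21": "area", "M22": "area",
            "M23": "volume", "M24": "volume",
            "M25": "sides_sum", "M26": "sides_sum",
            "M27": "angle", "M28": "angle",
            "M29": "dihedral", "M30": "dihedral",
        }[self.code]

    @property
    def tag(self) -> str:
        if self.code in _NEEDS_BASE:
            return f"{self.code}({self.base_metric.code})"
        return self.code


def _as_point(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("coordinates must be finite")
    return a


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with the 0-denominator terms contributing 0."""
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    return out


def pairwise_distance(spec: MetricSpec, a, b) -> float:
    """Evaluate one pairwise metric on two 3D points. Symmetric, d(a,a)=0."""
    x = _as_point(a)
    y = _as_point(b)
    code = spec.code
    if code in MINKOWSKI_P:
        return float(np.sum(np.abs(x - y) ** spec.p) ** (1.0 / spec.p))
    if code == "M8":
        return float(np.max(np.abs(x - y)))
    if code == "M10":  # Canberra
        return float(np.sum(_safe_div(np.abs(x - y), np.abs(x) + np.abs(y))))
    if code == "M11":  # Lance-Williams / Bray-Curtis
        den = np.sum(np.abs(x) + np.abs(y))
        return float(np.sum(np.abs(x - y)) / den) if den != 0 else 0.0
    if code == "M12":  # Clark
        return float(np.sqrt(np.sum(_safe_div(x - y, np.abs(x) + np.abs(y)) ** 2)))
    if code == "M13":  # Soergel
        val = float(np.sum(_safe_div(np.abs(x - y), np.maximum(x, y))))
        if spec.soergel_with_1_over_n:
            val /= x.size
        return val
    if code == "M14":  # Bhattacharyya
        if np.any(x < 0) or np.any(y < 0):
            if spec.nonneg_policy == "strict":
                raise ValueError("Bhattacharyya metric requires non-negative coordinates")
            shift = min(x.min(), y.min())
            x = x - shift
            y = y - shift
        return float(np.sqrt(np.sum((np.sqrt(x) - np.sqrt(y)) ** 2)))
    if code == "M15":  # Wave-Edges
        mx = np.maximum(x, y)
        return float(np.sum(np.where(mx != 0, 1.0 - _safe_div(np.minimum(x, y), mx), 0.0)))
    if code == "M16":  # angular separation, 1 - cosine
        den = np.linalg.norm(x) * np.linalg.norm(y)
        if den == 0:
            return 0.0
        return float(1.0 - np.dot(x, y) / den)
    raise AssertionError(code)


def distance_matrix(spec: MetricSpec, coords: np.ndarray) -> np.ndarray:
    """All-pairs metric matrix for an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    out = np.zeros((n, n))
    if spec.code in MINKOWSKI_P or spec.code == "M8":
        diff = np.abs(coords[:, None, :] - coords[None, :, :])
        if spec.code == "M8":
            out = diff.max(axis=2)
        else:
            out = np.sum(diff ** spec.p, axis=2) ** (1.0 / spec.p)
        return out
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(spec, coords[i], coords[j])
            out[i, j] = d
            out[j, i] = pairwise_distance(spec, coords[j], coords[i])
    return out


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0  # degenerate: coincident points give no angle
    c = np.dot(u, v) / (nu * nv)
    return float(math.acos(min(1.0, max(-1.0, c))))


def ternary_measure(spec: MultiMetricSpec, a, b, c) -> float:
    """Ternary measure of three points; for the bond angle the vertex is ``a``."""
    pa, pb, pc = _as_point(a), _as_point(b), _as_point(c)
    kind = spec.kind
    if kind == "angle":
        return _angle_between(pb - pa, pc - pa)
    if kind in ("perimeter", "area", "sides_sum"):
        d_ab = pairwise_distance(spec.base_metric, pa, pb)
        d_bc = pairwise_distance(spec.base_metric, pb, pc)
        d_ca = pairwise_distance(spec.base_metric, pc, pa)
        if kind == "perimeter":
            return d_ab + d_bc + d_ca
        if kind == "sides_sum":
            return d_ab + d_bc
        s = 0.5 * (d_ab + d_bc + d_ca)
        rad = s * (s - d_ab) * (s - d_bc) * (s - d_ca)
        return float(math.sqrt(max(rad, 0.0)))
    raise ValueError(f"{spec.code} is not defined for three points")


def quaternary_measure(spec: MultiMetricSpec, a, b, c, d) -> float:
    """Quaternary measure of four points (perimeter, sides sum, volume, dihedral)."""
    pa, pb, pc, pd = _as_point(a), _as_point(b), _as_point(c), _as_point(d)
    kind = spec.kind
    if kind == "volume":
        m = np.stack([pb - pa, pc - pa, pd - pa])
        return float(abs(np.linalg.det(m)) / 6.0)
    if kind == "dihedral":
        # planes (a,b,c) and (d,b,c); normals via cross products
        ua = np.cross(pa - pb, pc - pb)
        ub = np.cross(pd - pb, pc - pb)
        return _angle_between(ua, ub)
    if kind in ("perimeter", "sides_sum"):
        d_ab = pairwise_distance(spec.base_metric, pa, pb)
        d_bc = pairwise_distance(spec.base_metric, pb, pc)
        d_cd = pairwise_distance(spec.base_metric, pc, pd)
        if kind == "sides_sum":
            return d_ab + d_bc + d_cd
        return d_ab + d_bc + d_cd + pairwise_distance(spec.base_metric, pd, pa)
    raise ValueError(f"{spec.code} is not defined for four points")
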