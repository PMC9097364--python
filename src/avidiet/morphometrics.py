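"""Claw traditional-morphometric variables and jaw functional indices.

Claw shape is summarised by the outer-arc curvature angle (degrees) and
outer-arc length of the circle fitted exactly through three landmarks per
claw; jaw mechanics by six dimensionless indices measured off a 2D lateral
skull geometry (three mechanical advantages, relative articular offset and
two skull-length-normalised cranial heights).

All outputs are invariant under rigid motions of the input coordinates;
ratios and indices are additionally invariant under uniform scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import CollinearPointsError, GeometryError

__all__ = [
    "ClawLandmarks",
    "ClawFeatureVector",
    "SkullGeometry",
    "FunctionalIndexSet",
    "claw_curvature",
    "claw_arc_length",
    "tm_features",
    "functional_indices",
    "polygon_area",
]

DIGITS = ("DI", "DII", "DIII", "DIV")

#: circumradius / chord ratio beyond which a claw is reported as straight (0 deg)
STRAIGHT_RADIUS_RATIO = 1e6


@dataclass(frozen=True)
class ClawLandmarks:
    """Three planar landmarks on one claw: proximal base, outer-curve midpoint, tip."""

    digit: str
    proximal: tuple[float, float]
    midpoint: tuple[float, float]
    tip: tuple[float, float]

    def __post_init__(self):
        if self.digit not in DIGITS:
            raise ValueError(f"digit must be one of {DIGITS}, got {self.digit!r}")
        pts = [self.proximal, self.midpoint, self.tip]
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(pts[i], pts[j]):
                    raise GeometryError("claw landmarks must be pairwise distinct")

    def points(self) -> np.ndarray:
        return np.array([self.proximal, self.midpoint, self.tip], dtype=float)


@dataclass(frozen=True)
class ClawFeatureVector:
    """Per-digit curvature plus arc-length ratios against the reference digit."""

    curvature_deg: dict[str, float]
    arc_ratios: dict[str, float]
    reference: str

    def as_row(self) -> dict[str, float]:
        row = {f"Oo_{d}": self.curvature_deg[d] for d in DIGITS}
        row.update({f"ALo_{d}_{self.reference}": r for d, r in self.arc_ratios.items()})
        return row


def _circumcircle(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre and radius of the unique circle through three points."""
    (ax, ay), (bx, by), (cx, cy) = p
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    chord = max(np.linalg.norm(p[0] - p[2]), np.linalg.norm(p[0] - p[1]),
                np.linalg.norm(p[1] - p[2]))
    if d == 0:
        raise CollinearPointsError("claw landmarks are exactly collinear")
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    centre = np.array([ux, uy])
    radius = float(np.linalg.norm(p[0] - centre))
    if radius > STRAIGHT_RADIUS_RATIO * chord:
        raise CollinearPointsError("claw landmarks are numerically collinear")
    return centre, radius


def _arc_angle_rad(c: ClawLandmarks) -> float:
    """Central angle of the arc proximal -> tip passing through the midpoint."""
    pts = c.points()
    centre, _ = _circumcircle(pts)
    ang = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
    a0, am, a1 = ang
    # sweep counter-clockwise from proximal to tip; check midpoint membership
    ccw = (a1 - a0) % (2 * math.pi)
    mid_off = (am - a0) % (2 * math.pi)
    if mid_off <= ccw:
        return ccw
    return 2 * math.pi - ccw


def claw_curvature(c: ClawLandmarks) -> float:
    """Outer-arc curvature in degrees; 0 deg (with a warning) for straight claws."""
    try:
        return math.degrees(_arc_angle_rad(c))
    except CollinearPointsError:
        warnings.warn(f"claw {c.digit}: landmarks (near-)collinear, curvature set to 0",
                      stacklevel=2)
        return 0.0


def claw_arc_length(c: ClawLandmarks) -> float:
    """Length of the fitted outer arc (radius x angle); chord length if straight."""
    try:
        _, radius = _circumcircle(c.points())
        return radius * _arc_angle_rad(c)
    except CollinearPointsError:
        warnings.warn(f"claw {c.digit}: landmarks (near-)collinear, using chord length",
                      stacklevel=2)
        return float(np.linalg.norm(np.asarray(c.tip) - np.asarray(c.proximal)))


def tm_features(claws: dict[str, ClawLandmarks], reference: str = "DIII") -> ClawFeatureVector:
    """Traditional-morphometric feature vector: 4 curvatures + 3 arc ratios.

    ``claws`` maps digit id -> landmarks for all four digits; ``reference``
    (DIII or DIV in practice) supplies the denominator of the size ratios.
    """
    missing = [d for d in DIGITS if d not in claws]
    if missing:
        raise GeometryError(f"missing digits: {missing}")
    if reference not in DIGITS:
        raise ValueError(f"reference must be one of {DIGITS}")
    curv = {d: claw_curvature(claws[d]) for d in DIGITS}
    arcs = {d: claw_arc_length(claws[d]) for d in DIGITS}
    if arcs[reference] <= 0:
        raise GeometryError(f"reference digit {reference} has zero arc length")
    ratios = {d: arcs[d] / arcs[reference] for d in DIGITS if d != reference}
    return ClawFeatureVector(curvature_deg=curv, arc_ratios=ratios, reference=reference)


# ---------------------------------------------------------------------------
# Jaw functional indices


def polygon_area(poly) -> float:
    """Absolute shoelace area of a simple polygon (orientation-free)."""
    pts = np.asarray(poly, dtype=float)
    if len(pts) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    if not _ShapelyPolygon(pts).is_valid:
        raise GeometryError("polygon is self-intersecting")
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class SkullGeometry:
    """2D lateral skull geometry for functional-index measurement.

    Coordinates are Cartesian, y-up, in arbitrary but consistent units.
    ``adductor_line`` is two points defining the adductor line of action;
    ``axis`` is the skull long-axis unit vector (normalised on init).
    """

    condyle: tuple[float, float]
    anterior_bite: tuple[float, float]
    posterior_bite: tuple[float, float]
    adductor_line: tuple[tuple[float, float], tuple[float, float]]
    depressor: tuple[float, float]
    occlusal_rostral: tuple[float, float]
    occlusal_cranial: tuple[float, float]
    occlusal_outline: list[tuple[float, float]]
    axis: tuple[float, float]
    outline: list[tuple[float, float]]
    holes: list[list[tuple[float, float]]] = field(default_factory=list)
    reverse_ao: bool = False

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise GeometryError("skull axis vector must be nonzero")
        self.axis = tuple(a / n)
        outer = _ShapelyPolygon(self.outline)
        if not outer.is_valid:
            raise GeometryError("outer outline is self-intersecting")
        for h in self.holes:
            hp = _ShapelyPolygon(h)
            if not hp.is_valid:
                raise GeometryError("hole polygon is self-intersecting")
            if not outer.contains(hp):
                raise GeometryError("holes must lie strictly inside the outer outline")

    def skull_length(self) -> float:
        pts = np.asarray(self.outline, dtype=float)
        proj = pts @ np.asarray(self.axis)
        length = float(proj.max() - proj.min())
        if length <= 0:
            raise GeometryError("skull length must be positive")
        return length


@dataclass(frozen=True)
class FunctionalIndexSet:
    """The six dimensionless jaw indices."""

    AMA: float
    PMA: float
    OMA: float
    AO: float
    MCH: float
    ACH: float

    def as_row(self) -> dict[str, float]:
        return {"AMA": self.AMA, "PMA": self.PMA, "OMA": self.OMA,
                "AO": self.AO, "MCH": self.MCH, "ACH": self.ACH}


def _point_line_distance(p, a, b) -> float:
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise GeometryError("degenerate adductor line (coincident points)")
    v = p - a
    return abs(d[0] * v[1] - d[1] * v[0]) / n


def _equilibrium_offset(g: SkullGeometry) -> float:
    """Mean signed perpendicular deviation of the occlusal polyline from its chord.

    Translating the rostral-cranial chord by this amount balances the area
    ventral and dorsal to it.  Deviations are weighted by the along-chord
    extent of each polyline segment.
    """
    a = np.asarray(g.occlusal_rostral, dtype=float)
    b = np.asarray(g.occlusal_cranial, dtype=float)
    chord = b - a
    clen = np.linalg.norm(chord)
    if clen == 0:
        raise GeometryError("occlusal chord endpoints coincide")
    t_hat = chord / clen
    n_hat = np.array([-t_hat[1], t_hat[0]])
    pts = np.asarray(g.occlusal_outline, dtype=float)
    if len(pts) < 2:
        raise GeometryError("occlusal outline needs at least 2 points")
    s = (pts - a) @ t_hat
    dev = (pts - a) @ n_hat
    # trapezoidal mean of deviation along the chord direction
    ds = np.diff(s)
    if np.allclose(ds, 0):
        return float(dev.mean()) * (-1 if g.reverse_ao else 1)
    num = float(np.sum(0.5 * (dev[:-1] + dev[1:]) * ds))
    den = float(np.sum(ds))
    mean_dev = num / den
    return -mean_dev if g.reverse_ao else mean_dev


def functional_indices(g: SkullGeometry, subtract_holes: bool = False) -> FunctionalIndexSet:
    """Compute the six jaw indices from a skull geometry.

    AMA/PMA share the adductor inlever (perpendicular distance from the
    articular condyle to the adductor line of action) over the anterior and
    posterior outlever respectively; OMA uses the condyle-depressor distance.
    AO is the perpendicular distance from the condyle to the area-balancing
    occlusal line over skull length.  MCH is the outline extent perpendicular
    to the skull long axis over skull length; ACH is outline area (holes
    ignored unless ``subtract_holes``) over skull length squared.
    """
    condyle = np.asarray(g.condyle, dtype=float)
    out_ant = float(np.linalg.norm(np.asarray(g.anterior_bite) - condyle))
    out_post = float(np.linalg.norm(np.asarray(g.posterior_bite) - condyle))
    if out_ant == 0 or out_post == 0:
        raise GeometryError("zero outlever: bite point coincides with condyle")
    inlever = _point_line_distance(condyle, *g.adductor_line)
    ama = inlever / out_ant
    pma = inlever / out_post
    oma = float(np.linalg.norm(np.asarray(g.depressor) - condyle)) / out_ant

    length = g.skull_length()

    # AO: distance from condyle to the equilibrium occlusal line
    offset = _equilibrium_offset(g)
    a = np.asarray(g.occlusal_rostral, dtype=float)
    b = np.asarray(g.occlusal_cranial, dtype=float)
    t_hat = (b - a) / np.linalg.norm(b - a)
    n_hat = np.array([-t_hat[1], t_hat[0]])
    line_a = a + offset * n_hat
    line_b = b + offset * n_hat
    ao = _point_line_distance(condyle, line_a, line_b) / length

    axis = np.asarray(g.axis)
    normal = np.array([-axis[1], axis[0]])
    pts = np.asarray(g.outline, dtype=float)
    heights = pts @ normal
    mch = float(heights.max() - heights.min()) / length

    area = polygon_area(g.outline)
    if subtract_holes:
        area -= sum(polygon_area(h) for h in g.holes)
    ach = (area / length) / length

    return FunctionalIndexSet(AMA=ama, PMA=pma, OMA=oma, AO=ao, MCH=mch, ACH=ach)
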