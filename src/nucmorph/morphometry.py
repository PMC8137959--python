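"""Per-nucleus geometric features from binary segmentation masks.

Each segmented nucleus arrives as a small 2D binary array (one file per
cell in the source dataset).  From it we derive:

* an ordered outer contour traced through foreground *pixel centers*
  (a shape w pixels wide therefore has geometric extent w - 1),
* the convex hull and its area,
* the minimum-area enclosing (rotated) rectangle,
* a least-squares fitted ellipse (center, axes, Ramanujan perimeter, area),
* maximum and minimum Feret diameters with their angles,
* six dimensionless shape factors (esf, csf, sf1, sf2, elongation,
  convexity), all equal to 1 for a perfect circle except convexity,
  which compares fitted-ellipse area to hull area.

Coordinates are image coordinates throughout: origin at the top-left,
x = column, y = row, y increasing downward.  Angles are measured from
the +x axis in those coordinates.  All lengths are in pixels; physical
conversion (micrometres per pixel) is applied only on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel, label, regionprops


class MorphometryError(ValueError):
    """Raised when a mask or intermediate geometry is degenerate."""


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MinAreaRect:
    """Minimum-area enclosing rectangle of the convex hull.

    ``center`` is the rectangle's center; ``top_left`` the topmost
    (then leftmost) of its four corners — the source dataset's feature
    name ``rectCenter`` is ambiguous between the two, so both are kept.
    ``angle`` follows the convention of the source data: degrees in
    [-90, 0), -90 meaning axis-aligned, increasing toward 0 as the
    rectangle rotates clockwise.
    """

    center: tuple[float, float]
    top_left: tuple[float, float]
    width: float
    height: float
    angle: float
    area: float
    corners: tuple[tuple[float, float], ...] = field(repr=False, default=())


@dataclass(frozen=True)
class FittedEllipse:
    center: tuple[float, float]
    long_axis: float   # full major-axis length, px
    short_axis: float  # full minor-axis length, px
    theta: float       # major-axis orientation, radians
    perimeter: float
    area: float


@dataclass(frozen=True)
class FeretResult:
    max_diameter: float
    max_angle: float  # degrees in [-180, 180]
    min_diameter: float
    min_angle: float  # degrees in [-180, 180]


@dataclass(frozen=True)
class NucleusFeatures:
    """Full per-nucleus feature record (one row of cell_shapes.csv)."""

    patient_id: str
    patch_id: str
    cell_number: int
    rect: MinAreaRect
    ellipse: FittedEllipse
    feret: FeretResult
    hull_area: float
    esf: float
    csf: float
    sf1: float
    sf2: float
    elongation: float
    convexity: float

    def to_row(self) -> dict:
        """Flatten to the cell_shapes.csv column layout.

        Tuple-valued columns are serialized as ``"(x, y)"`` strings to
        match the released dataset's convention.
        """
        return {
            "patient_id": self.patient_id,
            "patch_id": self.patch_id,
            "cell_number": self.cell_number,
            "rectCenter": _fmt_xy(self.rect.center),
            "rectDimension": _fmt_xy((self.rect.width, self.rect.height)),
            "rotate_angle": self.rect.angle,
            "ellip_centroid": _fmt_xy(self.ellipse.center),
            "shortAxis": self.ellipse.short_axis,
            "longAxis": self.ellipse.long_axis,
            "ellip_perimt": self.ellipse.perimeter,
            "ellip_area": self.ellipse.area,
            "maxDiameter": self.feret.max_diameter,
            "maxAngle": self.feret.max_angle,
            "minDiameter": self.feret.min_diameter,
            "minAngle": self.feret.min_angle,
            "hull_area": self.hull_area,
            "esf": self.esf,
            "csf": self.csf,
            "sf1": self.sf1,
            "sf2": self.sf2,
            "elongation": self.elongation,
            "convexity": self.convexity,
        }


CELL_SHAPES_COLUMNS = [
    "patient_id", "patch_id", "cell_number",
    "rectCenter", "rectDimension", "rotate_angle",
    "ellip_centroid", "shortAxis", "longAxis", "ellip_perimt", "ellip_area",
    "maxDiameter", "maxAngle", "minDiameter", "minAngle",
    "hull_area", "esf", "csf", "sf1", "sf2", "elongation", "convexity",
]

#: scalar length/area/ratio features used for patient-level aggregation
#: (angles and positions are excluded: they carry no shape information)
GEOMETRIC_FEATURES = [
    "shortAxis", "longAxis", "ellip_perimt", "ellip_area",
    "maxDiameter", "minDiameter", "hull_area",
    "esf", "csf", "sf1", "sf2", "elongation", "convexity",
]


def _fmt_xy(xy: Sequence[float]) -> str:
    return f"({xy[0]}, {xy[1]})"


# ---------------------------------------------------------------------------
# mask validation and contour tracing
# ---------------------------------------------------------------------------


def validate_mask(mask: np.ndarray, context: str = "") -> np.ndarray:
    """Check the mask invariants and return it as a boolean array.

    Requires a 2D array with values in {0, 1}, at least 5 foreground
    pixels forming a single 8-connected component.
    """
    arr = np.asarray(mask)
    tag = f" [{context}]" if context else ""
    if arr.ndim != 2:
        raise MorphometryError(f"expected 2-dimensional mask, got {arr.ndim}D{tag}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise MorphometryError(f"non-binary mask (values {uniq.tolist()}){tag}")
    arr = arr.astype(bool)
    n_fg = int(arr.sum())
    if n_fg < 5:
        raise MorphometryError(f"mask has {n_fg} foreground pixels, need >= 5{tag}")
    _, n_comp = label(arr, connectivity=2, return_num=True)
    if n_comp != 1:
        raise MorphometryError(
            f"mask has {n_comp} 8-connected foreground components, need exactly 1{tag}"
        )
    return arr


# Moore neighborhood in clockwise order, (dr, dc), starting from "west".
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def mask_to_contour(mask: np.ndarray, context: str = "") -> np.ndarray:
    """Trace the outer boundary of the foreground through pixel centers.

    Returns an (n, 2) float array of (x, y) vertices forming a closed
    simple polygon (last vertex connects back to the first), oriented so
    the standard shoelace sum over (x, y) is non-negative.  Runs of
    collinear vertices are pruned, so an axis-aligned filled rectangle
    reduces to its 4 corners.

    Uses Moore-neighbor tracing with Jacob's stopping criterion.
    """
    arr = validate_mask(mask, context)
    fg = np.argwhere(arr)
    # start at topmost, then leftmost foreground pixel; entered from the west
    r0, c0 = fg[np.lexsort((fg[:, 1], fg[:, 0]))][0]
    start = (int(r0), int(c0))
    start_back = (start[0], start[1] - 1)  # west neighbor, background by construction

    def is_fg(p):
        r, c = p
        return 0 <= r < arr.shape[0] and 0 <= c < arr.shape[1] and arr[r, c]

    boundary = [start]
    cur, back = start, start_back
    max_steps = 4 * len(fg) + 8
    for _ in range(max_steps):
        # scan the Moore neighborhood of cur clockwise, starting just past
        # the backtrack pixel; consecutive ring positions are 8-adjacent,
        # so the pixel examined before the hit is a valid new backtrack
        d = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            idx = (d + k) % 8
            cand = (cur[0] + _MOORE[idx][0], cur[1] + _MOORE[idx][1])
            if is_fg(cand):
                nxt = cand
                pidx = (idx - 1) % 8
                back = (cur[0] + _MOORE[pidx][0], cur[1] + _MOORE[pidx][1])
                break
        if nxt is None:  # isolated pixel cannot occur (>=5 px, connected)
            break
        if nxt == start and back == start_back:
            break  # Jacob's criterion: re-entered start from the same side
        boundary.append(nxt)
        cur = nxt

    if len(boundary) < 3:
        raise MorphometryError(
            f"too few boundary points ({len(boundary)}) to form a contour"
            + (f" [{context}]" if context else "")
        )

    # (row, col) -> (x, y)
    pts = np.array([(c, r) for r, c in boundary], dtype=float)
    pts = _prune_collinear(pts)
    if len(pts) < 3:
        raise MorphometryError("degenerate (collinear) contour")
    if _shoelace_signed(pts) < 0:
        pts = pts[::-1]
    return pts


def _prune_collinear(pts: np.ndarray) -> np.ndarray:
    """Drop vertices lying exactly on the segment between their neighbors."""
    n = len(pts)
    keep = []
    for i in range(n):
        a, b, c = pts[i - 1], pts[i], pts[(i + 1) % n]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if cross != 0 or np.array_equal(a, c):
            keep.append(i)
    return pts[keep] if keep else pts[:0]


def _shoelace_signed(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(pts: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon."""
    return abs(_shoelace_signed(np.asarray(pts, dtype=float)))


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------


def convex_hull(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Convex hull of a point set with its shoelace area.

    Returns (hull_vertices, hull_area); vertices are ordered
    counter-clockwise in the (x, y) plane.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise MorphometryError("need at least 3 points for a convex hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise MorphometryError(f"degenerate (collinear) point set: {e}") from e
    verts = pts[hull.vertices]
    return verts, float(hull.volume)  # .volume is the area in 2D


# ---------------------------------------------------------------------------
# minimum-area rectangle (rotating calipers over hull edges)
# ---------------------------------------------------------------------------


def min_area_rect(hull: np.ndarray) -> MinAreaRect:
    """Minimum-area enclosing rectangle of a convex polygon.

    By the rotating-calipers theorem the optimal rectangle has one side
    collinear with a hull edge, so only edge directions are examined.
    Ties in area are broken by the smallest reported angle.
    """
    pts = np.asarray(hull, dtype=float)
    if len(pts) < 3:
        raise MorphometryError("degenerate hull: fewer than 3 vertices")

    best = None
    edges = np.roll(pts, -1, axis=0) - pts
    for ex, ey in edges:
        norm = math.hypot(ex, ey)
        if norm == 0:
            continue
        ux, uy = ex / norm, ey / norm          # edge direction
        vx, vy = -uy, ux                       # perpendicular
        pu = pts[:, 0] * ux + pts[:, 1] * uy
        pv = pts[:, 0] * vx + pts[:, 1] * vy
        w = pu.max() - pu.min()
        h = pv.max() - pv.min()
        area = w * h
        phi = math.degrees(math.atan2(uy, ux))
        angle = (phi % 90.0) - 90.0            # [-90, 0)
        cand = (area, angle, (ux, uy, vx, vy, pu.min(), pu.max(), pv.min(), pv.max(), w, h))
        if best is None or area < best[0] - 1e-12 or (
            abs(area - best[0]) <= 1e-12 and angle < best[1]
        ):
            best = cand
    if best is None:
        raise MorphometryError("degenerate hull: zero-length edges")

    area, angle, (ux, uy, vx, vy, u0, u1, v0, v1, w, h) = best
    # rectangle corners back in (x, y)
    corners = []
    for uu, vv in ((u0, v0), (u1, v0), (u1, v1), (u0, v1)):
        corners.append((uu * ux + vv * vx, uu * uy + vv * vy))
    cx = sum(c[0] for c in corners) / 4.0
    cy = sum(c[1] for c in corners) / 4.0
    top_left = min(corners, key=lambda c: (c[1], c[0]))  # topmost, then leftmost

    # width = extent along the caliper direction at angle+90 deg
    a = math.radians(angle + 90.0)
    dx, dy = math.cos(a), math.sin(a)
    # project corners on that direction and its perpendicular
    proj_w = [c[0] * dx + c[1] * dy for c in corners]
    proj_h = [-c[0] * dy + c[1] * dx for c in corners]
    width = max(proj_w) - min(proj_w)
    height = max(proj_h) - min(proj_h)

    return MinAreaRect(
        center=(cx, cy),
        top_left=top_left,
        width=float(width),
        height=float(height),
        angle=float(angle),
        area=float(area),
        corners=tuple((float(x), float(y)) for x, y in corners),
    )


# ---------------------------------------------------------------------------
# Feret diameters
# ---------------------------------------------------------------------------


def feret(hull: np.ndarray) -> FeretResult:
    """Maximum and minimum Feret diameters of a convex polygon.

    The Feret diameter along a direction is the distance between the two
    parallel supporting tangents perpendicular to that direction.  The
    maximum is attained by a pair of hull vertices (computed pairwise);
    the minimum is attained with one tangent along a hull edge (computed
    by sweeping edges).  Angles are degrees from +x in image coordinates,
    in [-180, 180]; min_angle is the caliper direction (perpendicular to
    the supporting edge).
    """
    pts = np.asarray(hull, dtype=float)
    n = len(pts)
    if n < 3:
        raise MorphometryError("degenerate hull: fewer than 3 vertices")

    # max: pairwise vertex distances
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    max_d = math.sqrt(float(d2[i, j]))
    if max_d == 0:
        raise MorphometryError("degenerate hull: all points coincide")
    dx, dy = pts[j] - pts[i]
    max_angle = math.degrees(math.atan2(dy, dx))

    # min: width perpendicular to each hull edge
    min_d = math.inf
    min_angle = 0.0
    edges = np.roll(pts, -1, axis=0) - pts
    for k, (ex, ey) in enumerate(edges):
        norm = math.hypot(ex, ey)
        if norm == 0:
            continue
        nx, ny = -ey / norm, ex / norm  # unit normal (caliper direction)
        proj = pts[:, 0] * nx + pts[:, 1] * ny
        width = proj.max() - proj.min()
        if width < min_d:
            min_d = float(width)
            min_angle = math.degrees(math.atan2(ny, nx))
    if not math.isfinite(min_d) or min_d <= 0:
        raise MorphometryError("degenerate hull: zero minimum width")

    return FeretResult(
        max_diameter=max_d, max_angle=max_angle,
        min_diameter=min_d, min_angle=min_angle,
    )


# ---------------------------------------------------------------------------
# ellipse fitting
# ---------------------------------------------------------------------------


def ellipse_perimeter(long_axis: float, short_axis: float) -> float:
    """Ellipse perimeter by Ramanujan's second approximation.

    With semi-axes a = long_axis/2 and b = short_axis/2 and
    h = ((a-b)/(a+b))^2, the perimeter is
    pi*(a+b)*(1 + 3h/(10 + sqrt(4 - 3h))).  Exact for a circle; relative
    error below 1e-6 for aspect ratios down to ~0.2.
    """
    if long_axis <= 0 or short_axis <= 0:
        raise MorphometryError("ellipse axes must be positive")
    if short_axis > long_axis:
        raise MorphometryError("short_axis must not exceed long_axis")
    a = long_axis / 2.0
    b = short_axis / 2.0
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def fit_ellipse(contour: np.ndarray) -> FittedEllipse:
    """Least-squares ellipse fit to contour points.

    Algebraic conic fit constrained to an ellipse (Halir–Flusser direct
    least squares, via scikit-image's EllipseModel).  Axis lengths are
    full lengths with short <= long; area = pi*a*b on the semi-axes;
    perimeter by :func:`ellipse_perimeter`.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 5:
        raise MorphometryError(f"need >= 5 contour points to fit an ellipse, got {len(pts)}")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise MorphometryError("ellipse fit degenerated to a non-ellipse conic")
    xc, yc = (float(v) for v in model.center)
    a, b = (float(v) for v in model.axis_lengths)  # semi-axes
    theta = float(model.theta)
    if a <= 0 or b <= 0 or not all(map(math.isfinite, (xc, yc, a, b))):
        raise MorphometryError("ellipse fit produced non-positive axes")
    if b > a:
        a, b = b, a
        theta += math.pi / 2.0
    long_axis, short_axis = 2.0 * a, 2.0 * b
    return FittedEllipse(
        center=(xc, yc),
        long_axis=long_axis,
        short_axis=short_axis,
        theta=theta,
        perimeter=ellipse_perimeter(long_axis, short_axis),
        area=math.pi * a * b,
    )


def fit_ellipse_moments(mask: np.ndarray) -> FittedEllipse:
    """Moments-based ellipse (second central moments of the mask).

    Fallback for contours where the algebraic fit degenerates; uses the
    region's inertia-equivalent ellipse.
    """
    arr = validate_mask(mask)
    props = regionprops(arr.astype(np.uint8))[0]
    long_axis = float(props.axis_major_length)
    short_axis = float(props.axis_minor_length)
    if short_axis <= 0 or long_axis <= 0:
        raise MorphometryError("moments-based ellipse degenerate")
    cy, cx = props.centroid
    return FittedEllipse(
        center=(float(cx), float(cy)),
        long_axis=long_axis,
        short_axis=short_axis,
        theta=float(-props.orientation),
        perimeter=ellipse_perimeter(long_axis, short_axis),
        area=math.pi * long_axis * short_axis / 4.0,
    )


# ---------------------------------------------------------------------------
# shape factors and orchestration
# ---------------------------------------------------------------------------


def shape_factors(
    ellipse: FittedEllipse, fr: FeretResult, hull_area: float
) -> tuple[float, float, float, float, float, float]:
    """The six dimensionless descriptors (esf, csf, sf1, sf2, elongation, convexity).

    esf = shortAxis/longAxis; csf = 4*pi*area/perimeter^2 of the fitted
    ellipse; sf1 = shortAxis/maxDiameter; sf2 = minDiameter/maxDiameter;
    elongation = maxDiameter/minDiameter = 1/sf2; convexity =
    sqrt(ellipse_area/hull_area).  The first five equal 1 for a perfect
    circle; csf decreases toward 0 with increasing ellipticity.
    """
    for name, v in (
        ("longAxis", ellipse.long_axis), ("ellip_perimt", ellipse.perimeter),
        ("maxDiameter", fr.max_diameter), ("minDiameter", fr.min_diameter),
        ("hull_area", hull_area),
    ):
        if v <= 0:
            raise MorphometryError(f"cannot form shape factors: {name} = {v}")
    esf = ellipse.short_axis / ellipse.long_axis
    csf = 4.0 * math.pi * ellipse.area / ellipse.perimeter**2
    sf1 = ellipse.short_axis / fr.max_diameter
    sf2 = fr.min_diameter / fr.max_diameter
    elongation = fr.max_diameter / fr.min_diameter
    convexity = math.sqrt(ellipse.area / hull_area)
    return esf, csf, sf1, sf2, elongation, convexity


def compute_features(
    mask: np.ndarray,
    patient_id: str = "",
    patch_id: str = "",
    cell_number: int = 0,
    ellipse_method: str = "fit",
) -> NucleusFeatures:
    """Run the full geometric pipeline on one nucleus mask.

    ellipse_method: "fit" (algebraic least squares on the contour, with
    automatic moments fallback if the fit degenerates) or "moments".
    """
    ctx = f"{patient_id}/{patch_id}/{cell_number}"
    try:
        contour = mask_to_contour(mask, context=ctx)
        hull, hull_area = convex_hull(contour)
        rect = min_area_rect(hull)
        fr = feret(hull)
        if ellipse_method == "moments":
            ell = fit_ellipse_moments(mask)
        else:
            try:
                ell = fit_ellipse(contour)
            except MorphometryError:
                ell = fit_ellipse_moments(mask)
        esf, csf, sf1, sf2, elong, convexity = shape_factors(ell, fr, hull_area)
    except MorphometryError as e:
        raise MorphometryError(f"{e} (nucleus {ctx})") from e
    return NucleusFeatures(
        patient_id=patient_id,
        patch_id=patch_id,
        cell_number=cell_number,
        rect=rect,
        ellipse=ell,
        feret=fr,
        hull_area=hull_area,
        esf=esf,
        csf=csf,
        sf1=sf1,
        sf2=sf2,
        elongation=elong,
        convexity=convexity,
    )
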