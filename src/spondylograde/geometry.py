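"""Endplate landmark extraction from a segmented vertebra mask.

A label mask encodes background 0, lumbar bodies L1..L5 as 1..5 and the
sacrum as 6. For each lumbar body the four endplate corners are recovered by:
largest connected component -> convex hull of pixel centres -> minimum-area
(rotated) bounding rectangle -> snap each rectangle corner to its nearest hull
vertex. The rectangle's long axis is taken as the endplate axis; "upper" is
the long side with smaller mean y (image y grows downward). For the sacrum
only the two superior corners are meaningful.

Coordinates are 0-based (x, y) pixel centres, x rightward, y downward.
Anterior maps to decreasing x by default (patient facing image-left) and is
configurable, since radiograph laterality varies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint
from skimage import measure

LUMBAR_LABELS = {"L1": 1, "L2": 2, "L3": 3, "L4": 4, "L5": 5}
SACRUM_LABEL = 6
ALL_LEVELS = [*LUMBAR_LABELS, "S1"]

#: Components smaller than this (pixels) are rejected as segmentation debris.
MIN_COMPONENT_AREA = 20


class MissingStructureError(ValueError):
    def __init__(self, level: str):
        self.level = level
        super().__init__(f"structure {level} absent from mask")


class DegenerateComponentError(ValueError):
    pass


Point = tuple[float, float]


@dataclass
class VertebraCorners:
    """Named endplate corners of one vertebra (sacrum: superior pair only)."""

    level: str
    upper_anterior: Point
    upper_posterior: Point
    lower_anterior: Point | None = None
    lower_posterior: Point | None = None

    def points(self) -> list[Point]:
        pts = [self.upper_anterior, self.upper_posterior]
        if self.lower_anterior is not None:
            pts += [self.lower_anterior, self.lower_posterior]
        return pts

    def to_dict(self) -> dict:
        d = {"level": self.level,
             "upper_anterior": list(self.upper_anterior),
             "upper_posterior": list(self.upper_posterior)}
        if self.lower_anterior is not None:
            d["lower_anterior"] = list(self.lower_anterior)
            d["lower_posterior"] = list(self.lower_posterior)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VertebraCorners":
        def pt(k):
            v = d.get(k)
            return None if v is None else (float(v[0]), float(v[1]))

        return cls(level=d["level"], upper_anterior=pt("upper_anterior"),
                   upper_posterior=pt("upper_posterior"),
                   lower_anterior=pt("lower_anterior"),
                   lower_posterior=pt("lower_posterior"))


@dataclass
class LandmarkSet:
    """Landmarks for the structures found in one study, plus missing flags."""

    corners: dict[str, VertebraCorners] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)
    anterior_direction: str = "left"

    def get(self, level: str) -> VertebraCorners | None:
        return self.corners.get(level)

    def n_points(self) -> int:
        return sum(len(c.points()) for c in self.corners.values())

    def to_dict(self) -> dict:
        return {
            "anterior_direction": self.anterior_direction,
            "corners": {k: v.to_dict() for k, v in self.corners.items()},
            "missing": self.missing,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            corners={k: VertebraCorners.from_dict(v) for k, v in d["corners"].items()},
            missing=list(d.get("missing", [])),
            anterior_direction=d.get("anterior_direction", "left"),
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_direction(anterior_direction: str) -> int:
    if anterior_direction not in ("left", "right"):
        raise ValueError(f"anterior_direction must be 'left' or 'right', got {anterior_direction!r}")
    return -1 if anterior_direction == "left" else 1


def clean_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Per-label binary opening to strip 1-px protrusions from a predicted mask.

    Convex-hull vertices are extremely sensitive to single protruding pixels
    along a component's boundary; a light opening removes them without moving
    true corners by more than the structuring element's radius. Intended for
    network predictions; exact (rasterised ground-truth) masks don't need it.
    """
    from scipy import ndimage

    out = np.zeros_like(mask)
    for label in range(1, 7):
        binary = np.asarray(mask) == label
        if binary.any():
            out[ndimage.binary_opening(binary, iterations=iterations)] = label
    return out


def largest_component(mask: np.ndarray, label: int) -> np.ndarray:
    """Largest 8-connected component of `label`, as a boolean mask."""
    if not 1 <= label <= 6:
        raise ValueError(f"label must be in 1..6, got {label}")
    binary = np.asarray(mask) == label
    if not binary.any():
        level = next((k for k, v in LUMBAR_LABELS.items() if v == label), "S1")
        raise MissingStructureError(level)
    lab = measure.label(binary, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def _hull_vertices(component: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of the component's pixel centres, as (x, y)."""
    ys, xs = np.nonzero(component)
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) < 3:
        raise DegenerateComponentError(f"component has only {len(pts)} pixels")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # collinear pixels
        raise DegenerateComponentError("component is degenerate (collinear pixels)") from exc
    return pts[hull.vertices]


def _min_area_rect(hull_pts: np.ndarray) -> np.ndarray:
    """Four corners of the minimum-area rotated rectangle around the hull."""
    rect = MultiPoint([tuple(p) for p in hull_pts]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise DegenerateComponentError("bounding rectangle degenerates to a line")
    return np.asarray(rect.exterior.coords[:-1], dtype=float)


def _axis_rect(hull_pts: np.ndarray) -> np.ndarray:
    x0, y0 = hull_pts.min(axis=0)
    x1, y1 = hull_pts.max(axis=0)
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


def _snap_to_hull(target: np.ndarray, hull_pts: np.ndarray) -> Point:
    """Hull vertex nearest `target`; ties broken by smaller y, then smaller x."""
    d2 = ((hull_pts - target) ** 2).sum(axis=1)
    order = np.lexsort((hull_pts[:, 0], hull_pts[:, 1], d2))
    best = hull_pts[order[0]]
    return (float(best[0]), float(best[1]))


def _oriented_rect_corners(rect: np.ndarray, sign: int) -> dict[str, np.ndarray]:
    """Assign the 4 rectangle corners to upper/lower x anterior/posterior.

    The rectangle ring has sides alternating between the two edge lengths.
    The longer side is the endplate axis; the long side with smaller mean y
    is "upper". Anterior is the end of each long side further along the
    configured anterior x-direction (ties resolved by smaller y).
    """
    sides = [(rect[i], rect[(i + 1) % 4]) for i in range(4)]
    lens = [np.linalg.norm(b - a) for a, b in sides]
    # pair opposite sides; sides 0,2 and 1,3 are parallel
    long_pair = (0, 2) if lens[0] + lens[2] >= lens[1] + lens[3] else (1, 3)
    s_a, s_b = sides[long_pair[0]], sides[long_pair[1]]
    mean_y_a = (s_a[0][1] + s_a[1][1]) / 2
    mean_y_b = (s_b[0][1] + s_b[1][1]) / 2
    upper, lower = (s_a, s_b) if mean_y_a <= mean_y_b else (s_b, s_a)

    def split(side):
        a, b = side
        key_a = (sign * a[0], -a[1])
        key_b = (sign * b[0], -b[1])
        return (a, b) if key_a >= key_b else (b, a)  # anterior first

    ua, up = split(upper)
    la, lp = split(lower)
    return {"upper_anterior": ua, "upper_posterior": up,
            "lower_anterior": la, "lower_posterior": lp}


def corner_points(component: np.ndarray, anterior_direction: str = "left",
                  rect_mode: str = "rotated", min_area: int = MIN_COMPONENT_AREA,
                  level: str = "") -> VertebraCorners:
    """Four endplate corners of a single vertebral-body component.

    `rect_mode` selects the bounding rectangle used for corner assignment:
    "rotated" (minimum-area, robust to tilt) or "axis" (axis-aligned).
    """
    sign = _check_direction(anterior_direction)
    component = np.asarray(component, dtype=bool)
    area = int(component.sum())
    if area < min_area:
        raise DegenerateComponentError(f"component area {area} px < minimum {min_area} px")
    hull_pts = _hull_vertices(component)
    rect = _min_area_rect(hull_pts) if rect_mode == "rotated" else _axis_rect(hull_pts)
    assigned = _oriented_rect_corners(rect, sign)
    return VertebraCorners(
        level=level,
        upper_anterior=_snap_to_hull(assigned["upper_anterior"], hull_pts),
        upper_posterior=_snap_to_hull(assigned["upper_posterior"], hull_pts),
        lower_anterior=_snap_to_hull(assigned["lower_anterior"], hull_pts),
        lower_posterior=_snap_to_hull(assigned["lower_posterior"], hull_pts),
    )


def sacrum_top_corners(mask: np.ndarray, anterior_direction: str = "left",
                       rect_mode: str = "rotated") -> VertebraCorners:
    """Superior anterior/posterior corners of the sacrum (label 6)."""
    component = largest_component(mask, SACRUM_LABEL)
    full = corner_points(component, anterior_direction, rect_mode, level="S1")
    return VertebraCorners(level="S1", upper_anterior=full.upper_anterior,
                           upper_posterior=full.upper_posterior)


def extract_all_landmarks(mask: np.ndarray, anterior_direction: str = "left",
                          rect_mode: str = "rotated") -> LandmarkSet:
    """Landmarks for L1..L5 and the sacrum; absent structures are flagged.

    Per-structure failures (missing label, degenerate component) are collected
    into ``missing`` rather than raised, so partially segmented studies still
    yield the levels that can be measured.
    """
    _check_direction(anterior_direction)
    result = LandmarkSet(anterior_direction=anterior_direction)
    for level, label in LUMBAR_LABELS.items():
        try:
            comp = largest_component(mask, label)
            result.corners[level] = corner_points(comp, anterior_direction,
                                                  rect_mode, level=level)
        except (MissingStructureError, DegenerateComponentError):
            result.missing.append(level)
    try:
        result.corners["S1"] = sacrum_top_corners(mask, anterior_direction, rect_mode)
    except (MissingStructureError, DegenerateComponentError):
        result.missing.append("S1")
    return result
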