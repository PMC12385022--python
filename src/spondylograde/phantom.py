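"""Synthetic lateral-lumbar phantoms with exact ground truth.

Each phantom is a 2-D grayscale image of five stacked vertebral bodies
(L1..L5) above a trapezoidal sacrum, with a paired integer label mask
(0 background, 1..5 = L1..L5, 6 = sacrum). Anterior slip at any of the five
interfaces (L1/L2 .. L5/S1) is injected as a pure in-plane translation of the
upper body along the direction of the lower body's superior endplate, so the
requested slip ratio is realised exactly in the continuous corner coordinates
that are stored as ground truth. A global tilt is applied as a rotation of
the whole column about the image centre, which leaves every slip ratio
unchanged.

The rendered image is class-dependent base intensity (bone brighter than
background, slightly different per level, as vertebrae differ in projected
density) modulated by a low-frequency multiplicative texture field and
corrupted by additive Gaussian noise — a deliberately simple stand-in for
radiographic appearance; see the methods note for what it does not emulate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .geometry import VertebraCorners, LandmarkSet, LUMBAR_LABELS
from . import grading

GRADE_NAMES = ["Normal", "I", "II", "III", "IV"]
INTERFACES = ["L1/L2", "L2/L3", "L3/L4", "L4/L5", "L5/S1"]

# Base 8-bit intensities per mask label (0 = background, 1..5 = L1..L5, 6 = sacrum).
CLASS_INTENSITY = np.array([40, 190, 175, 160, 145, 130, 110], dtype=float)


class PhantomSpecError(ValueError):
    """A PhantomSpec field violates its constraint (field named in message)."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lateral-lumbar phantom.

    ``per_level_slip_ratio`` orders the five interfaces superior to inferior:
    L1/L2, L2/L3, L3/L4, L4/L5, L5/S1. Ratios are fractions of the lower
    superior endplate's length and must lie in [0, 1).
    """

    image_height_px: int = 256
    image_width_px: int = 192
    per_level_slip_ratio: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    vertebra_width_px: int = 72
    vertebra_height_px: int = 28
    inter_body_gap_px: int = 8
    global_tilt_deg: float = 0.0
    noise_sd: float = 6.0
    texture_amplitude: float = 0.15
    anterior_direction: str = "left"
    seed: int = 0

    n_lumbar: int = 5  # anatomy of the lumbar spine; not configurable

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("image_height_px", "image_width_px", "vertebra_width_px",
                     "vertebra_height_px", "inter_body_gap_px"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise PhantomSpecError(f"{name} must be a positive integer, got {v!r}")
        if self.n_lumbar != 5:
            raise PhantomSpecError(f"n_lumbar is fixed at 5, got {self.n_lumbar}")
        ratios = tuple(float(r) for r in self.per_level_slip_ratio)
        if len(ratios) != 5:
            raise PhantomSpecError(
                f"per_level_slip_ratio needs 5 values (L1/L2..L5/S1), got {len(ratios)}")
        for r in ratios:
            if not (0.0 <= r < 1.0):
                raise PhantomSpecError(f"per_level_slip_ratio entries must be in [0,1), got {r}")
        self.per_level_slip_ratio = ratios
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.texture_amplitude < 0:
            raise PhantomSpecError(f"texture_amplitude must be >= 0, got {self.texture_amplitude}")
        if self.anterior_direction not in ("left", "right"):
            raise PhantomSpecError(
                f"anterior_direction must be 'left' or 'right', got {self.anterior_direction!r}")

    @classmethod
    def scaled(cls, image_height_px: int, image_width_px: int, **kwargs) -> "PhantomSpec":
        """Spec with body geometry scaled proportionally to the image size."""
        kwargs.setdefault("vertebra_width_px", max(8, int(round(0.375 * image_width_px))))
        kwargs.setdefault("vertebra_height_px", max(4, int(round(0.11 * image_height_px))))
        kwargs.setdefault("inter_body_gap_px", max(2, int(round(0.031 * image_height_px))))
        return cls(image_height_px=image_height_px, image_width_px=image_width_px, **kwargs)


@dataclass
class Phantom:
    """A rendered phantom with its exact ground truth."""

    image: np.ndarray  # uint8 (H, W)
    mask: np.ndarray   # uint8 (H, W), values 0..6
    truth_corners: LandmarkSet
    truth_ratios: dict[str, float]
    truth_grades: dict[str, str]
    spec: PhantomSpec


def _column_geometry(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Continuous corner coordinates of the untilted, uncentred column.

    Built bottom-up from the sacrum's superior endplate. u is the unit
    anterior direction along endplates, n the unit "up" (decreasing y).
    Returns polygons keyed 'L1'..'L5', 'sacrum', plus sacrum top corners.
    """
    w = float(spec.vertebra_width_px)
    h = float(spec.vertebra_height_px)
    gap = float(spec.inter_body_gap_px)
    sign = -1.0 if spec.anterior_direction == "left" else 1.0
    u = np.array([sign, 0.0])
    n = np.array([0.0, -1.0])

    # sacrum: trapezoid, top edge = superior endplate, narrowing downward
    s_post = np.array([0.0, 0.0])
    s_ant = s_post + w * u
    s_h = 1.4 * h
    inset = 0.18 * w
    sacrum_poly = np.array([
        s_post, s_ant,
        s_ant - inset * u - s_h * n,
        s_post + inset * u - s_h * n,
    ])

    polys = {"sacrum": sacrum_poly}
    lower_post, lower_ant = s_post, s_ant
    # build L5 upward to L1; slip ratios are ordered L1/L2..L5/S1
    for idx, level in enumerate(["L5", "L4", "L3", "L2", "L1"]):
        ratio = spec.per_level_slip_ratio[4 - idx]
        lp = lower_post + ratio * w * u + gap * n          # lower posterior
        la = lp + w * u                                    # lower anterior
        up_, ua = lp + h * n, la + h * n                   # upper posterior/anterior
        polys[level] = np.array([lp, la, ua, up_])
        lower_post, lower_ant = up_, ua
    return {"polys": polys, "sacrum_top": (s_ant.copy(), s_post.copy())}


def _place_and_tilt(geo: dict, spec: PhantomSpec) -> dict:
    """Centre the column in the frame, then rotate by the global tilt."""
    all_pts = np.vstack(list(geo["polys"].values()))
    lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
    extent = hi - lo
    margin_x = (spec.image_width_px - 1 - extent[0]) / 2.0
    margin_y = (spec.image_height_px - 1 - extent[1]) / 2.0
    if margin_x < 1 or margin_y < 1:
        raise PhantomSpecError(
            "image_width_px/image_height_px too small for the requested column "
            f"(needs ~{extent[0] + 2:.0f} x {extent[1] + 2:.0f} px)")
    shift = np.array([margin_x, margin_y]) - lo

    theta = math.radians(spec.global_tilt_deg)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    centre = np.array([(spec.image_width_px - 1) / 2.0, (spec.image_height_px - 1) / 2.0])

    def xform(pts):
        return (np.atleast_2d(pts) + shift - centre) @ rot.T + centre

    polys = {k: xform(v) for k, v in geo["polys"].items()}
    s_ant, s_post = geo["sacrum_top"]
    return {"polys": polys,
            "sacrum_top": (xform(s_ant)[0], xform(s_post)[0])}


def _rasterize(polys: dict[str, np.ndarray], shape: tuple) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.uint8)
    order = [("sacrum", 6)] + [(lvl, lab) for lvl, lab in LUMBAR_LABELS.items()]
    for name, label in order:
        pts = polys[name]
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
        mask[rr, cc] = label
    return mask


def _render(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    base = CLASS_INTENSITY[mask]
    img = base.astype(float)
    if spec.texture_amplitude > 0:
        field_ = rng.standard_normal(mask.shape)
        field_ = gaussian_filter(field_, sigma=max(mask.shape) / 16.0)
        sd = field_.std()
        if sd > 0:
            field_ /= sd
        img = img * (1.0 + spec.texture_amplitude * field_)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=mask.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom and its exact ground truth from `spec`.

    Determinism contract: the same spec (including seed) yields byte-identical
    image and mask arrays.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    geo = _place_and_tilt(_column_geometry(spec), spec)
    polys = geo["polys"]
    mask = _rasterize(polys, (spec.image_height_px, spec.image_width_px))
    image = _render(mask, spec, rng)

    corners = LandmarkSet(anterior_direction=spec.anterior_direction)
    for level in LUMBAR_LABELS:
        lp, la, ua, up_ = polys[level]
        corners.corners[level] = VertebraCorners(
            level=level,
            upper_anterior=tuple(ua), upper_posterior=tuple(up_),
            lower_anterior=tuple(la), lower_posterior=tuple(lp))
    s_ant, s_post = geo["sacrum_top"]
    corners.corners["S1"] = VertebraCorners(
        level="S1", upper_anterior=tuple(s_ant), upper_posterior=tuple(s_post))

    ratios = dict(zip(INTERFACES, spec.per_level_slip_ratio))
    grades = {k: str(grading.grade_from_ratio(v)) for k, v in ratios.items()}
    return Phantom(image=image, mask=mask, truth_corners=corners,
                   truth_ratios=ratios, truth_grades=grades, spec=spec)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

#: Slip-ratio band sampled for each grade. Normal levels carry exactly zero
#: slip (the generator's idealisation of a healthy spine); slipped levels are
#: sampled uniformly inside the Meyerding band, at least `boundary_margin`
#: away from each band edge.
GRADE_BANDS = {
    "I": (grading.DEFAULT_NORMAL_EPSILON, 0.25),
    "II": (0.25, 0.50),
    "III": (0.50, 0.75),
    "IV": (0.75, 0.95),
}


@dataclass
class DatasetManifest:
    """Index of a generated phantom dataset on disk."""

    entries: list[dict]
    grade_mix: dict[str, float]
    seed: int

    @property
    def n(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        return {"entries": self.entries, "grade_mix": self.grade_mix,
                "seed": self.seed, "n": self.n}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(entries=d["entries"], grade_mix=d["grade_mix"], seed=d["seed"])


def sample_spec(rng: np.random.Generator, grade: str,
                template: PhantomSpec | None = None,
                boundary_margin: float = 0.02,
                tilt_range_deg: tuple = (-5.0, 5.0)) -> PhantomSpec:
    """Draw a PhantomSpec whose worst level realises `grade`.

    The slipped interface is chosen uniformly among the five; all other
    levels are slip-free.
    """
    if template is None:
        template = PhantomSpec()
    ratios = [0.0] * 5
    if grade != "Normal":
        lo, hi = GRADE_BANDS[grade]
        level_idx = int(rng.integers(0, 5))
        ratios[level_idx] = float(rng.uniform(lo + boundary_margin, hi - boundary_margin))
    tilt = float(rng.uniform(*tilt_range_deg))
    return PhantomSpec(
        image_height_px=template.image_height_px,
        image_width_px=template.image_width_px,
        per_level_slip_ratio=tuple(ratios),
        vertebra_width_px=template.vertebra_width_px,
        vertebra_height_px=template.vertebra_height_px,
        inter_body_gap_px=template.inter_body_gap_px,
        global_tilt_deg=tilt,
        noise_sd=template.noise_sd,
        texture_amplitude=template.texture_amplitude,
        anterior_direction=template.anterior_direction,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(n: int, grade_mix: dict[str, float], seed: int, out_dir,
                     template: PhantomSpec | None = None,
                     boundary_margin: float = 0.02,
                     tilt_range_deg: tuple = (-5.0, 5.0)) -> DatasetManifest:
    """Write `n` phantoms (image PNG, mask PNG, truth JSON) plus a manifest.

    Study grades are drawn from `grade_mix` (proportions over Normal..IV that
    sum to 1) by a seeded multinomial; everything downstream of the seed is
    deterministic.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mix = {g: float(grade_mix.get(g, 0.0)) for g in GRADE_NAMES}
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"grade_mix proportions must sum to 1, got {total}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(GRADE_NAMES), size=n, p=[mix[g] for g in GRADE_NAMES])

    entries = []
    for i, gi in enumerate(draws):
        grade = GRADE_NAMES[int(gi)]
        spec = sample_spec(rng, grade, template=template,
                           boundary_margin=boundary_margin,
                           tilt_range_deg=tilt_range_deg)
        ph = generate_phantom(spec)
        stem = f"phantom_{i:05d}"
        img_path = out_dir / f"{stem}.png"
        mask_path = out_dir / f"{stem}_mask.png"
        truth_path = out_dir / f"{stem}_truth.json"
        Image.fromarray(ph.image, mode="L").save(img_path)
        Image.fromarray(ph.mask, mode="L").save(mask_path)
        with open(truth_path, "w") as fh:
            json.dump({
                "corners": ph.truth_corners.to_dict(),
                "ratios": ph.truth_ratios,
                "grades": ph.truth_grades,
                "spec": asdict(ph.spec),
            }, fh, indent=1)
        entries.append({
            "id": stem,
            "image": img_path.name,
            "mask": mask_path.name,
            "truth": truth_path.name,
            "grades": ph.truth_grades,
            "study_grade": grade,
        })

    manifest = DatasetManifest(entries=entries, grade_mix=mix, seed=seed)
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def load_pair(out_dir, entry: dict) -> tuple[np.ndarray, np.ndarray]:
    """Read one manifest entry's (image, mask) arrays."""
    out_dir = Path(out_dir)
    img = np.asarray(Image.open(out_dir / entry["image"]), dtype=np.uint8)
    mask = np.asarray(Image.open(out_dir / entry["mask"]), dtype=np.uint8)
    return img, mask
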