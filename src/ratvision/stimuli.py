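"""Procedural stimuli and simulated observers.

The visual objects are built from a small number of thick 3-D segments
("lobes") radiating from a common center, in the spirit of the lobed,
tripod-like shapes used in rodent discrimination experiments.  Views are
rendered by rotating the lobe skeleton in 3-D (azimuth about the vertical
axis), orthographically projecting, scaling so that the object's bounding
extent spans a requested visual angle, rotating in the image plane and
shifting horizontally.

Simulated observers ("responders") turn stimuli into binary choices so the
classification-image machinery can be exercised and validated without animal
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import ViewingGeometry

REGULAR = "regular"
OUTLINE = "outline"


@dataclass(frozen=True)
class Lobe:
    """A thick 3-D segment in object units."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("lobe thickness must be positive")


@dataclass(frozen=True)
class ObjectModel:
    object_id: str
    lobes: tuple[Lobe, ...]
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if len(self.lobes) < 2:
            raise ValueError("an object needs at least 2 lobes")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


@dataclass(frozen=True)
class ViewParams:
    """Transformation parameters of a rendered view (all angles in degrees)."""

    size_deg: float = 35.0
    azimuth_deg: float = 0.0
    inplane_deg: float = 0.0
    hshift_deg: float = 0.0
    style: str = REGULAR

    def __post_init__(self) -> None:
        if self.size_deg <= 0:
            raise ValueError("size_deg must be positive")
        if self.style not in (REGULAR, OUTLINE):
            raise ValueError(f"style must be '{REGULAR}' or '{OUTLINE}'")


@dataclass(frozen=True)
class StructuralVariantSpec:
    """Random perturbation of the lobe skeleton (a 'random tripod')."""

    angle_jitter_deg: float = 20.0
    length_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.angle_jitter_deg < 0 or self.length_jitter < 0:
            raise ValueError("jitters must be non-negative")


@dataclass(frozen=True)
class ResponderSpec:
    """A simulated observer producing binary choices.

    kind 'template': params['templates'] = (image_class0, image_class1);
    choice is the argmax dot product, replaced by a fair coin with
    probability ``lapse_rate``.

    kind 'planted_feature': params['pixels'] = boolean image mask of the
    planted feature, params['threshold'] = required mean mask visibility;
    the response is 1 ("correct") iff the mean occlusion-mask value over the
    planted pixels exceeds the threshold.

    kind 'ideal_observer': params['observer'] = a
    :class:`ratvision.saliency.IdealObserver`; the response is 1 iff the
    template-matching label equals params.get('target_label', 1).
    """

    kind: str
    lapse_rate: float = 0.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse rate must lie in [0, 1]")


def make_canonical_objects() -> tuple[ObjectModel, ObjectModel]:
    """Two fixed, documented object models.

    The first is a three-lobed, tripod-like object (one vertical lobe and two
    oblique lower lobes with opposite depth offsets).  The second is a
    four-lobed, cross-like object.  The construction is deterministic: every
    call returns bitwise-identical models.
    """
    tripod = ObjectModel(
        object_id="tripod",
        lobes=(
            Lobe((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 0.30),
            Lobe((0.0, 0.0, 0.0), (-0.85, -0.75, 0.30), 0.30),
            Lobe((0.0, 0.0, 0.0), (0.85, -0.75, -0.30), 0.30),
        ),
    )
    cross = ObjectModel(
        object_id="cross",
        lobes=(
            Lobe((0.0, 0.0, 0.0), (0.0, 0.95, 0.15), 0.26),
            Lobe((0.0, 0.0, 0.0), (0.0, -0.95, -0.15), 0.26),
            Lobe((0.0, 0.0, 0.0), (0.95, 0.10, -0.20), 0.26),
            Lobe((0.0, 0.0, 0.0), (-0.95, 0.10, 0.20), 0.26),
        ),
    )
    return tripod, cross


def _project_lobes(model: ObjectModel, azimuth_deg: float):
    """3-D azimuth rotation about the vertical axis + orthographic projection.

    Returns 2-D (x, y) endpoints per lobe, in object units.
    """
    az = math.radians(azimuth_deg)
    ca, sa = math.cos(az), math.sin(az)
    out = []
    for lobe in model.lobes:
        pts2d = []
        for p in (lobe.start, lobe.end):
            x, y, z = p
            xr = ca * x + sa * z
            pts2d.append((xr, y))  # orthographic: drop depth
        out.append((pts2d[0], pts2d[1], lobe.thickness))
    return out


def render_view(
    model: ObjectModel,
    view: ViewParams,
    geom: ViewingGeometry,
    *,
    outline_thickness: int = 2,
) -> np.ndarray:
    """Render a grayscale view in [0, 1] on a black background.

    The object's bounding extent (largest of width/height of the
    azimuth-projected geometry, including lobe thickness) spans
    ``view.size_deg * geom.ppd`` pixels within +/- 1 px.  The in-plane
    rotation is applied to the already scaled geometry about the image
    center, so a rotated view is exactly the rotation of the unrotated one
    (up to rasterization); the horizontal shift translates the result.
    """
    h, w = geom.res_h, geom.res_w
    size_px = view.size_deg * geom.ppd
    segs = _project_lobes(model, view.azimuth_deg)

    # scale and centering fixed by the pre-inplane geometry
    lo = np.array([np.inf, np.inf])
    hi = np.array([-np.inf, -np.inf])
    for a, b, thick in segs:
        r = thick / 2.0
        for p in (a, b):
            lo = np.minimum(lo, np.array(p) - r)
            hi = np.maximum(hi, np.array(p) + r)
    extent = float(max(hi - lo))
    scale = size_px / extent
    center_obj = (lo + hi) / 2.0

    cx0 = (w - 1) / 2.0
    cy = (h - 1) / 2.0
    ip = math.radians(view.inplane_deg)
    ci, si = math.cos(ip), math.sin(ip)

    def to_image(p):
        # object units -> centered image coords, y flipped to rows
        ux = (p[0] - center_obj[0]) * scale
        uy = -(p[1] - center_obj[1]) * scale
        # in-plane rotation about the image center (row/col frame)
        vx = ci * ux + si * uy
        vy = -si * ux + ci * uy
        return cx0 + view.hshift_deg * geom.ppd + vx, cy + vy

    # frame check from transformed endpoints (incl. thickness)
    for a, b, thick in segs:
        r = thick / 2.0 * scale
        for p in (a, b):
            px, py = to_image(p)
            if px - r < -1 or px + r > w or py - r < -1 or py + r > h:
                raise ValueError(
                    f"rendered object exceeds the image frame for view {view}"
                )

    img = np.zeros((h, w), dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    rows = np.arange(h, dtype=np.float64)
    for a, b, thick in segs:
        ax, ay = to_image(a)
        bx, by = to_image(b)
        r = thick / 2.0 * scale
        x0, x1 = sorted((ax, bx))
        y0, y1 = sorted((ay, by))
        ci0 = max(int(x0 - r - 2), 0)
        ci1 = min(int(x1 + r + 3), w)
        ri0 = max(int(y0 - r - 2), 0)
        ri1 = min(int(y1 + r + 3), h)
        if ci0 >= ci1 or ri0 >= ri1:
            continue
        X, Y = np.meshgrid(cols[ci0:ci1], rows[ri0:ri1])
        dx, dy = bx - ax, by - ay
        denom = dx * dx + dy * dy
        if denom == 0:
            d2 = (X - ax) ** 2 + (Y - ay) ** 2
        else:
            t = np.clip(((X - ax) * dx + (Y - ay) * dy) / denom, 0.0, 1.0)
            d2 = (X - (ax + t * dx)) ** 2 + (Y - (ay + t * dy)) ** 2
        patch = img[ri0:ri1, ci0:ci1]
        np.maximum(patch, np.where(d2 <= r * r, model.intensity, 0.0), out=patch)

    if view.style == OUTLINE:
        img = to_outline(img, thickness=outline_thickness)
    return img


def make_structural_variant(
    model: ObjectModel, spec: StructuralVariantSpec
) -> ObjectModel:
    """Perturb lobe directions and lengths; seeded and reproducible.

    Each lobe's direction is rotated about the viewing axis by an angle drawn
    uniformly in +/- angle_jitter_deg, and its length is scaled by a factor
    drawn uniformly in 1 +/- length_jitter.  The attachment point (lobe
    start) is preserved.
    """
    rng = np.random.default_rng(spec.seed)
    new_lobes = []
    for lobe in model.lobes:
        ang = math.radians(rng.uniform(-spec.angle_jitter_deg, spec.angle_jitter_deg))
        lf = 1.0 + rng.uniform(-spec.length_jitter, spec.length_jitter)
        sx, sy, sz = lobe.start
        dx = lobe.end[0] - sx
        dy = lobe.end[1] - sy
        dz = lobe.end[2] - sz
        c, s = math.cos(ang), math.sin(ang)
        ndx, ndy = c * dx - s * dy, s * dx + c * dy
        new_end = (sx + lf * ndx, sy + lf * ndy, sz + lf * dz)
        new_lobes.append(Lobe(lobe.start, new_end, lobe.thickness))
    return replace(model, lobes=tuple(new_lobes))


def to_outline(image: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Keep only the boundary of the filled region, interior set to 0."""
    mask = image > 1e-9
    if not mask.any():
        raise ValueError("to_outline: image contains no object pixels")
    interior = ndimage.binary_erosion(mask, iterations=thickness)
    return np.where(mask & ~interior, image, 0.0)


def simulate_responses(
    responder: ResponderSpec,
    trials: Sequence,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one binary label per trial.

    ``trials`` holds images, or ``(image, mask)`` pairs when the responder
    needs the occlusion mask (kind 'planted_feature').  With probability
    ``lapse_rate`` the deterministic choice is replaced by a fair coin,
    modelling exploratory lapses.
    """
    labels = np.empty(len(trials), dtype=np.int64)
    if responder.kind == "template":
        t0, t1 = responder.params["templates"]
        t0 = np.asarray(t0).ravel()
        t1 = np.asarray(t1).ravel()
        for i, trial in enumerate(trials):
            img = np.asarray(trial[0] if isinstance(trial, tuple) else trial).ravel()
            labels[i] = int(img @ t1 > img @ t0)
    elif responder.kind == "planted_feature":
        pix = np.asarray(responder.params["pixels"], dtype=bool)
        thr = float(responder.params["threshold"])
        for i, trial in enumerate(trials):
            if not (isinstance(trial, tuple) and len(trial) == 2):
                raise ValueError("planted_feature responder needs (image, mask) trials")
            mask = np.asarray(trial[1])
            labels[i] = int(mask[pix].mean() > thr)
    elif responder.kind == "ideal_observer":
        from .saliency import ideal_observer_classify

        observer = responder.params["observer"]
        target = responder.params.get("target_label", 1)
        for i, trial in enumerate(trials):
            img = trial[0] if isinstance(trial, tuple) else trial
            labels[i] = int(ideal_observer_classify(img, observer) == target)
    else:
        raise ValueError(f"unknown responder kind: {responder.kind!r}")

    if responder.lapse_rate > 0:
        lapse = rng.random(len(trials)) < responder.lapse_rate
        coin = rng.integers(0, 2, size=len(trials))
        labels = np.where(lapse, coin, labels)
    return labels
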