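"""Viewing geometry and the acuity-matched image-augmentation front end.

A head-free rodent viewing a screen from a fixed distance introduces
trial-to-trial variability in head pose.  Pitch and yaw rotations of the head
displace the retinal image vertically and horizontally, while roll rotations
rotate it in the image plane.  This module converts head-pose angles into the
equivalent affine image transformations and applies the blur/noise front end
that emulates the animal's low visual acuity.

The displacement produced by a head rotation of ``theta`` degrees at viewing
distance ``d`` is ``2 * d * tan(theta / 2)`` (cm on the screen plane), which
is then expressed as a fraction of the screen extent along that axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage


@dataclass(frozen=True)
class ViewingGeometry:
    """Physical layout of the stimulus display relative to the observer.

    Parameters
    ----------
    d : float
        Viewing distance in cm.
    screen_w, screen_h : float
        Physical screen size in cm.
    res_w, res_h : int
        Screen resolution in pixels.
    ppd : float
        Pixels per degree of visual angle.  The default follows the rig
        convention that the 224-pixel display spans roughly 96 degrees.
    """

    d: float = 30.0
    screen_w: float = 48.0
    screen_h: float = 27.0
    res_w: int = 224
    res_h: int = 224
    ppd: float = 224.0 / 96.0

    def __post_init__(self) -> None:
        for name in ("d", "screen_w", "screen_h", "res_w", "res_h", "ppd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ViewingGeometry.{name} must be positive")

    @property
    def cm_per_pixel_w(self) -> float:
        return self.screen_w / self.res_w

    @property
    def cm_per_pixel_h(self) -> float:
        return self.screen_h / self.res_h


@dataclass(frozen=True)
class HeadPoseRanges:
    """Full angular spans (degrees) of head-pose variability.

    Defaults are the measured spans for body-restrained but head-free rats:
    60 (pitch), 35 (roll) and 20 (yaw) degrees.
    """

    pitch_span: float = 60.0
    roll_span: float = 35.0
    yaw_span: float = 20.0

    def __post_init__(self) -> None:
        if min(self.pitch_span, self.roll_span, self.yaw_span) < 0:
            raise ValueError("head-pose spans must be non-negative")


@dataclass(frozen=True)
class NoiseBlurParams:
    """Gaussian blur (pixels) and additive Gaussian noise (intensity units)."""

    sigma_blur: float = 0.0
    sigma_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_blur < 0 or self.sigma_noise < 0:
            raise ValueError("sigma_blur and sigma_noise must be >= 0")


@dataclass(frozen=True)
class AugmentationSample:
    """One realized head pose expressed as image-plane transformation."""

    alpha_deg: float = 0.0
    x_frac: float = 0.0
    y_frac: float = 0.0


@dataclass(frozen=True)
class AugmentationConfig:
    """Bundle of everything `augment` needs."""

    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)
    pose: HeadPoseRanges = field(default_factory=HeadPoseRanges)
    blur_noise: NoiseBlurParams = field(default_factory=NoiseBlurParams)


def angular_displacement(theta_deg: float, d: float) -> float:
    """Screen-plane displacement (cm) produced by a head rotation.

    ``Delta = 2 * d * tan(theta / 2)``; odd and strictly increasing in theta
    on (-180, 180).
    """
    if abs(theta_deg) >= 180.0:
        raise ValueError("theta must satisfy |theta| < 180 degrees")
    return 2.0 * d * math.tan(math.radians(theta_deg) / 2.0)


def displacement_fraction(delta_cm: float, screen_dim_cm: float) -> float:
    """Half-width of the uniform translation distribution, in image fractions.

    The displacement in pixels relative to the image extent in pixels equals
    the displacement in cm relative to the screen extent in cm, and the
    translation is sampled uniformly in ``+/- delta / (2 * screen_dim)``.
    """
    if screen_dim_cm <= 0:
        raise ValueError("screen dimension must be positive")
    return delta_cm / (2.0 * screen_dim_cm)


def sample_head_pose(
    ranges: HeadPoseRanges,
    geom: ViewingGeometry,
    rng: np.random.Generator,
) -> AugmentationSample:
    """Draw one head pose and convert it to an image-plane sample.

    Roll maps directly to in-plane rotation (uniform on +/- roll_span/2).
    Pitch and yaw are drawn uniformly on +/- span/2 and converted through the
    tangent rule to vertical / horizontal shifts as image fractions.
    """
    roll = rng.uniform(-ranges.roll_span / 2.0, ranges.roll_span / 2.0) if ranges.roll_span else 0.0
    pitch = rng.uniform(-ranges.pitch_span / 2.0, ranges.pitch_span / 2.0) if ranges.pitch_span else 0.0
    yaw = rng.uniform(-ranges.yaw_span / 2.0, ranges.yaw_span / 2.0) if ranges.yaw_span else 0.0
    y_frac = math.copysign(
        displacement_fraction(abs(angular_displacement(pitch, geom.d)), geom.screen_h), pitch
    )
    x_frac = math.copysign(
        displacement_fraction(abs(angular_displacement(yaw, geom.d)), geom.screen_w), yaw
    )
    return AugmentationSample(alpha_deg=roll, x_frac=x_frac, y_frac=y_frac)


def apply_affine(image: np.ndarray, sample: AugmentationSample) -> np.ndarray:
    """Rotate about the image center then translate, bilinear, zero-filled."""
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("apply_affine expects a square 2-D image")
    if sample.alpha_deg == 0.0 and sample.x_frac == 0.0 and sample.y_frac == 0.0:
        return image.copy()
    h, w = image.shape
    # Row/col convention: rows increase downwards; y_frac > 0 shifts down.
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    t = np.array([sample.y_frac * h, sample.x_frac * w])
    a = math.radians(sample.alpha_deg)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    # Forward map: out = R @ (in - c) + c + t  =>  in = R^T @ (out - c - t) + c
    inv = rot.T
    offset = c - inv @ (c + t)
    return ndimage.affine_transform(
        image, inv, offset=offset, order=1, mode="constant", cval=0.0
    )


def apply_blur_noise(
    image: np.ndarray, params: NoiseBlurParams, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian blur, then i.i.d. additive Gaussian noise, then clip to [0,1]."""
    out = image
    if params.sigma_blur > 0:
        out = ndimage.gaussian_filter(out, sigma=params.sigma_blur, mode="nearest")
    if params.sigma_noise > 0:
        out = out + rng.normal(0.0, params.sigma_noise, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def augment(
    image: np.ndarray, config: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Full front end: random head-pose affine, then blur and noise.

    One fresh pose and one fresh noise pattern are drawn per call.  Any mask
    (occlusion) is expected to have been applied to ``image`` upstream.
    """
    sample = sample_head_pose(config.pose, config.geometry, rng)
    out = apply_affine(image, sample)
    return apply_blur_noise(out, config.blur_noise, rng)


def config_from_yaml(path) -> AugmentationConfig:
    """Load an augmentation config block from YAML.

    Expected keys: d_cm, screen_cm [w, h], res_px [w, h],
    pose_spans_deg [pitch, roll, yaw], sigma_blur_px, sigma_noise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    geom = ViewingGeometry(
        d=raw.get("d_cm", 30.0),
        screen_w=raw.get("screen_cm", [48.0, 27.0])[0],
        screen_h=raw.get("screen_cm", [48.0, 27.0])[1],
        res_w=raw.get("res_px", [224, 224])[0],
        res_h=raw.get("res_px", [224, 224])[1],
        ppd=raw.get("ppd", 224.0 / 96.0),
    )
    spans = raw.get("pose_spans_deg", [60.0, 35.0, 20.0])
    pose = HeadPoseRanges(pitch_span=spans[0], roll_span=spans[1], yaw_span=spans[2])
    bn = NoiseBlurParams(
        sigma_blur=raw.get("sigma_blur_px", 0.0), sigma_noise=raw.get("sigma_noise", 0.0)
    )
    return AugmentationConfig(geometry=geom, pose=pose, blur_noise=bn)
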