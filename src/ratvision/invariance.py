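"""View-invariance metrics for saliency maps and choices.

A screen-centered strategy keeps relying on the same display region as the
object transforms; an object-centered strategy keeps relying on the same
*object* region.  The two are dissociated by comparing the overlap
(intersection over union) of significant regions computed in raw screen
coordinates versus after inverse-transforming each map back to the default
view ("aligned" overlap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .geometry import ViewingGeometry
from .stimuli import ViewParams


@dataclass(frozen=True)
class OverlapResult:
    raw: float
    aligned: float
    view_a: ViewParams
    view_b: ViewParams


@dataclass(frozen=True)
class ConsistencyResult:
    fraction_tripod_regular: float
    fraction_tripod_outline: float
    tn: float
    fp: float
    fn: float
    tp: float

    @property
    def accuracy(self) -> float:
        return self.tn + self.tp


def raw_overlap(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
    """|A intersect B| / |A union B|; 0 when both masks are empty."""
    a = np.asarray(sig_a, dtype=bool)
    b = np.asarray(sig_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return float((a & b).sum() / union)


def _forward_matrix(
    view: ViewParams,
    default: ViewParams,
    geom: ViewingGeometry,
    azimuth_correction: bool,
):
    """Affine (col,row) map taking default-view coordinates to view coordinates.

    Composition mirrors the renderer: azimuth foreshortening (approximated
    as a horizontal compression by cos(azimuth) about the object's vertical
    axis), scaling by the size ratio, in-plane rotation, horizontal shift.
    """
    s = view.size_deg / default.size_deg
    ip = math.radians(view.inplane_deg - default.inplane_deg)
    # in (col,row) coordinates an object-frame rotation by +ip appears as
    # rotation by -ip (rows grow downward)
    ci, si = math.cos(ip), math.sin(ip)
    rot = np.array([[ci, si], [-si, ci]])
    if azimuth_correction:
        az = math.radians(view.azimuth_deg)
        az0 = math.radians(default.azimuth_deg)
        if abs(view.azimuth_deg) >= 90 or abs(default.azimuth_deg) >= 90:
            raise ValueError("azimuth inverse undefined for |azimuth| >= 90 degrees")
        squeeze = math.cos(az) / math.cos(az0)
    else:
        squeeze = 1.0
    m = rot @ (s * np.diag([squeeze, 1.0]))
    t = np.array([(view.hshift_deg - default.hshift_deg) * geom.ppd, 0.0])
    return m, t


def align_map(
    smap: np.ndarray,
    view: ViewParams,
    geom: ViewingGeometry,
    default: ViewParams | None = None,
    *,
    azimuth_correction: bool = True,
) -> np.ndarray:
    """Resample a per-pixel map from a view's coordinates to the default view.

    Inverse in-plane rotation and scaling about the image center, inverse
    horizontal shift, and (approximately) inverse azimuth foreshortening by
    horizontal re-expansion.  Boolean masks are resampled nearest-neighbour;
    float maps bilinearly.
    """
    default = ViewParams() if default is None else default
    m, t = _forward_matrix(view, default, geom, azimuth_correction)
    arr = np.asarray(smap)
    h, w = arr.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (col, row)
    # output (default coords) pixel o maps to input coords F(o) = C + t + M (o - C)
    # ndimage works in (row, col): swap axes of M and t
    m_rc = np.array([[m[1, 1], m[1, 0]], [m[0, 1], m[0, 0]]])
    t_rc = t[::-1]
    c_rc = center[::-1]
    offset = c_rc + t_rc - m_rc @ c_rc
    if arr.dtype == bool:
        out = ndimage.affine_transform(
            arr.astype(np.float32), m_rc, offset=offset, order=0, mode="constant", cval=0.0
        )
        return out > 0.5
    return ndimage.affine_transform(
        arr.astype(float), m_rc, offset=offset, order=1, mode="constant", cval=0.0
    )


def aligned_overlap(
    map_a: np.ndarray,
    view_a: ViewParams,
    map_b: np.ndarray,
    view_b: ViewParams,
    geom: ViewingGeometry,
    default: ViewParams | None = None,
    *,
    azimuth_correction: bool = True,
) -> float:
    """IoU of the two masks after realignment to the default view."""
    a = align_map(map_a, view_a, geom, default, azimuth_correction=azimuth_correction)
    b = align_map(map_b, view_b, geom, default, azimuth_correction=azimuth_correction)
    return raw_overlap(a, b)


def overlap_pair(
    map_a, view_a, map_b, view_b, geom, default=None, *, azimuth_correction=True
) -> OverlapResult:
    return OverlapResult(
        raw=raw_overlap(map_a, map_b),
        aligned=aligned_overlap(
            map_a, view_a, map_b, view_b, geom, default,
            azimuth_correction=azimuth_correction,
        ),
        view_a=view_a,
        view_b=view_b,
    )


def map_correlation(
    map_a: np.ndarray, map_b: np.ndarray, domain: np.ndarray | None = None
) -> float:
    """Pearson r over pixels defined (finite) in both maps."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("map shapes differ")
    valid = np.isfinite(a) & np.isfinite(b)
    if domain is not None:
        valid &= np.asarray(domain, dtype=bool)
    if valid.sum() < 3:
        raise ValueError("need at least 3 jointly defined pixels")
    av, bv = a[valid], b[valid]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("Pearson r undefined for a constant map")
    return float(stats.pearsonr(av, bv)[0])


def choice_fraction(choices: np.ndarray) -> float:
    """Fraction of trials on which the target ('tripod') was chosen."""
    choices = np.asarray(choices)
    if choices.size == 0:
        raise ValueError("empty choice vector")
    return float(choices.mean())


def outline_consistency(
    choices_regular: np.ndarray, choices_outline: np.ndarray
) -> ConsistencyResult:
    """Regular-vs-outline choice consistency, regular choices as ground truth.

    Confusion entries are fractions of all pairs; accuracy = TN + TP.
    """
    reg = np.asarray(choices_regular).astype(bool)
    out = np.asarray(choices_outline).astype(bool)
    if reg.shape != out.shape:
        raise ValueError("paired choice vectors must have equal length")
    n = reg.size
    if n == 0:
        raise ValueError("empty choice vectors")
    return ConsistencyResult(
        fraction_tripod_regular=float(reg.mean()),
        fraction_tripod_outline=float(out.mean()),
        tn=float((~reg & ~out).sum() / n),
        fp=float((~reg & out).sum() / n),
        fn=float((reg & ~out).sum() / n),
        tp=float((reg & out).sum() / n),
    )
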