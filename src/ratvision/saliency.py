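"""Classification-image estimators and the ideal-observer model.

Two behavioural saliency estimators are implemented.

The *bubbles* estimator occludes a stimulus with masks made of randomly
placed Gaussian apertures and correlates per-pixel mask transparency with
response correctness:

    S_ij = sum_mu m_ij^mu l_mu / sum_mu |m_ij^mu|

with m the mask, l in {0, 1} the trial outcome.  Pixel-wise significance is
assessed against a null built from random permutations of the outcome
vector (one-tailed, no multiplicity correction, matching common practice in
the animal literature).

The *structural-variant* estimator averages the variant images by choice:

    S_ij = E[T_ij | chosen] - E[T_ij | rejected]

with significance from a permutation null smoothed by a per-pixel Gaussian
fit.

The ideal observer stores one template per object view and labels an input
by the template with the largest dot product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.355


def bubble_sigma_px(size_deg: float, ppd: float, convention: str = "fwhm") -> float:
    """Gaussian sigma (pixels) for a bubble of a given visual-angle size.

    'Size' is interpreted as the full width at half maximum by default; the
    alternative convention treats the stated size directly as sigma.
    """
    if convention == "fwhm":
        return size_deg * ppd / FWHM_PER_SIGMA
    if convention == "sigma":
        return size_deg * ppd
    raise ValueError("convention must be 'fwhm' or 'sigma'")


@dataclass(frozen=True)
class BubbleMaskSpec:
    """Random Gaussian-aperture occlusion masks.

    ``sigma_px`` defaults to a 2-degree FWHM at the standard pixels-per-degree
    factor; ``region_fraction`` confines bubble centers to a centered square.
    """

    n_bubbles: int = 40
    sigma_px: float = bubble_sigma_px(2.0, 224.0 / 96.0)
    region_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_bubbles < 0:
            raise ValueError("n_bubbles must be >= 0")
        if not 0.0 < self.region_fraction <= 1.0:
            raise ValueError("region_fraction must lie in (0, 1]")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")


@dataclass
class MaskedTrialSet:
    """Occlusion masks (or variant images) with their binary outcomes."""

    masks: np.ndarray  # (N, H, W), values in [0, 1] for bubble masks
    labels: np.ndarray  # (N,) binary

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        self.labels = np.asarray(self.labels)
        if self.masks.ndim != 3 or len(self.masks) != len(self.labels):
            raise ValueError("masks must be (N, H, W) with one label per mask")


@dataclass
class SaliencyMap:
    S: np.ndarray
    sig_salient: np.ndarray
    sig_antisalient: np.ndarray
    p_threshold: float
    n_permutations: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.sig_salient & self.sig_antisalient):
            raise ValueError("salient and anti-salient regions must be disjoint")


@dataclass
class IdealObserver:
    """Template store; >= 1 template per class label."""

    templates: np.ndarray  # (T, H, W)
    labels: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates)
        self.labels = np.asarray(self.labels)
        if len(self.templates) != len(self.labels) or len(self.templates) == 0:
            raise ValueError("one label per template, at least one template")


def make_bubble_mask(
    spec: BubbleMaskSpec,
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    n_masks: int | None = None,
) -> np.ndarray:
    """Masks of ``n_bubbles`` Gaussian apertures, clipped at full transparency.

    Bubble centers are uniform in the centered square spanning
    ``region_fraction`` of each image dimension.  Returns (H, W) or
    (n_masks, H, W) float32 with values in [0, 1].
    """
    h, w = image_shape
    n = 1 if n_masks is None else n_masks
    out = np.zeros((n, h, w), dtype=np.float32)
    sig = spec.sigma_px
    half = int(np.ceil(4 * sig))
    win = np.arange(-half, half + 1, dtype=np.float32)
    if spec.n_bubbles > 0:
        r0, r1 = (1 - spec.region_fraction) / 2 * h, (1 + spec.region_fraction) / 2 * h
        c0, c1 = (1 - spec.region_fraction) / 2 * w, (1 + spec.region_fraction) / 2 * w
        rows = rng.uniform(r0, r1, size=(n, spec.n_bubbles))
        cols = rng.uniform(c0, c1, size=(n, spec.n_bubbles))
        for m in range(n):
            for k in range(spec.n_bubbles):
                ri, ci = rows[m, k], cols[m, k]
                ir, ic = int(round(ri)), int(round(ci))
                rr = np.exp(-((win + ir - ri) ** 2) / (2 * sig * sig))
                cc = np.exp(-((win + ic - ci) ** 2) / (2 * sig * sig))
                rsl = slice(max(ir - half, 0), min(ir + half + 1, h))
                csl = slice(max(ic - half, 0), min(ic + half + 1, w))
                out[m, rsl, csl] += np.outer(
                    rr[rsl.start - (ir - half) : rsl.stop - (ir - half)],
                    cc[csl.start - (ic - half) : csl.stop - (ic - half)],
                )
    np.clip(out, 0.0, 1.0, out=out)
    return out[0] if n_masks is None else out


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Alpha-mask against a uniform black background: p* = p * m."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return image * mask


def bubbles_saliency(trials: MaskedTrialSet) -> np.ndarray:
    """Raw bubbles map; pixels never covered by any mask are NaN."""
    if len(trials.masks) == 0:
        raise ValueError("empty trial set")
    m = trials.masks.reshape(len(trials.masks), -1)
    l = trials.labels.astype(np.float32)
    num = m.T @ l
    den = np.abs(m).sum(axis=0)
    S = np.full(m.shape[1], np.nan, dtype=np.float64)
    covered = den > 0
    S[covered] = num[covered] / den[covered]
    return S.reshape(trials.masks.shape[1:])


def _permutation_null_bubbles(
    trials: MaskedTrialSet, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null maps from outcome-vector permutations; shape (H*W, n_perm)."""
    m = trials.masks.reshape(len(trials.masks), -1).astype(np.float32)
    den = np.abs(m).sum(axis=0)
    perms = np.empty((len(trials.labels), n_perm), dtype=np.float32)
    base = trials.labels.astype(np.float32)
    for v in range(n_perm):
        perms[:, v] = rng.permutation(base)
    null = m.T @ perms
    with np.errstate(invalid="ignore", divide="ignore"):
        null /= den[:, None]
    null[den == 0] = np.nan
    return null


def permutation_significance_bubbles(
    trials: MaskedTrialSet,
    n_perm: int = 1000,
    p_th: float = 0.05,
    rng: np.random.Generator | None = None,
    *,
    return_null: bool = False,
):
    """One-tailed permutation test per pixel at threshold ``p_th``.

    A pixel is significantly salient if its observed value exceeds the
    (1 - p_th) quantile of its permutation null, anti-salient if it falls
    below the p_th quantile.  Never-covered pixels stay non-significant.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = np.unique(trials.labels)
    if len(labels) < 2:
        raise ValueError("trial outcomes contain a single label")
    S = bubbles_saliency(trials)
    null = _permutation_null_bubbles(trials, n_perm, rng)
    flat = S.ravel()
    covered = np.isfinite(flat)
    q_hi = np.nanquantile(null[covered], 1 - p_th, axis=1)
    q_lo = np.nanquantile(null[covered], p_th, axis=1)
    sal = np.zeros(flat.shape, dtype=bool)
    anti = np.zeros(flat.shape, dtype=bool)
    sal[covered] = flat[covered] > q_hi
    anti[covered] = flat[covered] < q_lo
    anti &= ~sal
    smap = SaliencyMap(
        S=S,
        sig_salient=sal.reshape(S.shape),
        sig_antisalient=anti.reshape(S.shape),
        p_threshold=p_th,
        n_permutations=n_perm,
    )
    return (smap, null) if return_null else smap


def area_matched_threshold(
    S: np.ndarray, null: np.ndarray, target_area: int
) -> SaliencyMap:
    """Choose p_th by bisection so the salient region has a target area.

    ``null`` is the (H*W, n_perm) permutation null from
    :func:`permutation_significance_bubbles` with ``return_null=True``.
    """
    flat = S.ravel()
    covered = np.isfinite(flat)
    n_perm = null.shape[1]
    if target_area > flat.size:
        raise ValueError("target_area exceeds the image area")

    def area(p: float) -> np.ndarray:
        q = np.nanquantile(null[covered], 1 - p, axis=1)
        sal = np.zeros(flat.shape, dtype=bool)
        sal[covered] = flat[covered] > q
        return sal

    if target_area == 0:
        smap_sal = np.zeros(flat.shape, dtype=bool)
        p_best = 0.0
    else:
        lo, hi = 1.0 / (n_perm + 1), 0.5
        a_lo, a_hi = area(lo).sum(), area(hi).sum()
        if not a_lo <= target_area <= a_hi:
            raise ValueError(
                f"target_area {target_area} unreachable; achievable range "
                f"[{a_lo}, {a_hi}] for p in [{lo:.4g}, 0.5]"
            )
        p_best, best_sal, best_err = lo, area(lo), abs(int(a_lo) - target_area)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            sal = area(mid)
            err = abs(int(sal.sum()) - target_area)
            if err < best_err:
                p_best, best_sal, best_err = mid, sal, err
            if sal.sum() > target_area:
                hi = mid
            elif sal.sum() < target_area:
                lo = mid
            else:
                break
        if best_err > 1:
            raise ValueError(
                f"bisection could not match area {target_area} within 1 px "
                f"(best |error| = {best_err})"
            )
        smap_sal = best_sal
    q_lo = np.nanquantile(null[covered], max(p_best, 1.0 / (n_perm + 1)), axis=1)
    anti = np.zeros(flat.shape, dtype=bool)
    anti[covered] = flat[covered] < q_lo
    anti &= ~smap_sal
    return SaliencyMap(
        S=S,
        sig_salient=smap_sal.reshape(S.shape),
        sig_antisalient=anti.reshape(S.shape),
        p_threshold=float(p_best),
        n_permutations=n_perm,
        meta={"area_matched": True, "target_area": int(target_area)},
    )


def top_area_region(S: np.ndarray, null: np.ndarray, area: int) -> np.ndarray:
    """The ``area`` pixels with the strongest null-standardized saliency.

    Ranks pixels by (S - null mean) / null SD and returns a boolean mask of
    the top ``area`` of them.  This is the size-matched analogue of the
    area-matched significance threshold, useful when the region of interest
    is smaller than the granularity the permutation quantiles can resolve.
    """
    import warnings

    flat = S.ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(null, axis=1)
        sd = np.nanstd(null, axis=1)
    z = np.full(flat.shape, -np.inf)
    ok = np.isfinite(flat) & np.isfinite(mu) & (sd > 0)
    z[ok] = (flat[ok] - mu[ok]) / sd[ok]
    if area <= 0:
        return np.zeros(S.shape, dtype=bool)
    mask = np.zeros(flat.shape, dtype=bool)
    mask[np.argsort(z)[-area:]] = True
    return mask.reshape(S.shape)


def ideal_observer_classify(image: np.ndarray, observer: IdealObserver):
    """Label of the template with the largest (unnormalized) dot product.

    Exact ties break toward the lowest template index.
    """
    img = np.asarray(image).ravel()
    t = observer.templates.reshape(len(observer.templates), -1)
    if t.shape[1] != img.size:
        raise ValueError("image and template shapes differ")
    scores = t @ img
    return observer.labels[int(np.argmax(scores))]


def tripod_saliency(trials: MaskedTrialSet) -> np.ndarray:
    """Choice-triggered average difference over variant images."""
    r = trials.labels.astype(bool)
    if not r.any() or r.all():
        raise ValueError("both choice classes must be present")
    T = trials.masks.astype(np.float64)
    return T[r].mean(axis=0) - T[~r].mean(axis=0)


def permutation_significance_tripod(
    trials: MaskedTrialSet,
    n_perm: int = 100,
    p_th: float = 0.01,
    rng: np.random.Generator | None = None,
) -> SaliencyMap:
    """Permutation test with a per-pixel Gaussian fit to the null.

    The choice vector is permuted ``n_perm`` times; at each pixel a 1-D
    Gaussian (mean, SD) is fitted to the null saliency values and the
    observed value is tested one-tailed at ``p_th`` on each side.  Pixels
    with zero null variance are left non-significant (and counted in a log
    message).
    """
    rng = np.random.default_rng() if rng is None else rng
    S = tripod_saliency(trials)
    T = trials.masks.reshape(len(trials.masks), -1).astype(np.float32)
    r = trials.labels.astype(np.float32)
    n1 = float(r.sum())
    n0 = float(len(r) - n1)
    col_sum = T.sum(axis=0)
    perms = np.empty((len(r), n_perm), dtype=np.float32)
    for v in range(n_perm):
        perms[:, v] = rng.permutation(r)
    # S^(v) = T' p (1/n1 + 1/n0) - sum(T)/n0, since class counts are preserved
    null = (T.T @ perms) * (1.0 / n1 + 1.0 / n0) - (col_sum / n0)[:, None]
    mu = null.mean(axis=1)
    sd = null.std(axis=1)
    flat = S.ravel()
    ok = sd > 0
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.info(
            "tripod permutation test: %d pixels with zero null variance "
            "marked non-significant", n_degenerate,
        )
    z = np.zeros(flat.shape)
    z[ok] = (flat[ok] - mu[ok]) / sd[ok]
    p_hi = stats.norm.sf(z)
    p_lo = stats.norm.cdf(z)
    sal = ok & (p_hi < p_th)
    anti = ok & (p_lo < p_th) & ~sal
    return SaliencyMap(
        S=S,
        sig_salient=sal.reshape(S.shape),
        sig_antisalient=anti.reshape(S.shape),
        p_threshold=p_th,
        n_permutations=n_perm,
    )


def overlay_rgb(smap: SaliencyMap) -> np.ndarray:
    """Grayscale map with red (salient) / cyan (anti-salient) overlays."""
    S = np.nan_to_num(smap.S, nan=0.0)
    lo, hi = S.min(), S.max()
    gray = (S - lo) / (hi - lo) if hi > lo else np.zeros_like(S)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    rgb[smap.sig_salient] = [1.0, 0.2, 0.2]
    rgb[smap.sig_antisalient] = [0.2, 1.0, 1.0]
    return rgb
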