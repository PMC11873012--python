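"""Contrast-sensitivity simulation and blur/noise calibration.

The front-end blur and noise parameters of the augmentation pipeline are
chosen so that a simple simulated observer reproduces a target contrast
sensitivity function (CSF).  The observer performs a grating-detection task:
images are either sinusoidal gratings (random orientation and phase, variable
contrast) or uniform mid-gray fields, both degraded by Gaussian blur and
additive Gaussian noise.  The observer measures local contrast as the
standard deviation of pixel intensities inside a grid of square patches and
feeds that feature vector to a linear SVM.

Psychometric functions p(detection | contrast) are estimated per spatial
frequency; the contrast threshold xi is the 50% point (interpolated in log
contrast) and sensitivity is sigma = 1 / xi.  A grid search over
(sigma_blur, sigma_noise, patch size) minimizes the L1 distance between the
simulated CSF and the target curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.svm import LinearSVC

from .geometry import NoiseBlurParams, ViewingGeometry

# Spatial-frequency grid: log-spaced from 0.04 to 1.0 cycles/deg with the
# reference peak frequency 0.1 included as a grid point.
DEFAULT_NU_GRID = np.concatenate(
    [np.geomspace(0.04, 0.1, 3)[:-1], np.geomspace(0.1, 1.0, 5)]
)
DEFAULT_CONTRAST_GRID = np.geomspace(0.005, 1.0, 12)


@dataclass(frozen=True)
class GratingSpec:
    nu: float  # cycles / degree
    contrast: float
    orientation: float = 0.0  # radians
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("spatial frequency must be positive")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


@dataclass
class PsychometricCurve:
    contrasts: np.ndarray
    p_detect: np.ndarray
    p_sd: np.ndarray

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        self.p_detect = np.asarray(self.p_detect, dtype=float)
        self.p_sd = np.asarray(self.p_sd, dtype=float)
        if not (len(self.contrasts) == len(self.p_detect) == len(self.p_sd)):
            raise ValueError("psychometric arrays must share a length")
        if np.any(np.diff(self.contrasts) <= 0):
            raise ValueError("contrasts must be strictly ascending")


@dataclass
class CSFCurve:
    nus: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        self.nus = np.asarray(self.nus, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if len(self.nus) != len(self.sensitivity):
            raise ValueError("nus and sensitivity must share a length")
        if np.any(self.sensitivity < 0):
            raise ValueError("sensitivity must be non-negative")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"nu": self.nus, "sensitivity": self.sensitivity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "CSFCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["nu"].to_numpy(), df["sensitivity"].to_numpy())


@dataclass
class CSFFitResult:
    sigma_blur: float
    sigma_noise: float
    patch_size: int
    l1: float
    landscape: np.ndarray  # (n_blur, n_noise, n_patch)
    sigma_blur_grid: np.ndarray
    sigma_noise_grid: np.ndarray
    patch_grid: np.ndarray
    best_csf: CSFCurve


def make_grating(
    spec: GratingSpec, geom: ViewingGeometry, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sine grating on a mid-gray background: 0.5 + (c/2) sin(2 pi nu u + phi).

    ``u`` is the position in degrees of visual angle along the orientation
    axis.  Frequencies above the Nyquist limit of the pixel grid raise.
    """
    if spec.nu > geom.ppd / 2.0:
        raise ValueError(
            f"nu={spec.nu} cycles/deg exceeds the Nyquist limit {geom.ppd / 2.0}"
        )
    h, w = geom.res_h, geom.res_w
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx * math.cos(spec.orientation) + yy * math.sin(spec.orientation)) / geom.ppd
    return 0.5 + (spec.contrast / 2.0) * np.sin(2 * np.pi * spec.nu * u + spec.phase)


def patch_contrasts(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Per-patch pixel standard deviation over a non-overlapping grid.

    The image is cropped to the largest centered multiple of ``patch_size``
    before tiling.  Accepts a single image (H, W) or a batch (N, H, W).
    """
    single = image.ndim == 2
    batch = image[None] if single else image
    n, h, w = batch.shape
    if patch_size > min(h, w):
        raise ValueError("patch_size exceeds the image side")
    gh, gw = h // patch_size, w // patch_size
    r0 = (h - gh * patch_size) // 2
    c0 = (w - gw * patch_size) // 2
    crop = batch[:, r0 : r0 + gh * patch_size, c0 : c0 + gw * patch_size]
    tiles = crop.reshape(n, gh, patch_size, gw, patch_size)
    # SD via E[x^2] - E[x]^2 (einsum avoids large centered intermediates)
    inv = 1.0 / (patch_size * patch_size)
    s1 = tiles.mean(axis=(2, 4))
    s2 = np.einsum("abcde,abcde->abd", tiles, tiles) * inv
    var = np.maximum(s2 - s1 * s1, 0.0)
    feats = np.sqrt(var).reshape(n, gh * gw)
    return feats[0] if single else feats


def _noise_stream(rng: np.random.Generator) -> np.random.Generator:
    """Fast, seeded child stream for bulk Gaussian noise."""
    return np.random.Generator(np.random.SFC64(int(rng.integers(2**63))))


class _NoisePool:
    """Frozen-noise pool: pre-drawn Gaussian fields reused across trials.

    Each trial adds a randomly chosen field under a random circular shift,
    so marginals stay i.i.d. standard normal while bulk generation cost is
    paid once.  (Frozen noise is standard practice in psychophysical
    simulation; the pool is large enough that repeats with identical
    alignment are rare.)
    """

    def __init__(self, shape: tuple[int, int], rng: np.random.Generator,
                 n_fields: int = 256) -> None:
        self.fields = _noise_stream(rng).standard_normal(
            (n_fields, *shape), dtype=np.float32
        )

    def add(self, imgs: np.ndarray, sigma: float, rng: np.random.Generator) -> None:
        n, h, w = imgs.shape
        idx = rng.integers(0, len(self.fields), size=n)
        sr = rng.integers(0, h, size=n)
        sc = rng.integers(0, w, size=n)
        s = np.float32(sigma)
        for i in range(n):
            imgs[i] += s * np.roll(self.fields[idx[i]], (sr[i], sc[i]), axis=(0, 1))


class _GratingBank:
    """Pre-blurred, zero-mean unit-amplitude grating patterns.

    Blurring commutes with contrast scaling (the blur is linear and the
    background is uniform), so one bank of blurred patterns per spatial
    frequency serves every contrast level; each sample picks a random
    pattern, scales it by c/2 and adds fresh noise.
    """

    def __init__(
        self,
        nu: float,
        sigma_blur: float,
        geom: ViewingGeometry,
        rng: np.random.Generator,
        n_patterns: int = 64,
    ) -> None:
        h, w = geom.res_h, geom.res_w
        yy, xx = np.mgrid[0:h, 0:w]
        pats = np.empty((n_patterns, h, w), dtype=np.float32)
        for k in range(n_patterns):
            ori = rng.uniform(0.0, np.pi)
            phase = rng.uniform(0.0, 2 * np.pi)
            u = (xx * math.cos(ori) + yy * math.sin(ori)) / geom.ppd
            pat = np.sin(2 * np.pi * nu * u + phase)
            if sigma_blur > 0:
                pat = ndimage.gaussian_filter(pat, sigma=sigma_blur, mode="nearest")
            pats[k] = pat.astype(np.float32)
        self.patterns = pats
        self.shape = (h, w)

    def sample(
        self,
        contrasts: np.ndarray,
        sigma_noise: float,
        rng: np.random.Generator,
        pool: "_NoisePool | None" = None,
    ) -> np.ndarray:
        """Degraded grating images (one per contrast value), clipped to [0,1]."""
        n = len(contrasts)
        idx = rng.integers(0, len(self.patterns), size=n)
        imgs = self.patterns[idx].copy()
        np.multiply(imgs, np.asarray(contrasts, dtype=np.float32)[:, None, None] / 2.0,
                    out=imgs)
        imgs += np.float32(0.5)
        if sigma_noise > 0:
            if pool is not None:
                pool.add(imgs, sigma_noise, rng)
            else:
                noise = np.empty_like(imgs)
                _noise_stream(rng).standard_normal(out=noise, dtype=np.float32)
                noise *= np.float32(sigma_noise)
                imgs += noise
        np.clip(imgs, 0.0, 1.0, out=imgs)
        return imgs


@dataclass
class DetectionObserver:
    """A trained grating-vs-gray linear detector with its stimulus context.

    The linear direction comes from the SVM; the decision criterion is
    anchored so that the false-alarm rate on held-out gray images equals
    ``fa_rate``.  A fixed, conservative criterion keeps the psychometric
    function anchored near the false-alarm level at zero contrast and makes
    "no signal at any contrast" yield zero sensitivity instead of an
    arbitrary response bias.
    """

    svm: LinearSVC
    nu: float
    blur_noise: NoiseBlurParams
    patch_size: int
    geom: ViewingGeometry
    direction: np.ndarray = field(repr=False, default=None)
    threshold: float = 0.0
    fa_rate: float = 0.1
    bank: _GratingBank = field(repr=False, default=None)
    noise_pool: "_NoisePool | None" = field(repr=False, default=None)

    def detect(self, images: np.ndarray) -> np.ndarray:
        feats = np.atleast_2d(patch_contrasts(images, self.patch_size))
        return (feats @ self.direction > self.threshold).astype(int)


def _gray_images(
    shape: tuple[int, int],
    n: int,
    sigma_noise: float,
    rng: np.random.Generator,
    pool: "_NoisePool | None" = None,
) -> np.ndarray:
    imgs = np.full((n, *shape), 0.5, dtype=np.float32)
    if sigma_noise > 0:
        if pool is not None:
            pool.add(imgs, sigma_noise, rng)
        else:
            noise = np.empty_like(imgs)
            _noise_stream(rng).standard_normal(out=noise, dtype=np.float32)
            noise *= np.float32(sigma_noise)
            imgs += noise
    np.clip(imgs, 0.0, 1.0, out=imgs)
    return imgs


def train_detection_observer(
    nu: float,
    blur_noise: NoiseBlurParams,
    patch_size: int,
    n_per_class: int = 5000,
    rng: np.random.Generator | None = None,
    *,
    geom: ViewingGeometry | None = None,
    contrast_grid: np.ndarray = DEFAULT_CONTRAST_GRID,
    n_patterns: int = 32,
    fa_rate: float = 0.1,
    n_criterion: int = 500,
    bank: _GratingBank | None = None,
    noise_pool: _NoisePool | None = None,
) -> DetectionObserver:
    """Train the patch-contrast linear detector for one spatial frequency.

    Grating trials draw their contrast uniformly from the test grid so a
    single detector serves the whole psychometric function.  After the SVM
    fixes the linear direction, the criterion is set on fresh gray images so
    the false-alarm rate equals ``fa_rate``.
    """
    rng = np.random.default_rng() if rng is None else rng
    geom = ViewingGeometry() if geom is None else geom
    if bank is None:
        bank = _GratingBank(nu, blur_noise.sigma_blur, geom, rng, n_patterns)
    contrasts = rng.choice(np.asarray(contrast_grid), size=n_per_class)
    gratings = bank.sample(contrasts, blur_noise.sigma_noise, rng, noise_pool)
    grays = _gray_images(bank.shape, n_per_class, blur_noise.sigma_noise, rng, noise_pool)
    X = np.concatenate(
        [patch_contrasts(gratings, patch_size), patch_contrasts(grays, patch_size)]
    )
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate features: all patch contrasts identical")
    y = np.concatenate([np.ones(n_per_class), np.zeros(n_per_class)])
    svm = LinearSVC(C=1.0, tol=1e-4, random_state=int(rng.integers(2**31)))
    svm.fit(X, y)
    direction = svm.coef_.ravel().copy()
    fresh_gray = _gray_images(bank.shape, n_criterion, blur_noise.sigma_noise, rng,
                              noise_pool)
    scores = patch_contrasts(fresh_gray, patch_size) @ direction
    threshold = float(np.quantile(scores, 1.0 - fa_rate))
    return DetectionObserver(
        svm, nu, blur_noise, patch_size, geom,
        direction=direction, threshold=threshold, fa_rate=fa_rate, bank=bank,
        noise_pool=noise_pool,
    )


def detection_probability(
    detector: DetectionObserver,
    contrast: float,
    n_trials: int = 200,
    n_reps: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Fraction of fresh grating trials reported as 'grating' (mean, SD)."""
    rng = np.random.default_rng() if rng is None else rng
    ps = np.empty(n_reps)
    for r in range(n_reps):
        imgs = detector.bank.sample(
            np.full(n_trials, contrast), detector.blur_noise.sigma_noise, rng,
            detector.noise_pool,
        )
        ps[r] = detector.detect(imgs).mean()
    return float(ps.mean()), float(ps.std())


def psychometric_curve(
    detector: DetectionObserver,
    contrast_grid: np.ndarray = DEFAULT_CONTRAST_GRID,
    n_trials: int = 200,
    n_reps: int = 3,
    rng: np.random.Generator | None = None,
) -> PsychometricCurve:
    rng = np.random.default_rng() if rng is None else rng
    means, sds = [], []
    for c in contrast_grid:
        m, s = detection_probability(detector, float(c), n_trials, n_reps, rng)
        means.append(m)
        sds.append(s)
    return PsychometricCurve(np.asarray(contrast_grid), np.array(means), np.array(sds))


def contrast_threshold(curve: PsychometricCurve) -> float:
    """Contrast at the first upward 50% crossing (log-contrast interpolation).

    Boundary rules: if the curve already exceeds 0.5 at the lowest tested
    contrast, the threshold is that contrast; if it never reaches 0.5 the
    threshold is infinite (zero sensitivity).
    """
    if len(curve.contrasts) == 0:
        raise ValueError("empty psychometric curve")
    p = curve.p_detect
    c = curve.contrasts
    above = np.nonzero(p >= 0.5)[0]
    if len(above) == 0:
        return math.inf
    i = int(above[0])
    if i == 0:
        return float(c[0])
    frac = (0.5 - p[i - 1]) / (p[i] - p[i - 1])
    log_xi = math.log10(c[i - 1]) + frac * (math.log10(c[i]) - math.log10(c[i - 1]))
    return float(10.0**log_xi)


def compute_csf(
    blur_noise: NoiseBlurParams,
    patch_size: int,
    nu_grid: np.ndarray = DEFAULT_NU_GRID,
    contrast_grid: np.ndarray = DEFAULT_CONTRAST_GRID,
    rng: np.random.Generator | None = None,
    *,
    geom: ViewingGeometry | None = None,
    n_per_class: int = 5000,
    n_trials: int = 200,
    n_reps: int = 3,
    bank_cache: dict | None = None,
) -> CSFCurve:
    """Simulated CSF: sigma(nu) = 1 / xi(nu) over the frequency grid.

    ``bank_cache`` (a dict) lets repeated calls reuse the pre-blurred
    grating banks keyed by (nu, sigma_blur), which speeds up grid searches
    where many noise levels share a blur level.
    """
    if len(nu_grid) == 0 or len(contrast_grid) == 0:
        raise ValueError("nu and contrast grids must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    geom = ViewingGeometry() if geom is None else geom
    sens = np.empty(len(nu_grid))
    pool = None
    if bank_cache is not None:
        if "noise_pool" not in bank_cache:
            bank_cache["noise_pool"] = _NoisePool((geom.res_h, geom.res_w), rng)
        pool = bank_cache["noise_pool"]
    for k, nu in enumerate(nu_grid):
        bank = None
        if bank_cache is not None:
            key = (float(nu), float(blur_noise.sigma_blur))
            if key not in bank_cache:
                bank_cache[key] = _GratingBank(
                    float(nu), blur_noise.sigma_blur, geom, rng
                )
            bank = bank_cache[key]
        det = train_detection_observer(
            float(nu), blur_noise, patch_size, n_per_class, rng,
            geom=geom, contrast_grid=contrast_grid, bank=bank, noise_pool=pool,
        )
        curve = psychometric_curve(det, contrast_grid, n_trials, n_reps, rng)
        xi = contrast_threshold(curve)
        sens[k] = 0.0 if math.isinf(xi) else 1.0 / xi
    return CSFCurve(np.asarray(nu_grid, dtype=float), sens)


def fit_csf(
    target: CSFCurve,
    sigma_blur_grid: np.ndarray,
    sigma_noise_grid: np.ndarray,
    patch_grid: np.ndarray = (28,),
    rng: np.random.Generator | None = None,
    *,
    geom: ViewingGeometry | None = None,
    contrast_grid: np.ndarray = DEFAULT_CONTRAST_GRID,
    n_per_class: int = 5000,
    n_trials: int = 200,
    n_reps: int = 3,
) -> CSFFitResult:
    """Grid search (sigma_blur, sigma_noise, patch size) minimizing L1.

    The L1 distance is the sum over the shared frequency grid of
    ``|sigma_sim(nu) - sigma_target(nu)|``.  Returns the argmin cell and the
    full landscape; ties go to the first cell in grid order.
    """
    rng = np.random.default_rng() if rng is None else rng
    sb = np.asarray(sigma_blur_grid, dtype=float)
    sn = np.asarray(sigma_noise_grid, dtype=float)
    pg = np.asarray(patch_grid, dtype=int)
    landscape = np.empty((len(sb), len(sn), len(pg)))
    bank_cache: dict = {}
    best = None
    for i, s_blur in enumerate(sb):
        for j, s_noise in enumerate(sn):
            for k, p in enumerate(pg):
                csf = compute_csf(
                    NoiseBlurParams(float(s_blur), float(s_noise)),
                    int(p),
                    target.nus,
                    contrast_grid,
                    rng,
                    geom=geom,
                    n_per_class=n_per_class,
                    n_trials=n_trials,
                    n_reps=n_reps,
                    bank_cache=bank_cache,
                )
                l1 = float(np.abs(csf.sensitivity - target.sensitivity).sum())
                landscape[i, j, k] = l1
                if best is None or l1 < best[0]:
                    best = (l1, i, j, k, csf)
    l1, i, j, k, csf = best
    return CSFFitResult(
        sigma_blur=float(sb[i]),
        sigma_noise=float(sn[j]),
        patch_size=int(pg[k]),
        l1=l1,
        landscape=landscape,
        sigma_blur_grid=sb,
        sigma_noise_grid=sn,
        patch_grid=pg,
        best_csf=csf,
    )


def peak_frequency(curve: CSFCurve) -> float:
    """Spatial frequency of maximal sensitivity (cycles/deg).

    Estimated, as is standard for contrast-sensitivity data, from a
    log-parabolic fit: a quadratic in log10(nu) is least-squares fitted to
    the points with positive sensitivity, weighted by sensitivity, and the
    vertex is returned.  This is robust to sampling noise on a coarse
    frequency grid; if the fit is degenerate (fewer than 3 positive points,
    non-concave, or vertex outside the sampled range) the grid argmax is
    returned instead.
    """
    s = curve.sensitivity
    mask = s > 0
    argmax_nu = float(curve.nus[int(np.argmax(s))])
    if mask.sum() < 3:
        return argmax_nu
    x = np.log10(curve.nus[mask])
    y = s[mask]
    A = np.vstack([x**2, x, np.ones_like(x)]).T
    coef = np.linalg.lstsq(A * y[:, None], y * y, rcond=None)[0]
    if coef[0] >= 0:
        return argmax_nu
    vertex = -coef[1] / (2 * coef[0])
    if not (x.min() <= vertex <= x.max()):
        return argmax_nu
    return float(10.0**vertex)


def rat_csf_standin(
    nus: np.ndarray = DEFAULT_NU_GRID,
    peak_sensitivity: float = 20.0,
    peak_nu: float = 0.1,
    zero_low: float = 0.04,
    zero_high: float = 1.0,
) -> CSFCurve:
    """Parametric stand-in for the rodent CSF built from printed descriptors.

    A piecewise log-parabola, unimodal on the log-frequency axis, with its
    maximum at ``peak_nu`` and zero sensitivity at ``zero_low`` and
    ``zero_high`` cycles/deg.  The peak sensitivity is configurable because
    only the shape descriptors, not absolute sensitivities, are published.
    """
    nus = np.asarray(nus, dtype=float)
    log_nu = np.log10(nus)
    lp = math.log10(peak_nu)
    w_left = lp - math.log10(zero_low)
    w_right = math.log10(zero_high) - lp
    width = np.where(log_nu < lp, w_left, w_right)
    sens = peak_sensitivity * (1.0 - ((log_nu - lp) / width) ** 2)
    return CSFCurve(nus, np.clip(sens, 0.0, None))
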