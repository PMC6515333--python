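"""Hybrid structural similarity between patches and regions.

Five complementary measures are combined multiplicatively into a single
similarity in (0, 1]:

* ``s_pm`` — phase-congruency measure: compares the contrast-invariant
  local-structure significance at two locations. Phase congruency is computed
  with a quadrature log-Gabor filter bank; it peaks where Fourier components
  are maximally in phase (edges, lines) regardless of contrast.
* ``s_im`` — intensity measure on patch means.
* ``s_cm`` — contrast measure on patch standard deviations.
* ``s_sm`` — structure measure: absolute normalized cross-covariance.
* ``s_dm`` — coordinate measure: Gaussian kernel on pixel distance.

Each pairwise measure has the luminance/contrast SSIM form
(2ab + c)/(a^2 + b^2 + c) with a small stabilizing constant, so it is
symmetric, equals 1 on identical inputs and decays with dissimilarity.

The hybrid similarity drives both the superpixel over-segmentation
(patch mode) and hierarchical region merging (region mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityConfig",
    "LogGaborBank",
    "build_log_gabor_bank",
    "phase_congruency",
    "patch_stats",
    "PatchStats",
    "s_pm",
    "s_im",
    "s_cm",
    "s_sm",
    "s_dm",
    "hybrid_similarity",
    "normalize_image",
]

#: default stabilizing constant (0.01 * L)^2 with dynamic range L = 1
_C_DEFAULT = 1e-4


@dataclass
class SimilarityConfig:
    """Constants and exponents of the hybrid similarity.

    ``alpha`` is the decay rate (1/pixels^2) of the coordinate measure;
    the convention alpha = 2K/N couples it to the target region count K and
    pixel count N, so spatial locality tightens as regions shrink. ``beta``
    are the per-measure exponents (all 1 by default: plain product).
    """

    p: int = 9
    c1: float = _C_DEFAULT
    c2: float = _C_DEFAULT
    c3: float = _C_DEFAULT
    c4: float = _C_DEFAULT
    alpha: float = 0.01
    beta: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    n_scales: int = 4
    n_orientations: int = 6
    min_wavelength: float = 3.0
    scale_multiplier: float = 2.1
    sigma_r: float = 0.55  # ratio sigma/omega0 of the radial log-Gaussian
    sigma_theta_factor: float = 0.6  # sigma_theta = factor * pi / n_orientations
    amplitude_floor: float = 1e-4

    @staticmethod
    def alpha_for(n_regions: int, n_pixels: int) -> float:
        """Conventional coordinate-decay rate alpha = 2K/N."""
        return 2.0 * n_regions / n_pixels


@dataclass
class LogGaborBank:
    """Frequency-domain quadrature log-Gabor filters for one image shape."""

    shape: tuple[int, int]
    n_scales: int
    n_orientations: int
    filters: np.ndarray  # (n_scales, n_orientations, H, W), real, >= 0, DC = 0


def build_log_gabor_bank(
    shape: tuple[int, int],
    n_scales: int = 4,
    n_orientations: int = 6,
    min_wavelength: float = 3.0,
    scale_multiplier: float = 2.1,
    sigma_r: float = 0.55,
    sigma_theta_factor: float = 0.6,
) -> LogGaborBank:
    """Build the log-Gabor bank G(w, theta) on the discrete frequency grid.

    Each filter is the product of a radial log-Gaussian
    exp(-log(w/w0)^2 / (2 sigma_r'^2)) and an angular Gaussian
    exp(-(theta - theta_j)^2 / (2 sigma_theta^2)); the DC bin is forced to 0
    (a log-Gabor has no DC response by construction).
    """
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError("image must be at least 8x8")
    if min_wavelength <= 0 or scale_multiplier <= 0:
        raise ValueError("center frequencies must be positive")

    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # avoid log(0); DC handled below
    theta = np.arctan2(-fy, fx)  # image y axis points down

    log_sigma = np.log(sigma_r)
    sigma_theta = sigma_theta_factor * np.pi / n_orientations

    filters = np.empty((n_scales, n_orientations, h, w))
    for n in range(n_scales):
        wavelength = min_wavelength * scale_multiplier**n
        omega0 = 1.0 / wavelength
        radial = np.exp(-(np.log(radius / omega0) ** 2) / (2 * log_sigma**2))
        radial[0, 0] = 0.0
        for j in range(n_orientations):
            angle = j * np.pi / n_orientations
            # wrapped angular distance, orientation is pi-periodic via sign symmetry
            d_sin = np.sin(theta) * np.cos(angle) - np.cos(theta) * np.sin(angle)
            d_cos = np.cos(theta) * np.cos(angle) + np.sin(theta) * np.sin(angle)
            dtheta = np.abs(np.arctan2(d_sin, d_cos))
            filters[n, j] = radial * np.exp(-(dtheta**2) / (2 * sigma_theta**2))
    return LogGaborBank((h, w), n_scales, n_orientations, filters)


def phase_congruency(
    image: np.ndarray,
    bank: LogGaborBank | None = None,
    amplitude_floor: float = 1e-4,
    cfg: SimilarityConfig | None = None,
    noise_compensation: float = 0.0,
) -> np.ndarray:
    """Per-pixel phase congruency in [0, 1].

    For each scale n and orientation j the image is filtered with the
    quadrature pair of the log-Gabor filter giving even/odd responses
    (e, o); the local amplitude is A = sqrt(e^2 + o^2) and the orientation
    energy E_j = sqrt((sum_n e)^2 + (sum_n o)^2). Phase congruency is

        PC(u) = sum_j E_j(u) / (sum_n sum_j A_nj(u) + floor)

    which is 1 when all components are in phase and ~0 on structureless
    regions (the floor regularizes the 0/0 limit on flat images). The input
    is min-max normalized internally — the per-slice normalization used
    throughout the similarity machinery — which makes the PC map exactly
    invariant to rescaling the image intensity.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite-valued")
    img = normalize_image(img)
    if cfg is not None:
        amplitude_floor = cfg.amplitude_floor
        if bank is None:
            bank = build_log_gabor_bank(
                img.shape, cfg.n_scales, cfg.n_orientations, cfg.min_wavelength,
                cfg.scale_multiplier, cfg.sigma_r, cfg.sigma_theta_factor,
            )
    if bank is None:
        bank = build_log_gabor_bank(img.shape)
    if bank.shape != img.shape:
        raise ValueError("filter bank shape does not match the image")

    F = np.fft.fft2(img)
    total_amplitude = np.zeros(img.shape)
    total_energy = np.zeros(img.shape)
    for j in range(bank.n_orientations):
        sum_e = np.zeros(img.shape)
        sum_o = np.zeros(img.shape)
        amp_smallest = None
        for n in range(bank.n_scales):
            # analytic (one-sided) filter: even + i*odd response in one IFFT
            resp = np.fft.ifft2(F * bank.filters[n, j])
            e, o = resp.real, resp.imag
            sum_e += e
            sum_o += o
            amp = np.hypot(e, o)
            if n == 0:
                amp_smallest = amp
            total_amplitude += amp
        energy_j = np.hypot(sum_e, sum_o)
        if noise_compensation > 0:
            # Rayleigh noise-energy estimate from the smallest-scale band,
            # extrapolated geometrically across scales; subtracted per
            # orientation as k standard-deviations-worth of noise energy
            tau = np.median(amp_smallest) / np.sqrt(np.log(4))
            mult_inv = 1.0 / 2.1
            total_tau = tau * (1 - mult_inv**bank.n_scales) / (1 - mult_inv)
            T = noise_compensation * total_tau
            energy_j = np.maximum(energy_j - T, 0.0)
        total_energy += energy_j
    pc = total_energy / (total_amplitude + amplitude_floor)
    return np.clip(pc, 0.0, 1.0)


def _ssim_form(a: float | np.ndarray, b: float | np.ndarray, c: float):
    return (2.0 * a * b + c) / (a * a + b * b + c)


def s_pm(pc_u, pc_v, c1: float = _C_DEFAULT):
    """Phase-congruency measure (2 p_u p_v + c1)/(p_u^2 + p_v^2 + c1)."""
    return _ssim_form(pc_u, pc_v, c1)


def s_im(mu_u, mu_v, c2: float = _C_DEFAULT):
    """Intensity measure on patch means."""
    return _ssim_form(mu_u, mu_v, c2)


def s_cm(sigma_u, sigma_v, c3: float = _C_DEFAULT):
    """Contrast measure on patch standard deviations."""
    return _ssim_form(sigma_u, sigma_v, c3)


def s_sm(patch_u: np.ndarray, patch_v: np.ndarray, c4: float = _C_DEFAULT) -> float:
    """Structure measure: stabilized absolute correlation of two patches.

    |2 sigma_uv + c4| / (sigma_u sigma_v + c4), clipped to [0, 1]; the
    cross-covariance sigma_uv uses the d-1 denominator. The absolute value
    folds anti-correlated structure onto correlated structure so the result
    stays in [0, 1].

    The leading factor 2 in the numerator keeps the same algebraic family as
    the other measures; with c4 -> 0 the measure is |rho| clipped at 1.
    """
    pu = np.asarray(patch_u, dtype=float).ravel()
    pv = np.asarray(patch_v, dtype=float).ravel()
    if pu.size != pv.size:
        raise ValueError("patches must have the same size")
    d = pu.size
    mu_u, mu_v = pu.mean(), pv.mean()
    du, dv = pu - mu_u, pv - mu_v
    denom = max(d - 1, 1)
    cov = float(du @ dv) / denom
    su = np.sqrt(float(du @ du) / denom)
    sv = np.sqrt(float(dv @ dv) / denom)
    val = abs(2.0 * cov + c4) / (su * sv + c4)
    return float(np.clip(val, 0.0, 1.0))


def s_dm(u, v, alpha: float):
    """Coordinate measure exp(-alpha ||u - v||^2) in (0, 1]."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d2 = np.sum((u - v) ** 2, axis=-1)
    return np.exp(-alpha * d2)


@dataclass
class PatchStats:
    """Summary of one p x p patch: mean, d-1 std, raw vector, center."""

    mean: float
    std: float
    patch: np.ndarray
    center: tuple[int, int]


def patch_stats(image: np.ndarray, center: tuple[int, int], p: int = 9) -> PatchStats:
    """Extract the p x p patch at ``center`` (row, col) with mirror padding.

    Mean uses 1/d; the standard deviation uses the d-1 denominator.
    """
    if p % 2 == 0:
        raise ValueError("patch side p must be odd")
    img = np.asarray(image, dtype=float)
    r = p // 2
    padded = np.pad(img, r, mode="reflect")
    cy, cx = center
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ValueError("patch center outside the image")
    patch = padded[cy : cy + p, cx : cx + p]
    mean = float(patch.mean())
    std = float(patch.std(ddof=1)) if p > 1 else 0.0
    return PatchStats(mean=mean, std=std, patch=patch.copy(), center=(cy, cx))


@dataclass
class RegionSummary:
    """Region-mode operand: pooled statistics of one (super)pixel region."""

    mean: float
    std: float
    pc_mean: float
    centroid: tuple[float, float]  # (row, col)
    histogram: np.ndarray  # intensity histogram (density), fixed bin count
    n_pixels: int = 0


def region_summary(
    image: np.ndarray,
    mask: np.ndarray,
    pc_map: np.ndarray,
    n_bins: int = 32,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> RegionSummary:
    """Pool per-pixel values of one region into a RegionSummary."""
    vals = np.asarray(image, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty region")
    ys, xs = np.nonzero(mask)
    hist, _ = np.histogram(vals, bins=n_bins, range=value_range)
    return RegionSummary(
        mean=float(vals.mean()),
        std=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        pc_mean=float(np.asarray(pc_map)[mask].mean()),
        centroid=(float(ys.mean()), float(xs.mean())),
        histogram=hist / vals.size,
        n_pixels=int(vals.size),
    )


def hybrid_similarity(
    u,
    v,
    cfg: SimilarityConfig,
    mode: str = "patch",
    image: np.ndarray | None = None,
    pc_map: np.ndarray | None = None,
) -> float:
    """Hybrid similarity S = Spm^b1 * Sim^b2 * Scm^b3 * Ssm^b4 * Sdm^b5.

    In ``patch`` mode ``u`` and ``v`` are (row, col) centers in ``image``
    (``pc_map`` required; the PC value at the patch center is used). In
    ``region`` mode they are :class:`RegionSummary` objects: the intensity,
    contrast and PC statistics are pooled over all region pixels, the
    structure term correlates the two regions' intensity histograms (regions
    differ in pixel count, so a per-pixel correlation is undefined), and the
    coordinate term uses region centroids.
    """
    b1, b2, b3, b4, b5 = cfg.beta
    if mode == "patch":
        if image is None or pc_map is None:
            raise ValueError("patch mode requires image and pc_map")
        su = patch_stats(image, u, cfg.p)
        sv = patch_stats(image, v, cfg.p)
        t_pm = s_pm(float(pc_map[u]), float(pc_map[v]), cfg.c1)
        t_im = s_im(su.mean, sv.mean, cfg.c2)
        t_cm = s_cm(su.std, sv.std, cfg.c3)
        t_sm = s_sm(su.patch, sv.patch, cfg.c4)
        t_dm = float(s_dm(np.asarray(u, float), np.asarray(v, float), cfg.alpha))
    elif mode == "region":
        if not isinstance(u, RegionSummary) or not isinstance(v, RegionSummary):
            raise ValueError("region mode requires RegionSummary operands")
        if u.n_pixels == 0 or v.n_pixels == 0:
            raise ValueError("empty region")
        t_pm = s_pm(u.pc_mean, v.pc_mean, cfg.c1)
        t_im = s_im(u.mean, v.mean, cfg.c2)
        t_cm = s_cm(u.std, v.std, cfg.c3)
        t_sm = s_sm(u.histogram, v.histogram, cfg.c4)
        t_dm = float(s_dm(np.asarray(u.centroid), np.asarray(v.centroid), cfg.alpha))
    else:
        raise ValueError("mode must be 'patch' or 'region'")
    return float(t_pm**b1 * t_im**b2 * t_cm**b3 * t_sm**b4 * t_dm**b5)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Min-max normalize a slice to [0, 1] (constants c then share a scale)."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)
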