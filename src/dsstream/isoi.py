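"""Intrinsic-signal retinotopy and visual-area segmentation.

A periodically swept bar evokes, at every pixel, an oscillation at the
sweep frequency whose phase encodes the pixel's retinotopic coordinate plus
a hemodynamic delay.  The pipeline is:

1. per-pixel Fourier phase/magnitude at the stimulus frequency;
2. delay subtraction using opposite sweep directions (the delay adds to the
   phase with the same sign in both, the retinotopic phase flips sign);
3. linear conversion of phase to visual degrees;
4. the visual-field sign map I = sin(angle between the azimuth and
   elevation retinotopic gradients), whose sign reversals mark area borders;
5. a three-step border detection: threshold at mean(|I|) + SD(|I|) with a
   3 x 3 median filter, an 8-neighbor retain/fill pass, and Sobel edge
   detection with connected-component labeling;
6. per-area geometry (size in mm^2, centroids relative to the largest area,
   V1 by construction) and FFT-power areal response strengths.

All phase arithmetic is circular (wrapped to [-pi, pi)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to [-pi, pi)."""
    return (np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi


def stimulus_frequency(extent_deg: float, speed_deg_per_s: float) -> float:
    """Sweep repetitions per second: speed / extent."""
    if extent_deg <= 0 or speed_deg_per_s <= 0:
        raise ValueError("extent and speed must be positive")
    return speed_deg_per_s / extent_deg


def fourier_component_map(stack: np.ndarray, frame_rate: float, stim_freq: float):
    """Per-pixel phase and magnitude of the DFT bin nearest ``stim_freq``.

    ``stack`` is (n_frames, h, w).  The returned phase is the argument of
    the complex coefficient, so a pixel following cos(2*pi*f*t + phi0) maps
    to phase phi0.  Magnitude is scaled to the cosine amplitude (2|X_k|/N).
    """
    stack = np.asarray(stack, float)
    n = stack.shape[0]
    if stim_freq > frame_rate / 2.0:
        raise ValueError("stimulus frequency above Nyquist")
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    k = int(np.argmin(np.abs(freqs - stim_freq)))
    coef = np.fft.rfft(stack, axis=0)[k]
    return np.angle(coef), 2.0 * np.abs(coef) / n


def delay_corrected_retinotopy(phase_forward: np.ndarray, phase_reverse: np.ndarray,
                               weights: np.ndarray | None = None):
    """Split forward/reverse phase maps into retinotopy and delay.

    With phi_fwd = theta + delta and phi_rev = -theta + delta the circular
    half-sum recovers the (spatially uniform) hemodynamic delay delta and
    phi_fwd - delta recovers theta over its full [-pi, pi) range.  The
    literal half-difference (phi_fwd - phi_rev)/2 is ambiguous by pi outside
    [-pi/2, pi/2), so the delay is estimated first — as the circular mean of
    the per-pixel half-sums, assuming |delta| < pi/2 (delays well under half
    a sweep period) — and subtracted.  ``weights`` (typically the product of
    forward and reverse response magnitudes) down-weight non-responsive
    pixels, whose phases are noise, in the delay estimate.

    Returns ``(retinotopic phase map, delay in radians)``.
    """
    pf = np.asarray(phase_forward, float)
    pr = np.asarray(phase_reverse, float)
    if pf.shape != pr.shape:
        raise ValueError("phase maps must share one pixel grid")
    w = np.ones_like(pf) if weights is None else np.asarray(weights, float)
    double_delay = w * np.exp(1j * (pf + pr))  # exp(i * 2 delta) per pixel
    delay = float(np.angle(np.sum(double_delay)) / 2.0)
    retinotopy = wrap_phase(pf - delay)
    return retinotopy, delay


def phase_to_degrees(phase_map: np.ndarray, sweep_extent_deg: float) -> np.ndarray:
    """Map phase range [-pi, pi) linearly onto [-extent/2, +extent/2)."""
    if sweep_extent_deg <= 0:
        raise ValueError("sweep extent must be positive")
    return np.asarray(phase_map, float) * sweep_extent_deg / (2.0 * np.pi)


@dataclass
class SignMap:
    """Visual-field sign values and the cleaned area mask derived from them."""

    sign: np.ndarray  # I in [-1, 1]
    threshold: float  # mean(|I|) + SD(|I|)
    mask: np.ndarray  # cleaned binary mask
    signed_mask: np.ndarray  # mask * sign(I), for area identity


def _masked_gaussian(x: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Normalized masked smoothing: off-mask pixels carry zero weight."""
    w = mask.astype(float)
    num = ndimage.gaussian_filter(x * w, sigma)
    den = ndimage.gaussian_filter(w, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    return out


def visual_field_sign(azimuth_map: np.ndarray, elevation_map: np.ndarray,
                      smooth_sigma: float = 2.0,
                      response_mask: np.ndarray | None = None) -> np.ndarray:
    """I = sin(angle(grad elevation) - angle(grad azimuth)) per pixel.

    The angle order makes the non-mirrored orientation (azimuth increasing
    along +x, elevation along +y) come out at I = +1.  Maps are
    Gaussian-smoothed (sigma in pixels) before central-difference
    gradients; pixels where either gradient vanishes get I = 0.

    ``response_mask`` marks pixels with a genuine visual response (e.g.
    Fourier magnitude above a floor): off-mask pixels carry meaningless
    phases, so they are excluded from the smoothing (normalized masked
    convolution) and get I = 0.
    """
    az = np.asarray(azimuth_map, float)
    el = np.asarray(elevation_map, float)
    if response_mask is not None and smooth_sigma > 0:
        az = _masked_gaussian(az, response_mask, smooth_sigma)
        el = _masked_gaussian(el, response_mask, smooth_sigma)
    elif smooth_sigma > 0:
        az = ndimage.gaussian_filter(az, smooth_sigma)
        el = ndimage.gaussian_filter(el, smooth_sigma)
    gay, gax = np.gradient(az)
    gey, gex = np.gradient(el)
    angle_a = np.arctan2(gay, gax)
    angle_e = np.arctan2(gey, gex)
    sign = np.sin(angle_e - angle_a)
    flat = ((gax == 0) & (gay == 0)) | ((gex == 0) & (gey == 0))
    sign[flat] = 0.0
    if response_mask is not None:
        sign[~np.asarray(response_mask, bool)] = 0.0
    return sign


def threshold_and_clean(sign: np.ndarray) -> SignMap:
    """Step 1 of border detection: threshold |I| and median-filter.

    Pixels with |I| >= mean(|I|) + SD(|I|) are retained (sign kept
    separately for area identity), then the binary mask is smoothed with a
    3 x 3 median filter.  A constant map yields an empty mask.
    """
    sign = np.asarray(sign, float)
    if not np.all(np.isfinite(sign)):
        raise ValueError("sign map must be finite")
    mag = np.abs(sign)
    thr = float(mag.mean() + mag.std())
    mask = mag >= thr if mag.std() > 0 else np.zeros_like(mag, bool)
    mask = ndimage.median_filter(mask.astype(np.uint8), size=3).astype(bool)
    return SignMap(sign=sign, threshold=thr, mask=mask,
                   signed_mask=mask * np.sign(sign))


_NEIGHBORS = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], int)


def neighbor_filter(mask: np.ndarray) -> np.ndarray:
    """Step 2: 8-neighbor retain/fill with zero padding at the borders.

    A nonzero pixel is kept iff >4 (i.e. >= 5) of its eight neighbors are
    nonzero; afterwards, zero pixels surrounded by >= 5 kept neighbors
    (gaps) are filled, in a single sweep.
    """
    m = np.asarray(mask).astype(bool)
    counts = ndimage.convolve(m.astype(int), _NEIGHBORS, mode="constant", cval=0)
    kept = m & (counts >= 5)
    kept_counts = ndimage.convolve(kept.astype(int), _NEIGHBORS, mode="constant",
                                   cval=0)
    filled = kept | (~kept & (kept_counts >= 5))
    return filled


@dataclass
class AreaSegmentation:
    """Labeled visual areas with size and centroid geometry."""

    labels: np.ndarray  # 0 = background
    edges: np.ndarray  # Sobel edge map of the binary mask
    area_mm2: np.ndarray  # per label (1-based)
    centroids_px: np.ndarray  # (n_areas, 2), (row, col)
    centroids_rel_mm: np.ndarray  # relative to the largest area's centroid
    signs: np.ndarray  # dominant visual-field sign per area
    reference_label: int  # largest area (V1 by construction)


def detect_borders(mask: np.ndarray, pixel_size_mm: float = 0.01,
                   sign: np.ndarray | None = None) -> AreaSegmentation:
    """Step 3: Sobel edges + connected components + centroid geometry.

    When a sign map is supplied, positive- and negative-sign pixels are
    labeled separately so adjacent mirror-polarity areas stay distinct.
    Sizes are converted to mm^2 via ``pixel_size_mm``; all centroids are
    re-expressed relative to the largest area (V1 by construction).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask: no areas to segment")
    edges = filters.sobel(m.astype(float)) > 0
    if sign is not None:
        pos = measure.label(m & (sign > 0), connectivity=2)
        neg = measure.label(m & (sign < 0), connectivity=2)
        labels = pos.copy()
        labels[neg > 0] = neg[neg > 0] + pos.max()
    else:
        labels = measure.label(m, connectivity=2)
    props = measure.regionprops(labels)
    sizes_px = np.array([p.area for p in props], float)
    centroids = np.array([p.centroid for p in props], float)
    signs = np.zeros(len(props))
    if sign is not None:
        for i, p in enumerate(props):
            signs[i] = np.sign(np.mean(sign[labels == p.label]))
    ref = int(np.argmax(sizes_px))
    rel_mm = (centroids - centroids[ref]) * pixel_size_mm
    return AreaSegmentation(
        labels=labels, edges=edges,
        area_mm2=sizes_px * pixel_size_mm ** 2,
        centroids_px=centroids, centroids_rel_mm=rel_mm,
        signs=signs, reference_label=int(props[ref].label),
    )


@dataclass
class ArealResponse:
    """Normalized spectral power map and per-area response strengths."""

    power_map: np.ndarray
    strengths: np.ndarray  # per area label (1-based), max over ROI


def areal_response_strength(stack: np.ndarray, frame_rate: float,
                            labels: np.ndarray, pre_stim_s: float = 10.0,
                            band_hz: tuple[float, float] = (0.05, 0.1)) -> ArealResponse:
    """Per-area stimulus-evoked response strength from spectral power.

    Each pixel time course is normalized by its mean over the pre-stimulus
    segment (>= 10 s required), the peak FFT power inside ``band_hz`` is
    taken over the stimulus segment, and each area's strength is the
    maximum power within its ROI.  Normalizing the signal before the FFT
    makes the strength invariant to a multiplicative gain on the stack.
    """
    stack = np.asarray(stack, float)
    pre = int(round(pre_stim_s * frame_rate))
    if pre < 1 or pre >= stack.shape[0]:
        raise ValueError("stack must include a pre-stimulus segment")
    pre_mean = stack[:pre].mean(axis=0)
    if np.any(pre_mean == 0):
        raise ValueError("pre-stimulus mean is zero for some pixels")
    post = stack[pre:] / pre_mean - 1.0
    n = post.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("no DFT bins inside the stimulus band")
    power = (np.abs(np.fft.rfft(post, axis=0)[in_band]) ** 2).max(axis=0) / n ** 2
    n_areas = int(labels.max())
    strengths = np.array([
        power[labels == lab].max() if np.any(labels == lab) else 0.0
        for lab in range(1, n_areas + 1)
    ])
    return ArealResponse(power_map=power, strengths=strengths)
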