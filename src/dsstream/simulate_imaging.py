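"""Synthetic intrinsic-signal imaging stacks with ground-truth maps.

Two generators back the ISOI analyses:

* :func:`synthesize_retinotopy_stack` renders periodic sweep responses.
  Each simulated cortical area carries a linear retinotopic gradient
  (degrees per pixel, optionally mirror-reversed in azimuth), and each
  pixel's time course is a sinusoid at the sweep frequency whose phase
  encodes its retinotopic coordinate plus a uniform hemodynamic delay.
  Forward and reverse sweeps are produced for both the azimuth and the
  elevation axis.  The rendered frequency is snapped so the recording spans
  an exact integer number of sweep periods (no spectral leakage).

* :func:`synthesize_isoi_grating_stack` renders areal grating responses:
  pixels inside responsive areas oscillate at the 20-s stimulus period
  (0.05 Hz) with amplitude proportional to the area's assigned strength,
  after a constant pre-stimulus segment used for normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import AZIMUTH_RANGE_DEG, ELEVATION_RANGE_DEG, StimulusProtocol


@dataclass(frozen=True)
class AreaDef:
    """One rectangular simulated visual area on the pixel grid."""

    name: str
    rows: tuple[int, int]  # [row0, row1)
    cols: tuple[int, int]
    mirrored: bool = False  # azimuth gradient reversed -> negative field sign
    azimuth_span_deg: tuple[float, float] = (-60.0, 60.0)
    elevation_span_deg: tuple[float, float] = (-40.0, 55.0)


def default_six_area_layout() -> list[AreaDef]:
    """A V1 + five-HVA layout with alternating mirror polarity.

    Rectangles are separated by >= 8-pixel gaps so gradient smoothing never
    merges neighbors; V1 is the largest area by construction.
    """
    return [
        AreaDef("V1", (50, 130), (20, 90), mirrored=False),
        AreaDef("AM", (6, 40), (30, 80), mirrored=True,
                azimuth_span_deg=(-40.0, 40.0), elevation_span_deg=(-30.0, 45.0)),
        AreaDef("RL", (20, 50), (100, 136), mirrored=True,
                azimuth_span_deg=(-35.0, 35.0), elevation_span_deg=(-25.0, 40.0)),
        AreaDef("AL", (60, 95), (100, 136), mirrored=False,
                azimuth_span_deg=(-45.0, 45.0), elevation_span_deg=(-30.0, 45.0)),
        AreaDef("PM", (60, 95), (146, 182), mirrored=True,
                azimuth_span_deg=(-40.0, 40.0), elevation_span_deg=(-30.0, 45.0)),
        AreaDef("LM", (105, 140), (100, 140), mirrored=True,
                azimuth_span_deg=(-50.0, 50.0), elevation_span_deg=(-35.0, 50.0)),
    ]


@dataclass
class RetinotopyGroundTruth:
    """Ground-truth coordinate maps for a simulated layout."""

    azimuth_deg: np.ndarray  # NaN outside areas
    elevation_deg: np.ndarray
    mask: np.ndarray  # bool, inside-any-area
    labels: np.ndarray  # int, 1-based per area in layout order
    signs: np.ndarray  # +1 / -1 per area (mirror polarity)
    centroids_px: np.ndarray  # (n_areas, 2), (row, col)
    names: list[str]


def _check_layout(layout: list[AreaDef], shape: tuple[int, int]) -> None:
    for a in layout:
        if not (0 <= a.rows[0] < a.rows[1] <= shape[0]
                and 0 <= a.cols[0] < a.cols[1] <= shape[1]):
            raise ValueError(f"area {a.name} outside the pixel grid")
    for i, a in enumerate(layout):
        for b in layout[i + 1:]:
            if (a.rows[0] < b.rows[1] and b.rows[0] < a.rows[1]
                    and a.cols[0] < b.cols[1] and b.cols[0] < a.cols[1]):
                raise ValueError(f"areas {a.name} and {b.name} overlap")


def layout_ground_truth(layout: list[AreaDef],
                        shape: tuple[int, int] = (160, 192)) -> RetinotopyGroundTruth:
    """Rasterize a layout into coordinate, label and sign maps."""
    _check_layout(layout, shape)
    az = np.full(shape, np.nan)
    el = np.full(shape, np.nan)
    labels = np.zeros(shape, int)
    signs = np.empty(len(layout))
    centroids = np.empty((len(layout), 2))
    for k, a in enumerate(layout):
        r0, r1 = a.rows
        c0, c1 = a.cols
        az_lo, az_hi = a.azimuth_span_deg
        if a.mirrored:
            az_lo, az_hi = az_hi, az_lo
        cols = np.linspace(az_lo, az_hi, c1 - c0)
        rows = np.linspace(*a.elevation_span_deg, r1 - r0)
        az[r0:r1, c0:c1] = cols[None, :]
        el[r0:r1, c0:c1] = rows[:, None]
        labels[r0:r1, c0:c1] = k + 1
        signs[k] = -1.0 if a.mirrored else 1.0
        centroids[k] = ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)
    return RetinotopyGroundTruth(azimuth_deg=az, elevation_deg=el,
                                 mask=labels > 0, labels=labels, signs=signs,
                                 centroids_px=centroids,
                                 names=[a.name for a in layout])


@dataclass
class RetinotopyStacks:
    """Forward/reverse sweep stacks for one axis plus rendering metadata."""

    forward: np.ndarray  # (n_frames, h, w)
    reverse: np.ndarray
    frame_rate: float
    stim_freq_hz: float  # frequency actually rendered (leakage-free)
    extent_deg: float
    center_deg: float  # midpoint of the swept range (phase 0 maps here)


def _render_axis(coord_deg: np.ndarray, mask: np.ndarray, extent: float,
                 center: float, nominal_freq: float, frame_rate: float,
                 n_periods: int, delay_s: float, amplitude: float,
                 noise_sd: float, rng: np.random.Generator) -> RetinotopyStacks:
    n_frames = int(round(n_periods / nominal_freq * frame_rate))
    freq = n_periods * frame_rate / n_frames  # snap to an exact DFT bin
    t = np.arange(n_frames) / frame_rate
    theta = np.where(mask,
                     2.0 * np.pi * (np.nan_to_num(coord_deg) - center) / extent,
                     0.0)
    delay_phase = -2.0 * np.pi * freq * delay_s
    omega_t = 2.0 * np.pi * freq * t
    amp = np.where(mask, amplitude, 0.0)
    fwd = 1.0 + amp * np.cos(omega_t[:, None, None] + theta + delay_phase)
    rev = 1.0 + amp * np.cos(omega_t[:, None, None] - theta + delay_phase)
    if noise_sd > 0:
        fwd = fwd + rng.normal(0.0, noise_sd, fwd.shape)
        rev = rev + rng.normal(0.0, noise_sd, rev.shape)
    return RetinotopyStacks(forward=fwd, reverse=rev, frame_rate=frame_rate,
                            stim_freq_hz=freq, extent_deg=extent,
                            center_deg=center)


def synthesize_retinotopy_stack(layout: list[AreaDef], protocol: StimulusProtocol,
                                seed: int, shape: tuple[int, int] = (160, 192),
                                n_periods: int = 4, delay_s: float = 0.0,
                                amplitude: float = 0.5, noise_sd: float = 0.0):
    """Render azimuth and elevation sweep stacks for a layout.

    Returns ``(stacks, truth)`` where ``stacks`` maps axis name ('azimuth',
    'elevation') to :class:`RetinotopyStacks` and ``truth`` is the
    :class:`RetinotopyGroundTruth`.  The hemodynamic delay enters as a
    constant phase offset identical in forward and reverse sweeps.
    """
    if protocol.kind != "retinotopy-bar":
        raise ValueError("protocol kind must be retinotopy-bar")
    truth = layout_ground_truth(layout, shape)
    rng = np.random.default_rng(seed)
    speed = protocol.sweep_speed_deg_per_s
    ranges = {"azimuth": AZIMUTH_RANGE_DEG, "elevation": ELEVATION_RANGE_DEG}
    coords = {"azimuth": truth.azimuth_deg, "elevation": truth.elevation_deg}
    stacks = {}
    for axis, (lo, hi) in ranges.items():
        extent, center = hi - lo, (hi + lo) / 2.0
        stacks[axis] = _render_axis(
            coords[axis], truth.mask, extent, center, speed / extent,
            protocol.frame_rate, n_periods, delay_s, amplitude, noise_sd, rng)
    return stacks, truth


def synthesize_isoi_grating_stack(strengths: dict[str, float],
                                  layout: list[AreaDef],
                                  protocol: StimulusProtocol, seed: int,
                                  shape: tuple[int, int] = (160, 192),
                                  n_cycles: int = 4,
                                  noise_sd: float = 0.0):
    """Render an areal grating-response stack.

    ``strengths`` maps area names to nonnegative response strengths; pixels
    inside an area oscillate at the stimulus period (stationary + motion,
    20 s -> 0.05 Hz) with peak-to-baseline amplitude proportional to the
    strength.  A ``protocol.pre_s`` pre-stimulus segment (constant baseline)
    is included for normalization.  Returns ``(stack, truth)``.
    """
    if protocol.kind != "isoi-grating":
        raise ValueError("protocol kind must be isoi-grating")
    if any(v < 0 for v in strengths.values()):
        raise ValueError("response strengths must be nonnegative")
    truth = layout_ground_truth(layout, shape)
    rng = np.random.default_rng(seed)
    fr = protocol.frame_rate
    period = protocol.stationary_s + protocol.drift_s
    f_stim = 1.0 / period
    pre = int(round(protocol.pre_s * fr))
    n_stim = int(round(n_cycles * period * fr))
    t = np.arange(n_stim) / fr
    amp_map = np.zeros(shape)
    for k, name in enumerate(truth.names):
        amp_map[truth.labels == k + 1] = strengths.get(name, 0.0)
    stack = np.ones((pre + n_stim, *shape))
    stack[pre:] += amp_map * 0.5 * (1.0 - np.cos(2.0 * np.pi * f_stim * t))[:, None, None]
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)
    return stack, truth
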