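"""Per-cell tuning statistics.

Direction selectivity is quantified by DSI = (R_pref - R_opp)/(R_pref +
R_opp), orientation selectivity by OSI = (R_pref - R_orth)/(R_pref +
R_orth), and the preferred direction by the full-quadrant angle of the
vector sum theta = atan2(sum R_i sin d_i, sum R_i cos d_i).  Negative mean
amplitudes are floored at zero before entering any ratio or the vector sum.
R_pref for the DSI is read at the sampled direction nearest theta (the
vector-sum preference), R_opp at the direction 180 deg away.

A cell is direction selective (DS) when it is visually responsive and its
DSI exceeds 0.3 at at least one TF.  ON-OFF classification of retinal cells
uses the ON-OFF index OOI = (R_ON - R_OFF)/(R_ON + R_OFF) per flash-spot
size; cells with mean |OOI| < 0.3 across the five sizes are ON-OFF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import TuningCurve

DS_THRESHOLD = 0.3
ONOFF_THRESHOLD = 0.3


def _floored_means(curve: TuningCurve, tf: float) -> np.ndarray:
    j = int(np.argmin(np.abs(curve.tfs - tf)))
    if not math.isclose(float(curve.tfs[j]), tf, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"TF {tf} not in sampling grid {curve.tfs}")
    return np.maximum(curve.mean_amplitude[:, j], 0.0)


def _nearest_direction_index(directions: np.ndarray, angle: float) -> int:
    delta = np.abs((directions - angle + 180.0) % 360.0 - 180.0)
    return int(np.argmin(delta))


def preferred_direction(curve: TuningCurve, tf: float):
    """Vector-sum preferred direction at one TF.

    Returns ``(theta_deg in [0, 360), resultant_length)``; theta is NaN when
    every floored response is zero (undefined preference).
    """
    r = _floored_means(curve, tf)
    if r.size < 2:
        raise ValueError("need at least two sampled directions")
    d = np.deg2rad(curve.directions)
    y = float(np.sum(r * np.sin(d)))
    x = float(np.sum(r * np.cos(d)))
    length = math.hypot(x, y)
    if np.all(r == 0.0):
        return float("nan"), 0.0
    return math.degrees(math.atan2(y, x)) % 360.0, length


def dsi(curve: TuningCurve, tf: float) -> float:
    """Direction-selectivity index at one TF, in [0, 1] after flooring."""
    r = _floored_means(curve, tf)
    theta, _ = preferred_direction(curve, tf)
    if math.isnan(theta):
        return 0.0
    i_pref = _nearest_direction_index(curve.directions, theta)
    i_opp = _nearest_direction_index(curve.directions, theta + 180.0)
    opp_err = abs((curve.directions[i_opp] - curve.directions[i_pref] - 180.0
                   + 180.0) % 360.0 - 180.0)
    if opp_err > 1e-6:
        raise ValueError("opposite direction not in the sampling grid")
    r_pref, r_opp = r[i_pref], r[i_opp]
    if r_pref + r_opp == 0.0:
        return 0.0
    return float((r_pref - r_opp) / (r_pref + r_opp))


def osi(curve: TuningCurve, tf: float) -> float:
    """Orientation-selectivity index: preferred axis vs orthogonal axis."""
    r = _floored_means(curve, tf)
    theta, _ = preferred_direction(curve, tf)
    if math.isnan(theta):
        return 0.0
    i_pref = _nearest_direction_index(curve.directions, theta)
    i_opp = _nearest_direction_index(curve.directions, theta + 180.0)
    i_o1 = _nearest_direction_index(curve.directions, theta + 90.0)
    i_o2 = _nearest_direction_index(curve.directions, theta + 270.0)
    for i, expect in ((i_o1, 90.0), (i_o2, 270.0)):
        err = abs((curve.directions[i] - curve.directions[i_pref] - expect
                   + 180.0) % 360.0 - 180.0)
        if err > 1e-6:
            raise ValueError("orthogonal axis not in the sampling grid")
    r_pref = (r[i_pref] + r[i_opp]) / 2.0
    r_orth = (r[i_o1] + r[i_o2]) / 2.0
    if r_pref + r_orth == 0.0:
        return 0.0
    return float((r_pref - r_orth) / (r_pref + r_orth))


def preferred_tf(curve: TuningCurve) -> float:
    """TF with the maximal peak (per-TF best-direction) mean amplitude.

    Ties break toward the lower TF; amplitudes are floored at zero.
    """
    peaks = np.maximum(curve.mean_amplitude, 0.0).max(axis=0)
    return float(curve.tfs[int(np.argmax(peaks))])  # argmax takes first max


def classify_ds(responsive: bool, dsi_per_tf) -> bool:
    """DS iff responsive and DSI > 0.3 (strict) at >= 1 TF."""
    return bool(responsive) and bool(np.max(np.asarray(dsi_per_tf, float)) > DS_THRESHOLD)


def axis_class(theta_deg: float) -> str:
    """'horizontal' within +/-45 deg of 0/180 (45-deg boundary horizontal)."""
    if math.isnan(theta_deg):
        raise ValueError("undefined preferred direction")
    dist = abs((theta_deg % 180.0 + 90.0) % 180.0 - 90.0)  # to nearest of 0/180
    return "horizontal" if dist <= 45.0 else "vertical"


def tf_response_ratio(curve: TuningCurve, tf_hi: float = 1.2,
                      tf_lo: float = 0.3) -> float:
    """Peak-amplitude ratio R(1.2 Hz)/R(0.3 Hz); NaN when denominator <= 0."""
    peaks = np.maximum(curve.mean_amplitude, 0.0).max(axis=0)
    j_hi = int(np.argmin(np.abs(curve.tfs - tf_hi)))
    j_lo = int(np.argmin(np.abs(curve.tfs - tf_lo)))
    if peaks[j_lo] <= 0.0:
        return float("nan")
    return float(peaks[j_hi] / peaks[j_lo])


def omr_ratio(frame_labels) -> float:
    """Optomotor ratio: frames with-stimulus / frames against-stimulus.

    Labels are strings in {'with', 'against', 'neither'}; NaN when no
    against-frames exist.
    """
    labels = np.asarray(frame_labels)
    n_with = int(np.sum(labels == "with"))
    n_against = int(np.sum(labels == "against"))
    if n_against == 0:
        return float("nan")
    return n_with / n_against


# ---------------------------------------------------------------------------
# flash-spot ON/OFF analysis


@dataclass
class FlashResponse:
    """ON/OFF peak responses and the ON-OFF index per spot size."""

    cell_id: int
    spot_diameters_um: np.ndarray
    r_on: np.ndarray  # peak dF/F0 during illumination
    r_off: np.ndarray  # peak dF/F0 after illumination
    ooi: np.ndarray = field(init=False)
    mean_abs_ooi: float = field(init=False)
    is_onoff: bool = field(init=False)

    def __post_init__(self) -> None:
        total = self.r_on + self.r_off
        with np.errstate(invalid="ignore", divide="ignore"):
            ooi = np.where(total == 0.0, 0.0, (self.r_on - self.r_off) / total)
        self.ooi = ooi
        self.mean_abs_ooi = float(np.mean(np.abs(ooi)))
        self.is_onoff = self.mean_abs_ooi < ONOFF_THRESHOLD


def ooi_and_onoff(r_on, r_off, spot_diameters_um, cell_id: int = 0) -> FlashResponse:
    """OOI per spot size and the ON-OFF call (mean |OOI| < 0.3)."""
    r_on = np.asarray(r_on, float)
    r_off = np.asarray(r_off, float)
    spots = np.asarray(spot_diameters_um, float)
    if not (r_on.shape == r_off.shape == spots.shape):
        raise ValueError("per-size arrays must align")
    return FlashResponse(cell_id=cell_id, spot_diameters_um=spots,
                         r_on=r_on, r_off=r_off)


def extract_flash_responses(dff, events, source_rate: float,
                            off_window_s: float = 2.0, off_gap_s: float = 1.0,
                            cell_id: int = 0) -> FlashResponse:
    """Flash-spot ON/OFF peaks from a dF/F trace and its event table.

    R_ON is the trial-averaged peak dF/F0 during the spot illumination and
    R_OFF the peak in the ``off_window_s`` seconds after it, per spot
    diameter.  The OFF window starts ``off_gap_s`` after light offset so
    the indicator's decay tail from the ON transient does not masquerade
    as an OFF response.  Peaks are floored at zero before the OOI ratio.
    """
    scale = dff.frame_rate / source_rate
    rows: dict[float, list[tuple[float, float]]] = {}
    for ev in events.itertuples():
        lo = int(round(ev.onset_frame * scale))
        hi = int(round(ev.offset_frame * scale))
        off_lo = hi + int(round(off_gap_s * dff.frame_rate))
        off_hi = min(dff.values.size,
                     off_lo + int(round(off_window_s * dff.frame_rate)))
        on_peak = float(dff.values[lo:hi].max())
        off_peak = float(dff.values[off_lo:off_hi].max())
        rows.setdefault(float(ev.spot_diameter_um), []).append((on_peak, off_peak))
    spots = np.array(sorted(rows))
    r_on = np.array([max(0.0, np.mean([p[0] for p in rows[s]])) for s in spots])
    r_off = np.array([max(0.0, np.mean([p[1] for p in rows[s]])) for s in spots])
    return ooi_and_onoff(r_on, r_off, spots, cell_id=cell_id)


# ---------------------------------------------------------------------------
# per-cell summary


@dataclass
class CellSummary:
    """All per-cell tuning metrics, one value per TF where applicable."""

    cell_id: int
    responsive: bool
    is_ds: bool
    dsi_per_tf: np.ndarray
    osi_per_tf: np.ndarray
    theta_per_tf: np.ndarray  # degrees; NaN where undefined
    resultant_per_tf: np.ndarray
    preferred_tf_hz: float
    tf_ratio: float
    tfs: np.ndarray
    group: str = ""
    projection: str = ""

    @property
    def axis_class_per_tf(self) -> list[str]:
        return [axis_class(t) if not math.isnan(t) else "undefined"
                for t in self.theta_per_tf]


def summarize_cell(curve: TuningCurve, responsive: bool, group: str = "",
                   projection: str = "") -> CellSummary:
    dsis = np.array([dsi(curve, tf) for tf in curve.tfs])
    osis = np.array([osi(curve, tf) for tf in curve.tfs])
    thetas, lengths = zip(*(preferred_direction(curve, tf) for tf in curve.tfs))
    return CellSummary(
        cell_id=curve.cell_id,
        responsive=responsive,
        is_ds=classify_ds(responsive, dsis),
        dsi_per_tf=dsis,
        osi_per_tf=osis,
        theta_per_tf=np.array(thetas),
        resultant_per_tf=np.array(lengths),
        preferred_tf_hz=preferred_tf(curve),
        tf_ratio=tf_response_ratio(curve),
        tfs=curve.tfs.copy(),
        group=group,
        projection=projection,
    )


def summary_table(summaries: list[CellSummary]) -> pd.DataFrame:
    """Flatten summaries to one row per cell (units in column names)."""
    rows = []
    for s in summaries:
        row = {
            "cell_id": s.cell_id, "group": s.group, "projection": s.projection,
            "responsive": s.responsive, "is_ds": s.is_ds,
            "preferred_tf_hz": s.preferred_tf_hz,
            "tf_ratio_1p2_over_0p3": s.tf_ratio,
        }
        for j, tf in enumerate(s.tfs):
            tag = f"{tf:g}hz"
            row[f"dsi_{tag}"] = s.dsi_per_tf[j]
            row[f"osi_{tag}"] = s.osi_per_tf[j]
            row[f"theta_deg_{tag}"] = s.theta_per_tf[j]
        rows.append(row)
    return pd.DataFrame(rows)
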