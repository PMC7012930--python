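"""Stimulus protocols and event schedules.

Every downstream stage indexes fluorescence traces through an event table
derived from a :class:`StimulusProtocol`: which direction/temporal-frequency
(TF) condition was on screen in which frames.  Four protocol kinds are
supported:

``drifting-grating``
    Full-field sinusoidal gratings drifting in a set of directions at a set
    of TFs; the cortical default is 12 directions x 4 TFs x 6 trials with
    3 s of drift and 3 s of gray screen per presentation, sampled at 30.9 Hz.
    The retinal default is 8 directions x 4 TFs x 3 trials.
``flash-spot``
    Static spots of several diameters flashed for 2 s, used to separate ON
    and OFF response components.
``retinotopy-bar``
    A bar swept periodically across the visual field (azimuth or elevation);
    the sweep frequency in Hz is speed/extent.
``isoi-grating``
    Gratings for intrinsic-signal areal responses: 10 s stationary + 10 s in
    motion, i.e. a 20-s (0.05 Hz) stimulus period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Screen coverage of the stimulation setup, visual degrees.
AZIMUTH_RANGE_DEG: tuple[float, float] = (-67.23, 67.23)
ELEVATION_RANGE_DEG: tuple[float, float] = (-41.98, 60.77)

#: Temporal frequencies (Hz) used in all drifting-grating experiments.
DEFAULT_TFS: tuple[float, ...] = (0.3, 0.75, 1.2, 1.8)

CORTICAL_DIRECTIONS: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 30))
RETINAL_DIRECTIONS: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 45))
DEFAULT_SPOT_DIAMETERS_UM: tuple[float, ...] = (50.0, 100.0, 200.0, 400.0, 800.0)

KINDS = ("drifting-grating", "flash-spot", "retinotopy-bar", "isoi-grating")


@dataclass(frozen=True)
class StimulusProtocol:
    """Immutable description of one stimulation run.

    ``drift_s`` is the stimulus-on duration of a single presentation (the 3-s
    drift for gratings, the 2-s illumination for flash spots, the 10-s motion
    phase for ISOI gratings) and ``gray_s`` the blank interval that follows
    it.  ``pre_s`` seconds of gray screen precede the first event so the
    baseline stage always sees stimulus-free data.  The pseudorandom event
    order is a deterministic function of ``order_seed``.
    """

    kind: str
    directions: tuple[float, ...] = ()
    tfs: tuple[float, ...] = ()
    spatial_frequency: float = 0.03  # cycles/degree
    n_trials: int = 6
    drift_s: float = 3.0
    gray_s: float = 3.0
    frame_rate: float = 30.9  # Hz
    pre_s: float = 12.0
    spot_diameters_um: tuple[float, ...] = ()
    sweep_extent_deg: float = float(np.diff(AZIMUTH_RANGE_DEG)[0])
    sweep_speed_deg_per_s: float = 9.0
    stationary_s: float = 0.0  # isoi-grating only
    order_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; expected one of {KINDS}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.kind in ("drifting-grating", "isoi-grating"):
            if not self.directions:
                raise ValueError("direction list must not be empty")
            if not self.tfs:
                raise ValueError("TF list must not be empty")
            if self.drift_s <= 0:
                raise ValueError("drift_s must be positive")
            wrapped = np.mod(np.asarray(self.directions, float), 360.0)
            if len(np.unique(np.round(wrapped, 9))) != len(wrapped):
                raise ValueError("directions must be distinct modulo 360")
        if self.kind == "flash-spot" and not self.spot_diameters_um:
            raise ValueError("flash-spot protocol needs spot diameters")
        if self.kind == "retinotopy-bar":
            if self.sweep_extent_deg <= 0 or self.sweep_speed_deg_per_s <= 0:
                raise ValueError("sweep extent and speed must be positive")

    # ------------------------------------------------------------------
    @property
    def event_duration_s(self) -> float:
        return self.drift_s + self.gray_s

    @property
    def sweep_frequency_hz(self) -> float:
        """Sweeps per second of the retinotopy bar (speed / extent)."""
        return self.sweep_speed_deg_per_s / self.sweep_extent_deg

    @property
    def n_events(self) -> int:
        if self.kind == "flash-spot":
            return len(self.spot_diameters_um) * self.n_trials
        return len(self.directions) * len(self.tfs) * self.n_trials

    @property
    def total_s(self) -> float:
        """Recording duration covered by the event schedule (incl. lead-in)."""
        per_event = self.event_duration_s
        if self.kind == "isoi-grating":
            per_event = self.stationary_s + self.drift_s
        return self.pre_s + self.n_events * per_event

    @property
    def n_frames(self) -> int:
        return int(round(self.total_s * self.frame_rate))

    # ------------------------------------------------------------------
    def events(self) -> pd.DataFrame:
        """Event table tiling the recording without overlap.

        Columns for grating kinds: ``onset_frame, offset_frame, direction,
        tf, trial``; for flash spots ``direction``/``tf`` are replaced by
        ``spot_diameter_um``.  ``onset_frame`` marks stimulus onset (motion
        onset for ISOI gratings); ``offset_frame`` is exclusive.
        """
        rng = np.random.default_rng(self.order_seed)
        if self.kind == "flash-spot":
            conditions = [(d,) for d in self.spot_diameters_um]
        else:
            conditions = [(d, tf) for d in self.directions for tf in self.tfs]

        rows = []
        slot = 0
        per_event = self.event_duration_s
        lead_s = 0.0
        if self.kind == "isoi-grating":
            per_event = self.stationary_s + self.drift_s
            lead_s = self.stationary_s
        for trial in range(self.n_trials):
            order = rng.permutation(len(conditions))
            for idx in order:
                t_on = self.pre_s + slot * per_event + lead_s
                onset = int(round(t_on * self.frame_rate))
                offset = int(round((t_on + self.drift_s) * self.frame_rate))
                if self.kind == "flash-spot":
                    rows.append((onset, offset, conditions[idx][0], trial))
                else:
                    rows.append((onset, offset, *conditions[idx], trial))
                slot += 1
        if self.kind == "flash-spot":
            cols = ["onset_frame", "offset_frame", "spot_diameter_um", "trial"]
        else:
            cols = ["onset_frame", "offset_frame", "direction", "tf", "trial"]
        df = pd.DataFrame(rows, columns=cols)
        return df.astype({"onset_frame": int, "offset_frame": int, "trial": int})

    def with_seed(self, order_seed: int) -> "StimulusProtocol":
        return replace(self, order_seed=order_seed)


def make_stimulus_protocol(kind: str, **params) -> StimulusProtocol:
    """Build a protocol of the given kind with study defaults filled in.

    ``drifting-grating`` defaults to the cortical 12-direction x 4-TF x
    6-trial schedule; pass ``directions=RETINAL_DIRECTIONS, n_trials=3`` for
    the retinal variant.  Unknown keyword arguments are rejected.
    """
    defaults: dict
    if kind == "drifting-grating":
        defaults = dict(
            directions=CORTICAL_DIRECTIONS,
            tfs=DEFAULT_TFS,
            n_trials=6,
            drift_s=3.0,
            gray_s=3.0,
            frame_rate=30.9,
        )
    elif kind == "flash-spot":
        defaults = dict(
            spot_diameters_um=DEFAULT_SPOT_DIAMETERS_UM,
            n_trials=3,
            drift_s=2.0,
            gray_s=3.0,
            frame_rate=30.9,
        )
    elif kind == "retinotopy-bar":
        defaults = dict(
            sweep_extent_deg=float(np.diff(AZIMUTH_RANGE_DEG)[0]),
            sweep_speed_deg_per_s=9.0,
            n_trials=10,
            frame_rate=6.0,
            pre_s=0.0,
        )
    elif kind == "isoi-grating":
        defaults = dict(
            directions=(0.0, 90.0, 180.0, 270.0),
            tfs=DEFAULT_TFS,
            n_trials=5,
            stationary_s=10.0,
            drift_s=10.0,
            gray_s=0.0,
            frame_rate=6.0,
            pre_s=10.0,
        )
    else:
        raise ValueError(f"unknown protocol kind {kind!r}; expected one of {KINDS}")

    valid = set(StimulusProtocol.__dataclass_fields__) - {"kind"}
    unknown = set(params) - valid
    if unknown:
        raise TypeError(f"unknown protocol parameters: {sorted(unknown)}")
    defaults.update(params)
    return StimulusProtocol(kind=kind, **defaults)
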