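"""Ground-truth-labeled synthetic two-photon recordings.

The generator emulates the statistical structure the tuning and population
analyses assume, so every downstream stage can be tested against a known
truth.  A cell's noiseless direction tuning at temporal frequency ``tf`` is

    R(d) = A_tf * [ (1 - dsi)/2 + dsi * g(d; theta, kappa) ]

where ``g`` is a von Mises bump rescaled to g(theta) = 1 and
g(theta + 180) = 0:

    g(d) = (exp(kappa * cos(d - theta)) - exp(-kappa)) / (exp(kappa) - exp(-kappa))

With this normalization the direction-selectivity index of the noiseless
curve equals ``dsi`` exactly (R_pref = A(1+dsi)/2, R_opp = A(1-dsi)/2), so
the generator parameter is directly recoverable by the pipeline.

The per-TF amplitude couples to the preferred direction through

    A_tf = tf_gain[tf] * max(0, 1 + c * w(tf) * cos(theta))

where ``c`` is ``tf_direction_coupling`` and ``w`` ramps linearly from 0 at
the lowest TF to 1 at the highest.  Positive ``c`` makes posterior-preferring
cells (theta near 0 deg; 0 deg = posterior, i.e. temporal-to-nasal motion on
the screen, angles counter-clockwise) grow their responses with TF — the
response motif whose loss the mutant populations emulate.

Traces are built as ``F(t) = baseline_f * (1 + drift(t) + s(t)) + noise``
where ``s`` is the stimulus drive convolved with a single-exponential
calcium-indicator kernel (tau default 0.6 s, GCaMP6f-like) and ``drift`` is
a sum of slow sinusoids (periods > 120 s) that the 60-s percentile baseline
stage must remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .protocols import DEFAULT_TFS, StimulusProtocol

POSTERIOR_DEG = 0.0  # direction convention: 0 deg = posterior motion

# ---------------------------------------------------------------------------
# ground truth


@dataclass
class TuningGroundTruth:
    """Generative parameters of one synthetic cell."""

    cell_id: int
    group: str = "control"  # "control" | "mutant"
    projection: str = "none"  # "unspecific" | "RL-p" | "PM-p" | "none"
    theta_true: float = 0.0  # preferred direction, degrees
    kappa: float = 4.0  # von Mises concentration
    dsi_true: float = 0.8
    tf_gain: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)  # amplitude per TF, dF/F0
    tf_direction_coupling: float = 0.0
    baseline_f: float = 100.0  # a.u.
    noise_sd: float = 0.0  # a.u. (trace noise)
    onoff_balance: float = 0.0  # in [-1, 1]; OOI of flash responses
    ensemble: str = ""

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(g <= 0 for g in self.tf_gain):
            raise ValueError("tf_gain must be positive for all TFs")


def _direction_profile(d_deg: np.ndarray | float, theta_deg: float, kappa: float,
                       dsi: float) -> np.ndarray:
    """Normalized tuning profile in [ (1-dsi)/2, (1+dsi)/2 ]."""
    delta = np.deg2rad(np.asarray(d_deg, float) - theta_deg)
    if kappa == 0:
        bump = np.full_like(np.cos(delta), 0.5)
    else:
        # (e^{k cos} - e^{-k}) / (e^k - e^{-k}), scaled by e^{-k} for stability
        bump = (np.exp(kappa * (np.cos(delta) - 1.0)) - math.exp(-2.0 * kappa)) \
            / -math.expm1(-2.0 * kappa)
    return (1.0 - dsi) / 2.0 + dsi * bump


def amplitude_at(truth: TuningGroundTruth, direction_deg: float, tf: float,
                 tfs: tuple[float, ...] = DEFAULT_TFS) -> float:
    """Noiseless plateau response amplitude (dF/F0) for one condition."""
    tfs = tuple(tfs)
    i = tfs.index(tf)
    w = i / (len(tfs) - 1) if len(tfs) > 1 else 1.0
    gain = truth.tf_gain[i] * max(
        0.0, 1.0 + truth.tf_direction_coupling * w
        * math.cos(math.radians(truth.theta_true - POSTERIOR_DEG))
    )
    return float(gain * _direction_profile(direction_deg, truth.theta_true,
                                           truth.kappa, truth.dsi_true))


def expected_trial_amplitude(truth: TuningGroundTruth, direction_deg: float, tf: float,
                             tfs: tuple[float, ...] = DEFAULT_TFS,
                             drift_s: float = 3.0, tau_s: float = 0.6) -> float:
    """Closed-form prediction of the pipeline's trial amplitude at zero noise.

    The trial amplitude is the mean of the upper half of dF/F0 samples in
    the drift window.  For a step drive of height R filtered by
    ``1 - exp(-t/tau)``, the upper half of samples is the second half of the
    window (the response is monotone), whose mean is

        R * (1 - (tau/h) * (exp(-h/tau) - exp(-2h/tau))),  h = drift_s/2.
    """
    r = amplitude_at(truth, direction_deg, tf, tfs)
    h = drift_s / 2.0
    factor = 1.0 - (tau_s / h) * (math.exp(-h / tau_s) - math.exp(-2.0 * h / tau_s))
    return r * factor


# ---------------------------------------------------------------------------
# population sampling


@dataclass
class EnsembleSpec:
    """One mixture component of a population.

    ``theta_mode_deg=None`` draws preferred directions uniformly on the
    circle; otherwise they are von Mises around the mode with concentration
    ``theta_concentration``.
    """

    weight: float
    theta_mode_deg: float | None = None
    theta_concentration: float = 3.0
    kappa_range: tuple[float, float] = (2.0, 6.0)
    dsi_range: tuple[float, float] = (0.4, 0.9)
    tf_gain_mean: tuple[float, ...] = (0.3, 0.3, 0.3, 0.3)
    tf_gain_jitter: float = 0.25  # lognormal sigma applied per cell
    tf_direction_coupling: float = 0.0
    baseline_range: tuple[float, float] = (80.0, 120.0)
    noise_sd: float = 0.0
    onoff_balance_range: tuple[float, float] = (-0.2, 0.2)
    name: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("mixture weights must be >= 0")
        for rng_ in (self.kappa_range, self.dsi_range):
            if rng_[1] < rng_[0] or rng_[0] < 0:
                raise ValueError("dispersion ranges must be nonnegative and ordered")


@dataclass
class PopulationSpec:
    """Mixture specification for one genetic group's cell population."""

    n_cells: int
    ensembles: list[EnsembleSpec]
    group: str = "control"
    projection: str = "none"

    def __post_init__(self) -> None:
        total = sum(e.weight for e in self.ensembles)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"ensemble weights must sum to 1 (got {total})")


def retinal_like_ensemble(weight: float, noise_sd: float = 0.0) -> EnsembleSpec:
    """Posterior-preferring, TF-increasing ensemble (retina-dependent motif)."""
    return EnsembleSpec(
        weight=weight,
        theta_mode_deg=POSTERIOR_DEG,
        theta_concentration=3.0,
        kappa_range=(2.0, 6.0),
        dsi_range=(0.45, 0.9),
        tf_gain_mean=(0.12, 0.17, 0.28, 0.24),
        tf_direction_coupling=0.6,
        noise_sd=noise_sd,
        name="retinal-like",
    )


def intrinsic_ensemble(weight: float, noise_sd: float = 0.0) -> EnsembleSpec:
    """Uniform-direction, TF-decreasing ensemble (retina-independent motif)."""
    return EnsembleSpec(
        weight=weight,
        theta_mode_deg=None,
        kappa_range=(2.0, 6.0),
        dsi_range=(0.35, 0.8),
        tf_gain_mean=(0.28, 0.22, 0.15, 0.11),
        tf_direction_coupling=0.0,
        noise_sd=noise_sd,
        name="intrinsic",
    )


def default_population_spec(group: str, n_cells: int = 800,
                            noise_sd: float = 0.0) -> PopulationSpec:
    """Study-condition mixtures: the mutant group differs from control only
    in the mass of the posterior-preferring, TF-increasing ensemble."""
    retinal_weight = 0.45 if group == "control" else 0.12
    return PopulationSpec(
        n_cells=n_cells,
        group=group,
        ensembles=[
            retinal_like_ensemble(retinal_weight, noise_sd),
            intrinsic_ensemble(1.0 - retinal_weight, noise_sd),
        ],
    )


def sample_population(spec: PopulationSpec, seed: int) -> list[TuningGroundTruth]:
    """Draw cells i.i.d. from the mixture; reproducible under a fixed seed."""
    rng = np.random.default_rng(seed)
    weights = np.array([e.weight for e in spec.ensembles])
    choices = rng.choice(len(spec.ensembles), size=spec.n_cells, p=weights)
    cells: list[TuningGroundTruth] = []
    for i, ci in enumerate(choices):
        ens = spec.ensembles[ci]
        if ens.theta_mode_deg is None:
            theta = float(rng.uniform(0.0, 360.0))
        else:
            theta = float(np.rad2deg(rng.vonmises(
                np.deg2rad(ens.theta_mode_deg), ens.theta_concentration)) % 360.0)
        gains = tuple(
            float(g * rng.lognormal(0.0, ens.tf_gain_jitter)) for g in ens.tf_gain_mean
        )
        cells.append(TuningGroundTruth(
            cell_id=i,
            group=spec.group,
            projection=spec.projection,
            theta_true=theta,
            kappa=float(rng.uniform(*ens.kappa_range)),
            dsi_true=float(rng.uniform(*ens.dsi_range)),
            tf_gain=gains,
            tf_direction_coupling=ens.tf_direction_coupling,
            baseline_f=float(rng.uniform(*ens.baseline_range)),
            noise_sd=ens.noise_sd,
            onoff_balance=float(rng.uniform(*ens.onoff_balance_range)),
            ensemble=ens.name,
        ))
    return cells


# ---------------------------------------------------------------------------
# trace synthesis


@dataclass
class SyntheticRecording:
    """Per-ROI fluorescence traces plus the event table and ground truth."""

    traces: np.ndarray  # (n_cells, n_frames), a.u.
    frame_rate: float
    events: pd.DataFrame
    truth: list[TuningGroundTruth]
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        if len(self.events) and int(self.events["offset_frame"].max()) > self.traces.shape[1]:
            raise ValueError("event window extends past end of trace")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("trace values must be finite")


def _slow_drift(n_frames: int, frame_rate: float, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Sum of low-frequency sinusoids with periods > 120 s (relative units)."""
    if amplitude == 0.0:
        return np.zeros(n_frames)
    t = np.arange(n_frames) / frame_rate
    periods = np.array([150.0, 260.0, 410.0])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=periods.size)
    comps = np.sin(2.0 * np.pi * t[None, :] / periods[:, None] + phases[:, None])
    drift = comps.sum(axis=0)
    return amplitude * drift / periods.size


def synthesize_recording(truth: list[TuningGroundTruth], protocol: StimulusProtocol,
                         seed: int, tau_s: float = 0.6,
                         drift_amplitude: float = 0.02) -> SyntheticRecording:
    """Render fluorescence traces for a population under a protocol.

    ``drift-grating`` events drive each cell with its closed-form amplitude
    for the event's (direction, TF); ``flash-spot`` events drive an ON step
    during illumination and an OFF step after it, split according to
    ``onoff_balance`` (= the cell's ground-truth OOI).
    """
    if not truth:
        raise ValueError("empty population")
    if protocol.kind not in ("drifting-grating", "flash-spot"):
        raise ValueError(f"cannot synthesize traces for protocol kind {protocol.kind!r}")
    rng = np.random.default_rng(seed)
    events = protocol.events()
    n_frames = protocol.n_frames
    fr = protocol.frame_rate
    # single-exponential indicator kernel as a recursive (AR(1)) filter
    decay = math.exp(-1.0 / (tau_s * fr))

    traces = np.empty((len(truth), n_frames))
    for row, cell in enumerate(truth):
        drive = np.zeros(n_frames)
        if protocol.kind == "drifting-grating":
            for onset, offset, d, tf in zip(events["onset_frame"], events["offset_frame"],
                                            events["direction"], events["tf"]):
                drive[onset:offset] = amplitude_at(cell, float(d), float(tf), protocol.tfs)
        else:
            peak = cell.tf_gain[0]
            r_on = peak * (1.0 + cell.onoff_balance) / 2.0
            r_off = peak * (1.0 - cell.onoff_balance) / 2.0
            off_frames = int(round(min(protocol.gray_s, protocol.drift_s) * fr))
            for onset, offset in zip(events["onset_frame"], events["offset_frame"]):
                drive[onset:offset] = r_on
                drive[offset:offset + off_frames] = r_off
        # dF/F0-scale response with indicator decay: y[t] = max(drive, decay*y[t-1])
        # approximated linearly as drive filtered by (1-a)/(1-a z^-1) which has
        # unit DC gain and exponential decay
        signal = lfilter([1.0 - decay], [1.0, -decay], drive)
        drift = _slow_drift(n_frames, fr, drift_amplitude, rng)
        f = cell.baseline_f * (1.0 + drift + signal)
        if cell.noise_sd > 0:
            f = f + rng.normal(0.0, cell.noise_sd * cell.baseline_f, size=n_frames)
        traces[row] = f
    return SyntheticRecording(traces=traces, frame_rate=fr, events=events,
                              truth=list(truth), protocol=protocol)


def synthesize_trial_amplitudes(truth: list[TuningGroundTruth],
                                protocol: StimulusProtocol, seed: int,
                                trial_noise_sd: float = 0.05) -> pd.DataFrame:
    """Amplitude-level fast path: closed-form plateau amplitudes plus
    i.i.d. Gaussian trial noise, skipping trace rendering.

    Returns a long table (cell_id, direction, tf, trial, amplitude) suitable
    for :func:`dsstream.traces.build_tuning_curve`.  Negative draws are kept;
    the tuning formulas floor negatives themselves.
    """
    if protocol.kind != "drifting-grating":
        raise ValueError("amplitude-level synthesis requires a drifting-grating protocol")
    rng = np.random.default_rng(seed)
    dirs = np.asarray(protocol.directions)
    tfs = np.asarray(protocol.tfs)
    rows = []
    for cell in truth:
        mean = np.array([[amplitude_at(cell, d, tf, protocol.tfs) for tf in tfs]
                         for d in dirs])
        draws = mean[:, :, None] + rng.normal(
            0.0, trial_noise_sd, size=(dirs.size, tfs.size, protocol.n_trials))
        for i, d in enumerate(dirs):
            for j, tf in enumerate(tfs):
                for k in range(protocol.n_trials):
                    rows.append((cell.cell_id, float(d), float(tf), k,
                                 float(draws[i, j, k])))
    return pd.DataFrame(rows, columns=["cell_id", "direction", "tf", "trial",
                                       "amplitude"])
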