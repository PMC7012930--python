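import numpy as np
import pytest

from dsstream.traces import TuningCurve


@pytest.fixture
def curve_factory():
    """Build a TuningCurve from a (n_directions, n_tfs) mean-amplitude array
    (every trial equal) or a full (n_dir, n_tf, n_trial) array."""

    def _make(amplitudes, directions=None, tfs=(0.3, 0.75, 1.2, 1.8),
              n_trials=6, cell_id=0):
        amps = np.asarray(amplitudes, float)
        if amps.ndim == 1:
            amps = amps[:, None]
            tfs = tfs[: 1]
        if amps.ndim == 2:
            amps = np.repeat(amps[:, :, None], n_trials, axis=2)
        if directions is None:
            directions = np.linspace(0.0, 360.0, amps.shape[0], endpoint=False)
        return TuningCurve(cell_id=cell_id,
                           directions=np.asarray(directions, float),
                           tfs=np.asarray(tfs, float),
                           trial_amplitudes=amps)

    return _make
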