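"""On-disk formats: CSV traces/events, JSON sidecars, TIFF stacks.

Recordings are stored as a wide per-ROI CSV of fluorescence (one column per
ROI, one row per frame, a.u.), an event CSV, and a JSON sidecar carrying
the protocol and ground truth.  Retinotopy stacks round-trip through
multi-page TIFF with a JSON sidecar for frame rate and geometry.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocols import StimulusProtocol
from .simulate import SyntheticRecording, TuningGroundTruth


def save_recording(rec: SyntheticRecording, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {f"roi_{c.cell_id}": rec.traces[i] for i, c in enumerate(rec.truth)}
    pd.DataFrame(cols).to_csv(out / "traces.csv", index=False)
    rec.events.to_csv(out / "events.csv", index=False)
    sidecar = {
        "frame_rate_hz": rec.frame_rate,
        "protocol": dataclasses.asdict(rec.protocol),
        "truth": [dataclasses.asdict(t) for t in rec.truth],
    }
    (out / "recording.json").write_text(json.dumps(sidecar, indent=2))


def load_recording(in_dir: str | Path) -> SyntheticRecording:
    src = Path(in_dir)
    traces_df = pd.read_csv(src / "traces.csv")
    events = pd.read_csv(src / "events.csv")
    sidecar = json.loads((src / "recording.json").read_text())
    proto_kwargs = sidecar["protocol"]
    for key in ("directions", "tfs", "spot_diameters_um"):
        proto_kwargs[key] = tuple(proto_kwargs[key])
    protocol = StimulusProtocol(**proto_kwargs)
    truth = []
    for t in sidecar["truth"]:
        t["tf_gain"] = tuple(t["tf_gain"])
        truth.append(TuningGroundTruth(**t))
    traces = traces_df[[f"roi_{t.cell_id}" for t in truth]].to_numpy().T
    return SyntheticRecording(traces=traces, frame_rate=sidecar["frame_rate_hz"],
                              events=events, truth=truth, protocol=protocol)


def save_stack(stack: np.ndarray, path: str | Path, frame_rate: float,
               **metadata) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, np.float32))
    sidecar = {"frame_rate_hz": frame_rate, **metadata}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stack(path: str | Path):
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return stack, sidecar
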