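"""Run configuration: one place for every analysis constant.

Thresholds collected here: the 0.06 dF/F0 responsiveness gate, the 0.3 DSI
gate for DS classification, the 0.3 mean-|OOI| gate for ON-OFF cells, the
8 x 8 grid segmentation, and the 0.05 significance level of the per-grid
chi-square comparison.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 0
    responsiveness_threshold: float = 0.06  # dF/F0
    dsi_threshold: float = 0.3
    ooi_threshold: float = 0.3
    grid_n: int = 8
    alpha: float = 0.05
    n_cells_per_group: int = 400
    trial_noise_sd: float = 0.05  # amplitude-level trial noise, dF/F0
    trace_level: bool = False  # render full traces instead of trial amplitudes
    percentile_step_s: float = 1.0  # baseline percentile lattice
    include_isoi: bool = False
    out_dir: str = "dsstream_out"

    def __post_init__(self) -> None:
        for key in ("responsiveness_threshold", "dsi_threshold", "ooi_threshold",
                    "alpha"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a JSON config; absent keys take defaults, unknown keys error."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text().strip()
        if text:
            try:
                data = json.loads(text)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed config file {path}: {exc}") from exc
            if not isinstance(data, dict):
                raise ValueError("config must be a JSON object")
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
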