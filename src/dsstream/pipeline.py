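"""End-to-end pipeline: simulate -> process -> tuning -> population (-> isoi).

The pipeline exists so the whole analysis chain can be exercised, logged
and reproduced from a single :class:`~dsstream.config.RunConfig`; every
stage is also importable on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import isoi, population, simulate, simulate_imaging, tuning, traces
from .config import RunConfig
from .protocols import make_stimulus_protocol

log = logging.getLogger("dsstream")


def simulate_groups(config: RunConfig):
    """Draw control and mutant populations and their tuning curves."""
    protocol = make_stimulus_protocol("drifting-grating",
                                      order_seed=config.seed)
    curves: list[traces.TuningCurve] = []
    summaries: list[tuning.CellSummary] = []
    truths = []
    next_id = 0
    for gi, group in enumerate(("control", "mutant")):
        spec = simulate.default_population_spec(group, config.n_cells_per_group)
        cells = simulate.sample_population(spec, seed=config.seed * 2 + gi)
        for c in cells:
            c.cell_id += next_id
        next_id += len(cells)
        if config.trace_level:
            for c in cells:
                c.noise_sd = config.trial_noise_sd
            rec = simulate.synthesize_recording(cells, protocol,
                                                seed=config.seed * 2 + gi + 1000)
            group_curves, dffs = traces.extract_tuning_curves(
                rec.traces, rec.events, protocol.frame_rate,
                cell_ids=[c.cell_id for c in cells],
                percentile_step_s=config.percentile_step_s)
        else:
            table = simulate.synthesize_trial_amplitudes(
                cells, protocol, seed=config.seed * 2 + gi + 1000,
                trial_noise_sd=config.trial_noise_sd)
            group_curves = [
                traces.build_tuning_curve(sub, cell_id=int(cid))
                for cid, sub in table.groupby("cell_id")
            ]
        for c, curve in zip(cells, group_curves):
            responsive, _ = traces.classify_responsive(
                curve, "cortical", threshold=config.responsiveness_threshold)
            summaries.append(tuning.summarize_cell(curve, responsive,
                                                   group=group,
                                                   projection=c.projection))
        curves.extend(group_curves)
        truths.extend(cells)
    return curves, summaries, truths


def analyze_population(summaries, curves, config: RunConfig):
    """Response matrix -> PCA -> grid -> per-grid classification."""
    rm = population.build_response_matrix(summaries, curves)
    embedding, evr = population.embed_pca(rm.matrix)
    assignment = population.segment_grid(embedding, n=config.grid_n)
    counts_a = population.grid_counts(assignment, rm.groups, "control", config.grid_n)
    counts_b = population.grid_counts(assignment, rm.groups, "mutant", config.grid_n)
    comparison = population.classify_grids(counts_a, counts_b, alpha=config.alpha)
    return rm, embedding, evr, assignment, comparison


def run_isoi(config: RunConfig):
    """Retinotopy round trip on the six-area synthetic layout."""
    layout = simulate_imaging.default_six_area_layout()
    protocol = make_stimulus_protocol("retinotopy-bar")
    stacks, truth = simulate_imaging.synthesize_retinotopy_stack(
        layout, protocol, seed=config.seed)
    maps = {}
    mag_product = None
    for axis, st in stacks.items():
        pf, mf = isoi.fourier_component_map(st.forward, st.frame_rate, st.stim_freq_hz)
        pr, mr = isoi.fourier_component_map(st.reverse, st.frame_rate, st.stim_freq_hz)
        w = mf * mr
        mag_product = w if mag_product is None else mag_product * w
        phase, delay = isoi.delay_corrected_retinotopy(pf, pr, weights=w)
        maps[axis] = isoi.phase_to_degrees(phase, st.extent_deg) + st.center_deg
    response_mask = mag_product > 0.05 * mag_product.max()
    sign = isoi.visual_field_sign(maps["azimuth"], maps["elevation"],
                                  response_mask=response_mask)
    sm = isoi.threshold_and_clean(sign)
    mask = isoi.neighbor_filter(sm.mask)
    seg = isoi.detect_borders(mask, sign=sm.sign)
    return maps, sign, seg, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return a results dictionary."""
    results: dict = {"config": config.to_dict()}
    stage = "simulate"
    try:
        curves, summaries, truths = simulate_groups(config)
        n_resp = sum(s.responsive for s in summaries)
        n_ds = sum(s.is_ds for s in summaries)
        log.info("simulate: %d cells generated, %d responsive, %d DS",
                 len(summaries), n_resp, n_ds)
        results["counts"] = {"generated": len(summaries), "responsive": n_resp,
                             "ds": n_ds}
        results["cell_summaries"] = tuning.summary_table(summaries)

        stage = "population"
        rm, embedding, evr, assignment, comparison = analyze_population(
            summaries, curves, config)
        n_sig = int(np.sum(comparison.classes != "unchanged"))
        log.info("population: %d DS cells embedded, %d significant grids",
                 rm.matrix.shape[0], n_sig)
        results["counts"]["significant_grids"] = n_sig
        results["response_matrix"] = rm
        results["embedding"] = embedding
        results["explained_variance_ratio"] = evr
        results["grid_assignment"] = assignment
        results["grid_comparison"] = comparison

        if config.include_isoi:
            stage = "isoi"
            maps, sign, seg, truth = run_isoi(config)
            log.info("isoi: %d areas segmented", seg.area_mm2.size)
            results["isoi"] = {"maps": maps, "sign": sign, "segmentation": seg,
                               "truth": truth}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()).hexdigest()[:16]


def write_report(results: dict, out_dir: str | Path) -> dict:
    """Write CSV tables and a JSON manifest; deterministic file naming.

    Returns the manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    summaries = results.get("cell_summaries", pd.DataFrame(columns=["cell_id"]))
    if summaries.empty and summaries.columns.empty:
        summaries = pd.DataFrame(columns=["cell_id"])
    path = out / "cell_summaries.csv"
    summaries.to_csv(path, index=False)
    written.append(path.name)

    comparison = results.get("grid_comparison")
    if comparison is not None:
        n = comparison.n
        ix, iy = np.meshgrid(range(n), range(n), indexing="ij")
        grid_df = pd.DataFrame({
            "grid_x": ix.ravel(), "grid_y": iy.ravel(),
            "count_control": comparison.counts_a.ravel().astype(int),
            "count_mutant": comparison.counts_b.ravel().astype(int),
            "fraction_control": comparison.fractions_a.ravel(),
            "fraction_mutant": comparison.fractions_b.ravel(),
            "chi2_yates": comparison.chi2.ravel(),
            "p_value": comparison.p.ravel(),
            "class": comparison.classes.ravel(),
            "mutation_index": comparison.mi.ravel(),
        })
        path = out / "grid_comparison.csv"
        grid_df.to_csv(path, index=False)
        written.append(path.name)

    seg = results.get("isoi", {}).get("segmentation") if "isoi" in results else None
    if seg is not None:
        area_df = pd.DataFrame({
            "label": np.arange(1, seg.area_mm2.size + 1),
            "area_mm2": seg.area_mm2,
            "centroid_row_px": seg.centroids_px[:, 0],
            "centroid_col_px": seg.centroids_px[:, 1],
            "rel_row_mm": seg.centroids_rel_mm[:, 0],
            "rel_col_mm": seg.centroids_rel_mm[:, 1],
            "field_sign": seg.signs,
        })
        path = out / "area_table.csv"
        area_df.to_csv(path, index=False)
        written.append(path.name)

    manifest = {
        "config": results.get("config", {}),
        "config_hash": _config_hash(results.get("config", {})),
        "counts": results.get("counts", {}),
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
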