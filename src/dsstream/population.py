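"""Population decomposition, grid segmentation and group comparison.

The population machinery condenses every DS cell into eight numbers — the
peak dF/F0 amplitude and the DSI at each of the four TFs — decomposes the
resulting n_cells x 8 response matrix into two principal components,
partitions the pooled 2-D embedding into an n x n grid (default 8 x 8), and
compares the per-grid fraction of cells between two groups (control vs
mutant) with a Yates-corrected chi-square test on the 2 x 2 table
(in-grid vs out-of-grid) x group.  Grids with p < 0.05 are classed
``decreased`` or ``increased`` in the mutant according to the sign of the
fraction difference; no multiple-testing correction is applied across
grids (an optional Benjamini-Hochberg flag is provided).

Two normalized-difference indices summarize per-grid composition:

    MI  = (F_control - F_mutant) / (F_control + F_mutant)
    PTI = (F_RLp - F_PMp) / (F_RLp + F_PMp)

both in [-1, 1] with 0/0 mapped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circstats import rayleigh_test  # noqa: F401  (module surface)
from .tuning import CellSummary
from .traces import TuningCurve

ALPHA = 0.05


@dataclass
class ResponseMatrix:
    """n_cells x 8 matrix: peak amplitudes then DSIs at the 4 TFs."""

    matrix: np.ndarray
    cell_ids: np.ndarray
    groups: np.ndarray
    projections: np.ndarray
    preferred_tfs: np.ndarray
    tfs: np.ndarray

    @property
    def column_names(self) -> list[str]:
        return ([f"amp_{tf:g}hz" for tf in self.tfs]
                + [f"dsi_{tf:g}hz" for tf in self.tfs])


def build_response_matrix(summaries: list[CellSummary],
                          curves: list[TuningCurve],
                          require_both_groups: bool = True) -> ResponseMatrix:
    """Assemble the DS-cell response matrix, sorted by preferred TF then id.

    Columns are (amp@0.3, amp@0.75, amp@1.2, amp@1.8, DSI@0.3, ..., DSI@1.8).
    Non-DS cells are dropped.
    """
    by_id = {c.cell_id: c for c in curves}
    rows, ids, groups, projs, ptfs = [], [], [], [], []
    for s in summaries:
        if not s.is_ds:
            continue
        curve = by_id[s.cell_id]
        if curve.tfs.size != 4:
            raise ValueError("response matrix needs all four TF conditions")
        peaks = np.maximum(curve.mean_amplitude, 0.0).max(axis=0)
        rows.append(np.concatenate([peaks, s.dsi_per_tf]))
        ids.append(s.cell_id)
        groups.append(s.group)
        projs.append(s.projection)
        ptfs.append(s.preferred_tf_hz)
    if not rows:
        raise ValueError("no DS cells to assemble")
    groups_arr = np.asarray(groups)
    if require_both_groups and np.unique(groups_arr).size < 2:
        raise ValueError("both groups must be present in the response matrix")
    order = np.lexsort((np.asarray(ids), np.asarray(ptfs)))
    return ResponseMatrix(
        matrix=np.asarray(rows)[order],
        cell_ids=np.asarray(ids)[order],
        groups=groups_arr[order],
        projections=np.asarray(projs)[order],
        preferred_tfs=np.asarray(ptfs)[order],
        tfs=np.asarray(by_id[ids[0]].tfs, float),
    )


def embed_pca(matrix: np.ndarray, sign_column: int = 3):
    """Top-2 PCA of the z-scored response matrix.

    Columns are standardized (amplitudes and DSIs live on different scales);
    zero-variance columns are dropped with a warning.  Each component's sign
    is fixed so its loading on ``sign_column`` (default: amplitude at the
    highest TF) is >= 0, falling back to the first nonzero loading — PCA is
    otherwise sign-ambiguous.

    Returns ``(embedding (n, 2), explained_variance_ratio (2,))``.
    """
    x = np.asarray(matrix, float)
    if x.shape[0] < 3:
        raise ValueError("PCA embedding needs at least three cells")
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    col_map = np.flatnonzero(keep)
    # deterministic PCA via SVD of the centered standardized matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    ratio = var[:2] / var.sum()
    comps = vt[:2]
    scores = x @ comps.T
    for k in range(2):
        anchor = np.flatnonzero(col_map == sign_column)
        j = int(anchor[0]) if anchor.size else 0
        pivot = comps[k, j]
        if pivot == 0:
            nz = np.flatnonzero(comps[k])
            pivot = comps[k, nz[0]] if nz.size else 1.0
        if pivot < 0:
            scores[:, k] *= -1.0
    return scores, ratio


def segment_grid(embedding: np.ndarray, n: int = 8) -> np.ndarray:
    """Assign each point to an n x n grid cell of the pooled bounding box.

    Bins are half-open; points on the top/right boundary fall in the last
    bin.  Returns integer pairs (ix, iy), 0-based from the box minimum.
    """
    e = np.asarray(embedding, float)
    if not np.all(np.isfinite(e)):
        raise ValueError("embedding must be finite")
    lo = e.min(axis=0)
    span = e.max(axis=0) - lo
    if np.any(span == 0):
        raise ValueError("degenerate bounding box (zero extent)")
    idx = np.floor((e - lo) / span * n).astype(int)
    return np.clip(idx, 0, n - 1)


def grid_counts(assignment: np.ndarray, labels: np.ndarray, label: str,
                n: int = 8) -> np.ndarray:
    """Per-grid counts (n x n, indexed [ix, iy]) for one group label."""
    counts = np.zeros((n, n), int)
    sel = assignment[np.asarray(labels) == label]
    for ix, iy in sel:
        counts[ix, iy] += 1
    return counts


def grid_fraction_maps(assignment: np.ndarray, labels: np.ndarray,
                       groups: tuple[str, str], n: int = 8):
    """Per-group fraction maps F_g[i] = count(g in grid i)/count(g)."""
    maps = {}
    for g in groups:
        counts = grid_counts(assignment, labels, g, n)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"group {g!r} is empty")
        maps[g] = counts / total
    return maps


def yates_chi2(table: np.ndarray):
    """Yates-corrected chi-square on a 2 x 2 table: (chi2, p).

    Closed form n(|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d)); delegates to
    scipy, which implements exactly this for 2 x 2 with correction.
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("Yates correction applies to 2 x 2 tables")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return float("nan"), float("nan")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GridComparison:
    """Per-grid two-group comparison over an n x n PCA partition."""

    n: int
    counts_a: np.ndarray  # control
    counts_b: np.ndarray  # mutant
    fractions_a: np.ndarray
    fractions_b: np.ndarray
    chi2: np.ndarray
    p: np.ndarray
    classes: np.ndarray  # 'decreased' | 'increased' | 'unchanged'
    mi: np.ndarray  # mutation index per grid


def classify_grids(counts_a: np.ndarray, counts_b: np.ndarray,
                   alpha: float = ALPHA, fdr: bool = False) -> GridComparison:
    """Classify each grid as decreased/increased/unchanged in group b.

    Each grid's 2 x 2 table is (in-grid vs out-of-grid) x (group a vs b),
    tested with the Yates-corrected chi-square.  ``fdr=True`` applies a
    Benjamini-Hochberg correction across the tested grids before
    classifying (off by default, matching per-grid P < 0.05 usage).
    """
    counts_a = np.asarray(counts_a, float)
    counts_b = np.asarray(counts_b, float)
    n = counts_a.shape[0]
    tot_a, tot_b = counts_a.sum(), counts_b.sum()
    if tot_a == 0 or tot_b == 0:
        raise ValueError("both groups need at least one cell")
    frac_a, frac_b = counts_a / tot_a, counts_b / tot_b
    chi2 = np.full((n, n), np.nan)
    pvals = np.full((n, n), np.nan)
    for ix in range(n):
        for iy in range(n):
            a, b = counts_a[ix, iy], counts_b[ix, iy]
            if a == 0 and b == 0:
                continue
            table = np.array([[a, tot_a - a], [b, tot_b - b]])
            chi2[ix, iy], pvals[ix, iy] = yates_chi2(table)
    p_eff = pvals.copy()
    if fdr:
        flat = pvals[np.isfinite(pvals)]
        if flat.size:
            from statsmodels.stats.multitest import multipletests

            adj = multipletests(flat, method="fdr_bh")[1]
            p_eff[np.isfinite(pvals)] = adj
    classes = np.full((n, n), "unchanged", dtype=object)
    sig = np.isfinite(p_eff) & (p_eff < alpha)
    classes[sig & (frac_b < frac_a)] = "decreased"
    classes[sig & (frac_b > frac_a)] = "increased"
    return GridComparison(n=n, counts_a=counts_a, counts_b=counts_b,
                          fractions_a=frac_a, fractions_b=frac_b,
                          chi2=chi2, p=pvals, classes=classes,
                          mi=mutation_index(frac_a, frac_b))


def mutation_index(f_control, f_mutant):
    """MI = (F_ctrl - F_mut)/(F_ctrl + F_mut), elementwise; 0/0 -> 0."""
    fc = np.asarray(f_control, float)
    fm = np.asarray(f_mutant, float)
    if np.any(fc < 0) or np.any(fm < 0):
        raise ValueError("fractions must be nonnegative")
    total = fc + fm
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total == 0.0, 0.0, (fc - fm) / total)
    return out if out.ndim else float(out)


def projection_target_index(f_rlp, f_pmp):
    """PTI = (F_RLp - F_PMp)/(F_RLp + F_PMp), elementwise; 0/0 -> 0."""
    fr = np.asarray(f_rlp, float)
    fp = np.asarray(f_pmp, float)
    if np.any(fr < 0) or np.any(fp < 0):
        raise ValueError("fractions must be nonnegative")
    total = fr + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total == 0.0, 0.0, (fr - fp) / total)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# delegated standard tests


def compare_direction_distributions(thetas_a, thetas_b):
    """Two-sample two-sided Kolmogorov-Smirnov test on preferred directions.

    Angles are linearized onto [0, 360) with the cut at 0 deg (= posterior).
    """
    a = np.mod(np.asarray(thetas_a, float), 360.0)
    b = np.mod(np.asarray(thetas_b, float), 360.0)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def group_scalar_tests(values_a, values_b, paired: bool = False):
    """Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired), two-sided."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        if np.all(a == b):
            raise ValueError("all paired differences are zero")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
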