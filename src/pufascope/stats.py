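"""Group statistics for the lipidomics read-outs, plus viability metrics.

The central multiple-testing tool is the adaptive two-stage linear step-up
false discovery rate procedure (Benjamini–Krieger–Yekutieli family):

* stage 1: Benjamini–Hochberg step-up at q' = q/(1+q); its rejection count r1
  estimates the number of true nulls m0 = m - r1;
* stage 2: Benjamini–Hochberg step-up at the inflated level q·m/m0; the
  stage-2 rejections are the procedure's output.

Degenerate cases: r1 = 0 leaves m0 = m, so the procedure reduces to plain
Benjamini–Hochberg at q; m0 = 0 (everything rejected at stage 1) rejects all
hypotheses. Because m/m0 >= 1 the procedure always rejects a superset of
plain Benjamini–Hochberg at the same q. Adjusted values ("q values") are the
stage-2 step-up adjusted p values scaled by m0/m, so ``q_i <= q`` reproduces
the rejection decision exactly.

Two-sample t-tests delegate to scipy (pooled-variance Student by default,
Welch on request). Ties in p are resolved by a stable sort on (p, name) so
tabulated outputs are reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import quantify

log = logging.getLogger(__name__)

__all__ = [
    "FdrResult",
    "death_rate",
    "fdr_two_stage_step_up",
    "normalize_viability",
    "t_test_unpaired",
    "volcano",
]


def t_test_unpaired(
    x: np.ndarray, y: np.ndarray, equal_variance: bool = True
) -> tuple[float, float]:
    """Two-sided unpaired t-test: (t statistic, p value).

    ``equal_variance=True`` is the classical pooled-variance Student test;
    ``False`` gives Welch's correction. Each group needs >=2 finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("each group needs >=2 finite replicate values")
    t, p = sps.ttest_ind(x, y, equal_var=equal_variance)
    return float(t), float(p)


def _bh_rejections(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear (BH) step-up at ``level`` on sorted p."""
    m = p_sorted.size
    thresholds = level * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresholds)[0]
    return 0 if passing.size == 0 else int(passing[-1]) + 1


@dataclass
class FdrResult:
    rejected: np.ndarray  # boolean, original order
    q_values: np.ndarray  # adjusted values, original order
    m0: int  # estimated number of true nulls


def fdr_two_stage_step_up(p_values: np.ndarray, q: float = 0.05) -> FdrResult:
    """Adaptive two-stage linear step-up FDR at level ``q`` (see module docs)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult(np.zeros(0, bool), np.zeros(0), 0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("FDR level q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]

    r1 = _bh_rejections(p_sorted, q / (1.0 + q))
    m0 = m - r1
    if m0 == 0:
        rejected = np.ones(m, dtype=bool)
        q_values = np.zeros(m)
        return FdrResult(rejected, q_values, 0)

    level2 = q * m / m0
    r2 = _bh_rejections(p_sorted, level2)
    rejected_sorted = np.zeros(m, dtype=bool)
    rejected_sorted[:r2] = True

    # step-up adjusted values at the stage-2 scaling: q_i = min_{j>=i} m0 p_(j)/j
    ranks = np.arange(1, m + 1)
    adj = np.minimum.accumulate((m0 * p_sorted / ranks)[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)

    rejected = np.zeros(m, dtype=bool)
    q_values = np.zeros(m)
    rejected[order] = rejected_sorted
    q_values[order] = adj
    return FdrResult(rejected, q_values, int(m0))


def volcano(
    amounts: pd.DataFrame,
    annotations: pd.DataFrame,
    contrast: tuple[str, str],
    timepoint: float | None = None,
    value_col: str = "amount_nmol_per_mg",
    fdr_level: float = 0.05,
    equal_variance: bool = True,
    epsilon: float | None = None,
    on_log_scale: bool = True,
) -> pd.DataFrame:
    """Per-species volcano table: log2 fold change, p, q and significance flag.

    Fold changes come from :func:`pufascope.quantify.fold_changes`; p values
    from unpaired two-sided t-tests on per-replicate values; q values from the
    two-stage step-up FDR applied across all species of the panel (pass one
    class/contrast at a time to correct per figure panel).

    ``on_log_scale`` (default) runs the t-tests on log2-transformed amounts:
    MS intensity noise is multiplicative, so the log scale is where the
    t-test's equal-variance assumption holds — the standard volcano-plot
    convention. Zeros are floored at ``epsilon`` (the fold-change floor)
    before the transform. Set False to test raw values.
    """
    treated, vehicle = contrast
    fc = quantify.fold_changes(
        amounts, annotations, contrast, timepoint=timepoint,
        value_col=value_col, epsilon=epsilon,
    )
    t_samples = quantify._group_samples(annotations, treated, timepoint)
    v_samples = quantify._group_samples(annotations, vehicle, timepoint)
    if on_log_scale and epsilon is None:
        positive = amounts.loc[amounts[value_col] > 0, value_col]
        epsilon = float(positive.min()) * 1e-3 if not positive.empty else 1e-12
    rows = []
    for sp in fc["species"]:
        x = amounts.loc[
            (amounts["species"] == sp) & amounts["sample_id"].isin(t_samples), value_col
        ].to_numpy()
        y = amounts.loc[
            (amounts["species"] == sp) & amounts["sample_id"].isin(v_samples), value_col
        ].to_numpy()
        if on_log_scale:
            x = np.log2(np.maximum(x, epsilon))
            y = np.log2(np.maximum(y, epsilon))
        t, p = t_test_unpaired(x, y, equal_variance=equal_variance)
        rows.append({"species": sp, "t": t, "p": p})
    table = fc.merge(pd.DataFrame(rows), on="species")
    # stable (p, species) order fixes tie-breaking bit-for-bit
    table = table.sort_values(["p", "species"], kind="stable", ignore_index=True)
    res = fdr_two_stage_step_up(table["p"].to_numpy(), q=fdr_level)
    table["q"] = res.q_values
    table["significant"] = res.rejected
    return table[["species", "fold_change", "log2fc", "t", "p", "q", "significant"]]


def normalize_viability(readings: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Readings as % of the control mean (controls average to 100% by construction)."""
    controls = np.asarray(controls, dtype=float)
    mean = controls.mean()
    if not mean > 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * np.asarray(readings, dtype=float) / mean


def death_rate(positive_objects: float, confluence_pct: float) -> float:
    """Dead-cell objects per confluence unit; NaN with warning at zero confluence."""
    if confluence_pct <= 0:
        log.warning("confluence is zero; death rate undefined")
        return float("nan")
    return positive_objects / confluence_pct
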