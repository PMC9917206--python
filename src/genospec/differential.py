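"""Four-contrast differential calling with a summed-FDR threshold.

Genes and proteins are tested on log2 values with equal-variance Student's t
across four genotype contrasts:

    1. Z+ vs A+
    2. Z+ vs pooled [Z- & A-]
    3. Z+ vs Z-
    4. Z- vs A-   (specificity contrast)

A feature is called differential when the sum of its Benjamini-Hochberg
q-values over contrasts 1-3 falls below a single threshold, contrast 4 is
non-significant (so the signal is specific to the Z+ group rather than a
transgene-background effect), and the sign of the fold change agrees across
contrasts 1-3.  The summed-q and specificity thresholds are separate config
values because proteomic calls typically need lower stringency than
transcriptomic ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from genospec.matrices import ExpressionMatrix

#: contrast name -> (group A labels, group B labels); order matters: the first
#: three involve Z+ and feed the summed threshold, the fourth is the veto.
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "Z+_vs_A+": (("Z+",), ("A+",)),
    "Z+_vs_Z-A-": (("Z+",), ("Z-", "A-")),
    "Z+_vs_Z-": (("Z+",), ("Z-",)),
    "Z-_vs_A-": (("Z-",), ("A-",)),
}

SUMMED_CONTRASTS = ("Z+_vs_A+", "Z+_vs_Z-A-", "Z+_vs_Z-")
SPECIFICITY_CONTRAST = "Z-_vs_A-"


def _t_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise equal-variance two-sided t-test for 2-D arrays.

    Zero pooled variance with equal means -> (t=0, p=1); with unequal means
    -> (t=+-inf, p=0), the convention for a perfectly separated degenerate
    feature.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    if degenerate.any():
        eq = degenerate & (diff == 0)
        ne = degenerate & (diff != 0)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.sign(diff[ne]) * np.inf
        p[ne] = 0.0
    return t, p


def student_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided equal-variance Student's t; t > 0 when mean(a) > mean(b)."""
    t, p = _t_matrix(np.atleast_2d(group_a), np.atleast_2d(group_b))
    return float(t[0]), float(p[0])


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance alternative, for sensitivity analyses."""
    res = stats.ttest_ind(group_a, group_b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1.

    NaN inputs yield NaN outputs; the remaining values are adjusted as if the
    NaNs were absent.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    valid = ~np.isnan(arr)
    if ((arr[valid] < 0) | (arr[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    if valid.sum():
        q[valid] = multipletests(arr[valid], method="fdr_bh")[1]
    return q


def run_contrasts(expr: ExpressionMatrix, welch: bool = False) -> pd.DataFrame:
    """Per-feature t/p/q and log2 fold change for each of the four contrasts.

    Expects log2-scale values (unit tag ``log2rpkm`` or ``log2intensity``).
    q-values are adjusted within each contrast across all features.  Columns
    are ``{t,p,q,lfc}_<contrast>``.
    """
    if expr.unit == "rpkm":
        raise ValueError("run_contrasts expects log2-scale values; call log_transform first")
    if expr.genotypes is None:
        raise ValueError("expression matrix carries no genotype labels")
    active = expr.values.columns[~expr.outlier.to_numpy()]
    vals = expr.values[active]
    genos = expr.genotypes.reindex(active)

    cols_of: dict[str, list[str]] = {}
    for g in ("Z+", "Z-", "A+", "A-"):
        cols = [s for s in active if genos[s] == g]
        if len(cols) < 2:
            raise ValueError(f"genotype {g} has {len(cols)} usable sample(s); need >= 2")
        cols_of[g] = cols

    out = pd.DataFrame(index=vals.index)
    for name, (ga, gb) in CONTRASTS.items():
        a = vals[[c for g in ga for c in cols_of[g]]].to_numpy()
        b = vals[[c for g in gb for c in cols_of[g]]].to_numpy()
        if welch:
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
            t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        else:
            t, p = _t_matrix(a, b)
        out[f"t_{name}"] = t
        out[f"p_{name}"] = p
        out[f"q_{name}"] = bh_adjust(p)
        out[f"lfc_{name}"] = a.mean(axis=1) - b.mean(axis=1)
    return out


@dataclass(frozen=True)
class DifferentialCall:
    feature: str
    direction: str | None  # "up" | "down" | None
    summed_q: float
    specificity_q: float
    is_deg: bool


def call_degs(
    contrast_table: pd.DataFrame,
    summed_q_threshold: float = 0.15,
    specificity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the summed-FDR + specificity + direction-consistency rule.

    is_deg  <=>  q1+q2+q3 <= summed_q_threshold
             AND q4 > specificity_alpha
             AND sign(lfc) identical (and non-zero) across contrasts 1-3.

    Returns a frame indexed by feature with ``summed_q``, ``specificity_q``,
    ``direction`` and ``is_deg`` columns.
    """
    if not (0 < summed_q_threshold <= 3):
        raise ValueError("summed_q_threshold must lie in (0, 3]")
    if not (0 < specificity_alpha <= 1):
        raise ValueError("specificity_alpha must lie in (0, 1]")
    qs = np.column_stack([contrast_table[f"q_{c}"].to_numpy() for c in SUMMED_CONTRASTS])
    lfcs = np.column_stack([contrast_table[f"lfc_{c}"].to_numpy() for c in SUMMED_CONTRASTS])
    summed = qs.sum(axis=1)
    q4 = contrast_table[f"q_{SPECIFICITY_CONTRAST}"].to_numpy()

    signs = np.sign(lfcs)
    all_up = (signs > 0).all(axis=1)
    all_down = (signs < 0).all(axis=1)
    consistent = all_up | all_down
    is_deg = (summed <= summed_q_threshold) & (q4 > specificity_alpha) & consistent

    direction = np.where(all_up, "up", np.where(all_down, "down", None))
    return pd.DataFrame(
        {
            "summed_q": summed,
            "specificity_q": q4,
            "direction": direction,
            "is_deg": is_deg,
            "lfc_Z+_vs_A+": contrast_table["lfc_Z+_vs_A+"].to_numpy(),
        },
        index=contrast_table.index,
    )


def write_results_tsv(contrast_table: pd.DataFrame, calls: pd.DataFrame, path) -> None:
    """Full per-feature results: per-contrast statistics plus the call columns."""
    merged = contrast_table.join(calls[["summed_q", "specificity_q", "direction", "is_deg"]])
    merged.to_csv(path, sep="\t", index_label="feature_id")
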