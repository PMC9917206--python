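"""qPCR quantification and RNA-seq cross-validation.

Relative expression follows the comparative-Ct convention with a panel of
housekeeping genes:

    dCt      = mean Ct(target) - geometric mean of per-housekeeping mean Cts
    rel_expr = 2^(-dCt) * 10,000

Group-level log2 fold changes derived from relative expression are compared
to RNA-seq fold changes by Spearman rank correlation (exact permutation p for
n <= 8, t approximation otherwise).
"""

from __future__ import annotations

from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REL_EXPR_SCALE = 10_000.0


def relative_expression(
    target_cts: Sequence[float],
    housekeeping_cts: Sequence[Sequence[float]],
    housekeeping_mean: str = "geometric",
) -> tuple[float, float]:
    """(dCt, relative expression) for one target in one sample.

    ``housekeeping_cts`` holds one Ct vector per housekeeping gene; each is
    averaged first and the per-gene means are combined by geometric mean
    (arithmetic available via ``housekeeping_mean="arithmetic"``).
    """
    target = np.asarray(target_cts, dtype=float)
    if target.size == 0 or not np.isfinite(target).all():
        raise ValueError("target Ct values must be finite and non-empty")
    if not housekeeping_cts:
        raise ValueError("at least one housekeeping gene is required")
    hk_means = []
    for cts in housekeeping_cts:
        arr = np.asarray(cts, dtype=float)
        if arr.size == 0 or not np.isfinite(arr).all():
            raise ValueError("housekeeping Ct values must be finite and non-empty")
        hk_means.append(arr.mean())
    if housekeeping_mean == "geometric":
        hk = float(stats.gmean(hk_means))
    elif housekeeping_mean == "arithmetic":
        hk = float(np.mean(hk_means))
    else:
        raise ValueError(f"unknown housekeeping_mean {housekeeping_mean!r}")
    delta_ct = float(target.mean()) - hk
    return delta_ct, float(2.0 ** (-delta_ct) * REL_EXPR_SCALE)


def qpcr_log2fc(
    rel_by_group: Mapping[str, Sequence[float]], group_a: str, group_b: str
) -> float:
    """log2 of the ratio of group-mean relative expression, a over b."""
    a = np.asarray(rel_by_group[group_a], dtype=float)
    b = np.asarray(rel_by_group[group_b], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need >= 1 value")
    mb = b.mean()
    if mb == 0:
        raise ValueError("zero mean relative expression in the denominator group")
    return float(np.log2(a.mean() / mb))


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n).

    Enumerates all n! rank permutations; ties in the observed data are not
    re-broken, so this is exact for tie-free data and a close approximation
    otherwise.
    """
    base = np.arange(1, n + 1, dtype=float)
    target = abs(rho) - 1e-12
    hits = total = 0
    for perm in permutations(base):
        r = stats.pearsonr(base, np.asarray(perm)).statistic
        total += 1
        if abs(r) >= target:
            hits += 1
    return hits / total


def validate_against_rnaseq(
    qpcr_lfcs: Mapping[str, float], rnaseq_lfcs: Mapping[str, float]
) -> tuple[float, float, pd.DataFrame]:
    """Spearman rank correlation between qPCR and RNA-seq log2 fold changes.

    Computed over genes present in both inputs (>= 3 required; average ranks
    for ties).  Returns (rho, p, paired table).
    """
    genes = sorted(set(qpcr_lfcs) & set(rnaseq_lfcs))
    if len(genes) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(genes)}")
    q = np.array([qpcr_lfcs[g] for g in genes], dtype=float)
    r = np.array([rnaseq_lfcs[g] for g in genes], dtype=float)
    res = stats.spearmanr(q, r)
    rho = float(res.statistic)
    n = len(genes)
    p = _exact_spearman_p(rho, n) if n <= 8 else float(res.pvalue)
    table = pd.DataFrame({"gene_id": genes, "qpcr_log2fc": q, "rnaseq_log2fc": r})
    return rho, p, table


# ---------------------------------------------------------------------------
# Long-format qPCR tables (gene, sample, genotype, ct, is_housekeeping)

QPCR_COLUMNS = ("gene_id", "sample_id", "genotype", "ct", "is_housekeeping")


def read_qpcr_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df


def write_qpcr_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def qpcr_fold_changes(
    table: pd.DataFrame, group_a: str = "Z+", group_b: str = "A+"
) -> dict[str, float]:
    """Per-gene log2 fold change (group_a vs group_b) from a long qPCR table.

    For every sample, each target gene's Ct replicates are reduced against
    that sample's housekeeping panel to a relative-expression value; fold
    changes then compare genotype means.
    """
    hk = table[table["is_housekeeping"].astype(bool)]
    targets = table[~table["is_housekeeping"].astype(bool)]
    rel: dict[str, dict[str, list[float]]] = {}
    for (gene, sample), grp in targets.groupby(["gene_id", "sample_id"]):
        hk_here = hk[hk["sample_id"] == sample]
        if hk_here.empty:
            raise ValueError(f"sample {sample} has no housekeeping Ct values")
        hk_vectors = [g["ct"].to_list() for _, g in hk_here.groupby("gene_id")]
        _, r = relative_expression(grp["ct"].to_list(), hk_vectors)
        geno = grp["genotype"].iloc[0]
        rel.setdefault(gene, {}).setdefault(geno, []).append(r)
    return {
        gene: qpcr_log2fc(groups, group_a, group_b)
        for gene, groups in rel.items()
        if group_a in groups and group_b in groups
    }
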