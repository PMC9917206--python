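"""Transcript-protein matching, pooled correlation, and DEG/DEP intersection.

Protein quantification covers far fewer features than RNA-seq, and the two
layers correlate only weakly; these helpers quantify the overlap, compute the
pooled Pearson correlation over all (gene, sample) points, and intersect
differential lists across the two layers through an id map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from genospec.matrices import ExpressionMatrix


@dataclass
class MatchedPairs:
    """Aligned transcript/protein values for matched features over shared samples.

    ``transcript`` and ``protein`` are frames of identical shape: one row per
    matched (gene, protein) pair, one column per shared sample, both on a log2
    scale.  ``overlap`` is matched proteins / total proteins (NaN when the
    protein matrix is empty).
    """

    transcript: pd.DataFrame
    protein: pd.DataFrame
    pairs: pd.DataFrame  # columns: gene_id, protein_id
    overlap: float


def match_features(
    expr: ExpressionMatrix,
    protein_log2: pd.DataFrame,
    protein_to_gene: Mapping[str, str],
) -> MatchedPairs:
    """Match protein rows to transcript rows via ``protein_to_gene``.

    Both inputs must be on a log2 scale; rows of ``protein_log2`` whose mapped
    gene is absent from ``expr`` are counted as unmatched.  Restricted to the
    samples the two matrices share (error when none).
    """
    if expr.unit == "rpkm":
        raise ValueError("transcript matrix must be log2-scale")
    shared = [s for s in expr.values.columns if s in protein_log2.columns]
    if protein_log2.shape[0] and not shared:
        raise ValueError("no shared samples between transcript and protein matrices")

    rows = []
    for pid in protein_log2.index:
        gid = protein_to_gene.get(pid)
        if gid is not None and gid in expr.values.index:
            rows.append((gid, pid))
    n_prot = protein_log2.shape[0]
    overlap = (len(rows) / n_prot) if n_prot else float("nan")
    pairs = pd.DataFrame(rows, columns=["gene_id", "protein_id"])
    t = expr.values.loc[pairs["gene_id"], shared].reset_index(drop=True) if len(rows) else pd.DataFrame(columns=shared)
    p = protein_log2.loc[pairs["protein_id"], shared].reset_index(drop=True) if len(rows) else pd.DataFrame(columns=shared)
    return MatchedPairs(transcript=t, protein=p, pairs=pairs, overlap=overlap)


def correlate_omics(
    pairs: MatchedPairs, method: str = "pearson", per_gene: bool = False
) -> tuple[float, float, int]:
    """Correlation between transcript and protein levels.

    Default pools every (gene, sample) point into a single Pearson
    correlation; ``per_gene=True`` instead correlates within each gene across
    samples and returns the mean r (p is NaN in that mode).
    """
    if method != "pearson":
        raise ValueError("only Pearson correlation is supported")
    x = pairs.transcript.to_numpy(dtype=float).ravel()
    y = pairs.protein.to_numpy(dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if per_gene:
        rs = []
        for i in range(pairs.transcript.shape[0]):
            xi = pairs.transcript.iloc[i].to_numpy(dtype=float)
            yi = pairs.protein.iloc[i].to_numpy(dtype=float)
            if np.std(xi) > 0 and np.std(yi) > 0:
                rs.append(stats.pearsonr(xi, yi).statistic)
        return float(np.mean(rs)), float("nan"), len(rs)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance on one axis")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)


def intersect_calls(
    degs: Iterable[str],
    deps: Iterable[str],
    dep_to_gene: Mapping[str, str] | None = None,
) -> dict:
    """Intersect DEG and DEP lists in gene-id space.

    ``dep_to_gene`` maps protein ids to gene ids (identity when omitted).  A
    protein whose mapped gene is a DEG counts as shared, so paralogs that
    collapse onto one gene can each match it.
    """
    deg_set = set(degs)
    dep_genes = {dep_to_gene.get(d, d) if dep_to_gene else d for d in deps}
    shared = sorted(deg_set & dep_genes)
    union = deg_set | dep_genes
    return {
        "shared_ids": shared,
        "n_shared": len(shared),
        "n_degs": len(deg_set),
        "n_deps": len(dep_genes),
        "jaccard": (len(shared) / len(union)) if union else 0.0,
    }


def write_correlation_json(r: float, p: float, n: int, path) -> None:
    with open(path, "w") as fh:
        json.dump({"r": r, "p": p, "n": n}, fh, sort_keys=True, indent=2)
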