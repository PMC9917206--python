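"""Expression-matrix assembly: consolidation, filtering, RPKM, outlier screening.

Counts are held feature x sample in a :class:`CountMatrix` together with the
per-sample genotype label and an outlier flag.  Normalised values live in an
:class:`ExpressionMatrix` whose unit tag records whether values are RPKM or
log2(RPKM + pseudocount); operations check the tag so a matrix cannot be
log-transformed twice by accident.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPES = ("Z+", "Z-", "A+", "A-")


@dataclass
class CountMatrix:
    """Integer read counts (features x samples) with sample genotype labels.

    Parameters
    ----------
    counts
        Non-negative integer counts, index = feature ids, columns = sample ids.
    genotypes
        Sample id -> genotype label, one of ``Z+``, ``Z-``, ``A+``, ``A-``.
    outlier
        Sample id -> bool; flagged samples are excluded from downstream
        statistics but kept in the matrix for provenance.
    """

    counts: pd.DataFrame
    genotypes: pd.Series
    outlier: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.outlier is None:
            self.outlier = pd.Series(False, index=self.counts.columns)
        missing = [s for s in self.counts.columns if s not in self.genotypes.index]
        if missing:
            raise ValueError(f"samples without genotype label: {missing[:5]}")
        self.genotypes = self.genotypes.reindex(self.counts.columns)
        self.outlier = self.outlier.reindex(self.counts.columns).fillna(False).astype(bool)
        bad = set(self.genotypes.unique()) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def active_samples(self) -> pd.Index:
        """Sample ids not flagged as outliers."""
        return self.counts.columns[~self.outlier.to_numpy()]

    def samples_of(self, genotype: str, include_outliers: bool = False) -> pd.Index:
        mask = self.genotypes == genotype
        if not include_outliers:
            mask &= ~self.outlier
        return self.counts.columns[mask.to_numpy()]

    def library_sizes(self) -> pd.Series:
        """Per-sample totals of feature-assigned reads."""
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Real-valued expression (genes x samples) with a unit tag."""

    values: pd.DataFrame
    unit: str  # "rpkm" | "log2rpkm" | "log2intensity"
    genotypes: pd.Series = field(default=None)  # type: ignore[assignment]
    outlier: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unit not in ("rpkm", "log2rpkm", "log2intensity"):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if self.unit == "rpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("rpkm values must be non-negative")
        cols = self.values.columns
        if self.genotypes is not None:
            self.genotypes = self.genotypes.reindex(cols)
        if self.outlier is None:
            self.outlier = pd.Series(False, index=cols)
        else:
            self.outlier = self.outlier.reindex(cols).fillna(False).astype(bool)


def consolidate_features(
    transcript_counts: CountMatrix, feature_to_gene: Mapping[str, str]
) -> CountMatrix:
    """Sum transcript-level counts into gene-level counts.

    Every feature id must be covered by ``feature_to_gene``; unmapped ids
    raise with the offending names so upstream annotation gaps surface
    immediately rather than as silently dropped counts.
    """
    unmapped = [f for f in transcript_counts.feature_ids if f not in feature_to_gene]
    if unmapped:
        raise KeyError(
            f"{len(unmapped)} feature id(s) missing from the feature->gene map, "
            f"e.g. {unmapped[:10]}"
        )
    genes = transcript_counts.counts.index.map(feature_to_gene.__getitem__)
    consolidated = transcript_counts.counts.groupby(genes, sort=True).sum()
    consolidated.index.name = transcript_counts.counts.index.name
    return CountMatrix(
        counts=consolidated,
        genotypes=transcript_counts.genotypes.copy(),
        outlier=transcript_counts.outlier.copy(),
    )


def filter_low_expression(
    counts: CountMatrix, min_count: int = 100, min_samples: int = 3, strict: bool = True
) -> CountMatrix:
    """Keep genes whose raw count exceeds ``min_count`` in >= ``min_samples`` samples.

    The comparison is strict (``count > min_count``) by default; outlier-flagged
    samples do not contribute to the tally.  Row order is preserved.
    """
    if min_count < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    active = counts.active_samples()
    if min_samples > len(active):
        raise ValueError(
            f"min_samples={min_samples} exceeds the {len(active)} non-outlier samples"
        )
    sub = counts.counts[active]
    hits = (sub > min_count) if strict else (sub >= min_count)
    keep = hits.sum(axis=1) >= min_samples
    return CountMatrix(
        counts=counts.counts.loc[keep],
        genotypes=counts.genotypes.copy(),
        outlier=counts.outlier.copy(),
    )


def rpkm(
    counts: CountMatrix,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    value = count / (length/1000) / (library_size/1e6).

    ``library_sizes`` should be the column sums of the *pre-filter*
    consolidated matrix so that normalisation does not depend on the
    low-expression filter; when omitted they are taken from ``counts`` itself.
    """
    missing = counts.feature_ids.difference(lengths.index)
    if len(missing):
        raise KeyError(f"genes without length: {missing[:10].tolist()}")
    lens = lengths.reindex(counts.feature_ids).astype(float)
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.library_sizes()
    libs = library_sizes.reindex(counts.sample_ids).astype(float)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    vals = counts.counts.div(lens / 1e3, axis=0).div(libs / 1e6, axis=1)
    return ExpressionMatrix(
        values=vals,
        unit="rpkm",
        genotypes=counts.genotypes.copy(),
        outlier=counts.outlier.copy(),
    )


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); requires an ``rpkm`` matrix."""
    if m.unit != "rpkm":
        raise ValueError(f"log_transform expects unit 'rpkm', got {m.unit!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    return ExpressionMatrix(
        values=np.log2(m.values + pseudocount),
        unit="log2rpkm",
        genotypes=m.genotypes,
        outlier=m.outlier,
    )


def screen_outliers(
    counts: CountMatrix,
    method: str = "library_size_mad",
    k: float = 3.0,
    min_correlation: float = 0.5,
    min_deviation: float = 0.1,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Flag aberrant samples within each genotype group.

    ``library_size_mad`` flags samples whose log10 library size deviates from
    the genotype median by more than ``k`` median absolute deviations AND by
    more than ``min_deviation`` log10 units (~26%); the absolute floor keeps
    near-identical groups, where the MAD is minuscule, from flagging ordinary
    sampling noise.
    ``correlation`` flags samples whose median Spearman correlation with the
    other samples of the genotype falls below ``min_correlation``.

    Returns a new matrix with updated outlier flags plus a per-sample report.
    Raises if flagging would leave any genotype with fewer than two samples.
    """
    if method not in ("library_size_mad", "correlation"):
        raise ValueError(f"unknown method {method!r}")
    for g in GENOTYPES:
        if (counts.genotypes == g).sum() and (counts.genotypes == g).sum() < 3:
            raise ValueError(f"genotype {g} has < 3 samples; screening unreliable")

    flags = counts.outlier.copy()
    rows = []
    for g in counts.genotypes.unique():
        samples = counts.counts.columns[(counts.genotypes == g).to_numpy()]
        if method == "library_size_mad":
            lib = np.log10(counts.counts[samples].sum(axis=0).astype(float) + 1.0)
            med = float(lib.median())
            mad = float((lib - med).abs().median())
            for s in samples:
                dev = abs(float(lib[s]) - med)
                if mad > 0:
                    score = dev / mad
                    flag = score > k and dev > min_deviation
                else:
                    # All-but-identical group: any non-zero deviation is infinitely
                    # many MADs away; k = inf still flags nothing.
                    score = math.inf if dev > min_deviation else 0.0
                    flag = dev > min_deviation and math.isfinite(k)
                rows.append({"sample": s, "genotype": g, "statistic": score, "flagged": flag})
                if flag:
                    flags[s] = True
        else:
            sub = counts.counts[samples].astype(float)
            rho = sub.corr(method="spearman")
            for s in samples:
                others = [c for c in samples if c != s]
                score = float(rho.loc[s, others].median()) if others else 1.0
                flag = score < min_correlation
                rows.append({"sample": s, "genotype": g, "statistic": score, "flagged": flag})
                if flag:
                    flags[s] = True

    report = pd.DataFrame(rows).set_index("sample")
    for g in counts.genotypes.unique():
        left = ((counts.genotypes == g) & ~flags).sum()
        if left < 2:
            raise ValueError(
                f"outlier screen would leave genotype {g} with {left} sample(s)"
            )
    return (
        CountMatrix(counts=counts.counts.copy(), genotypes=counts.genotypes.copy(), outlier=flags),
        report,
    )


# ---------------------------------------------------------------------------
# TSV readers / writers


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_metadata_tsv(cm: CountMatrix, path) -> None:
    meta = pd.DataFrame(
        {"genotype": cm.genotypes, "outlier": cm.outlier.astype(int)}
    )
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path) -> tuple[pd.Series, pd.Series]:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    genotypes = meta["genotype"]
    if "outlier" in meta.columns:
        outlier = meta["outlier"].astype(bool)
    else:
        outlier = pd.Series(False, index=meta.index)
    return genotypes, outlier


def read_counts_tsv(matrix_path, metadata_path) -> CountMatrix:
    df = read_matrix_tsv(matrix_path)
    genotypes, outlier = read_metadata_tsv(metadata_path)
    return CountMatrix(counts=df, genotypes=genotypes, outlier=outlier)


def write_lengths_tsv(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


def read_lengths_tsv(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["length_bp"]
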