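"""Frequency-ratio over-representation of annotation terms.

Differential genes are translated to the annotation id space through an
ortholog map (paralogs collapsing onto one target gene are de-duplicated),
then each term is scored by

    score = (k/n) / (K/N)

where k = differential genes annotated to the term, n = mapped differential
genes, K = background genes annotated to the term, and N = the background
universe (all genes annotated in the category's database).  A score of 1
means the term occurs among differential genes at the background frequency;
score > 1 marks the term as over-represented.  No significance test is part
of the rule; an upper-tail hypergeometric p-value is available as an optional
extra column only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


@dataclass
class AnnotationDB:
    """Named term -> gene-id sets for one annotation category (GO-BP-like or KEGG-like)."""

    category: str
    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid} has an empty gene set")
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}

    @property
    def background(self) -> frozenset[str]:
        """All genes annotated anywhere in this category."""
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, category: str = "GO_BP") -> AnnotationDB:
    """Read a GMT file: term <tab> description <tab> gene ids..."""
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            terms[parts[0]] = frozenset(g for g in parts[2:] if g)
            names[parts[0]] = parts[1]
    return AnnotationDB(category=category, terms=terms, names=names)


def write_gmt(db: AnnotationDB, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(db.terms):
            genes = "\t".join(sorted(db.terms[tid]))
            fh.write(f"{tid}\t{db.names.get(tid, tid)}\t{genes}\n")


def percent(k: int, n: int, decimals: int = 1) -> float:
    """100*k/n rounded half-up to ``decimals`` places, computed exactly."""
    if n == 0:
        return float("nan")
    scale = 10 ** decimals
    x = Fraction(100 * scale * k, n)
    rounded = (x + Fraction(1, 2)).__floor__()
    return rounded / scale


def map_orthologs(
    ids: Iterable[str], ortholog_map: Mapping[str, str] | None
) -> dict[str, str]:
    """source id -> target id for ids present in the map (identity when map is None)."""
    if ortholog_map is None:
        return {i: i for i in ids}
    return {i: ortholog_map[i] for i in ids if i in ortholog_map}


def map_to_annotations(
    diff_ids: Iterable[str],
    ortholog_map: Mapping[str, str] | None,
    db: AnnotationDB,
) -> tuple[set[str], set[str], float]:
    """Map differential ids through orthologs into the annotation space.

    Returns ``(mapped_source_ids, mapped_target_ids, mapping_rate)`` where a
    source id is mapped when its ortholog image is annotated to at least one
    term, and mapping_rate = 100 * mapped / total as a percentage rounded
    half-up to one decimal (NaN for an empty list).
    """
    diff = list(dict.fromkeys(diff_ids))
    bg = db.background
    images = map_orthologs(diff, ortholog_map)
    mapped_source = {i for i, tgt in images.items() if tgt in bg}
    mapped_target = {images[i] for i in mapped_source}
    return mapped_source, mapped_target, percent(len(mapped_source), len(diff))


def enrichment_score(k: int, n: int, K: int, N: int) -> float:
    """Frequency ratio (k/n)/(K/N); 1 = background frequency, 0 iff k = 0."""
    if n <= 0 or K <= 0:
        raise ValueError("n and K must be positive")
    if N < K or N < n:
        raise ValueError("background N must be >= both K and n")
    if not (0 <= k <= min(n, K)):
        raise ValueError("k must satisfy 0 <= k <= min(n, K)")
    return (k / n) / (K / N)


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of drawing k term genes
    among n differential genes from a universe of N with K in the term."""
    if n <= 0 or K <= 0 or N < K or N < n or not (0 <= k <= min(n, K)):
        raise ValueError("inconsistent hypergeometric parameters")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    score: float
    direction: str  # "all_up" | "all_down" | "mixed"
    over_represented: bool
    members: tuple[str, ...]  # differential genes in the term (target id space)
    p: float | None = None


def score_all_terms(
    diff_directions: Mapping[str, str],
    db: AnnotationDB,
    ortholog_map: Mapping[str, str] | None = None,
    with_p: bool = False,
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Score every term containing at least one mapped differential gene.

    ``diff_directions`` maps each differential source gene id to "up" or
    "down".  Paralogs merging onto one target gene are de-duplicated before k
    and n are computed; a target gene reached by both an up- and a
    down-regulated source is treated as direction-conflicting and renders its
    terms ``mixed``.  The background defaults to all genes annotated in the
    category; pass ``background`` (e.g. all expressed genes mapped into the
    annotation space) to override.
    """
    bg = frozenset(background) if background is not None else db.background
    N = len(bg)
    images = map_orthologs(diff_directions.keys(), ortholog_map)

    target_dir: dict[str, str] = {}
    for src, tgt in images.items():
        if tgt not in bg:
            continue
        d = diff_directions[src]
        if tgt in target_dir and target_dir[tgt] != d:
            target_dir[tgt] = "conflict"
        else:
            target_dir.setdefault(tgt, d)
    n = len(target_dir)
    results: list[EnrichmentResult] = []
    if n == 0:
        return results

    for tid in sorted(db.terms):
        term_genes = db.terms[tid] & bg
        members = sorted(set(target_dir) & term_genes)
        k = len(members)
        if k == 0:
            continue
        K = len(term_genes)
        score = enrichment_score(k, n, K, N)
        dirs = {target_dir[g] for g in members}
        if dirs == {"up"}:
            direction = "all_up"
        elif dirs == {"down"}:
            direction = "all_down"
        else:
            direction = "mixed"
        results.append(
            EnrichmentResult(
                term_id=tid,
                term_name=db.names.get(tid, tid),
                k=k,
                n=n,
                K=K,
                N=N,
                score=score,
                direction=direction,
                over_represented=score > 1,
                members=tuple(members),
                p=hypergeom_p(k, n, K, N) if with_p else None,
            )
        )
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "score": r.score,
            "direction": r.direction,
            "over_represented": r.over_represented,
            "members": ",".join(r.members),
        }
        if r.p is not None:
            row["p_hypergeom"] = r.p
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_tsv(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
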