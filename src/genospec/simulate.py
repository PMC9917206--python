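"""Synthetic paired transcriptome/proteome data with planted effects.

The generator emulates the statistical structure the pipeline assumes: four
genotype groups (Z+, Z-, A+, A-) of ~6 samples each, negative-binomial
gene counts with log-normal baseline means, a planted gene set suppressed
2-7-fold in the Z+ group only plus a planted up-regulated set, a protein
layer weakly coupled to the transcript layer (target pooled Pearson r ~ 0.22),
GMT-style annotation databases with planted single-direction terms, a
many-to-one ortholog map, and a qPCR table whose 2^-dCt fold changes track
the planted truth up to Gaussian Ct noise.  Every artefact derives from one
integer seed through named child generators, so outputs are bit-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from genospec.matrices import CountMatrix

GENOTYPES = ("Z+", "Z-", "A+", "A-")

# named child streams carved out of the master seed
_STREAMS = ("baseline", "counts", "proteome", "annotations", "orthologs", "qpcr", "lengths", "outliers", "plant")


def _rng(seed: int, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_STREAMS))[idx])


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


@dataclass
class SimulationConfig:
    """Conditions for one synthetic study.

    ``planted_down`` / ``planted_up`` map gene ids to multiplicative fold
    changes (> 1) applied to the negative-binomial mean in Z+ samples only
    (division for the down set, multiplication for the up set).
    """

    seed: int = 0
    n_genes: int = 6000
    n_proteins: int = 4000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g: 6 for g in GENOTYPES}
    )
    planted_down: dict[str, float] = field(default_factory=dict)
    planted_up: dict[str, float] = field(default_factory=dict)
    planted_protein_down: dict[str, float] = field(default_factory=dict)
    planted_protein_up: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.05
    target_crossomics_r: float = 0.22
    protein_noise_sd: float = 0.3
    protein_log_offset: float = 40.0
    n_terms: dict[str, int] = field(default_factory=lambda: {"GO_BP": 250, "KEGG": 120})
    term_size_range: tuple[int, int] = (5, 50)
    planted_term_fraction: float = 0.8
    n_outliers: int = 0
    baseline_log_mean: float = 5.5
    baseline_log_sigma: float = 1.5
    qpcr_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if set(self.group_sizes) != set(GENOTYPES):
            raise ValueError(f"group_sizes must cover exactly {GENOTYPES}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every genotype group needs >= 2 samples")
        sets = [
            set(self.planted_down),
            set(self.planted_up),
            set(self.planted_protein_down),
            set(self.planted_protein_up),
        ]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"planted sets overlap: {sorted(overlap)[:5]}")
        ids = set(gene_ids(self.n_genes))
        stray = set().union(*sets) - ids
        if stray:
            raise ValueError(f"planted gene ids outside the universe: {sorted(stray)[:5]}")
        for d in (self.planted_down, self.planted_up, self.planted_protein_down, self.planted_protein_up):
            for fold in d.values():
                if not fold > 1:
                    raise ValueError("planted fold changes must be strictly > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (-1 < self.target_crossomics_r < 1):
            raise ValueError("target_crossomics_r must lie in (-1, 1)")
        lo, hi = self.term_size_range
        if lo < 2 or hi > self.n_genes or lo > hi:
            raise ValueError("term_size_range must lie within [2, n_genes]")


@dataclass
class GroundTruth:
    """What was planted: recovered by the pipeline, asserted by tests."""

    true_deg: dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down"
    true_dep: dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down" (protein layer)
    true_lfc: dict[str, float] = field(default_factory=dict)  # gene -> log2 fold Z+ vs A+
    true_enriched_terms: dict[str, list[str]] = field(default_factory=dict)
    true_crossomics_r: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, sort_keys=True, indent=2)


def baseline_means(config: SimulationConfig) -> pd.Series:
    """Seed-deterministic per-gene baseline NB means (log-normal)."""
    rng = _rng(config.seed, "baseline")
    means = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, config.n_genes)
    return pd.Series(means, index=gene_ids(config.n_genes))


def default_config(
    seed: int = 0,
    n_genes: int = 6000,
    n_planted_down: int = 100,
    n_planted_up: int = 100,
    n_planted_protein_down: int = 40,
    n_planted_protein_up: int = 40,
    min_planted_baseline: float = 200.0,
    **kwargs,
) -> SimulationConfig:
    """Study-default conditions with planted genes drawn among well-expressed ones.

    Planted genes are sampled from genes whose baseline mean clears
    ``min_planted_baseline`` so that a planted effect is not erased by the
    low-expression filter, mirroring the well-expressed pathway genes such a
    study validates.  Fold changes are uniform on [2, 7].  Protein-level
    effects are planted on genes disjoint from the transcript-planted sets,
    emulating post-transcriptional regulation (the DEG and DEP lists do not
    overlap).
    """
    probe = SimulationConfig(seed=seed, n_genes=n_genes, **kwargs)
    means = baseline_means(probe)
    eligible = means.index[means >= min_planted_baseline].to_numpy()
    n_plant = n_planted_down + n_planted_up + n_planted_protein_down + n_planted_protein_up
    if len(eligible) < n_plant:
        raise ValueError("not enough well-expressed genes to plant effects in")
    rng = _rng(seed, "plant")
    chosen = rng.choice(eligible, size=n_plant, replace=False)
    folds = rng.uniform(2.0, 7.0, size=n_plant)
    splits = np.cumsum([n_planted_down, n_planted_up, n_planted_protein_down])
    blocks = np.split(np.arange(n_plant), splits)
    pick = lambda idx: {chosen[i]: float(folds[i]) for i in idx}
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        planted_down=pick(blocks[0]),
        planted_up=pick(blocks[1]),
        planted_protein_down=pick(blocks[2]),
        planted_protein_up=pick(blocks[3]),
        **kwargs,
    )


def null_config(seed: int = 0, n_genes: int = 6000, **kwargs) -> SimulationConfig:
    """No planted effects: all four group means identical for every gene."""
    return SimulationConfig(seed=seed, n_genes=n_genes, **kwargs)


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts with planted Z+-only effects.

    Counts are NB with mean m and variance m + dispersion * m^2; planted
    fold changes divide (down) or multiply (up) the mean in Z+ columns only.
    """
    means = baseline_means(config).to_numpy()
    genes = gene_ids(config.n_genes)
    samples: list[str] = []
    genotypes: list[str] = []
    for g in GENOTYPES:
        for i in range(config.group_sizes[g]):
            samples.append(f"{g}_{i + 1}")
            genotypes.append(g)
    mean_matrix = np.tile(means[:, None], (1, len(samples)))
    zplus = [j for j, g in enumerate(genotypes) if g == "Z+"]
    idx = {g: i for i, g in enumerate(genes)}
    for g, fold in config.planted_down.items():
        mean_matrix[idx[g], zplus] /= fold
    for g, fold in config.planted_up.items():
        mean_matrix[idx[g], zplus] *= fold

    rng = _rng(config.seed, "counts")
    r = 1.0 / config.dispersion
    p = r / (r + mean_matrix)
    counts = rng.negative_binomial(r, p)

    if config.n_outliers:
        out_rng = _rng(config.seed, "outliers")
        cols = out_rng.choice(len(samples), size=config.n_outliers, replace=False)
        for c in cols:
            # aberrant library: ~10% of the usual depth
            counts[:, c] = out_rng.binomial(counts[:, c], 0.1)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        genotypes=pd.Series(genotypes, index=samples),
    )
    truth = GroundTruth(
        true_deg={**{g: "down" for g in config.planted_down}, **{g: "up" for g in config.planted_up}},
        true_lfc={
            **{g: -float(np.log2(f)) for g, f in config.planted_down.items()},
            **{g: float(np.log2(f)) for g, f in config.planted_up.items()},
        },
    )
    return cm, truth


def generate_gene_lengths(config: SimulationConfig) -> pd.Series:
    rng = _rng(config.seed, "lengths")
    lengths = rng.integers(300, 15_000, config.n_genes)
    return pd.Series(lengths, index=gene_ids(config.n_genes), name="length_bp")


def generate_proteome(
    counts: CountMatrix,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    lengths: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Protein intensities weakly coupled to transcript abundance.

    The model is linear in log space with two noise components:

        log2 intensity = a * x_gs + b_g + eps_gs + offset

    where ``x_gs`` is the transcript signal (log2(RPKM + 1) when ``lengths``
    are supplied, log2(count + 1) otherwise), ``b_g`` is a gene-level
    decoupling offset (translation efficiency, turnover) and ``eps_gs`` is
    small per-sample measurement noise (sd ``protein_noise_sd``).  The
    variance of ``b_g`` is solved against the pooled spread of ``x`` so the
    population (gene, sample)-pooled Pearson correlation equals
    ``target_crossomics_r``; a = sign of the target, a = 0 for target 0
    (fully independent intensities).  Most cross-omics decoupling therefore
    sits between genes, while within a gene intensities track transcripts --
    which is what lets protein-specific planted effects remain detectable.

    Proteins are drawn from genes clearing the low-expression filter
    (abundant proteins are the ones detected), excluding transcript-planted
    genes, and always including the protein-planted genes, whose fold changes
    multiply the intensity in Z+ samples only.
    """
    if counts.counts.empty:
        raise ValueError("count matrix is empty")
    r_target = config.target_crossomics_r
    if not (-1 < r_target < 1):
        raise ValueError("target_crossomics_r must lie in (-1, 1)")
    rng = _rng(config.seed, "proteome")

    detected = counts.counts.index[(counts.counts > 100).sum(axis=1) >= 3]
    transcript_planted = set(config.planted_down) | set(config.planted_up)
    protein_planted = list(config.planted_protein_down) + list(config.planted_protein_up)
    pool = detected.difference(transcript_planted).difference(protein_planted).to_numpy()
    n_fill = min(config.n_proteins - len(protein_planted), len(pool))
    chosen = np.concatenate(
        [np.array(protein_planted, dtype=object), rng.choice(pool, size=n_fill, replace=False)]
    )

    sub = counts.counts.loc[chosen].to_numpy(dtype=float)
    if lengths is not None:
        lens = lengths.reindex(chosen).to_numpy(dtype=float)
        libs = counts.counts.sum(axis=0).to_numpy(dtype=float)
        x = np.log2(sub / (lens[:, None] / 1e3) / (libs[None, :] / 1e6) + 1.0)
    else:
        x = np.log2(sub + 1.0)
    sigma_x = x.std()

    eps = rng.normal(0.0, config.protein_noise_sd, size=x.shape)
    if r_target == 0:
        b = rng.normal(0.0, sigma_x, size=x.shape[0])
        y = b[:, None] + eps
    else:
        a = np.sign(r_target)
        var_b = sigma_x**2 * (1.0 / r_target**2 - 1.0) - config.protein_noise_sd**2
        b = rng.normal(0.0, 1.0, size=x.shape[0])
        # orthogonalise the decoupling offsets against the gene means and pin
        # their sample variance, so the solved-for pooled correlation is
        # realised rather than merely expected
        xbar = x.mean(axis=1)
        xc = xbar - xbar.mean()
        b -= b.mean()
        if (xc**2).sum() > 0:
            b -= (b @ xc) / (xc @ xc) * xc
        if b.std() > 0:
            b *= np.sqrt(max(var_b, 0.0)) / b.std()
        y = a * x + b[:, None] + eps
    y += config.protein_log_offset

    zplus = [j for j, g in enumerate(counts.genotypes) if g == "Z+"]
    idx = {g: i for i, g in enumerate(chosen)}
    for g, fold in config.planted_protein_down.items():
        y[idx[g], zplus] -= np.log2(fold)
    for g, fold in config.planted_protein_up.items():
        y[idx[g], zplus] += np.log2(fold)

    protein_ids = [f"p_{g}" for g in chosen]
    intensities = pd.DataFrame(2.0**y, index=protein_ids, columns=counts.counts.columns)
    if truth is not None:
        truth.true_crossomics_r = r_target
        truth.true_dep = {
            **{g: "down" for g in config.planted_protein_down},
            **{g: "up" for g in config.planted_protein_up},
        }
    return intensities, {p: g for p, g in zip(protein_ids, chosen)}


def generate_ortholog_map(
    ids: Sequence[str], seed: int = 0, paralog_fraction: float = 0.1
) -> dict[str, str]:
    """Model-organism gene -> human gene; a fraction of consecutive gene pairs
    are paralogs sharing one human target (many-to-one)."""
    rng = _rng(seed, "orthologs")
    mapping: dict[str, str] = {}
    i = 0
    h = 0
    ids = list(ids)
    while i < len(ids):
        hid = f"HG{h:05d}"
        if i + 1 < len(ids) and rng.random() < paralog_fraction:
            mapping[ids[i]] = hid
            mapping[ids[i + 1]] = hid
            i += 2
        else:
            mapping[ids[i]] = hid
            i += 1
        h += 1
    return mapping


def generate_annotations(
    config: SimulationConfig,
    truth: GroundTruth,
    ortholog_map: Mapping[str, str],
):
    """Random GMT-style term databases per category plus planted terms.

    Each planted term draws ``planted_term_fraction`` of its members from the
    human images of planted genes of one direction and the rest from
    elsewhere, and is recorded in ``truth.true_enriched_terms``.
    """
    from genospec.enrichment import AnnotationDB

    rng = _rng(config.seed, "annotations")
    universe = np.array(sorted(set(ortholog_map.values())))
    down_h = sorted({ortholog_map[g] for g in config.planted_down if g in ortholog_map})
    up_h = sorted({ortholog_map[g] for g in config.planted_up if g in ortholog_map})
    lo, hi = config.term_size_range

    dbs: dict[str, AnnotationDB] = {}
    for category, n_terms in config.n_terms.items():
        terms: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        for t in range(n_terms):
            size = int(rng.integers(lo, hi + 1))
            tid = f"{category}:T{t:04d}"
            terms[tid] = frozenset(rng.choice(universe, size=size, replace=False))
            names[tid] = f"random process {t}"
        planted_here: list[str] = []
        for tag, pool in (("DOWN", down_h), ("UP", up_h)):
            if not pool:
                continue
            size = int(np.clip(rng.integers(lo, hi + 1), 2, None))
            n_true = max(2, int(round(size * config.planted_term_fraction)))
            n_true = min(n_true, len(pool))
            members = set(rng.choice(np.array(pool), size=n_true, replace=False))
            others = np.setdiff1d(universe, np.array(sorted(members | set(down_h) | set(up_h))))
            n_fill = max(0, size - n_true)
            if n_fill and len(others):
                members |= set(rng.choice(others, size=min(n_fill, len(others)), replace=False))
            tid = f"{category}:PLANTED_{tag}"
            terms[tid] = frozenset(members)
            names[tid] = f"planted {tag.lower()}-regulated process"
            planted_here.append(tid)
        if terms:
            dbs[category] = AnnotationDB(category=category, terms=terms, names=names)
            truth.true_enriched_terms[category] = planted_here
        else:
            dbs[category] = AnnotationDB(category=category, terms={}, names={})
            truth.true_enriched_terms[category] = []
    return dbs


def generate_qpcr(
    truth: GroundTruth,
    genes: Sequence[str],
    noise_sd: float = 0.2,
    n_per_group: int = 6,
    seed: int = 0,
    genotypes: Sequence[str] = ("Z+", "A+"),
) -> pd.DataFrame:
    """Long-format qPCR Ct table whose 2^-dCt fold changes track the truth.

    Two housekeeping genes are held at fixed baseline Cts; each target gene
    gets a baseline Ct, shifted by -true_lfc in Z+ samples (one cycle per
    doubling), with N(0, noise_sd) added to every Ct measurement.  Two
    technical replicates per (gene, sample).
    """
    rng = _rng(seed, "qpcr")
    hk_base = {"hk_rpl13a": 19.0, "hk_lsm12b": 21.0}
    rows = []
    gene_base = {g: float(rng.uniform(24.0, 28.0)) for g in genes}
    for geno in genotypes:
        for i in range(n_per_group):
            sample = f"qs_{geno}_{i + 1}"
            for hk, base in hk_base.items():
                for _ in range(2):
                    rows.append((hk, sample, geno, base + rng.normal(0.0, noise_sd), 1))
            for g in genes:
                ct = gene_base[g]
                if geno == "Z+":
                    ct -= truth.true_lfc.get(g, 0.0)
                for _ in range(2):
                    rows.append((g, sample, geno, ct + rng.normal(0.0, noise_sd), 0))
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "genotype", "ct", "is_housekeeping"]
    )


@dataclass
class SyntheticDataset:
    """One complete simulated study, ready for the pipeline."""

    config: SimulationConfig
    counts: CountMatrix
    lengths: pd.Series
    proteins: pd.DataFrame  # raw intensities, proteins x samples
    protein_to_gene: dict[str, str]
    ortholog_map: dict[str, str]
    annotations: dict  # category -> AnnotationDB
    qpcr: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig, qpcr_genes: int = 6) -> SyntheticDataset:
    """Generate every layer of a synthetic study from one config."""
    counts, truth = generate_counts(config)
    lengths = generate_gene_lengths(config)
    ortholog_map = generate_ortholog_map(gene_ids(config.n_genes), seed=config.seed)
    annotations = generate_annotations(config, truth, ortholog_map)
    proteins, protein_to_gene = generate_proteome(counts, config, truth, lengths=lengths)
    planted = sorted(truth.true_lfc, key=lambda g: truth.true_lfc[g])
    if planted:
        step = max(1, len(planted) // qpcr_genes)
        chosen = planted[::step][:qpcr_genes]
    else:
        chosen = list(counts.counts.index[:qpcr_genes])
    qpcr = generate_qpcr(truth, chosen, noise_sd=config.qpcr_noise_sd, seed=config.seed)
    return SyntheticDataset(
        config=config,
        counts=counts,
        lengths=lengths,
        proteins=proteins,
        protein_to_gene=protein_to_gene,
        ortholog_map=ortholog_map,
        annotations=annotations,
        qpcr=qpcr,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write every layer as plain-text files (TSV / GMT / JSON)."""
    from pathlib import Path

    from genospec.enrichment import write_gmt
    from genospec.matrices import write_lengths_tsv, write_matrix_tsv, write_metadata_tsv
    from genospec.qpcr import write_qpcr_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(ds.counts.counts, out / "counts.tsv")
    write_metadata_tsv(ds.counts, out / "metadata.tsv")
    write_lengths_tsv(ds.lengths, out / "gene_lengths.tsv")
    write_matrix_tsv(ds.proteins, out / "protein_intensities.tsv")
    pd.Series(ds.protein_to_gene, name="gene_id").to_csv(
        out / "protein_to_gene.tsv", sep="\t", index_label="protein_id"
    )
    pd.Series(ds.ortholog_map, name="human_gene_id").to_csv(
        out / "ortholog_map.tsv", sep="\t", index_label="gene_id"
    )
    for category, db in ds.annotations.items():
        write_gmt(db, out / f"annotations_{category}.gmt")
    write_qpcr_tsv(ds.qpcr, out / "qpcr.tsv")
    ds.truth.to_json(out / "truth.json")
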