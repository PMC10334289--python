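"""Synthetic DIP-Seq and RNA-Seq data with recorded ground truth.

The generator emulates the statistical structure the analysis assumes:
uniform background tag placement, rectangular enrichment domains of
configurable fold, two-group designs with planted differential domains
near gene TSSs, multi-condition designs sharing a planted signature gene
set, and negative-binomially distributed RNA-Seq counts with planted
differentially expressed genes.

It does not model sequence: no CpG density, no mappability, no PCR
duplicates.  Tags are fixed-length reads placed by their start position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomeModel, TagSet

__all__ = [
    "Domain",
    "ConditionDesign",
    "SimulationDesign",
    "GroundTruth",
    "make_genome",
    "make_genes",
    "simulate_dip_sample",
    "simulate_condition_set",
    "simulate_rna_counts",
]

DEFAULT_TAG_LENGTH = 36  # bp; read length is configurable, never inferred


@dataclass(frozen=True)
class Domain:
    """A rectangular enrichment domain: tag density is fold x background inside."""

    chrom: str
    start: int
    end: int
    fold: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("domain start >= end")
        if self.fold < 1:
            raise ValueError("domain fold must be >= 1")


@dataclass(frozen=True)
class ConditionDesign:
    """One condition of a multi-condition experiment.

    ``specific_genes`` get planted domains only in this condition, on top
    of the signature genes shared by every condition.
    """

    condition_id: str
    n_treated: int = 2
    n_control: int = 2
    specific_genes: tuple[str, ...] = ()


@dataclass
class SimulationDesign:
    """Everything needed to simulate a full multi-condition DIP experiment."""

    genome: GenomeModel
    genes: pd.DataFrame
    signature_genes: tuple[str, ...]
    conditions: tuple[ConditionDesign, ...]
    depth: int = 100_000
    fold: float = 8.0
    domain_width: int = 2_000
    tag_length: int = DEFAULT_TAG_LENGTH
    assay: str = "5hmC"
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(self.genes["gene_id"])
        missing = set(self.signature_genes) - known
        if missing:
            raise ValueError(f"signature genes not in gene table: {sorted(missing)[:5]}")
        for cond in self.conditions:
            missing = set(cond.specific_genes) - known
            if missing:
                raise ValueError(
                    f"condition {cond.condition_id}: unknown genes {sorted(missing)[:5]}"
                )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: per-condition domains and gene sets, plus the signature."""

    domains_by_condition: dict[str, list[Domain]]
    genes_by_condition: dict[str, set[str]]
    signature_genes: set[str]
    de_genes: dict[str, float] = field(default_factory=dict)  # gene_id -> lfc


def make_genome(n_chroms: int, lengths: Sequence[int], seed: int = 0) -> GenomeModel:
    """Build a GenomeModel with chromosomes chr1..chrN of the given lengths."""
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    return GenomeModel(tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(lengths)))


def make_genes(
    genome: GenomeModel,
    n_genes: int,
    min_len: int = 2_000,
    max_len: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping genes uniformly on the genome.

    Lengths are uniform in [min_len, max_len]; strands Bernoulli(1/2).
    Placement spreads genes across chromosomes proportionally to length
    and positions them with random gaps, so packing is feasible whenever
    total gene length fits in the genome.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    # genes per chromosome, proportional to chromosome length
    total = genome.total_length
    quota = {name: int(round(n_genes * length / total)) for name, length in genome.chroms}
    while sum(quota.values()) < n_genes:
        quota[genome.names[0]] += 1
    while sum(quota.values()) > n_genes:
        for name in genome.names:
            if quota[name] > 0 and sum(quota.values()) > n_genes:
                quota[name] -= 1

    rows = []
    idx = 0
    for name, chrom_len in genome.chroms:
        k = quota[name]
        if k == 0:
            continue
        lens = rng.integers(min_len, max_len + 1, size=k)
        slack = chrom_len - int(lens.sum())
        if slack < 0:
            raise ValueError(
                f"cannot place {k} genes of up to {max_len} bp on {name} ({chrom_len} bp)"
            )
        # random gaps before each gene and after the last one
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        gaps = np.diff(np.concatenate([[0], cuts]))
        pos = 0
        for g, L in zip(gaps, lens):
            start = pos + int(g)
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{idx:04d}", f"Gene{idx}", name, strand, start, start + int(L)))
            pos = start + int(L)
    genes = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "strand", "tx_start", "tx_end"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["tx_start"], genes["tx_end"])
    genes["length"] = genes["tx_end"] - genes["tx_start"]
    return genes


def simulate_dip_sample(
    genome: GenomeModel,
    domains: Sequence[Domain],
    depth: int,
    seed: int,
    tag_length: int = DEFAULT_TAG_LENGTH,
    sample_id: str = "sample",
    assay: str = "5hmC",
) -> TagSet:
    """Draw exactly ``depth`` tags from a piecewise-constant start density.

    Density is proportional to 1 outside domains and to ``fold`` inside
    (the background rate cancels in the normalisation; total depth is what
    fixes the absolute scale).  Tag length is fixed, clipped at the
    chromosome end.  Overlapping domains multiply their folds.
    """
    if genome.total_length < 1:
        raise ValueError("zero-length genome")
    # Build per-chromosome piecewise segments (pos breakpoints, weight per piece).
    seg_chrom: list[str] = []
    seg_start: list[int] = []
    seg_len: list[int] = []
    seg_weight: list[float] = []
    for name, chrom_len in genome.chroms:
        cuts = {0, chrom_len}
        doms = [d for d in domains if d.chrom == name]
        for d in doms:
            if d.end > chrom_len or d.start < 0:
                raise ValueError(f"domain {d} outside {name}")
            cuts.add(d.start)
            cuts.add(d.end)
        edges = sorted(cuts)
        for a, b in zip(edges[:-1], edges[1:]):
            w = 1.0
            for d in doms:
                if d.start <= a and b <= d.end:
                    w *= d.fold
            seg_chrom.append(name)
            seg_start.append(a)
            seg_len.append(b - a)
            seg_weight.append(w)

    seg_len_arr = np.asarray(seg_len, dtype=np.float64)
    mass = seg_len_arr * np.asarray(seg_weight)
    prob = mass / mass.sum()
    rng = np.random.default_rng(seed)
    seg_idx = rng.choice(len(prob), size=depth, p=prob)
    offsets = rng.random(depth) * seg_len_arr[seg_idx]
    starts = np.asarray(seg_start)[seg_idx] + offsets.astype(np.int64)

    chrom_arr = np.asarray(seg_chrom, dtype=object)[seg_idx]
    chrom_lengths = pd.Series(chrom_arr).map(genome.lengths).to_numpy(dtype=np.int64)
    ends = np.minimum(starts + tag_length, chrom_lengths)
    # a tag must have positive length even at the chromosome edge
    starts = np.minimum(starts, chrom_lengths - 1)
    ends = np.maximum(ends, starts + 1)

    order = np.lexsort((starts, chrom_arr.astype(str)))
    tags = pd.DataFrame(
        {
            "chrom": pd.Series(chrom_arr[order], dtype=str),
            "start": starts[order],
            "end": ends[order],
            "strand": np.where(rng.random(depth) < 0.5, "+", "-")[order],
        }
    )
    return TagSet(sample_id=sample_id, assay=assay, genome=genome, tags=tags)


def _tss_domain(genes: pd.DataFrame, gene_id: str, width: int, genome: GenomeModel, fold: float) -> Domain:
    row = genes.loc[genes["gene_id"] == gene_id].iloc[0]
    chrom_len = genome.lengths[row["chrom"]]
    center = int(row["tss"])
    start = max(0, center - width // 2)
    end = min(chrom_len, start + width)
    start = max(0, end - width)
    if start >= end:
        raise ValueError(f"cannot place a {width} bp domain for gene {gene_id}")
    return Domain(row["chrom"], start, end, fold)


def simulate_condition_set(design: SimulationDesign) -> tuple[dict[str, list[TagSet]], GroundTruth]:
    """Simulate every sample of a multi-condition design.

    For each condition, treated samples carry domains centered on the TSS
    of every signature gene plus that condition's specific genes; control
    samples are pure background.  Returns tagsets keyed by condition, with
    sample ids ``<cond>_trt_<i>`` / ``<cond>_ctl_<i>``, and the ground truth.
    """
    rng = np.random.default_rng(design.seed)
    tagsets: dict[str, list[TagSet]] = {}
    domains_by_condition: dict[str, list[Domain]] = {}
    genes_by_condition: dict[str, set[str]] = {}
    for cond in design.conditions:
        planted = list(design.signature_genes) + list(cond.specific_genes)
        doms = [
            _tss_domain(design.genes, g, design.domain_width, design.genome, design.fold)
            for g in planted
        ]
        domains_by_condition[cond.condition_id] = doms
        genes_by_condition[cond.condition_id] = set(planted)
        samples = []
        for i in range(cond.n_treated):
            samples.append(
                simulate_dip_sample(
                    design.genome,
                    doms,
                    design.depth,
                    seed=int(rng.integers(0, 2**31)),
                    tag_length=design.tag_length,
                    sample_id=f"{cond.condition_id}_trt_{i + 1}",
                    assay=design.assay,
                )
            )
        for i in range(cond.n_control):
            samples.append(
                simulate_dip_sample(
                    design.genome,
                    [],
                    design.depth,
                    seed=int(rng.integers(0, 2**31)),
                    tag_length=design.tag_length,
                    sample_id=f"{cond.condition_id}_ctl_{i + 1}",
                    assay=design.assay,
                )
            )
        tagsets[cond.condition_id] = samples
    truth = GroundTruth(
        domains_by_condition=domains_by_condition,
        genes_by_condition=genes_by_condition,
        signature_genes=set(design.signature_genes),
    )
    return tagsets, truth


def simulate_rna_counts(
    genes: pd.DataFrame,
    n_samples_per_group: int,
    baseline_mean: float,
    dispersion: float,
    de_genes: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """NB-distributed RNA-Seq counts for a two-group design.

    Counts follow NB with Var = mu + dispersion * mu^2; dispersion 0
    degenerates to Poisson.  Group B means are mu * 2**lfc for planted DE
    genes.  Columns are A_1..A_n, B_1..B_n.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if baseline_mean < 0:
        raise ValueError("negative baseline mean")
    de_genes = de_genes or {}
    rng = np.random.default_rng(seed)
    gene_ids = genes["gene_id"].to_numpy()
    lfc = np.array([de_genes.get(g, 0.0) for g in gene_ids])
    mu_a = np.full(len(gene_ids), float(baseline_mean))
    mu_b = mu_a * 2.0**lfc

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu)
        # NB via gamma-Poisson mixture: shape r = 1/alpha, mean mu
        r = 1.0 / dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        return rng.poisson(lam)

    cols = {}
    for i in range(n_samples_per_group):
        cols[f"A_{i + 1}"] = draw(mu_a)
    for i in range(n_samples_per_group):
        cols[f"B_{i + 1}"] = draw(mu_b)
    matrix = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = GroundTruth(
        domains_by_condition={},
        genes_by_condition={},
        signature_genes=set(),
        de_genes=dict(de_genes),
    )
    return matrix, truth
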