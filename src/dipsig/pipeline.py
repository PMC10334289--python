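"""End-to-end orchestration: simulate -> segment -> union -> count ->
NB test -> annotate -> select -> intersect -> signature -> enrich.

One config drives the whole run; one master seed drives every stage, with
per-stage seeds derived by a stable CRC32 hash of (master, stage, sample)
so adding a sample never reshuffles the others.  Every stage writes its
intermediate to the output directory, and the report records parameters
so a run stays auditable.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .annotation import annotate_regions, select_top
from .differential import count_region_tags, nb_test, union_regions
from .io import CategoryMap, GeneSet, GenomeModel, TagSet
from .segmentation import segment_sample
from .setstats import (
    IntersectionResult,
    Universe,
    derive_signature,
    fisher_overlap,
    venn_counts,
)
from .simulate import (
    ConditionDesign,
    GroundTruth,
    SimulationDesign,
    make_genes,
    make_genome,
    simulate_condition_set,
)

log = logging.getLogger("dipsig")

__all__ = ["PipelineConfig", "SignatureReport", "run_pipeline", "compare_to_truth", "load_config"]


@dataclass
class PipelineConfig:
    """All parameters of a study-shaped run.

    Either ``design`` (simulation mode) or ``tag_files``/``genome_path``/
    ``genes_path`` (file mode) must be provided.  Defaults follow the
    analysis this package implements: 1 kb windows, permutation alpha
    0.01, top-1500 regions at p < 0.01 with tag difference > 10, a 50 kb
    annotation window centered on the TSS, and FDR 1e-3 for overlap
    significance.
    """

    design: SimulationDesign | None = None
    genome_path: str | None = None
    genes_path: str | None = None
    # file mode: condition -> {"treated": [bed...], "control": [bed...]}
    tag_files: Mapping[str, Mapping[str, Sequence[str]]] | None = None
    gmt_path: str | None = None
    window: int = 1000
    step: int | None = None  # default window // 2
    alpha: float = 0.01
    n_perm: int = 1000
    max_gap: int = 0
    n_top: int = 1500
    p_cut: float = 0.01
    min_abs_tagdiff: float = 10.0
    direction: str = "up"
    annotation_mode: str = "tss_window"
    half_window: int = 25_000
    dispersion_mode: str = "per-row"
    overlap_fdr_alpha: float = 1e-3
    seed: int = 0
    assay: str = "5hmC"


@dataclass
class SignatureReport:
    """Everything a run produced, with JSON serialisation for reports."""

    config_summary: dict
    condition_tables: dict[str, pd.DataFrame]
    gene_sets: dict[str, GeneSet]
    pairwise: list[IntersectionResult]
    multiset: IntersectionResult | None
    signature: GeneSet | None
    venn: dict[tuple[int, ...], int] | None
    enrichment: pd.DataFrame | None = None
    truth_metrics: dict | None = None

    def to_json_dict(self) -> dict:
        def inter(r: IntersectionResult) -> dict:
            return {
                "sets": list(r.set_labels),
                "sizes": list(r.set_sizes),
                "universe": r.universe_size,
                "observed": r.observed,
                "expected": r.expected,
                "fold": r.fold if np.isfinite(r.fold) else None,
                "p_value": r.p_value,
                "log10_p": r.log10_p,
                "method": r.method,
            }

        return {
            "config": self.config_summary,
            "gene_sets": {k: v.sorted() for k, v in self.gene_sets.items()},
            "n_regions_tested": {k: int(len(v)) for k, v in self.condition_tables.items()},
            "pairwise": [inter(r) for r in self.pairwise],
            "multiset": inter(self.multiset) if self.multiset else None,
            "signature": self.signature.sorted() if self.signature else None,
            "venn": {"".join(map(str, k)): v for k, v in self.venn.items()} if self.venn else None,
            "enrichment": self.enrichment.to_dict(orient="records")
            if self.enrichment is not None
            else None,
            "truth_metrics": self.truth_metrics,
        }


def derive_seed(master: int, *parts: object) -> int:
    """Stable per-stage seed below 2**31 from the master seed and labels."""
    key = ":".join([str(master), *map(str, parts)]).encode()
    return zlib.crc32(key) % (2**31)


def _condition_samples_from_files(
    config: PipelineConfig, genome: GenomeModel
) -> dict[str, list[TagSet]]:
    samples: dict[str, list[TagSet]] = {}
    for cond, groups in config.tag_files.items():
        tagsets = []
        for role in ("treated", "control"):
            for i, path in enumerate(groups.get(role, [])):
                sid = f"{cond}_{'trt' if role == 'treated' else 'ctl'}_{i + 1}"
                tagsets.append(dio.read_tags_bed(path, genome, sid, config.assay))
        samples[cond] = tagsets
    return samples


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    resume: bool = False,
) -> SignatureReport:
    """Run the full multi-condition analysis and return the report.

    With ``outdir`` set, every intermediate (per-sample regions, per-
    condition differential tables, gene sets, the JSON report) is written
    there; ``resume`` reuses cached per-sample segmentations on disk.
    """
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    truth: GroundTruth | None = None
    if config.design is not None:
        genome = config.design.genome
        genes = config.design.genes
        samples, truth = simulate_condition_set(config.design)
    elif config.tag_files and config.genome_path and config.genes_path:
        genome = dio.read_chrom_sizes(config.genome_path)
        genes = dio.read_gene_table(config.genes_path)
        samples = _condition_samples_from_files(config, genome)
    else:
        raise ValueError("config needs either a simulation design or input file paths")

    universe = Universe(frozenset(genes["gene_id"]))
    step = config.step or max(1, config.window // 2)

    condition_tables: dict[str, pd.DataFrame] = {}
    gene_sets: dict[str, GeneSet] = {}
    for cond, tagsets in samples.items():
        log.info("condition %s: segmenting %d samples (W=%d, S=%d, alpha=%g, n_perm=%d)",
                 cond, len(tagsets), config.window, step, config.alpha, config.n_perm)
        per_sample_regions = []
        for ts in tagsets:
            cache = out / f"regions_{ts.sample_id}.bed" if out else None
            if resume and cache and cache.exists():
                regions = dio.read_regions_bed(cache)
            else:
                regions = segment_sample(
                    ts,
                    window=config.window,
                    step=step,
                    alpha=config.alpha,
                    n_perm=config.n_perm,
                    seed=derive_seed(config.seed, "segment", ts.sample_id),
                    max_gap=config.max_gap,
                )
                if cache is not None:
                    dio.write_regions_bed(regions, cache)
            per_sample_regions.append(regions)
        union = union_regions(per_sample_regions)
        if union.empty:
            condition_tables[cond] = pd.DataFrame(
                columns=["id", "pval", "tagdiff", "lfc", "direction"]
            )
            gene_sets[cond] = GeneSet(label=cond, genes=frozenset())
            continue
        matrix = count_region_tags(tagsets, union)
        labels = ["treated" if "_trt_" in s else "control" for s in matrix.columns]
        # control is group A, treated group B, so "up" = enriched after treatment
        order = sorted(range(len(labels)), key=lambda i: labels[i] != "control")
        matrix = matrix.iloc[:, order]
        labels = [labels[i] for i in order]
        table = nb_test(matrix, labels, dispersion_mode=config.dispersion_mode)
        table = table.merge(union[["id", "chrom", "start", "end"]], on="id")
        annotated = annotate_regions(
            table, genes, mode=config.annotation_mode, half_window=config.half_window
        )
        gene_sets[cond] = select_top(
            annotated,
            n_top=config.n_top,
            p_cut=config.p_cut,
            min_abs_tagdiff=config.min_abs_tagdiff,
            direction=config.direction,
            label=cond,
        )
        condition_tables[cond] = annotated
        if out:
            table.to_csv(out / f"dhr_{cond}.tsv", sep="\t", index=False)
            dio.write_gene_set(gene_sets[cond], out / f"genes_{cond}.txt")

    conds = list(gene_sets)
    pairwise = [
        fisher_overlap(gene_sets[a], gene_sets[b], universe)
        for i, a in enumerate(conds)
        for b in conds[i + 1 :]
    ]
    multiset = None
    signature = None
    venn = None
    if len(conds) >= 2:
        signature, multiset = derive_signature(
            [gene_sets[c] for c in conds], universe, label="signature"
        )
        if len(conds) <= 6:
            venn = venn_counts([gene_sets[c] for c in conds])

    enrichment_table = None
    if config.gmt_path:
        from .enrichment import enrich_all, fit_pwf, uniform_pwf

        cmap = dio.read_gmt(config.gmt_path)
        selected_union = set().union(*[gene_sets[c].genes for c in conds]) if conds else set()
        flags = genes["gene_id"].isin(selected_union).to_numpy()
        if signature is not None and len(signature) and 0 < flags.sum() < len(flags):
            pwf = fit_pwf(flags, genes["length"].to_numpy(), genes["gene_id"].tolist())
            enrichment_table = enrich_all(
                signature, cmap, universe, pwf, fdr_alpha=config.overlap_fdr_alpha
            )
            if out is not None:
                enrichment_table.to_csv(out / "enrichment_signature.tsv", sep="\t", index=False)

    report = SignatureReport(
        config_summary={
            "window": config.window,
            "step": step,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
            "n_top": config.n_top,
            "p_cut": config.p_cut,
            "min_abs_tagdiff": config.min_abs_tagdiff,
            "direction": config.direction,
            "half_window": config.half_window,
            "annotation_mode": config.annotation_mode,
            "dispersion_mode": config.dispersion_mode,
            "universe_size": universe.size,
            "seed": config.seed,
            "conditions": conds,
        },
        condition_tables=condition_tables,
        gene_sets=gene_sets,
        pairwise=pairwise,
        multiset=multiset,
        signature=signature,
        venn=venn,
        enrichment=enrichment_table,
    )
    if truth is not None:
        report.truth_metrics = compare_to_truth(report, truth)
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2)
    return report


def compare_to_truth(report: SignatureReport, truth: GroundTruth) -> dict:
    """Sensitivity/precision of recovered gene sets and the signature.

    Precision of an empty recovery is 1 by convention (no false calls).
    """

    def prf(recovered: set[str], planted: set[str]) -> dict:
        tp = len(recovered & planted)
        sens = tp / len(planted) if planted else 1.0
        prec = tp / len(recovered) if recovered else 1.0
        return {
            "n_recovered": len(recovered),
            "n_planted": len(planted),
            "true_positives": tp,
            "sensitivity": sens,
            "precision": prec,
        }

    metrics: dict = {"conditions": {}}
    for cond, gs in report.gene_sets.items():
        planted = truth.genes_by_condition.get(cond, set())
        metrics["conditions"][cond] = prf(set(gs.genes), planted)
    if report.signature is not None:
        m = prf(set(report.signature.genes), truth.signature_genes)
        m["false_genes"] = m["n_recovered"] - m["true_positives"]
        metrics["signature"] = m
    return metrics


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file.

    A ``simulation`` block describes the synthetic design (chromosome
    lengths, gene count, signature size, conditions, depth, fold); its
    genome, genes, and planted gene choices are constructed
    deterministically from the config seed.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = {k: v for k, v in raw.items() if k != "simulation"}
    sim = raw.get("simulation")
    design = None
    if sim:
        seed = int(raw.get("seed", 0))
        genome = make_genome(len(sim["chrom_lengths"]), sim["chrom_lengths"], seed)
        genes = make_genes(
            genome,
            sim["n_genes"],
            sim.get("min_gene_len", 2_000),
            sim.get("max_gene_len", 10_000),
            seed=derive_seed(seed, "genes"),
        )
        rng = np.random.default_rng(derive_seed(seed, "plant"))
        gene_ids = genes["gene_id"].tolist()
        n_sig = sim.get("n_signature", 45)
        n_specific = sim.get("n_specific", 10)
        picks = rng.choice(len(gene_ids), size=n_sig, replace=False)
        signature = tuple(gene_ids[i] for i in picks)
        rest = [g for g in gene_ids if g not in set(signature)]
        conditions = []
        for cond_id in sim["conditions"]:
            spec = tuple(rng.choice(rest, size=min(n_specific, len(rest)), replace=False))
            conditions.append(
                ConditionDesign(
                    condition_id=cond_id,
                    n_treated=sim.get("n_treated", 2),
                    n_control=sim.get("n_control", 2),
                    specific_genes=spec,
                )
            )
        design = SimulationDesign(
            genome=genome,
            genes=genes,
            signature_genes=signature,
            conditions=tuple(conditions),
            depth=sim.get("depth", 100_000),
            fold=sim.get("fold", 8.0),
            domain_width=sim.get("domain_width", 2_000),
            seed=derive_seed(seed, "tags"),
        )
    return PipelineConfig(design=design, **params)
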