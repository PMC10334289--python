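"""Gene-level tag counting, differential expression, and DHR x DEG overlap.

Differential expression reuses the NB machinery from
:mod:`dipsig.differential`; genes are selected at an unadjusted p cutoff
(default 0.01) because region-level epigenomic contrasts often carry
pathway-level signal even when no single gene survives FDR control.  The
association between differential regions and expression is a gene-set
overlap (Fisher) against an explicit universe.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import GeneSet, TagSet
from .setstats import IntersectionResult, Universe, fisher_overlap

__all__ = [
    "count_gene_tags",
    "de_select",
    "dhr_deg_intersection",
]


def count_gene_tags(tagsets: Sequence[TagSet], genes: pd.DataFrame) -> pd.DataFrame:
    """Count matrix of tag starts falling in [tx_start, tx_end) per gene.

    Strand-agnostic; a tag inside two overlapping genes counts for both
    (gene rows are independent interval queries, not a partition).
    """
    g = genes.reset_index(drop=True)
    cols = {}
    for ts in tagsets:
        counts = np.zeros(len(g), dtype=np.int64)
        for chrom, grp in g.groupby("chrom", sort=False):
            pos = ts.starts(chrom)
            counts[grp.index.to_numpy()] = np.searchsorted(
                pos, grp["tx_end"].to_numpy()
            ) - np.searchsorted(pos, grp["tx_start"].to_numpy())
        cols[ts.sample_id] = counts
    return pd.DataFrame(cols, index=pd.Index(g["gene_id"], name="id"))


def de_select(
    diff_results: pd.DataFrame,
    direction: Literal["up", "down"],
    p_cut: float = 0.01,
    label: str | None = None,
) -> GeneSet:
    """Differentially expressed genes at an unadjusted p cutoff.

    Filters by the sign of the log fold change (zero-lfc rows belong to
    neither direction) and p < p_cut; gene ids are deduplicated.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must be in (0, 1)")
    sign = diff_results["lfc"] > 0 if direction == "up" else diff_results["lfc"] < 0
    sel = diff_results[sign & (diff_results["pval"] < p_cut)]
    return GeneSet(
        label=label or f"deg_{direction}",
        genes=frozenset(sel["id"]),
        provenance={"direction": direction, "p_cut": p_cut, "n_rows": int(len(sel))},
    )


def dhr_deg_intersection(
    dhr_gene_set: GeneSet, deg_set: GeneSet, universe: Universe
) -> IntersectionResult:
    """Fisher overlap between region-associated genes and DE genes."""
    return fisher_overlap(dhr_gene_set, deg_set, universe)
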