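"""Region-to-gene annotation, top-region gene-set selection, and metagene
tag-density matrices.

A differential region is annotated to at most one gene: the gene whose
TSS is closest to the region midpoint within a +/- half_window (default
25 kb, i.e. a 50 kb window centered on the TSS), or, in gene-body mode,
a gene whose transcript span contains the midpoint.  Regions with no
eligible gene are dropped.  Gene sets are then selected by p-value rank
with a p cutoff and a minimum absolute normalised tag difference, and
deduplicated keeping each gene's best-p region.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io import GeneSet, TagSet

__all__ = [
    "annotate_regions",
    "select_top",
    "metagene_matrix",
]

DEFAULT_HALF_WINDOW = 25_000  # bp; +/-25 kb = a 50 kb window centered on the TSS


def annotate_regions(
    diff_regions: pd.DataFrame,
    genes: pd.DataFrame,
    mode: Literal["tss_window", "gene_body"] = "tss_window",
    half_window: int = DEFAULT_HALF_WINDOW,
) -> pd.DataFrame:
    """Assign each region to its closest eligible gene.

    ``diff_regions`` needs chrom/start/end (plus any stat columns, which
    are carried through).  Distance is region midpoint minus TSS, signed.
    Ties on |distance| break toward the lexicographically smaller gene_id.
    Regions with no eligible gene are dropped.
    """
    if genes.empty:
        raise ValueError("empty gene table")
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    if diff_regions.empty:
        return diff_regions.assign(gene_id=pd.Series(dtype=str), tss_distance=pd.Series(dtype=float))

    out_rows = []
    regions = diff_regions.reset_index(drop=True)
    mid = (regions["start"].to_numpy() + regions["end"].to_numpy()) / 2.0
    for chrom, grp in regions.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        # order by (tss, gene_id) so equidistant ties resolve to smaller id
        g = g.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        tss = g["tss"].to_numpy(dtype=float)
        gidx = grp.index.to_numpy()
        for ridx in gidx:
            m = mid[ridx]
            if mode == "tss_window":
                dist = m - tss
                eligible = np.abs(dist) <= half_window
            elif mode == "gene_body":
                eligible = (g["tx_start"].to_numpy() <= m) & (m < g["tx_end"].to_numpy())
                dist = m - tss
            else:
                raise ValueError(f"unknown annotation mode {mode!r}")
            if not eligible.any():
                continue
            cand = np.flatnonzero(eligible)
            absd = np.abs(dist[cand])
            best_abs = absd.min()
            tied = cand[absd == best_abs]
            if len(tied) > 1:
                ids = [g["gene_id"].iloc[t] for t in tied]
                best = tied[ids.index(min(ids))]
            else:
                best = tied[0]
            row = regions.loc[ridx].to_dict()
            row["gene_id"] = g["gene_id"].iloc[best]
            row["tss_distance"] = float(dist[best])
            out_rows.append(row)
    if not out_rows:
        return regions.iloc[0:0].assign(gene_id=pd.Series(dtype=str), tss_distance=pd.Series(dtype=float))
    return pd.DataFrame(out_rows).reset_index(drop=True)


def select_top(
    annotated: pd.DataFrame,
    n_top: int = 1500,
    p_cut: float = 0.01,
    min_abs_tagdiff: float = 10.0,
    direction: Literal["up", "down", "any"] = "up",
    label: str = "selected",
) -> GeneSet:
    """Select the gene set behind the top differential regions.

    Filter by direction, p < p_cut and tagdiff > min_abs_tagdiff; rank by
    ascending p; truncate to the top ``n_top`` regions (before gene
    dedup); then deduplicate genes keeping each gene's best-p region.
    """
    if n_top < 1 or not 0 < p_cut <= 1:
        raise ValueError("n_top must be >= 1 and p_cut in (0, 1]")
    df = annotated
    if direction != "any":
        df = df[df["direction"] == direction]
    df = df[(df["pval"] < p_cut) & (df["tagdiff"] > min_abs_tagdiff)]
    df = df.sort_values(["pval", "gene_id"], kind="mergesort").head(n_top)
    genes = frozenset(df["gene_id"])
    return GeneSet(
        label=label,
        genes=genes,
        provenance={
            "n_top": n_top,
            "p_cut": p_cut,
            "min_abs_tagdiff": min_abs_tagdiff,
            "direction": direction,
            "n_regions_selected": int(len(df)),
        },
    )


def metagene_matrix(
    tagset: TagSet,
    genes: pd.DataFrame,
    expression: Mapping[str, float],
    n_body_bins: int = 40,
    flank_bp: int = 2_000,
    flank_bins: int = 10,
    cap_quantile: float = 0.80,
) -> pd.DataFrame:
    """Median-normalised tag-density matrix over flank/body/flank bins.

    One row per gene (sorted by descending expression), columns are
    ``flank_bins`` upstream bins of fixed width, ``n_body_bins`` bins over
    the scaled gene body, and ``flank_bins`` downstream bins, oriented so
    upstream is 5'.  Density is tags/bp per bin; the matrix is divided by
    the median of its positive entries and capped at its ``cap_quantile``
    quantile (computed over all entries).
    """
    missing = set(genes["gene_id"]) - set(expression)
    if missing:
        raise ValueError(f"expression missing for genes: {sorted(missing)[:5]}")
    n_cols = flank_bins + n_body_bins + flank_bins
    mat = np.zeros((len(genes), n_cols))
    gene_ids = []
    for i, row in enumerate(genes.itertuples(index=False)):
        gene_ids.append(row.gene_id)
        pos = tagset.starts(row.chrom)
        up_edges = np.linspace(row.tx_start - flank_bp, row.tx_start, flank_bins + 1)
        body_edges = np.linspace(row.tx_start, row.tx_end, n_body_bins + 1)
        dn_edges = np.linspace(row.tx_end, row.tx_end + flank_bp, flank_bins + 1)
        edges = np.concatenate([up_edges[:-1], body_edges[:-1], dn_edges])
        counts = np.diff(np.searchsorted(pos, edges))
        widths = np.diff(edges)
        dens = np.where(widths > 0, counts / np.maximum(widths, 1e-12), 0.0)
        if row.strand == "-":
            dens = dens[::-1]
        mat[i] = dens
    positive = mat[mat > 0]
    if positive.size:
        mat = mat / np.median(positive)
    cap = np.quantile(mat, cap_quantile)
    mat = np.minimum(mat, cap)
    order = sorted(range(len(gene_ids)), key=lambda i: -expression[gene_ids[i]])
    cols = (
        [f"up_{j + 1}" for j in range(flank_bins)]
        + [f"body_{j + 1}" for j in range(n_body_bins)]
        + [f"down_{j + 1}" for j in range(flank_bins)]
    )
    return pd.DataFrame(mat[order], index=pd.Index([gene_ids[i] for i in order], name="gene_id"), columns=cols)
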