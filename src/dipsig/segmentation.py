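"""Sliding-window segmentation of DIP-Seq tags with a Monte-Carlo null.

The genome is tiled with windows of width W at step S; each window counts
the tags whose start position it contains.  The enrichment threshold c*
is the smallest count whose upper-tail probability, under repeated uniform
re-placement of the tags (per chromosome, preserving tag totals), is at
most alpha.  Windows at or above c* are called enriched and merged into
regions.

Assigning tags by start position (rather than fragment overlap) keeps the
permutation null exactly exchangeable: a re-placed tag contributes to
windows in precisely the same way a real one does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomeModel, TagSet

__all__ = [
    "WindowGrid",
    "EnrichmentThreshold",
    "count_window_tags",
    "permutation_null",
    "call_enriched_windows",
    "merge_windows",
    "segment_sample",
    "optimize_window_size",
]


@dataclass
class WindowGrid:
    """Per-chromosome window tilings and tag counts for one sample."""

    window: int
    step: int
    genome: GenomeModel
    starts: dict[str, np.ndarray]  # window start per chrom
    ends: dict[str, np.ndarray]  # window end, clipped at chrom length
    counts: dict[str, np.ndarray]

    @property
    def n_windows(self) -> int:
        return sum(len(v) for v in self.counts.values())

    def all_counts(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.genome.names if c in self.counts])


@dataclass
class EnrichmentThreshold:
    """Monte-Carlo null for window counts and the implied call threshold.

    ``null_hist[c]`` is the number of null windows with count exactly c,
    pooled over all permutations and chromosomes.  ``c_star`` is
    min{c : P_null(count >= c) <= alpha}; alpha >= 1 degenerates to 0.
    """

    window: int
    step: int
    alpha: float
    n_perm: int
    null_hist: np.ndarray
    c_star: int

    def tail_probability(self, c: int) -> float:
        """P_null(count >= c) from the pooled histogram."""
        if c <= 0:
            return 1.0
        total = self.null_hist.sum()
        if c >= len(self.null_hist):
            return 0.0
        return float(self.null_hist[c:].sum() / total)


def _window_starts(chrom_len: int, window: int, step: int) -> np.ndarray:
    """Starts of all windows tiling [0, chrom_len); the last may be partial."""
    n = max(1, math.ceil(chrom_len / step))
    starts = np.arange(n, dtype=np.int64) * step
    return starts[starts < chrom_len]


def count_window_tags(tagset: TagSet, window: int, step: int | None = None) -> WindowGrid:
    """Count tag starts per window of width ``window`` at step ``step``.

    Default step is window/2 (half-overlapping tiles).  A tag is counted in
    every window whose [start, start+W) span contains its start position.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or max(1, window // 2)
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    genome = tagset.genome
    if window > max(l for _, l in genome.chroms):
        raise ValueError("window larger than every chromosome")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for name, chrom_len in genome.chroms:
        ws = _window_starts(chrom_len, window, step)
        we = np.minimum(ws + window, chrom_len)
        pos = tagset.starts(name)
        counts[name] = (
            np.searchsorted(pos, we, side="left") - np.searchsorted(pos, ws, side="left")
        ).astype(np.int64)
        starts[name] = ws
        ends[name] = we
    return WindowGrid(window=window, step=step, genome=genome, starts=starts, ends=ends, counts=counts)


def _null_window_hist(
    n_tags: int, chrom_len: int, window: int, step: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Histogram of window counts under uniform re-placement of n_tags.

    Positions are binned into cells of width gcd(window, step); a window
    count is then the sum of a fixed run of consecutive cells, which lets
    all permutations be processed as vectorised bincounts.
    """
    g = math.gcd(window, step)
    n_cells = math.ceil(chrom_len / g)
    cells_per_window = window // g
    cells_per_step = step // g
    ws = _window_starts(chrom_len, window, step)
    first_cell = ws // g
    # clip the run of cells for the trailing partial window
    last_cell_excl = np.minimum(first_cell + cells_per_window, n_cells)

    hist = np.zeros(n_tags + 1, dtype=np.int64)
    # chunk permutations to bound memory at ~32 MB of positions
    chunk = max(1, int(4e6 // max(n_tags, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        pos = rng.integers(0, chrom_len, size=(k, n_tags))
        cell = pos // g
        offset = (np.arange(k, dtype=np.int64) * n_cells)[:, None]
        flat = np.bincount((cell + offset).ravel(), minlength=k * n_cells)
        cum = np.concatenate(
            [np.zeros((k, 1), dtype=np.int64), np.cumsum(flat.reshape(k, n_cells), axis=1)], axis=1
        )
        wcounts = cum[:, last_cell_excl] - cum[:, first_cell]
        hist += np.bincount(wcounts.ravel(), minlength=n_tags + 1)
        done += k
    return hist


def permutation_null(
    tagset: TagSet,
    window: int,
    step: int | None = None,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentThreshold:
    """Monte-Carlo null distribution of window counts and threshold c*.

    Tags are re-placed uniformly at random ``n_perm`` times, preserving the
    per-chromosome tag total, and all null window counts are pooled.
    """
    step = step or max(1, window // 2)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(tagset) == 0:
        raise ValueError("cannot build a permutation null from zero tags")
    rng = np.random.default_rng(seed)
    max_tags = max(len(tagset.starts(c)) for c in tagset.genome.names)
    hist = np.zeros(max_tags + 1, dtype=np.int64)
    for name, chrom_len in tagset.genome.chroms:
        n_tags = len(tagset.starts(name))
        if n_tags == 0:
            # a tagless chromosome contributes all-zero windows
            n_windows = len(_window_starts(chrom_len, window, step))
            hist[0] += n_windows * n_perm
            continue
        h = _null_window_hist(n_tags, chrom_len, window, step, n_perm, rng)
        hist[: len(h)] += h
    if alpha >= 1:
        c_star = 0
    else:
        tail = np.cumsum(hist[::-1])[::-1] / hist.sum()
        ok = np.flatnonzero(tail <= alpha)
        c_star = int(ok[0]) if len(ok) else int(len(hist))
    return EnrichmentThreshold(
        window=window, step=step, alpha=alpha, n_perm=n_perm, null_hist=hist, c_star=c_star
    )


def call_enriched_windows(grid: WindowGrid, threshold: EnrichmentThreshold) -> pd.DataFrame:
    """Windows with count >= c* (inclusive), as a chrom/start/end/count frame."""
    if grid.window != threshold.window:
        raise ValueError("grid and threshold were built with different window sizes")
    rows = []
    for name in grid.genome.names:
        mask = grid.counts[name] >= threshold.c_star
        for s, e, c in zip(grid.starts[name][mask], grid.ends[name][mask], grid.counts[name][mask]):
            rows.append((name, int(s), int(e), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def merge_windows(windows: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Coalesce overlapping, book-ended, or <= max_gap-separated windows.

    Input needs chrom/start/end columns; output regions are disjoint,
    sorted, and cover exactly the union of the inputs (gaps bridged only
    up to max_gap).  With half-open intervals, end == next start merges.
    """
    if windows.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "id"])
    w = windows.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    rows = []
    cur_chrom, cur_start, cur_end = None, None, None
    for row in w.itertuples(index=False):
        if row.chrom != cur_chrom or row.start > cur_end + max_gap:
            if cur_chrom is not None:
                rows.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = row.chrom, row.start, row.end
        else:
            cur_end = max(cur_end, row.end)
    rows.append((cur_chrom, cur_start, cur_end))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["id"] = [f"r{i + 1}" for i in range(len(out))]
    return out


def segment_sample(
    tagset: TagSet,
    window: int = 1000,
    step: int | None = None,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    max_gap: int = 0,
) -> pd.DataFrame:
    """Full single-sample segmentation: count, null, call, merge."""
    grid = count_window_tags(tagset, window, step)
    thr = permutation_null(tagset, window, step, alpha=alpha, n_perm=n_perm, seed=seed)
    called = call_enriched_windows(grid, thr)
    return merge_windows(called, max_gap=max_gap)


def optimize_window_size(
    tagset: TagSet,
    candidate_windows: Sequence[int],
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> int:
    """Pick the candidate window size yielding the most merged enriched regions.

    Ties break toward the smallest window.
    """
    if not candidate_windows:
        raise ValueError("need at least one candidate window size")
    best_w, best_n = None, -1
    for w in sorted(candidate_windows):
        n = len(segment_sample(tagset, window=w, alpha=alpha, n_perm=n_perm, seed=seed))
        if n > best_n:
            best_w, best_n = w, n
    return best_w
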