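"""Overlap statistics for gene sets.

Two-set overlaps use the one-sided Fisher exact (hypergeometric upper
tail) test.  For m > 2 sets the exact null distribution of the total
m-set intersection size, under independent uniform draws of subsets of
the observed sizes from a common universe, is built by convolving
hypergeometric kernels:

    P_m(x) = sum_j P_{m-1}(j) * Hypergeom(x | N, j, n_m)

carried in log-space so upper-tail p-values far below floating-point
underflow (p ~ 1e-70) remain exact in the log domain.  A Monte-Carlo
oracle is provided for validation, and ``derive_signature`` returns the
plain intersection of all input sets together with its exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .io import GeneSet

__all__ = [
    "Universe",
    "IntersectionResult",
    "fisher_overlap",
    "multiset_exact_test",
    "mc_overlap_oracle",
    "derive_signature",
    "venn_counts",
]


@dataclass(frozen=True)
class Universe:
    """The background gene population all overlap tests condition on."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("universe must be non-empty")

    @property
    def size(self) -> int:
        return len(self.genes)

    def check_subset(self, gene_set: GeneSet) -> None:
        extra = gene_set.genes - self.genes
        if extra:
            raise ValueError(
                f"set {gene_set.label!r} has members outside the universe: {sorted(extra)[:5]}"
            )


@dataclass(frozen=True)
class IntersectionResult:
    """Observed k-set overlap with its expectation and enrichment p-value.

    ``log10_p`` carries the exact magnitude even when ``p_value``
    underflows to 0 in double precision.
    """

    set_labels: tuple[str, ...]
    set_sizes: tuple[int, ...]
    universe_size: int
    observed: int
    expected: float
    p_value: float
    log10_p: float
    method: str

    @property
    def fold(self) -> float:
        return self.observed / self.expected if self.expected > 0 else float("nan")


def _expected(sizes: Sequence[int], n_universe: int) -> float:
    e = float(n_universe)
    for n in sizes:
        e *= n / n_universe
    return e


def fisher_overlap(set_a: GeneSet, set_b: GeneSet, universe: Universe) -> IntersectionResult:
    """One-sided enrichment p for a two-set overlap: P(X >= x_obs),
    X ~ Hypergeom(N, |A|, |B|)."""
    universe.check_subset(set_a)
    universe.check_subset(set_b)
    n = universe.size
    x_obs = len(set_a.genes & set_b.genes)
    logp = hypergeom.logsf(x_obs - 1, n, len(set_a), len(set_b))
    p = float(np.exp(logp))
    return IntersectionResult(
        set_labels=(set_a.label, set_b.label),
        set_sizes=(len(set_a), len(set_b)),
        universe_size=n,
        observed=x_obs,
        expected=_expected([len(set_a), len(set_b)], n),
        p_value=min(p, 1.0),
        log10_p=float(logp / np.log(10)),
        method="fisher",
    )


def _multiset_log_pmf(sizes: Sequence[int], n_universe: int) -> np.ndarray:
    """Log-pmf of the total intersection size of m independent uniform
    subsets of the given sizes, over support 0..min(sizes)."""
    sizes = list(sizes)
    if any(s > n_universe for s in sizes):
        raise ValueError("set size exceeds universe size")
    # state: log P(intersection of first k sets has size j), j = 0..cur_max
    cur_max = sizes[0]
    logp = np.full(cur_max + 1, -np.inf)
    logp[cur_max] = 0.0
    for n_k in sizes[1:]:
        new_max = min(cur_max, n_k)
        j = np.arange(cur_max + 1)
        x = np.arange(new_max + 1)
        # kernel[j, x] = log P(Hypergeom(N, j, n_k) = x)
        kernel = hypergeom.logpmf(x[None, :], n_universe, j[:, None], n_k)
        logp = logsumexp(logp[:, None] + kernel, axis=0)
        cur_max = new_max
    return logp


def multiset_exact_test(sets: Sequence[GeneSet], universe: Universe) -> IntersectionResult:
    """Exact enrichment test for the total intersection of m >= 2 sets."""
    if len(sets) < 2:
        raise ValueError("multiset_exact_test needs at least 2 sets")
    for s in sets:
        universe.check_subset(s)
    n = universe.size
    sizes = [len(s) for s in sets]
    inter = frozenset.intersection(*[s.genes for s in sets])
    x_obs = len(inter)
    log_pmf = _multiset_log_pmf(sizes, n)
    log_tail = logsumexp(log_pmf[x_obs:]) if x_obs < len(log_pmf) else -np.inf
    log_tail = min(log_tail, 0.0)
    return IntersectionResult(
        set_labels=tuple(s.label for s in sets),
        set_sizes=tuple(sizes),
        universe_size=n,
        observed=x_obs,
        expected=_expected(sizes, n),
        p_value=float(np.exp(log_tail)) if x_obs > 0 else 1.0,
        log10_p=float(log_tail / np.log(10)) if x_obs > 0 else 0.0,
        method="exact_multiset",
    )


def mc_overlap_oracle(
    set_sizes: Sequence[int],
    universe_size: int,
    x_obs: int,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of P(intersection >= x_obs) with add-one smoothing.

    Draws m independent uniform subsets of the stated sizes per replicate.
    Deterministic under ``seed``; intended as a validation oracle for the
    exact test, not as a production path.
    """
    if n_draws < 1000:
        raise ValueError("use at least 1000 draws")
    if any(s > universe_size for s in set_sizes):
        raise ValueError("set size exceeds universe size")
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, int(2e6 // max(universe_size, 1)))
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        inter = np.ones((k, universe_size), dtype=bool)
        for n_s in set_sizes:
            # uniform subset of size n_s: the n_s smallest of k x N uniforms
            u = rng.random((k, universe_size))
            thresh = np.partition(u, n_s - 1, axis=1)[:, n_s - 1]
            inter &= u <= thresh[:, None]
        hits += int((inter.sum(axis=1) >= x_obs).sum())
        done += k
    return (hits + 1) / (n_draws + 1)


def derive_signature(
    gene_sets: Sequence[GeneSet], universe: Universe, label: str = "signature"
) -> tuple[GeneSet, IntersectionResult]:
    """Intersection of all input sets plus its exact multi-set p-value."""
    if len(gene_sets) < 2:
        raise ValueError("need at least 2 gene sets")
    inter = frozenset.intersection(*[s.genes for s in gene_sets])
    result = multiset_exact_test(gene_sets, universe)
    signature = GeneSet(
        label=label,
        genes=inter,
        provenance={
            "source_sets": [s.label for s in gene_sets],
            "method": "multi-set intersection",
            "p_value": result.p_value,
            "log10_p": result.log10_p,
        },
    )
    return signature, result


def venn_counts(gene_sets: Sequence[GeneSet]) -> dict[tuple[int, ...], int]:
    """Counts per non-empty membership pattern across up to 6 sets.

    Keys are 0/1 tuples, one flag per input set; values sum to the size of
    the union.
    """
    m = len(gene_sets)
    if m < 2:
        raise ValueError("need at least 2 sets")
    if m > 6:
        raise ValueError("venn_counts supports at most 6 sets")
    union = frozenset.union(*[s.genes for s in gene_sets])
    counts: dict[tuple[int, ...], int] = {}
    for g in union:
        pattern = tuple(int(g in s.genes) for s in gene_sets)
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts
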