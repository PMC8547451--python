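"""Minimal primer-panel selection as a set-cover problem.

Many designed pairs amplify overlapping gene sets, so running all of them
on a qPCR array wastes wells.  Selecting the smallest subset of pairs that
still amplifies every coverable gene is the classic NP-hard set-cover
problem; the panel selector uses the standard greedy ln(n)-approximation
(pick the pair covering the most still-uncovered genes, repeat), followed
by a redundancy sweep that drops any selected pair whose coverage the rest
of the selection already provides.  An exhaustive minimum-cardinality
solver is included for small instances, primarily as a cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .ispcr import CoverageMatrix

__all__ = ["CoverSolution", "greedy_min_cover", "exact_min_cover"]


@dataclass
class CoverSolution:
    selected_pair_ids: list[str]
    covered_gene_ids: set[str]
    n_uncoverable: int


def _coverage_sets(matrix: CoverageMatrix) -> dict[str, frozenset[str]]:
    return {pid: matrix.covered_by(pid) for pid in matrix.pair_ids}


def greedy_min_cover(matrix: CoverageMatrix) -> CoverSolution:
    """Greedy set cover over the amplification matrix.

    Repeatedly selects the pair covering the most uncovered genes (ties:
    fewest genes covered in total, then ascending pair id) until no pair
    adds coverage, so the covered set always equals the union over all
    candidate pairs.  A final sweep removes pairs whose contribution is
    subsumed by the remaining selection, leaving every retained pair with
    at least one uniquely-covered gene.
    """
    cov = _coverage_sets(matrix)
    all_genes = set(matrix.gene_ids)
    coverable = set().union(*cov.values()) if cov else set()
    uncovered = set(coverable)
    selected: list[str] = []
    while uncovered:
        best = min(
            matrix.pair_ids,
            key=lambda pid: (-len(cov[pid] & uncovered), len(cov[pid]), pid),
        )
        gain = cov[best] & uncovered
        if not gain:
            break
        selected.append(best)
        uncovered -= gain

    # redundancy sweep: drop pairs covered by the rest of the selection
    changed = True
    while changed:
        changed = False
        for pid in list(selected):
            others = set().union(
                *(cov[q] for q in selected if q != pid), set()
            )
            if cov[pid] <= others:
                selected.remove(pid)
                changed = True
                break

    covered = set().union(*(cov[p] for p in selected), set())
    return CoverSolution(
        selected_pair_ids=selected,
        covered_gene_ids=covered,
        n_uncoverable=len(all_genes - coverable),
    )


def exact_min_cover(matrix: CoverageMatrix, max_pairs: int = 20) -> CoverSolution:
    """Exhaustive minimum-cardinality cover of the coverable gene set.

    Enumerates pair subsets by increasing size; intended as a test oracle
    and refuses instances with more than ``max_pairs`` candidates.
    """
    if len(matrix.pair_ids) > max_pairs:
        raise ValueError(
            f"{len(matrix.pair_ids)} candidate pairs exceed the exact-solver "
            f"limit of {max_pairs}"
        )
    cov = _coverage_sets(matrix)
    all_genes = set(matrix.gene_ids)
    coverable = set().union(*cov.values()) if cov else set()
    if not coverable:
        return CoverSolution([], set(), len(all_genes))
    ids = sorted(matrix.pair_ids)
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            union = set().union(*(cov[p] for p in combo))
            if union >= coverable:
                return CoverSolution(list(combo), union, len(all_genes - coverable))
    raise AssertionError("unreachable: full set always covers the coverable genes")
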