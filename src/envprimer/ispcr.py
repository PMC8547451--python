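"""IUPAC expansion and in silico PCR under the exact-match rule.

A degenerate primer encodes a set of plain-ACGT oligos (its expansions);
a qPCR well ultimately contains those plain oligos, so amplification is
evaluated per expanded pair.  A pair is predicted to amplify a template
when the forward primer matches the template exactly (100 %, no
mismatches) and the reverse primer's reverse complement matches exactly
downstream, with the product length inside the allowed range.  Both
template orientations are scanned, since gene collections do not guarantee
a deposition strand; ``N`` in a template never matches any primer base.

The pairwise results are collected in a boolean primer-pair × gene
:class:`CoverageMatrix`, from which per-cluster targeting rates (covered /
cluster size, %) are derived.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqio import IUPAC_TO_BASES, reverse_complement

__all__ = [
    "PrimerPair",
    "Amplicon",
    "CoverageMatrix",
    "expand_iupac",
    "degeneracy",
    "expand_primer_pairs",
    "find_amplicons",
    "build_coverage_matrix",
    "targeting_rates",
]


@dataclass(frozen=True)
class PrimerPair:
    """A fully nondegenerate primer pair ready for in silico PCR."""

    pair_id: str
    fwd: str
    rev: str
    parent_id: str = ""

    def __post_init__(self) -> None:
        for seq in (self.fwd, self.rev):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(
                    f"pair {self.pair_id!r}: primers must be nonempty plain ACGT"
                )


@dataclass(frozen=True)
class Amplicon:
    """A predicted product: half-open [start, end) on the given template."""

    template_id: str
    start: int
    end: int
    orientation: str  # "sense" | "antisense"

    @property
    def length(self) -> int:
        return self.end - self.start


def _base_sets(seq: str) -> list[str]:
    sets = []
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_TO_BASES:
            raise ValueError(f"invalid IUPAC code {ch!r} at position {pos}")
        sets.append(IUPAC_TO_BASES[ch])
    return sets


def degeneracy(seq: str) -> int:
    """Number of plain-ACGT sequences an IUPAC string encodes."""
    if not seq:
        raise ValueError("empty sequence")
    n = 1
    for bases in _base_sets(seq):
        n *= len(bases)
    return n


def expand_iupac(seq: str) -> set[str]:
    """All plain-ACGT expansions of an IUPAC string (cartesian product)."""
    if not seq:
        raise ValueError("empty sequence")
    return {"".join(combo) for combo in itertools.product(*_base_sets(seq))}


def expand_primer_pairs(pairs) -> list[PrimerPair]:
    """Expand degenerate pairs to nondegenerate ones, deduplicated globally.

    ``pairs`` is any iterable of objects exposing a pair id and degenerate
    forward/reverse sequences (design output or published-primer records).
    Each pair contributes the cross product of its forward and reverse
    expansions; duplicates on (fwd, rev) across the whole collection keep
    only their first occurrence.  Expanded ids are the parent id plus an
    ordinal suffix following lexicographic (fwd, rev) order.
    """
    expanded: list[PrimerPair] = []
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        parent, fwd_deg, rev_deg = _pair_fields(pair)
        combos = sorted(
            (f, r)
            for f in expand_iupac(fwd_deg)
            for r in expand_iupac(rev_deg)
        )
        for ordinal, (f, r) in enumerate(combos, start=1):
            if (f, r) in seen:
                continue
            seen.add((f, r))
            expanded.append(
                PrimerPair(pair_id=f"{parent}.{ordinal}", fwd=f, rev=r, parent_id=parent)
            )
    return expanded


def total_expansion_count(pairs) -> int:
    """Pre-deduplication expansion count: Σ degeneracy(F)·degeneracy(R)."""
    return sum(
        degeneracy(f) * degeneracy(r) for _, f, r in map(_pair_fields, pairs)
    )


def _pair_fields(pair) -> tuple[str, str, str]:
    if hasattr(pair, "fwd_seq"):
        return pair.pair_id, pair.fwd_seq, pair.rev_seq
    if hasattr(pair, "forward_seq"):
        return pair.pair_id, pair.forward_seq, pair.reverse_seq
    return pair.pair_id, pair.fwd, pair.rev


def _scan_one_strand(
    fwd: str, rev: str, template: str, product_len_range: tuple[int, int]
) -> list[tuple[int, int]]:
    """All (start, end) with fwd exact at start and revcomp(rev) ending at end."""
    lo, hi = product_len_range
    rc_rev = reverse_complement(rev)
    fwd_sites = _find_all(template, fwd)
    rev_sites = _find_all(template, rc_rev)
    out = []
    for i in fwd_sites:
        for j in rev_sites:
            if j < i + len(fwd):
                continue
            product = j + len(rc_rev) - i
            if lo <= product <= hi:
                out.append((i, j + len(rc_rev)))
    return out


def _find_all(template: str, pattern: str) -> list[int]:
    sites, i = [], template.find(pattern)
    while i != -1:
        sites.append(i)
        i = template.find(pattern, i + 1)
    return sites


def find_amplicons(
    pair: PrimerPair,
    template: str,
    template_id: str = "",
    product_len_range: tuple[int, int] = (50, 1500),
) -> list[Amplicon]:
    """Predicted products of an exact-match PCR on both template orientations.

    All combinations of forward/reverse binding sites are enumerated;
    products outside ``product_len_range`` are dropped.  Templates may
    contain ``N``, which matches nothing.
    """
    template = template.upper()
    amplicons = [
        Amplicon(template_id, s, e, "sense")
        for s, e in _scan_one_strand(pair.fwd, pair.rev, template, product_len_range)
    ]
    rc = reverse_complement(template)
    n = len(template)
    amplicons += [
        Amplicon(template_id, n - e, n - s, "antisense")
        for s, e in _scan_one_strand(pair.fwd, pair.rev, rc, product_len_range)
    ]
    return sorted(amplicons, key=lambda a: (a.start, a.end, a.orientation))


@dataclass
class CoverageMatrix:
    """Boolean amplification matrix: rows are primer pairs, columns genes."""

    table: pd.DataFrame  # bool, index=pair_ids, columns=gene_ids
    cluster_of_gene: dict[str, str] = field(default_factory=dict)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.columns)

    def covered_by(self, pair_id: str) -> frozenset[str]:
        row = self.table.loc[pair_id]
        return frozenset(row.index[row])

    def write_tsv(self, path: str | Path) -> None:
        self.table.astype(int).to_csv(path, sep="\t", index_label="pair_id")


def build_coverage_matrix(
    pairs: list[PrimerPair],
    genes: list[tuple[str, str]],
    product_len_range: tuple[int, int] = (50, 1500),
    cluster_of_gene: dict[str, str] | None = None,
) -> CoverageMatrix:
    """Evaluate every pair against every gene; cell = amplifies at least once."""
    if not pairs or not genes:
        raise ValueError("coverage matrix needs >= 1 pair and >= 1 gene")
    data = {
        gene_id: [
            bool(find_amplicons(p, seq, gene_id, product_len_range)) for p in pairs
        ]
        for gene_id, seq in genes
    }
    table = pd.DataFrame(data, index=[p.pair_id for p in pairs], dtype=bool)
    return CoverageMatrix(table=table, cluster_of_gene=dict(cluster_of_gene or {}))


def targeting_rates(
    matrix: CoverageMatrix, selected_pair_ids: list[str] | None = None
) -> tuple[dict[str, tuple[int, int, float]], tuple[int, int, float]]:
    """Per-cluster and overall targeting rates of a primer selection.

    The targeting rate of a cluster is the number of its genes amplified by
    at least one selected pair, divided by the cluster size, in percent
    (2 decimals).  Genes without a cluster label are grouped under
    ``"unassigned"``.  Returns ``(per_cluster, overall)`` with entries
    ``(covered, total, percent)``.
    """
    sub = matrix.table if selected_pair_ids is None else matrix.table.loc[selected_pair_ids]
    gene_hit = sub.any(axis=0)
    per_cluster: dict[str, list[str]] = {}
    for gene in matrix.gene_ids:
        label = matrix.cluster_of_gene.get(gene, "unassigned")
        per_cluster.setdefault(label, []).append(gene)
    rates = {}
    for label in sorted(per_cluster):
        members = per_cluster[label]
        covered = int(sum(gene_hit[g] for g in members))
        rates[label] = (covered, len(members), round(100.0 * covered / len(members), 2))
    total = len(matrix.gene_ids)
    covered_all = int(gene_hit.sum())
    return rates, (covered_all, total, round(100.0 * covered_all / total, 2))


def write_rate_report(
    rates: dict[str, tuple[int, int, float]],
    overall: tuple[int, int, float],
    path: str | Path,
) -> None:
    """Per-cluster targeting-rate TSV with a final overall row."""
    with open(path, "w") as fh:
        fh.write("cluster\tcovered\ttotal\ttargeting_rate_pct\n")
        for label, (cov, tot, pct) in rates.items():
            fh.write(f"{label}\t{cov}\t{tot}\t{pct:.2f}\n")
        fh.write(f"overall\t{overall[0]}\t{overall[1]}\t{overall[2]:.2f}\n")
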