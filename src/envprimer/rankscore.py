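"""Metagenome-weighted ranking of cluster representatives (the R-score).

Each cluster representative is scored by how strongly its gene family shows
up in a set of reference metagenomes.  Read alignments against the
representatives are filtered to high-identity hits (>= 97 % by default) and
reduced to one best hit per read per metagenome; from the retained hits two
statistics are computed per representative:

* **abundance** — total number of retained read hits across all metagenomes;
* **prevalence** — number of distinct metagenomes with at least one hit.

Both are min–max normalized to [0, 1] across representatives and averaged
into the representation score ``r_score = (norm_abundance +
norm_prevalence) / 2``.  Clusters are then taken in descending R-score order
until their cumulative score reaches a user fraction (80 % by default) of
the total — those clusters' member genes become the primer-design targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .cluster import Cluster
from .seqio import AlignmentHit, NtAaMap


@dataclass(frozen=True)
class HitFilterParams:
    """Thresholds deciding which alignment hits count as observations.

    ``min_aln_fraction_of_read`` is only enforceable when the read length is
    known (hit tables do not carry it); pass ``read_length`` to
    :func:`filter_and_assign` to activate it.
    """

    min_identity: float = 97.0
    min_aln_fraction_of_read: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if not 0.0 <= self.min_aln_fraction_of_read <= 1.0:
            raise ValueError("min_aln_fraction_of_read must be in [0, 1]")


@dataclass
class ClusterRank:
    rep_id: str
    abundance: int
    prevalence: int
    norm_abundance: float
    norm_prevalence: float
    r_score: float


def filter_and_assign(
    hits: list[AlignmentHit],
    params: HitFilterParams,
    read_length: int | None = None,
) -> list[AlignmentHit]:
    """Identity-filter hits and keep one best hit per read per metagenome.

    A hit survives if ``pct_identity >= min_identity`` (and, when
    ``read_length`` is given, if the alignment spans at least
    ``min_aln_fraction_of_read`` of the read).  Among a read's surviving
    hits within one metagenome only the highest-bitscore hit is kept, ties
    going to the lexicographically smallest subject — so no read is counted
    twice.  The same read id in different metagenomes is independent.
    """
    min_aln = (
        params.min_aln_fraction_of_read * read_length
        if read_length is not None
        else None
    )
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        if hit.pct_identity < params.min_identity:
            continue
        if min_aln is not None and hit.aln_length < min_aln:
            continue
        key = (hit.metagenome_id, hit.query_id)
        cur = best.get(key)
        if (
            cur is None
            or hit.bitscore > cur.bitscore
            or (hit.bitscore == cur.bitscore and hit.subject_id < cur.subject_id)
        ):
            best[key] = hit
    return [best[k] for k in sorted(best)]


def abundance_prevalence(
    filtered_hits: list[AlignmentHit],
    reps: list[str],
    metagenomes: list[str],
) -> dict[str, tuple[int, int]]:
    """Per-representative (abundance, prevalence) from filtered hits.

    Representatives with no hits get (0, 0).  A hit whose subject is not in
    ``reps`` is an error: it means the hits were produced against a
    different representative set than the one being ranked.
    """
    if not reps:
        raise ValueError("representative list must be nonempty")
    rep_set = set(reps)
    mg_set = set(metagenomes)
    counts: dict[str, int] = {r: 0 for r in reps}
    seen_mgs: dict[str, set[str]] = {r: set() for r in reps}
    for hit in filtered_hits:
        if hit.subject_id not in rep_set:
            raise ValueError(
                f"hit subject {hit.subject_id!r} is not a known representative; "
                "hits and clustering disagree"
            )
        if hit.metagenome_id not in mg_set:
            raise ValueError(f"unknown metagenome id {hit.metagenome_id!r}")
        counts[hit.subject_id] += 1
        seen_mgs[hit.subject_id].add(hit.metagenome_id)
    return {r: (counts[r], len(seen_mgs[r])) for r in reps}


def _minmax(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        # A statistic that is constant across reps carries no ranking signal;
        # treating everyone as maximal keeps R-score's "mean of two [0,1]
        # terms" reading and avoids zeroing out uniformly-observed genes.
        return [1.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def r_scores(stats: dict[str, tuple[int, int]]) -> list[ClusterRank]:
    """Min–max normalize abundance and prevalence; R-score is their mean."""
    if not stats:
        raise ValueError("need at least one representative")
    reps = list(stats)
    norm_ab = _minmax([float(stats[r][0]) for r in reps])
    norm_pr = _minmax([float(stats[r][1]) for r in reps])
    return [
        ClusterRank(
            rep_id=r,
            abundance=stats[r][0],
            prevalence=stats[r][1],
            norm_abundance=na,
            norm_prevalence=np_,
            r_score=(na + np_) / 2.0,
        )
        for r, na, np_ in zip(reps, norm_ab, norm_pr)
    ]


def select_clusters(
    ranks: list[ClusterRank],
    clusters: list[Cluster],
    nt_aa_map: NtAaMap,
    cum_threshold: float = 0.8,
) -> tuple[list[Cluster], list[str]]:
    """Take top clusters by R-score until the cumulative-score fraction is met.

    Clusters are sorted by descending R-score (ties by ascending rep id) and
    included until the running sum of scores reaches ``cum_threshold`` times
    the total; the crossing cluster is included.  Returns the selected
    clusters and their member genes mapped back to nucleotide ids.
    """
    if not 0.0 < cum_threshold <= 1.0:
        raise ValueError("cum_threshold must be in (0, 1]")
    total = sum(r.r_score for r in ranks)
    if total == 0.0:
        raise ValueError(
            "all R-scores are zero: no representative was observed in the references"
        )
    by_rep = {c.rep_id: c for c in clusters}
    ordered = sorted(ranks, key=lambda r: (-r.r_score, r.rep_id))
    selected: list[Cluster] = []
    cum = 0.0
    for rank in ordered:
        selected.append(by_rep[rank.rep_id])
        cum += rank.r_score
        if cum >= cum_threshold * total - 1e-12:
            break
    gene_ids = [
        nt_id
        for cl in selected
        for aa_id in sorted(cl.member_ids)
        for nt_id in sorted(nt_aa_map.nt_for(aa_id))
    ]
    return selected, gene_ids


def write_rank_table(ranks: list[ClusterRank], path: str | Path) -> None:
    """Export ranked representatives as TSV, including the cumulative share."""
    ordered = sorted(ranks, key=lambda r: (-r.r_score, r.rep_id))
    total = sum(r.r_score for r in ordered) or 1.0
    cum = 0.0
    with open(path, "w") as fh:
        fh.write(
            "rep_id\tabundance\tprevalence\tnorm_abundance\tnorm_prevalence"
            "\tr_score\tcumulative_share\n"
        )
        for r in ordered:
            cum += r.r_score
            fh.write(
                f"{r.rep_id}\t{r.abundance}\t{r.prevalence}\t"
                f"{r.norm_abundance:.6f}\t{r.norm_prevalence:.6f}\t"
                f"{r.r_score:.6f}\t{cum / total:.6f}\n"
            )
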