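"""Greedy identity clustering of protein sequences and threshold selection.

Candidate target genes usually arrive as hundreds of near-identical protein
sequences.  Clustering them at an amino-acid identity threshold collapses
the redundancy to one representative per cluster, and sweeping that
threshold (80–100 %, 1 % steps by default) exposes where the family's
internal structure breaks apart: the threshold at which the cluster count
rises fastest — the argmax of the symmetric first-order difference of the
clusters-versus-threshold curve — is recommended as the operating point.

The clustering itself is greedy incremental in the longest-first style of
CD-HIT: sequences are inserted in order of decreasing length, each joining
the first existing cluster whose representative it matches at or above the
threshold, otherwise founding a new cluster.  Identity between two proteins
is counted on the optimal global alignment (BLOSUM62, gap open 11 /
extend 1) and divided by the length of the shorter sequence — the CD-HIT
convention, which makes a perfect fragment 100 % identical to its parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Cluster",
    "ClusterSweep",
    "pairwise_identity",
    "greedy_cluster",
    "sweep_thresholds",
    "recommend_threshold",
    "write_sweep_tsv",
]


@dataclass
class Cluster:
    """One identity cluster: the representative and all member protein ids."""

    rep_id: str
    member_ids: list[str]


@dataclass
class ClusterSweep:
    """Cluster counts across a threshold sweep, with per-threshold partitions."""

    thresholds: list[float]
    n_clusters: list[int]
    clusters_by_threshold: dict[float, list[Cluster]]

    def clusters_at(self, threshold: float) -> list[Cluster]:
        return self.clusters_by_threshold[threshold]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two protein sequences.

    Identical positions in the optimal global alignment, divided by the
    length of the shorter sequence, times 100.  The shorter-sequence
    denominator means a subsequence that aligns perfectly scores 100.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two nonempty sequences")
    if a == b:
        return 100.0
    alignment = _ALIGNER.align(a, b)[0]
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        matches += sum(
            1 for x, y in zip(a[a_start:a_end], b[b_start:b_end]) if x == y
        )
    return 100.0 * matches / min(len(a), len(b))


def greedy_cluster(
    seqs: list[tuple[str, str]], threshold: float
) -> list[Cluster]:
    """Greedy incremental clustering at a percent-identity threshold.

    Sequences are processed longest-first (ties broken by ascending id) and
    each joins the first cluster whose representative it matches at
    ``identity >= threshold``; representatives are cluster founders, so they
    are always the longest member.  The output partitions the input.
    """
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in clustering input")
    by_id = dict(seqs)
    order = sorted(ids, key=lambda i: (-len(by_id[i]), i))
    clusters: list[Cluster] = []
    for seq_id in order:
        seq = by_id[seq_id]
        placed = False
        for cl in clusters:
            if pairwise_identity(seq, by_id[cl.rep_id]) >= threshold:
                cl.member_ids.append(seq_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rep_id=seq_id, member_ids=[seq_id]))
    return clusters


def sweep_thresholds(
    seqs: list[tuple[str, str]],
    lo: float = 80.0,
    hi: float = 100.0,
    step: float = 1.0,
) -> ClusterSweep:
    """Cluster at every threshold in ``lo..hi`` (inclusive, ``step`` apart)."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    thresholds: list[float] = []
    t = lo
    while t <= hi + 1e-9:
        thresholds.append(round(t, 6))
        t += step
    by_threshold = {t: greedy_cluster(seqs, t) for t in thresholds}
    return ClusterSweep(
        thresholds=thresholds,
        n_clusters=[len(by_threshold[t]) for t in thresholds],
        clusters_by_threshold=by_threshold,
    )


def recommend_threshold(sweep: ClusterSweep) -> float:
    """Threshold maximizing the symmetric first-order difference of the curve.

    For each interior threshold t the difference is
    ``(N(t+step) - N(t-step)) / (2*step)``; the argmax is returned, with
    ties broken toward the lowest threshold.  Needs at least 3 thresholds.
    """
    ts, ns = sweep.thresholds, sweep.n_clusters
    if len(ts) < 3:
        raise ValueError("threshold recommendation needs >= 3 sweep points")
    best_t, best_d = None, None
    for k in range(1, len(ts) - 1):
        d = (ns[k + 1] - ns[k - 1]) / (ts[k + 1] - ts[k - 1])
        if best_d is None or d > best_d:
            best_t, best_d = ts[k], d
    return best_t


def write_sweep_tsv(sweep: ClusterSweep, path: str | Path) -> None:
    """Export the sweep curve as a two-column (threshold, n_clusters) TSV."""
    with open(path, "w") as fh:
        fh.write("threshold\tn_clusters\n")
        for t, n in zip(sweep.thresholds, sweep.n_clusters):
            fh.write(f"{t:g}\t{n}\n")
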