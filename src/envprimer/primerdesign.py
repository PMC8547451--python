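"""Degenerate primer-pair design from clustered nucleotide targets.

For each cluster of target genes the members are put into a multiple
alignment (progressive center-star around the longest member, or a
user-supplied pre-aligned block), and every gap-free window of primer
length is turned into a minimal IUPAC consensus covering the observed
bases.  A window survives if its degeneracy stays within the per-primer
cap (6 by default, mirroring common degenerate-qPCR practice) and if every
one of its plain-ACGT expansions passes the melting-temperature and GC
windows individually — a degenerate primer is synthesized as a mixture, so
its worst oligo matters, not its average.  Surviving upstream windows are
paired with downstream windows when the amplicon each member would yield
lies in the qPCR product range and the two primers' Tm intervals are
compatible.

Consensus windows cover every base observed in the alignment, so by
construction each emitted pair amplifies every cluster member it was
designed on — the in silico PCR stage re-checks exactly that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .seqio import BASES_TO_IUPAC, IUPAC_TO_BASES, reverse_complement
from .thermo import gc_percent, melting_temp
from .ispcr import expand_iupac

logger = logging.getLogger(__name__)

__all__ = [
    "DesignParams",
    "DegeneratePrimerPair",
    "column_consensus",
    "center_star_align",
    "design_primer_pairs",
]


@dataclass(frozen=True)
class DesignParams:
    """Tunable design constraints; defaults suit SYBR-style qPCR assays."""

    primer_len_range: tuple[int, int] = (18, 25)
    product_len_range: tuple[int, int] = (70, 200)
    tm_range: tuple[float, float] = (55.0, 65.0)
    max_tm_gap_within_pair: float = 3.0
    gc_range: tuple[float, float] = (35.0, 65.0)
    max_degeneracy_per_primer: int = 6
    tm_method: str = "nearest_neighbor"
    na_mM: float = 50.0
    #: candidate windows combine combinatorially, so a cluster can admit
    #: thousands of valid pairs; only the top-ranked ones are emitted.
    #: None lifts the cap.
    max_pairs_per_cluster: int | None = 50

    def __post_init__(self) -> None:
        for name in ("primer_len_range", "product_len_range", "tm_range", "gc_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if self.max_degeneracy_per_primer < 1:
            raise ValueError("max_degeneracy_per_primer must be >= 1")


@dataclass
class DegeneratePrimerPair:
    """A designed pair; coordinates are 0-based half-open on the alignment."""

    pair_id: str
    fwd_seq: str
    rev_seq: str  # 5'→3' on the antisense strand
    fwd_start: int
    rev_end: int
    degeneracy_fwd: int
    degeneracy_rev: int
    tm_fwd_range: tuple[float, float]
    tm_rev_range: tuple[float, float]
    cluster_id: str = ""
    n_members_matched: int = 0


def column_consensus(aligned_block: list[str]) -> tuple[str, int]:
    """Minimal IUPAC consensus of equal-length, gap-free aligned strings.

    Per column the smallest IUPAC code covering the union of observed bases
    (IUPAC codes in the input contribute their whole base set) is chosen;
    the returned degeneracy is the product of per-column base-set sizes.
    """
    if not aligned_block:
        raise ValueError("empty alignment block")
    length = len(aligned_block[0])
    if any(len(row) != length for row in aligned_block):
        raise ValueError("alignment block rows have unequal lengths")
    consensus = []
    degeneracy = 1
    for col in range(length):
        bases: set[str] = set()
        for row in aligned_block:
            ch = row[col]
            if ch == "-":
                raise ValueError(f"gap character in alignment block at column {col}")
            if ch not in IUPAC_TO_BASES:
                raise ValueError(f"invalid base {ch!r} at column {col}")
            bases.update(IUPAC_TO_BASES[ch])
        consensus.append(BASES_TO_IUPAC[frozenset(bases)])
        degeneracy *= len(bases)
    return "".join(consensus), degeneracy


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_NT_ALIGNER = _nt_aligner()


def center_star_align(seqs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Progressive center-star multiple alignment of nucleotide sequences.

    The longest sequence (ties → smallest id) is the center; every other
    member is pairwise-aligned to it and the pairwise alignments are merged
    by propagating center gaps, the classic center-star construction.
    Input order is preserved in the output.
    """
    if not seqs:
        raise ValueError("nothing to align")
    if len(seqs) == 1:
        return list(seqs)
    center_id = min(seqs, key=lambda kv: (-len(kv[1]), kv[0]))[0]
    by_id = dict(seqs)
    center = by_id[center_id]

    msa: dict[str, list[str]] = {center_id: list(center)}
    center_row = list(center)  # center with accumulated MSA gaps
    for seq_id, seq in seqs:
        if seq_id == center_id:
            continue
        aln = _NT_ALIGNER.align(center, seq)[0]
        c_gapped, s_gapped = str(aln[0]), str(aln[1])
        center_row, msa = _merge(center_row, msa, seq_id, c_gapped, s_gapped)
    return [(seq_id, "".join(msa[seq_id])) for seq_id, _ in seqs]


def _merge(
    center_row: list[str],
    msa: dict[str, list[str]],
    new_id: str,
    c_gapped: str,
    s_gapped: str,
) -> tuple[list[str], dict[str, list[str]]]:
    """Merge one pairwise (center, new) alignment into the running MSA."""
    new_center: list[str] = []
    new_rows: dict[str, list[str]] = {k: [] for k in msa}
    new_seq_row: list[str] = []
    i = j = 0
    while i < len(center_row) or j < len(c_gapped):
        msa_gap = i < len(center_row) and center_row[i] == "-"
        pw_gap = j < len(c_gapped) and c_gapped[j] == "-"
        if msa_gap:
            # column where the MSA center already has a gap (earlier insertion)
            new_center.append("-")
            for k in msa:
                new_rows[k].append(msa[k][i])
            new_seq_row.append("-")
            i += 1
        elif pw_gap:
            # insertion in the new sequence relative to the center
            new_center.append("-")
            for k in msa:
                new_rows[k].append("-")
            new_seq_row.append(s_gapped[j])
            j += 1
        else:
            new_center.append(center_row[i])
            for k in msa:
                new_rows[k].append(msa[k][i])
            new_seq_row.append(s_gapped[j])
            i += 1
            j += 1
    new_rows[new_id] = new_seq_row
    return new_center, new_rows


def _gapfree_windows(rows: list[str], lo: int, hi: int):
    """Yield (start, length) for windows with no gap in any row."""
    ncol = len(rows[0])
    gap_col = [any(row[c] == "-" for row in rows) for c in range(ncol)]
    for start in range(ncol):
        for length in range(lo, hi + 1):
            end = start + length
            if end > ncol:
                break
            if any(gap_col[start:end]):
                continue
            yield start, end


def _window_ok(consensus: str, deg: int, params: DesignParams) -> tuple[float, float] | None:
    """Tm interval over expansions if the window passes all filters, else None."""
    if deg > params.max_degeneracy_per_primer:
        return None
    tms = []
    for oligo in sorted(expand_iupac(consensus)):
        if not params.gc_range[0] <= gc_percent(oligo) <= params.gc_range[1]:
            return None
        tm = melting_temp(oligo, method=params.tm_method, na_mM=params.na_mM)
        if not params.tm_range[0] <= tm <= params.tm_range[1]:
            return None
        tms.append(tm)
    return (min(tms), max(tms))


def _tm_compatible(
    a: tuple[float, float], b: tuple[float, float], max_gap: float
) -> bool:
    # worst pairing of one expansion from each primer
    return max(a[1] - b[0], b[1] - a[0], 0.0) <= max_gap


def design_primer_pairs(
    targets_by_cluster: dict[str, list[tuple[str, str]]],
    params: DesignParams = DesignParams(),
    prealigned: bool = False,
) -> list[DegeneratePrimerPair]:
    """Design degenerate pairs per cluster of nucleotide target sequences.

    ``targets_by_cluster`` maps a cluster label to its member
    ``(gene_id, nt_seq)`` list; members are center-star aligned unless
    ``prealigned`` says the sequences already carry a common gap structure.
    Emitted pairs are sorted within a cluster by (members matched exactly,
    descending; coordinates ascending) and numbered ``<cluster>_p<k>``.
    A cluster where no window passes the constraints contributes nothing
    (logged as a warning, not an error).
    """
    all_pairs: list[DegeneratePrimerPair] = []
    for cluster_id in sorted(targets_by_cluster):
        members = targets_by_cluster[cluster_id]
        if not members:
            continue
        aligned = list(members) if prealigned else center_star_align(members)
        rows = [seq.upper() for _, seq in aligned]
        candidates = _cluster_candidates(cluster_id, aligned, rows, params)
        if not candidates:
            logger.warning(
                "cluster %s: no primer window satisfies the design constraints",
                cluster_id,
            )
        all_pairs.extend(candidates)
    return all_pairs


def _cluster_candidates(
    cluster_id: str,
    aligned: list[tuple[str, str]],
    rows: list[str],
    params: DesignParams,
) -> list[DegeneratePrimerPair]:
    lo_len, hi_len = params.primer_len_range
    windows = []  # (start, end, consensus, degeneracy, tm_interval)
    for start, end in _gapfree_windows(rows, lo_len, hi_len):
        consensus, deg = column_consensus([r[start:end] for r in rows])
        tm_iv = _window_ok(consensus, deg, params)
        if tm_iv is not None:
            windows.append((start, end, consensus, deg, tm_iv))

    # per-member cumulative non-gap counts, to get true product lengths
    prefix = []
    for row in rows:
        acc, run = [0], 0
        for ch in row:
            run += ch != "-"
            acc.append(run)
        prefix.append(acc)

    lo_prod, hi_prod = params.product_len_range
    raw: list[DegeneratePrimerPair] = []
    for fs, fe, f_cons, f_deg, f_tm in windows:
        for rs, re_, r_cons, r_deg, r_tm in windows:
            if rs < fe:
                continue
            if not _tm_compatible(f_tm, r_tm, params.max_tm_gap_within_pair):
                continue
            member_lens = [p[re_] - p[fs] for p in prefix]
            if any(not lo_prod <= m <= hi_prod for m in member_lens):
                continue
            rev_primer = reverse_complement(r_cons)
            n_match = _count_exact_members(rows, fs, fe, f_cons, rs, re_, r_cons)
            raw.append(
                DegeneratePrimerPair(
                    pair_id="",
                    fwd_seq=f_cons,
                    rev_seq=rev_primer,
                    fwd_start=fs,
                    rev_end=re_,
                    degeneracy_fwd=f_deg,
                    degeneracy_rev=r_deg,
                    tm_fwd_range=f_tm,
                    tm_rev_range=r_tm,
                    cluster_id=cluster_id,
                    n_members_matched=n_match,
                )
            )
    raw.sort(key=lambda p: (-p.n_members_matched, p.fwd_start, p.rev_end))
    if params.max_pairs_per_cluster is not None:
        raw = raw[: params.max_pairs_per_cluster]
    for k, pair in enumerate(raw, start=1):
        pair.pair_id = f"{cluster_id}_p{k}"
    return raw


def _count_exact_members(
    rows: list[str], fs: int, fe: int, f_cons: str, rs: int, re_: int, r_cons: str
) -> int:
    f_exp = expand_iupac(f_cons)
    r_exp = expand_iupac(r_cons)
    return sum(
        1
        for row in rows
        if row[fs:fe] in f_exp and row[rs:re_] in r_exp
    )
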