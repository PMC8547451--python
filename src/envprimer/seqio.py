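"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: FASTA (nucleotide or protein), two-column nucleotide↔protein id
maps, 12-column BLAST/DIAMOND tabular hit files (``-outfmt 6``), and TSV
primer tables.  Parsing is strict: malformed input raises
:class:`FormatError` with the offending line number rather than being
silently skipped, because every downstream count (abundance, prevalence,
coverage) depends on the inputs being exactly what the user thinks they are.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "B", "Z", "U", "*"}
IUPAC_CODES = set("ACGTRYSWKMBDHVN")

#: Maps each IUPAC nucleotide code to the set of plain bases it covers.
IUPAC_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Inverse of :data:`IUPAC_TO_BASES`: frozenset of bases -> minimal code.
BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FormatError(ValueError):
    """A file violated its format contract; message carries file/line context."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) DNA string."""
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise FormatError(f"cannot complement non-IUPAC characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One candidate target gene: nucleotide sequence plus its linked protein."""

    gene_id: str
    nt_seq: str
    aa_id: str
    aa_seq: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if not self.nt_seq:
            raise ValueError(f"gene {self.gene_id!r}: empty nucleotide sequence")


@dataclass(frozen=True)
class AlignmentHit:
    """One read-versus-representative alignment row, tagged with its metagenome."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    bitscore: float
    metagenome_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length {self.aln_length} must be >= 1")
        if not self.metagenome_id:
            raise ValueError("metagenome_id must be nonempty")


@dataclass(frozen=True)
class PrimerPairRecord:
    """A primer pair as exchanged on disk; sequences may carry IUPAC codes.

    ``forward_seq`` is written 5'→3' on the sense strand, ``reverse_seq``
    5'→3' on the antisense strand (the usual bench convention).
    """

    pair_id: str
    forward_seq: str
    reverse_seq: str
    source: str = "designed"
    metadata: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if not seq:
                raise ValueError(f"pair {self.pair_id!r}: empty {label} sequence")
            for pos, ch in enumerate(seq, start=1):
                if ch not in IUPAC_CODES:
                    raise ValueError(
                        f"pair {self.pair_id!r}: non-IUPAC character {ch!r} "
                        f"at position {pos} of {label} primer"
                    )


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Parse a FASTA file into ``[(id, sequence), ...]``.

    The record id is the first whitespace-delimited token of the header line
    (the token aligners put in tabular output).  Sequences are uppercased;
    IUPAC ambiguity codes are legal for DNA.  Duplicate ids, characters
    outside the alphabet, and empty records are hard errors.
    """
    if alphabet == "dna":
        allowed = DNA_ALPHABET | IUPAC_CODES
    elif alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    else:
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")

    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {current_id!r} has no sequence")
        records.append((current_id, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if current_id in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate identifier {current_id!r}")
                seen.add(current_id)
                header_line = lineno
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                seq = line.upper()
                bad = set(seq) - allowed
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: character(s) {sorted(bad)} outside "
                        f"{alphabet} alphabet"
                    )
                if alphabet == "dna" and "U" in seq:
                    raise FormatError(f"{path}:{lineno}: RNA base 'U' not accepted")
                chunks.append(seq)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapping at ``width`` columns."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class NtAaMap:
    """Bidirectional nucleotide-id ↔ protein-id map.

    Several nucleotide genes may share one protein (silent variants), so the
    nt→aa direction is many-to-one; one nucleotide id mapping to two proteins
    is rejected.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.nt_to_aa: dict[str, str] = {}
        self.aa_to_nt: dict[str, list[str]] = {}
        for nt_id, aa_id in pairs:
            if nt_id in self.nt_to_aa:
                raise FormatError(f"nucleotide id {nt_id!r} mapped more than once")
            self.nt_to_aa[nt_id] = aa_id
            self.aa_to_nt.setdefault(aa_id, []).append(nt_id)

    def __len__(self) -> int:
        return len(self.nt_to_aa)

    def aa_for(self, nt_id: str) -> str:
        return self.nt_to_aa[nt_id]

    def nt_for(self, aa_id: str) -> list[str]:
        return self.aa_to_nt[aa_id]


def read_nt_aa_map(path: str | Path) -> NtAaMap:
    """Read a two-column tab-separated nucleotide-id / protein-id file."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0].strip() or not cols[1].strip():
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            pairs.append((cols[0].strip(), cols[1].strip()))
    try:
        return NtAaMap(pairs)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


# qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
_HIT_COLUMNS = 12


def read_hit_table(path: str | Path, metagenome_id: str) -> list[AlignmentHit]:
    """Parse a 12-column BLAST/DIAMOND tabular file into AlignmentHits.

    Only the columns the ranking step consumes (query, subject, identity,
    alignment length, bitscore) are retained; the rest are validated for
    arity but not interpreted.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length = int(cols[3])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            try:
                hits.append(
                    AlignmentHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=pident,
                        aln_length=length,
                        bitscore=bitscore,
                        metagenome_id=metagenome_id,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hit_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write hit rows (dicts with the 12 outfmt-6 keys) as a tabular file."""
    keys = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(row[k]) for k in keys) + "\n")


_PRIMER_REQUIRED = ["pair_id", "forward_seq", "reverse_seq"]


def read_primer_table(path: str | Path) -> list[PrimerPairRecord]:
    """Read a primer TSV with columns pair_id / forward_seq / reverse_seq.

    A header row naming the three required columns is optional; extra columns
    are preserved as opaque metadata.
    """
    path = Path(path)
    records: list[PrimerPairRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        return records
    start = 0
    extra_names: list[str] = []
    if [c.strip() for c in rows[0][:3]] == _PRIMER_REQUIRED:
        extra_names = [c.strip() for c in rows[0][3:]]
        start = 1
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        pair_id, fwd, rev = row[0].strip(), row[1].strip().upper(), row[2].strip().upper()
        extras = tuple(zip(extra_names, (c.strip() for c in row[3:])))
        try:
            records.append(
                PrimerPairRecord(pair_id=pair_id, forward_seq=fwd, reverse_seq=rev,
                                 source="published", metadata=extras)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_primer_table(records: Iterable[PrimerPairRecord], path: str | Path) -> None:
    """Write primer pairs as TSV with a header row; round-trips with the reader."""
    records = list(records)
    extra_names: list[str] = []
    for rec in records:
        for name, _ in rec.metadata:
            if name not in extra_names:
                extra_names.append(name)
    with open(path, "w") as fh:
        fh.write("\t".join(_PRIMER_REQUIRED + extra_names) + "\n")
        for rec in records:
            extras = dict(rec.metadata)
            row = [rec.pair_id, rec.forward_seq, rec.reverse_seq]
            row += [extras.get(name, "") for name in extra_names]
            fh.write("\t".join(row) + "\n")
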