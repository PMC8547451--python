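"""Deterministic synthetic gene families, mock metagenomes, and hit tables.

Real inputs to the pipeline are a curated gene family (hundreds of
nucleotide/protein sequence pairs with clustered subfamily structure) and
large environmental read collections — neither of which is practical to
ship or download in tests.  This module fabricates both with known ground
truth:

* :func:`gen_gene_family` builds a family of protein-coding genes organized
  into subfamilies.  A random ancestor gene is mutated at disjoint codon
  positions to produce subfamily ancestors at a controlled between-subfamily
  amino-acid divergence, and each member gene further mutates its ancestor
  at disjoint positions to a controlled within-subfamily divergence, plus a
  sprinkle of synonymous codon swaps so nucleotide variation exceeds
  amino-acid variation, as in real coding genes.  No in-frame stops are
  introduced.  Realized divergences land within ~2 % of the requested ones
  (rounding to whole codon counts is the only slack).

* :func:`gen_read_set` samples error-free reads uniformly along genes, with
  per-gene per-metagenome planted weights controlling how many reads each
  gene contributes in each metagenome, plus uniform-random background reads
  that match nothing; the realized read counts are returned as truth.

* :func:`gen_hit_table` converts a read set into 12-column tabular hit
  files directly from that truth — the stand-in for running an aligner on
  synthetic data whose alignments are known by construction.

Everything is reproducible bit-for-bit from the seeds carried in
:class:`FamilySpec` and :class:`ReadSetSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .seqio import write_fasta, write_hit_table

__all__ = [
    "FamilySpec",
    "ReadSetSpec",
    "GeneFamily",
    "ReadSet",
    "gen_gene_family",
    "gen_read_set",
    "gen_hit_table",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: amino acid -> codons encoding it (stop codons excluded)
CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    CODONS_FOR_AA.setdefault(aa, []).append(codon)
AMINO_ACIDS = sorted(CODONS_FOR_AA)


@dataclass(frozen=True)
class FamilySpec:
    """Shape of the synthetic gene family."""

    n_subfamilies: int = 3
    genes_per_subfamily: int = 4
    gene_length_nt: int = 450
    within_subfamily_aa_divergence: float = 0.02
    between_subfamily_aa_divergence: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_length_nt % 3:
            raise ValueError("gene_length_nt must be a multiple of 3")
        w, b = self.within_subfamily_aa_divergence, self.between_subfamily_aa_divergence
        for name, d in (("within", w), ("between", b)):
            if not 0.0 <= d <= 0.5:
                raise ValueError(f"{name}-subfamily divergence must be in [0, 0.5]")
        if w >= b and w > 0:
            raise ValueError("within-subfamily divergence must be < between")


@dataclass(frozen=True)
class ReadSetSpec:
    """Shape of the mock metagenome read sets.

    ``weights[g, m]`` is the planted sampling weight of gene ``g`` in
    metagenome ``m``; reads in a metagenome are multinomially split across
    genes in proportion to its weight column, after reserving
    ``background_read_fraction`` of reads for random background.
    """

    weights: tuple  # (n_genes, n_metagenomes) nested tuple of floats
    n_metagenomes: int = 5
    reads_per_metagenome: int = 200
    read_length: int = 90
    background_read_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != self.n_metagenomes:
            raise ValueError("weights must be (n_genes, n_metagenomes)")
        if (w < 0).any():
            raise ValueError("planted weights must be nonnegative")
        if not (w.sum(axis=1) > 0).any():
            raise ValueError("at least one gene must have positive total weight")
        if not 0.0 <= self.background_read_fraction <= 1.0:
            raise ValueError("background_read_fraction must be in [0, 1]")


@dataclass
class GeneFamily:
    nt_records: list[tuple[str, str]]
    aa_records: list[tuple[str, str]]
    nt_aa_pairs: list[tuple[str, str]]
    subfamily_of_gene: dict[str, int]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "nt_fasta": outdir / "genes_nt.fasta",
            "aa_fasta": outdir / "genes_aa.fasta",
            "nt_aa_map": outdir / "nt_aa_map.tsv",
            "truth": outdir / "family_truth.json",
        }
        write_fasta(self.nt_records, paths["nt_fasta"])
        write_fasta(self.aa_records, paths["aa_fasta"])
        with open(paths["nt_aa_map"], "w") as fh:
            for nt_id, aa_id in self.nt_aa_pairs:
                fh.write(f"{nt_id}\t{aa_id}\n")
        with open(paths["truth"], "w") as fh:
            json.dump({"subfamily_of_gene": self.subfamily_of_gene}, fh, indent=1)
        return paths


@dataclass
class ReadSet:
    metagenome_ids: list[str]
    #: metagenome id -> list of (read_id, sequence, source_gene_id | None)
    reads: dict[str, list[tuple[str, str, str | None]]]
    #: realized read counts, genes × metagenomes
    truth_counts: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for mg in self.metagenome_ids:
            path = outdir / f"{mg}.fasta"
            write_fasta([(rid, seq) for rid, seq, _ in self.reads[mg]], path)
            paths[mg] = path
        truth_path = outdir / "read_truth.json"
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "counts": {
                        g: {m: int(self.truth_counts.loc[g, m]) for m in self.metagenome_ids}
                        for g in self.truth_counts.index
                    }
                },
                fh,
                indent=1,
            )
        paths["truth"] = truth_path
        return paths


def _mutate_codon(codon: str, rng: np.random.Generator) -> str:
    """Replace a codon by one encoding a different amino acid (never a stop)."""
    old_aa = _STANDARD.forward_table[codon]
    choices = [aa for aa in AMINO_ACIDS if aa != old_aa]
    new_aa = choices[rng.integers(len(choices))]
    codons = CODONS_FOR_AA[new_aa]
    return codons[rng.integers(len(codons))]


def _synonymous_swap(codon: str, rng: np.random.Generator) -> str:
    aa = _STANDARD.forward_table[codon]
    options = CODONS_FOR_AA[aa]
    return options[rng.integers(len(options))]


def gen_gene_family(spec: FamilySpec) -> GeneFamily:
    """Generate the synthetic family; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    n_codons = spec.gene_length_nt // 3

    # per-gene mutations stack on top of ancestor mutations, so the ancestor
    # share is reduced to keep realized between-gene divergence on target
    k_within = round(spec.within_subfamily_aa_divergence * n_codons / 2)
    k_between = max(
        0,
        round(
            (spec.between_subfamily_aa_divergence
             - spec.within_subfamily_aa_divergence) * n_codons / 2
        ),
    )
    need = spec.n_subfamilies * k_between + (
        spec.n_subfamilies * spec.genes_per_subfamily * k_within
    )
    if need > n_codons:
        raise ValueError(
            "divergence targets unreachable: "
            f"{need} mutated codon positions needed but only {n_codons} available"
        )

    root = []
    for _ in range(n_codons):
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        codons = CODONS_FOR_AA[aa]
        root.append(codons[rng.integers(len(codons))])

    # disjoint mutable positions: first for subfamily ancestors, then per gene
    positions = rng.permutation(n_codons)
    cursor = 0

    nt_records, aa_records, pairs = [], [], []
    subfamily_of_gene: dict[str, int] = {}
    for sf in range(spec.n_subfamilies):
        ancestor = list(root)
        for pos in positions[cursor : cursor + k_between]:
            ancestor[pos] = _mutate_codon(ancestor[pos], rng)
        cursor += k_between
        for g in range(spec.genes_per_subfamily):
            gene = list(ancestor)
            for pos in positions[cursor : cursor + k_within]:
                gene[pos] = _mutate_codon(gene[pos], rng)
            cursor += k_within
            # synonymous-biased extra variation: ~5% of codons swap silently
            for pos in range(n_codons):
                if rng.random() < 0.05:
                    gene[pos] = _synonymous_swap(gene[pos], rng)
            nt_seq = "".join(gene)
            aa_seq = "".join(_STANDARD.forward_table[c] for c in gene)
            gene_id = f"sf{sf + 1}_g{g + 1}"
            aa_id = f"sf{sf + 1}_p{g + 1}"
            nt_records.append((gene_id, nt_seq))
            aa_records.append((aa_id, aa_seq))
            pairs.append((gene_id, aa_id))
            subfamily_of_gene[gene_id] = sf + 1
    return GeneFamily(nt_records, aa_records, pairs, subfamily_of_gene)


_BASES = np.array(list("ACGT"))


def gen_read_set(genes: list[tuple[str, str]], spec: ReadSetSpec) -> ReadSet:
    """Sample planted reads plus background from the weight matrix."""
    weights = np.asarray(spec.weights, dtype=float)
    if weights.shape[0] != len(genes):
        raise ValueError(
            f"weights have {weights.shape[0]} gene rows but {len(genes)} genes given"
        )
    for gene_id, seq in genes:
        if spec.read_length > len(seq):
            raise ValueError(
                f"read_length {spec.read_length} exceeds gene {gene_id!r} "
                f"length {len(seq)}"
            )
    rng = np.random.default_rng(spec.seed)
    metagenome_ids = [f"mg{m + 1}" for m in range(spec.n_metagenomes)]
    gene_ids = [g for g, _ in genes]
    seq_of = dict(genes)
    counts = pd.DataFrame(0, index=gene_ids, columns=metagenome_ids, dtype=int)
    reads: dict[str, list[tuple[str, str, str | None]]] = {}

    for m, mg in enumerate(metagenome_ids):
        n_bg = int(round(spec.background_read_fraction * spec.reads_per_metagenome))
        n_planted = spec.reads_per_metagenome - n_bg
        col = weights[:, m]
        if col.sum() > 0 and n_planted > 0:
            per_gene = rng.multinomial(n_planted, col / col.sum())
        else:
            per_gene = np.zeros(len(genes), dtype=int)
            n_bg = spec.reads_per_metagenome
        entries: list[tuple[str, str, str | None]] = []
        k = 0
        for g_idx, gene_id in enumerate(gene_ids):
            seq = seq_of[gene_id]
            for _ in range(int(per_gene[g_idx])):
                start = int(rng.integers(0, len(seq) - spec.read_length + 1))
                entries.append(
                    (f"{mg}_r{k + 1}", seq[start : start + spec.read_length], gene_id)
                )
                k += 1
            counts.loc[gene_id, mg] = int(per_gene[g_idx])
        for _ in range(n_bg):
            bg = "".join(_BASES[rng.integers(0, 4, size=spec.read_length)])
            entries.append((f"{mg}_r{k + 1}", bg, None))
            k += 1
        reads[mg] = entries
    return ReadSet(metagenome_ids, reads, counts)


def gen_hit_table(
    read_set: ReadSet,
    rep_of_gene: dict[str, str],
    noise: float = 0.0,
    seed: int = 0,
) -> dict[str, list[dict]]:
    """Emit outfmt-6 rows from the read set's ground truth.

    Every planted read produces one hit against the representative of its
    source gene with identity ``100·(1 − noise)`` jittered by ±0.5 (capped
    at 100); background reads produce nothing.  Returns rows keyed by
    metagenome id, ready for :func:`envprimer.seqio.write_hit_table`.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tables: dict[str, list[dict]] = {}
    for mg in read_set.metagenome_ids:
        rows = []
        for read_id, seq, source in read_set.reads[mg]:
            if source is None:
                continue
            pident = min(100.0, 100.0 * (1.0 - noise) + rng.uniform(-0.5, 0.5))
            aln_aa = max(1, len(seq) // 3)
            bitscore = round(2.0 * aln_aa * pident / 100.0, 1)
            rows.append(
                {
                    "qseqid": read_id,
                    "sseqid": rep_of_gene[source],
                    "pident": f"{pident:.1f}",
                    "length": aln_aa,
                    "mismatch": int(round(noise * aln_aa)),
                    "gapopen": 0,
                    "qstart": 1,
                    "qend": len(seq),
                    "sstart": 1,
                    "send": aln_aa,
                    "evalue": "1e-30",
                    "bitscore": bitscore,
                }
            )
        tables[mg] = rows
    return tables


def write_hit_tables(
    tables: dict[str, list[dict]], outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for mg, rows in tables.items():
        path = outdir / f"{mg}.hits.tsv"
        write_hit_table(rows, path)
        paths[mg] = path
    return paths
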