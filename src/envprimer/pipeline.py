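"""End-to-end orchestration: cluster → rank → design → evaluate → cover.

Each stage reads the artifacts of the previous stage from the run
directory, writes its own TSV/FASTA artifacts plus a JSON manifest
(parameter values and SHA-256 of inputs), and is deterministic: rerunning a
stage on identical inputs reproduces its outputs byte for byte.  The stage
functions are plain library calls so the shell interface in
:mod:`envprimer.cli` stays thin.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import cover as _cover
from . import ispcr as _ispcr
from . import primerdesign as _design
from . import rankscore as _rank
from . import seqio

__all__ = [
    "RunConfig",
    "run_cluster",
    "run_rank",
    "run_design",
    "run_evaluate",
    "run_cover",
    "run_all",
    "compare_published",
]


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    nt_fasta: Path
    aa_fasta: Path
    nt_aa_map: Path
    hit_dir: Path
    outdir: Path
    sweep_lo: float = 80.0
    sweep_hi: float = 100.0
    sweep_step: float = 1.0
    threshold: float | None = None  # None → use recommendation
    hit_filter: _rank.HitFilterParams = field(default_factory=_rank.HitFilterParams)
    cum_threshold: float = 0.8
    design: _design.DesignParams = field(default_factory=_design.DesignParams)
    published_product_len_range: tuple[int, int] = (50, 1500)

    def __post_init__(self) -> None:
        for name in ("nt_fasta", "aa_fasta", "nt_aa_map", "hit_dir", "outdir"):
            setattr(self, name, Path(getattr(self, name)))

    def validate_inputs(self) -> None:
        for name in ("nt_fasta", "aa_fasta", "nt_aa_map", "hit_dir"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, inputs: list[Path], params: dict) -> None:
    manifest = {
        "stage": stage,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "params": params,
    }
    with open(cfg.outdir / f"{stage}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{produced_by}' stage first"
        )
    return path


def run_cluster(cfg: RunConfig) -> dict:
    """Sweep clustering thresholds, pick one, persist the chosen partition."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    proteins = seqio.read_fasta(cfg.aa_fasta, alphabet="protein")
    sweep = _cluster.sweep_thresholds(proteins, cfg.sweep_lo, cfg.sweep_hi, cfg.sweep_step)
    recommended = _cluster.recommend_threshold(sweep)
    chosen = cfg.threshold if cfg.threshold is not None else recommended
    clusters = sweep.clusters_at(chosen)

    _cluster.write_sweep_tsv(sweep, cfg.outdir / "sweep.tsv")
    with open(cfg.outdir / "clusters.tsv", "w") as fh:
        fh.write("rep_id\tn_members\tmember_ids\n")
        for cl in clusters:
            fh.write(f"{cl.rep_id}\t{len(cl.member_ids)}\t{','.join(sorted(cl.member_ids))}\n")
    _write_manifest(
        cfg, "cluster", [cfg.aa_fasta],
        {"lo": cfg.sweep_lo, "hi": cfg.sweep_hi, "step": cfg.sweep_step,
         "recommended": recommended, "chosen": chosen},
    )
    return {"recommended_threshold": recommended, "chosen_threshold": chosen,
            "n_clusters": len(clusters), "clusters": clusters, "sweep": sweep}


def _load_clusters(cfg: RunConfig) -> list[_cluster.Cluster]:
    path = _require(cfg.outdir / "clusters.tsv", "cluster")
    clusters = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rep, _, members = line.rstrip("\n").split("\t")
            clusters.append(_cluster.Cluster(rep, members.split(",")))
    return clusters


def run_rank(cfg: RunConfig) -> dict:
    """Score clusters against the reference hit tables and pick target genes."""
    clusters = _load_clusters(cfg)
    hit_files = sorted(cfg.hit_dir.glob("*.tsv"))
    if not hit_files:
        raise FileNotFoundError(f"no .tsv hit tables found in {cfg.hit_dir}")
    metagenomes = [p.name.removesuffix(".hits.tsv").removesuffix(".tsv") for p in hit_files]
    hits = []
    for mg, path in zip(metagenomes, hit_files):
        hits.extend(seqio.read_hit_table(path, metagenome_id=mg))

    filtered = _rank.filter_and_assign(hits, cfg.hit_filter)
    reps = [cl.rep_id for cl in clusters]
    stats = _rank.abundance_prevalence(filtered, reps, metagenomes)
    ranks = _rank.r_scores(stats)
    nt_aa = seqio.read_nt_aa_map(cfg.nt_aa_map)
    selected, gene_ids = _rank.select_clusters(ranks, clusters, nt_aa, cfg.cum_threshold)

    _rank.write_rank_table(ranks, cfg.outdir / "rank.tsv")
    with open(cfg.outdir / "selected_clusters.tsv", "w") as fh:
        fh.write("rep_id\tnt_gene_ids\n")
        for cl in selected:
            members = sorted(
                nt_id for aa in cl.member_ids for nt_id in nt_aa.nt_for(aa)
            )
            fh.write(f"{cl.rep_id}\t{','.join(members)}\n")
    _write_manifest(
        cfg, "rank", [cfg.nt_aa_map, *hit_files],
        {"min_identity": cfg.hit_filter.min_identity,
         "cum_threshold": cfg.cum_threshold},
    )
    return {"ranks": ranks, "selected": selected, "gene_ids": gene_ids}


def _load_selection(cfg: RunConfig) -> dict[str, list[str]]:
    path = _require(cfg.outdir / "selected_clusters.tsv", "rank")
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            rep, genes = line.rstrip("\n").split("\t")
            out[rep] = genes.split(",")
    return out

_DESIGN_COLUMNS = [
    "pair_id", "forward_seq", "reverse_seq", "cluster", "fwd_start", "rev_end",
    "degeneracy_fwd", "degeneracy_rev", "tm_fwd_min", "tm_fwd_max",
    "tm_rev_min", "tm_rev_max", "n_members_matched",
]


def run_design(cfg: RunConfig) -> dict:
    """Design degenerate pairs for every selected cluster."""
    selection = _load_selection(cfg)
    nt = dict(seqio.read_fasta(cfg.nt_fasta, alphabet="dna"))
    targets = {rep: [(g, nt[g]) for g in genes] for rep, genes in selection.items()}
    pairs = _design.design_primer_pairs(targets, cfg.design)
    rows = [
        {
            "pair_id": p.pair_id, "forward_seq": p.fwd_seq, "reverse_seq": p.rev_seq,
            "cluster": p.cluster_id, "fwd_start": p.fwd_start, "rev_end": p.rev_end,
            "degeneracy_fwd": p.degeneracy_fwd, "degeneracy_rev": p.degeneracy_rev,
            "tm_fwd_min": f"{p.tm_fwd_range[0]:.2f}", "tm_fwd_max": f"{p.tm_fwd_range[1]:.2f}",
            "tm_rev_min": f"{p.tm_rev_range[0]:.2f}", "tm_rev_max": f"{p.tm_rev_range[1]:.2f}",
            "n_members_matched": p.n_members_matched,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_DESIGN_COLUMNS).to_csv(
        cfg.outdir / "designed_pairs.tsv", sep="\t", index=False
    )
    _write_manifest(cfg, "design", [cfg.nt_fasta, cfg.outdir / "selected_clusters.tsv"],
                    asdict(cfg.design))
    return {"pairs": pairs}


def _load_designed(cfg: RunConfig) -> pd.DataFrame:
    path = _require(cfg.outdir / "designed_pairs.tsv", "design")
    return pd.read_csv(path, sep="\t", dtype={"pair_id": str, "cluster": str})


def run_evaluate(cfg: RunConfig) -> dict:
    """Expand designed pairs and run in silico PCR against the target genes."""
    designed = _load_designed(cfg)
    selection = _load_selection(cfg)
    nt = dict(seqio.read_fasta(cfg.nt_fasta, alphabet="dna"))
    deg_pairs = [
        seqio.PrimerPairRecord(r.pair_id, r.forward_seq, r.reverse_seq)
        for r in designed.itertuples()
    ]
    expanded = _ispcr.expand_primer_pairs(deg_pairs)
    n_pre_dedup = _ispcr.total_expansion_count(deg_pairs)

    cluster_of_gene = {g: rep for rep, genes in selection.items() for g in genes}
    genes = [(g, nt[g]) for g in sorted(cluster_of_gene)]
    matrix = _ispcr.build_coverage_matrix(
        expanded, genes, cfg.design.product_len_range, cluster_of_gene
    )
    rates, overall = _ispcr.targeting_rates(matrix)

    seqio.write_primer_table(
        [seqio.PrimerPairRecord(p.pair_id, p.fwd, p.rev) for p in expanded],
        cfg.outdir / "expanded_pairs.tsv",
    )
    matrix.write_tsv(cfg.outdir / "coverage.tsv")
    _ispcr.write_rate_report(rates, overall, cfg.outdir / "rate_report.tsv")
    _write_manifest(
        cfg, "evaluate",
        [cfg.outdir / "designed_pairs.tsv", cfg.nt_fasta],
        {"product_len_range": list(cfg.design.product_len_range),
         "n_expanded_pre_dedup": n_pre_dedup,
         "n_expanded_dedup": len(expanded)},
    )
    return {"expanded": expanded, "n_pre_dedup": n_pre_dedup,
            "matrix": matrix, "rates": rates, "overall": overall}


def _load_matrix(cfg: RunConfig) -> _ispcr.CoverageMatrix:
    path = _require(cfg.outdir / "coverage.tsv", "evaluate")
    table = pd.read_csv(path, sep="\t", index_col="pair_id").astype(bool)
    selection = _load_selection(cfg)
    cluster_of_gene = {g: rep for rep, genes in selection.items() for g in genes}
    return _ispcr.CoverageMatrix(table=table, cluster_of_gene=cluster_of_gene)


def run_cover(cfg: RunConfig) -> dict:
    """Reduce the evaluated pairs to a minimal panel and report its rates."""
    matrix = _load_matrix(cfg)
    expanded = {
        rec.pair_id: rec
        for rec in seqio.read_primer_table(_require(cfg.outdir / "expanded_pairs.tsv", "evaluate"))
    }
    solution = _cover.greedy_min_cover(matrix)
    rates, overall = _ispcr.targeting_rates(matrix, solution.selected_pair_ids)

    seqio.write_primer_table(
        [
            seqio.PrimerPairRecord(pid, expanded[pid].forward_seq, expanded[pid].reverse_seq)
            for pid in solution.selected_pair_ids
        ],
        cfg.outdir / "final_primers.tsv",
    )
    cov_sets = {pid: matrix.covered_by(pid) for pid in solution.selected_pair_ids}
    with open(cfg.outdir / "provenance.tsv", "w") as fh:
        fh.write("pair_id\tuniquely_covered_genes\n")
        for pid in solution.selected_pair_ids:
            others = set().union(
                *(cov_sets[q] for q in solution.selected_pair_ids if q != pid), set()
            )
            unique = sorted(cov_sets[pid] - others)
            fh.write(f"{pid}\t{','.join(unique)}\n")
    _ispcr.write_rate_report(rates, overall, cfg.outdir / "final_rate_report.tsv")
    _write_manifest(cfg, "cover", [cfg.outdir / "coverage.tsv"], {})
    return {"solution": solution, "rates": rates, "overall": overall}


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in order; returns the merged stage results."""
    cfg.validate_inputs()
    out = {}
    out.update(run_cluster(cfg))
    out.update(run_rank(cfg))
    out.update(run_design(cfg))
    out.update(run_evaluate(cfg))
    out.update(run_cover(cfg))
    return out


def compare_published(
    cfg: RunConfig, published_tsv: Path, out_path: Path | None = None
) -> pd.DataFrame:
    """Side-by-side per-cluster targeting rates: designed panel vs published.

    Published degenerate primers are fully expanded to nondegenerate form
    and evaluated under the same exact-match in silico PCR, but with the
    wide published-primer product window, since external pairs were not
    designed against this run's product range.
    """
    matrix = _load_matrix(cfg)
    final = seqio.read_primer_table(_require(cfg.outdir / "final_primers.tsv", "cover"))
    designed_rates, designed_overall = _ispcr.targeting_rates(
        matrix, [rec.pair_id for rec in final]
    )

    published = seqio.read_primer_table(published_tsv)
    expanded_pub = _ispcr.expand_primer_pairs(published)
    selection = _load_selection(cfg)
    cluster_of_gene = {g: rep for rep, genes in selection.items() for g in genes}
    nt = dict(seqio.read_fasta(cfg.nt_fasta, alphabet="dna"))
    genes = [(g, nt[g]) for g in sorted(cluster_of_gene)]
    pub_matrix = _ispcr.build_coverage_matrix(
        expanded_pub, genes, cfg.published_product_len_range, cluster_of_gene
    )
    pub_rates, pub_overall = _ispcr.targeting_rates(pub_matrix)

    rows = []
    for label in sorted(designed_rates):
        d_cov, d_tot, d_pct = designed_rates[label]
        p_cov, _, p_pct = pub_rates.get(label, (0, d_tot, 0.0))
        rows.append(
            {"cluster": label, "n_genes": d_tot,
             "published_covered": p_cov, "published_rate_pct": p_pct,
             "designed_covered": d_cov, "designed_rate_pct": d_pct}
        )
    rows.append(
        {"cluster": "overall", "n_genes": designed_overall[1],
         "published_covered": pub_overall[0], "published_rate_pct": pub_overall[2],
         "designed_covered": designed_overall[0], "designed_rate_pct": designed_overall[2]}
    )
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False, float_format="%.2f")
    return df
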