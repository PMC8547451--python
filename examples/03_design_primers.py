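"""Design degenerate qPCR primer pairs for one cluster of target genes.

Aligns the four member genes of a subfamily, enumerates conserved windows,
and emits degenerate primer pairs under the default constraints (18-25 nt,
70-200 bp product, Tm 55-65 degC, GC 35-65 %, degeneracy <= 6).
"""

from envprimer import DesignParams, design_primer_pairs, gen_gene_family
from envprimer.synthfix import FamilySpec

family = gen_gene_family(FamilySpec(seed=7))
cluster_members = family.nt_records[0:4]

pairs = design_primer_pairs({"sf1": cluster_members}, DesignParams())
print(f"designed {len(pairs)} candidate pairs; top 5:")
for p in pairs[:5]:
    print(f"  {p.pair_id}: F={p.fwd_seq} R={p.rev_seq} "
          f"deg={p.degeneracy_fwd}x{p.degeneracy_rev} "
          f"Tm_F=[{p.tm_fwd_range[0]:.1f},{p.tm_fwd_range[1]:.1f}] "
          f"members={p.n_members_matched}/4")
# Degeneracy 1x1 means a fully conserved window; a 2-fold code (R, Y, ...)
# appears where members disagree at one column.  Every emitted pair
# amplifies all four members it was designed on.
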