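"""Shared fixtures: one synthetic gene family and read set reused session-wide.

The family has 3 subfamilies of 4 genes (150 aa each) at ~2 % within- and
~30 % between-subfamily amino-acid divergence; the read set plants a strong
abundance/prevalence skew: subfamily 1 in all 5 metagenomes at high weight,
subfamily 2 in 3, subfamily 3 in 1 at low weight.
"""

from __future__ import annotations

import numpy as np
import pytest

from envprimer.synthfix import (
    FamilySpec,
    ReadSetSpec,
    gen_gene_family,
    gen_hit_table,
    gen_read_set,
)

FAMILY_SEED = 7


@pytest.fixture(scope="session")
def family_spec() -> FamilySpec:
    return FamilySpec(seed=FAMILY_SEED)


@pytest.fixture(scope="session")
def family(family_spec):
    return gen_gene_family(family_spec)


def skewed_weights(n_genes: int = 12, n_metagenomes: int = 5) -> np.ndarray:
    """Planted weights: sf1 everywhere/strong, sf2 in 3 mgs, sf3 in 1/weak."""
    w = np.zeros((n_genes, n_metagenomes))
    w[0:4, :] = 5.0
    w[4:8, 0:3] = 2.0
    w[8:12, 0:1] = 0.5
    return w


@pytest.fixture(scope="session")
def read_spec() -> ReadSetSpec:
    return ReadSetSpec(
        weights=tuple(map(tuple, skewed_weights())),
        n_metagenomes=5,
        reads_per_metagenome=200,
        read_length=90,
        background_read_fraction=0.1,
        seed=FAMILY_SEED + 2,
    )


@pytest.fixture(scope="session")
def read_set(family, read_spec):
    return gen_read_set(family.nt_records, read_spec)


@pytest.fixture(scope="session")
def rep_of_gene(family) -> dict[str, str]:
    """Subfamily representative = lexicographically smallest protein id
    (all proteins share one length, matching the clustering tie-break)."""
    aa_of = {g: a for (g, _), (a, _) in zip(family.nt_records, family.aa_records)}
    reps: dict[int, str] = {}
    for gene_id, sf in family.subfamily_of_gene.items():
        reps[sf] = min(reps.get(sf, aa_of[gene_id]), aa_of[gene_id])
    return {g: reps[sf] for g, sf in family.subfamily_of_gene.items()}


@pytest.fixture(scope="session")
def hit_tables(read_set, rep_of_gene):
    return gen_hit_table(read_set, rep_of_gene, noise=0.0, seed=FAMILY_SEED + 3)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, family, read_set, hit_tables):
    """The whole fixture written to disk in the formats the pipeline reads."""
    from envprimer.synthfix import write_hit_tables

    root = tmp_path_factory.mktemp("fixture")
    family.write(root)
    read_set.write(root / "reads")
    write_hit_tables(hit_tables, root / "hits")
    return root
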