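"""IUPAC expansion, exact-match in silico PCR, and coverage accounting."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from envprimer.ispcr import (
    PrimerPair,
    build_coverage_matrix,
    degeneracy,
    expand_iupac,
    expand_primer_pairs,
    find_amplicons,
    targeting_rates,
    total_expansion_count,
)
from envprimer.seqio import IUPAC_TO_BASES, PrimerPairRecord

IUPAC = "ACGTRYSWKMBDHVN"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestExpansion:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ATG", {"ATG"}), ("ARG", {"AAG", "AGG"}), ("ACGT", {"ACGT"})],
    )
    def test_examples(self, seq, expected):
        assert expand_iupac(seq) == expected

    @pytest.mark.parametrize("seq, deg", [("ACGT", 1), ("RY", 4), ("NRB", 24), ("NN", 16)])
    def test_degeneracy_examples(self, seq, deg):
        assert degeneracy(seq) == deg
        assert len(expand_iupac(seq)) == deg

    def test_cardinality_exhaustive_up_to_length_4(self):
        for n in range(1, 5):
            for combo in itertools.product(IUPAC, repeat=n):
                seq = "".join(combo)
                expansions = expand_iupac(seq)
                assert len(expansions) == degeneracy(seq)
                assert all(set(e) <= set("ACGT") for e in expansions)
                # every expansion respects its column's base set
                for e in expansions:
                    assert all(b in IUPAC_TO_BASES[c] for b, c in zip(e, seq))

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.text(alphabet=IUPAC, min_size=1, max_size=8))
    def test_cardinality_random_strings(self, seq):
        assert len(expand_iupac(seq)) == degeneracy(seq)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            expand_iupac("ACXG")
        with pytest.raises(ValueError):
            degeneracy("")


class TestExpandPrimerPairs:
    def test_small_cross_product(self):
        pairs = expand_primer_pairs([PrimerPairRecord("p", "AR", "C")])
        assert {(p.fwd, p.rev) for p in pairs} == {("AA", "C"), ("AG", "C")}
        assert [p.pair_id for p in pairs] == ["p.1", "p.2"]

    def test_random_pairs_count_equals_sum_of_products(self):
        rng = random.Random(23)
        parents = [
            PrimerPairRecord(
                f"p{i}",
                "".join(rng.choices(IUPAC, k=rng.randint(3, 6))),
                "".join(rng.choices(IUPAC, k=rng.randint(3, 6))),
            )
            for i in range(30)
        ]
        expanded = expand_primer_pairs(parents)
        brute = {
            (f, r)
            for p in parents
            for f in expand_iupac(p.forward_seq)
            for r in expand_iupac(p.reverse_seq)
        }
        assert {(p.fwd, p.rev) for p in expanded} == brute
        assert len(expanded) <= total_expansion_count(parents)
        assert total_expansion_count(parents) == sum(
            degeneracy(p.forward_seq) * degeneracy(p.reverse_seq) for p in parents
        )

    def test_global_deduplication(self):
        a = PrimerPairRecord("a", "ACGT", "TTTT")
        b = PrimerPairRecord("b", "ACGT", "TTTT")
        expanded = expand_primer_pairs([a, b])
        assert len(expanded) == 1
        assert expanded[0].parent_id == "a"
        assert total_expansion_count([a, b]) == 2


def naive_amplicons(fwd, rev, template, bounds):
    """All-positions/all-orientations scan checking characters directly.

    The antisense pass checks complement matching against the original
    template in place, a different route from the implementation's
    reverse-complemented rescan.
    """
    lo, hi = bounds
    out = set()

    def eq(sub, pat):
        return len(sub) == len(pat) and all(x == y for x, y in zip(sub, pat))

    rc_rev = "".join(_COMP.get(b, "?") for b in reversed(rev))
    for i in range(len(template)):
        if not eq(template[i : i + len(fwd)], fwd):
            continue
        for j in range(i + len(fwd), len(template)):
            if eq(template[j : j + len(rc_rev)], rc_rev):
                length = j + len(rc_rev) - i
                if lo <= length <= hi:
                    out.add((i, j + len(rc_rev), "sense"))
    # antisense: fwd anneals to the reverse strand; on the given string this
    # means revcomp(fwd) appears downstream of rev
    rc_fwd = "".join(_COMP.get(b, "?") for b in reversed(fwd))
    for i in range(len(template)):
        if not eq(template[i : i + len(rev)], rev):
            continue
        for j in range(i + len(rev), len(template)):
            if eq(template[j : j + len(rc_fwd)], rc_fwd):
                length = j + len(rc_fwd) - i
                if lo <= length <= hi:
                    out.add((i, j + len(rc_fwd), "antisense"))
    return out


class TestFindAmplicons:
    def test_constructed_sense_product(self):
        fwd, rev = "AAACC", "GGGAA"
        from envprimer.seqio import reverse_complement

        template = fwd + "T" * 20 + reverse_complement(rev)
        (amp,) = find_amplicons(PrimerPair("p", fwd, rev), template, "t", (10, 100))
        assert (amp.start, amp.end, amp.orientation) == (0, 30, "sense")
        assert amp.length == 30

    def test_single_mismatch_kills_amplification(self):
        fwd, rev = "AAACC", "GGGAA"
        from envprimer.seqio import reverse_complement

        template = "AAACG" + "T" * 20 + reverse_complement(rev)
        assert find_amplicons(PrimerPair("p", fwd, rev), template, "t", (10, 100)) == []

    def test_n_in_template_never_matches(self):
        template = "AANCC" + "T" * 20 + "TTCCC"
        assert find_amplicons(PrimerPair("p", "AAACC", "GGGAA"), template, "t", (10, 100)) == []

    def test_multiple_forward_sites_give_multiple_products(self):
        from envprimer.seqio import reverse_complement

        fwd, rev = "ACGTA", "GGGAA"
        rc = reverse_complement(rev)
        template = fwd + "T" * 5 + fwd + "T" * 5 + rc
        amps = find_amplicons(PrimerPair("p", fwd, rev), template, "t", (5, 100))
        assert len(amps) == 2

    def test_matches_naive_scanner_on_random_instances(self):
        rng = random.Random(31)
        n_nonempty = 0
        for _ in range(200):
            template = "".join(rng.choices("ACGTN", weights=[10, 10, 10, 10, 1],
                                           k=rng.randint(50, 400)))
            if rng.random() < 0.6:
                # plant primers so matching cases actually occur
                k = rng.randint(4, 8)
                i = rng.randint(0, len(template) - 2 * k - 10)
                j = rng.randint(i + k + 5, len(template) - k)
                fwd = template[i : i + k].replace("N", "A")
                rc_rev = template[j : j + k].replace("N", "A")
                rev = "".join(_COMP[b] for b in reversed(rc_rev))
                template = template[:i] + fwd + template[i + k : j] + rc_rev + template[j + k :]
            else:
                fwd = "".join(rng.choices("ACGT", k=rng.randint(4, 8)))
                rev = "".join(rng.choices("ACGT", k=rng.randint(4, 8)))
            bounds = (rng.randint(5, 30), rng.randint(40, 500))
            got = {
                (a.start, a.end, a.orientation)
                for a in find_amplicons(PrimerPair("p", fwd, rev), template, "t", bounds)
            }
            assert got == naive_amplicons(fwd, rev, template, bounds)
            n_nonempty += bool(got)
        assert n_nonempty > 20  # the comparison exercised real matches


class TestCoverage:
    def make_matrix(self):
        from envprimer.seqio import reverse_complement

        genes = {
            "g1": "AAACC" + "T" * 20 + reverse_complement("GGGAA"),
            "g2": "AAACC" + "C" * 20 + reverse_complement("GGGAA"),
            "g3": "C" * 40,
        }
        pairs = [
            PrimerPair("pA", "AAACC", "GGGAA"),
            PrimerPair("pB", "C" * 5, "G" * 5),
        ]
        labels = {"g1": "c1", "g2": "c1", "g3": "c2"}
        return build_coverage_matrix(pairs, sorted(genes.items()), (10, 100), labels)

    def test_matrix_matches_hand_truth(self):
        m = self.make_matrix()
        assert m.covered_by("pA") == {"g1", "g2"}
        assert m.covered_by("pB") == {"g2", "g3"}

    def test_primer_longer_than_template_is_uncovered(self):
        m = build_coverage_matrix(
            [PrimerPair("p", "A" * 30, "T" * 30)], [("g", "A" * 20)], (10, 100)
        )
        assert not m.table.loc["p", "g"]

    def test_targeting_rates_and_monotonicity(self):
        m = self.make_matrix()
        rates_all, overall_all = targeting_rates(m)
        assert rates_all["c1"] == (2, 2, 100.0)
        assert overall_all == (3, 3, 100.0)
        rates_one, overall_one = targeting_rates(m, ["pA"])
        assert rates_one["c1"] == (2, 2, 100.0)
        assert rates_one["c2"] == (0, 1, 0.0)
        # adding a pair never decreases any rate
        for label in rates_all:
            assert rates_all[label][2] >= rates_one[label][2]
        assert overall_all[2] >= overall_one[2]

    def test_rate_rounding_two_decimals(self):
        from envprimer.seqio import reverse_complement

        amplifiable = "AAACC" + "T" * 20 + reverse_complement("GGGAA")
        genes = [("g1", amplifiable), ("g2", amplifiable), ("g3", "C" * 40)]
        m = build_coverage_matrix(
            [PrimerPair("p", "AAACC", "GGGAA")], genes, (10, 100),
            {g: "c" for g, _ in genes},
        )
        rates, overall = targeting_rates(m)
        assert rates["c"] == (2, 3, 66.67)
        assert overall == (2, 3, 66.67)
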