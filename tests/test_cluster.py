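"""Protein identity, greedy clustering, and threshold recommendation."""

import random

import pytest
from Bio.Align import substitution_matrices

from envprimer.cluster import (
    Cluster,
    ClusterSweep,
    greedy_cluster,
    pairwise_identity,
    recommend_threshold,
    sweep_thresholds,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 11.0, 1.0


def exhaustive_identity_counts(a: str, b: str) -> set[int]:
    """Identity counts over ALL maximum-score global alignments of a and b.

    Enumerates every monotone alignment path recursively (tiny inputs only),
    scoring with BLOSUM62 and affine gaps (open 11, extend 1).  Serves as
    the independent oracle for the alignment-based identity convention.
    """
    best: dict[str, float] = {"score": float("-inf")}
    results: dict[float, set[int]] = {}

    def rec(i, j, score, idents, last):
        if i == len(a) and j == len(b):
            results.setdefault(score, set()).add(idents)
            best["score"] = max(best["score"], score)
            return
        if i < len(a) and j < len(b):
            s = BLOSUM62[a[i], b[j]]
            rec(i + 1, j + 1, score + s, idents + (a[i] == b[j]), "M")
        if i < len(a):
            cost = GAP_EXTEND if last == "X" else GAP_OPEN + GAP_EXTEND
            rec(i + 1, j, score - cost, idents, "X")
        if j < len(b):
            cost = GAP_EXTEND if last == "Y" else GAP_OPEN + GAP_EXTEND
            rec(i, j + 1, score - cost, idents, "Y")

    rec(0, 0, 0.0, 0, "M")
    return results[best["score"]]


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGT", "ACGT") == 100.0

    def test_single_substitution(self):
        assert pairwise_identity("ACGT", "ACGA") == 75.0

    def test_prefix_scores_full_identity_by_shorter_denominator(self):
        # the optimal alignment matches all 3 residues of the shorter string
        assert 3 in exhaustive_identity_counts("MKVLA", "MKV")
        assert pairwise_identity("MKVLA", "MKV") == 100.0

    def test_agrees_with_exhaustive_alignment_oracle(self):
        rng = random.Random(11)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            a = "".join(rng.choices(aas, k=rng.randint(2, 5)))
            b = "".join(rng.choices(aas, k=rng.randint(2, 5)))
            allowed = {
                100.0 * n / min(len(a), len(b))
                for n in exhaustive_identity_counts(a, b)
            }
            assert pairwise_identity(a, b) in [pytest.approx(v) for v in allowed]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")


def reference_greedy(seqs, threshold):
    """Step-by-step reference of the insertion procedure, coded separately."""
    by_id = dict(seqs)
    pending = sorted(by_id, key=lambda i: (-len(by_id[i]), i))
    clusters: list[list[str]] = []
    for sid in pending:
        for members in clusters:
            if pairwise_identity(by_id[sid], by_id[members[0]]) >= threshold:
                members.append(sid)
                break
        else:
            clusters.append([sid])
    return [Cluster(m[0], m) for m in clusters]


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        seqs = [("a", "MKVLA"), ("b", "MKVLA"), ("c", "MKVLA")]
        clusters = greedy_cluster(seqs, 99.0)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["a", "b", "c"]
        assert clusters[0].rep_id == "a"

    def test_threshold_splits_known_identity_pair(self):
        # 9/10 identical positions -> identity exactly 90
        a, b = "MKVLAWYEDQ", "MKVLAWYEDA"
        assert pairwise_identity(a, b) == 90.0
        assert len(greedy_cluster([("a", a), ("b", b)], 95.0)) == 2
        assert len(greedy_cluster([("a", a), ("b", b)], 85.0)) == 1

    def test_matches_reference_implementation_on_family(self, family):
        for threshold in (85.0, 96.0, 99.0):
            ours = greedy_cluster(family.aa_records, threshold)
            ref = reference_greedy(family.aa_records, threshold)
            assert [(c.rep_id, sorted(c.member_ids)) for c in ours] == [
                (c.rep_id, sorted(c.member_ids)) for c in ref
            ]

    def test_partitions_input_at_every_threshold(self, family):
        ids = {i for i, _ in family.aa_records}
        for threshold in (80.0, 92.0, 100.0):
            clusters = greedy_cluster(family.aa_records, threshold)
            seen: list[str] = []
            for c in clusters:
                assert c.rep_id in c.member_ids
                seen.extend(c.member_ids)
            assert len(seen) == len(set(seen)) == len(ids)
            assert set(seen) == ids

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([("a", "MKV"), ("a", "MKV")], 90.0)


class TestSweep:
    def test_constant_curves_for_degenerate_inputs(self):
        same = [(f"s{i}", "MKVLAWYEDQMKVLAWYEDQ") for i in range(4)]
        sweep = sweep_thresholds(same, 80, 100, 5)
        assert sweep.n_clusters == [1] * len(sweep.thresholds)

    def test_monotone_nondecreasing_on_family(self, family):
        sweep = sweep_thresholds(family.aa_records, 80, 100, 2)
        assert all(
            a <= b for a, b in zip(sweep.n_clusters, sweep.n_clusters[1:])
        )

    def test_subfamily_structure_steps_from_three(self, family):
        sweep = sweep_thresholds(family.aa_records, 80, 100, 1)
        assert sweep.n_clusters[0] == 3
        assert sweep.n_clusters[-1] == len(family.aa_records)


def brute_force_recommendation(thresholds, counts):
    best_t, best_d = None, None
    for k in range(1, len(thresholds) - 1):
        d = (counts[k + 1] - counts[k - 1]) / (thresholds[k + 1] - thresholds[k - 1])
        if best_d is None or d > best_d:
            best_t, best_d = thresholds[k], d
    return best_t


def make_sweep(thresholds, counts):
    return ClusterSweep(list(thresholds), list(counts), {})


class TestRecommendThreshold:
    def test_constructed_curve_picks_rise_onset(self):
        sweep = make_sweep([94, 95, 96, 97, 98], [10, 10, 12, 40, 41])
        assert recommend_threshold(sweep) == 96

    def test_flat_curve_tie_breaks_to_lowest_interior(self):
        sweep = make_sweep([80, 81, 82, 83], [5, 5, 5, 5])
        assert recommend_threshold(sweep) == 81

    def test_matches_brute_force_on_random_curves(self):
        rng = random.Random(3)
        for _ in range(100):
            n = rng.randint(3, 21)
            thresholds = list(range(80, 80 + n))
            counts = sorted(rng.randint(1, 200) for _ in range(n))
            sweep = make_sweep(thresholds, counts)
            assert recommend_threshold(sweep) == brute_force_recommendation(
                thresholds, counts
            )

    def test_short_sweep_rejected(self):
        with pytest.raises(ValueError):
            recommend_threshold(make_sweep([80, 81], [1, 2]))
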