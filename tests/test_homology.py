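import numpy as np
import pytest

from mirhunt.homology import (
    MatureQuery,
    collapse_redundant,
    dereplicate_queries,
    queries_from_records,
    scan,
)
from mirhunt.io_formats import SequenceRecord, reverse_complement

from conftest import random_rna


def brute_force_scan(queries, ests, max_mismatches):
    """Independent double loop over every window and both strands."""
    found = set()
    for est in ests:
        for strand in "+-":
            seq = est.residues if strand == "+" else reverse_complement(est.residues)
            n = len(seq)
            for q in queries:
                L = len(q.residues)
                for s in range(n - L + 1):
                    window = seq[s:s + L]
                    mm = sum(
                        1 for a, b in zip(q.residues, window)
                        if a != b or a == "N" or b == "N"
                    )
                    if mm <= max_mismatches:
                        start0 = s if strand == "+" else n - s - L
                        found.add((q.id, est.id, strand, start0 + 1, start0 + L, mm))
    return found


def as_tuples(hits):
    return {(h.query_id, h.est_id, h.strand, h.est_start, h.est_end, h.mismatches)
            for h in hits}


def make_query(qid, residues):
    return MatureQuery(id=qid, family="miRtest", residues=residues)


class TestDereplicate:
    def test_identical_matures_merge_with_aliases(self):
        seq = "UGACAGAAGAGAGUGAGCAC"
        qs = [make_query("osa-miR156a", seq), make_query("ath-miR156a", seq)]
        out = dereplicate_queries(qs)
        assert len(out) == 1
        assert out[0].id == "ath-miR156a"  # lexicographically smallest id
        assert out[0].aliases == ("osa-miR156a",)

    def test_unique_set_unchanged(self, rng):
        qs = [make_query(f"q{i}", random_rna(rng, 21)) for i in range(5)]
        assert len(dereplicate_queries(qs)) == 5

    def test_cardinality_with_planted_duplicates(self, rng):
        uniques = [random_rna(rng, 21) for _ in range(40)]
        qs = [make_query(f"q{i:03d}", s) for i, s in enumerate(uniques)]
        k = 7
        qs += [make_query(f"dup{i}", uniques[i]) for i in range(k)]
        assert len(dereplicate_queries(qs)) == len(qs) - k


class TestScan:
    def test_verbatim_plant_found_at_zero_mismatches(self, rng):
        q = make_query("q1", random_rna(rng, 21))
        flank5, flank3 = random_rna(rng, 50), random_rna(rng, 50)
        est = SequenceRecord("e1", "", flank5 + q.residues + flank3)
        hits = [h for h in scan([q], [est], 4) if h.mismatches == 0]
        assert any(h.est_start == 51 and h.est_end == 71 and h.strand == "+"
                   for h in hits)

    @pytest.mark.parametrize("n_subs,expect_hit", [(4, True), (5, False)])
    def test_mismatch_budget_boundary(self, rng, n_subs, expect_hit):
        base = random_rna(rng, 22)
        q = make_query("q1", base)
        mutated = list(base)
        for p in rng.choice(22, size=n_subs, replace=False):
            mutated[p] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[p]]
        est = SequenceRecord("e1", "", random_rna(rng, 30) + "".join(mutated)
                             + random_rna(rng, 30))
        hits = scan([q], [est], 4)
        relevant = [h for h in hits if h.strand == "+" and h.est_start == 31]
        assert bool(relevant) == expect_hit

    def test_equals_brute_force_oracle(self, rng):
        queries = [make_query(f"q{i:02d}", random_rna(rng, int(rng.integers(18, 25))))
                   for i in range(10)]
        ests = [SequenceRecord(f"e{i:02d}", "",
                               random_rna(rng, int(rng.integers(25, 120)), "ACGUN"))
                for i in range(20)]
        # plant a couple of near-matches so the hit set is non-trivial
        e = ests[0].residues
        ests[0] = SequenceRecord("e00", "", e[:5] + queries[0].residues + e[5:])
        ests[1] = SequenceRecord(
            "e01", "", reverse_complement(queries[1].residues) + ests[1].residues)
        for budget in range(0, 5):
            assert as_tuples(scan(queries, ests, budget)) == \
                brute_force_scan(queries, ests, budget)

    def test_strand_symmetry(self, rng):
        queries = [make_query(f"q{i}", random_rna(rng, 20)) for i in range(3)]
        ests = [SequenceRecord(f"e{i}", "", random_rna(rng, 60)) for i in range(5)]
        ests[0] = SequenceRecord("e0", "", ests[0].residues + queries[0].residues)
        flipped = [SequenceRecord(e.id, "", reverse_complement(e.residues))
                   for e in ests]
        orig = {(h.query_id, h.est_id, h.strand, h.mismatches, h.matched_subsequence)
                for h in scan(queries, ests, 4)}
        swap = {(h.query_id, h.est_id, {"+": "-", "-": "+"}[h.strand], h.mismatches,
                 h.matched_subsequence)
                for h in scan(queries, flipped, 4)}
        assert orig == swap

    def test_monotone_in_budget(self, rng):
        queries = [make_query("q0", random_rna(rng, 19))]
        ests = [SequenceRecord(f"e{i}", "", random_rna(rng, 200)) for i in range(5)]
        previous = set()
        for budget in range(0, 8):
            current = as_tuples(scan(queries, ests, budget))
            assert previous <= current
            previous = current

    def test_query_longer_than_est_is_no_hit(self, rng):
        q = make_query("q1", random_rna(rng, 24))
        est = SequenceRecord("tiny", "", random_rna(rng, 10))
        assert scan([q], [est], 4) == []

    def test_n_positions_never_match(self):
        q = make_query("q1", "AUGCAUGCAUGCAUGCAUGC")
        est = SequenceRecord("e1", "", "AUGCAUGCAUGCAUGCAUGN")
        (hit,) = [h for h in scan([q], [est], 4) if h.strand == "+"]
        assert hit.mismatches == 1


class TestCollapseRedundant:
    def test_same_sequence_two_accessions_collapse(self, rng):
        q = make_query("q1", random_rna(rng, 21))
        body = random_rna(rng, 80) + q.residues + random_rna(rng, 80)
        ests = [SequenceRecord("accA", "", body), SequenceRecord("accB", "", body)]
        hits = scan([q], ests, 0)
        reps = collapse_redundant(hits, ests)
        assert len({h.est_id for h in reps}) == 1
        assert reps[0].est_id == "accA"  # tie on length -> smallest id

    def test_unrelated_ests_stay_separate(self, rng):
        q = make_query("q1", random_rna(rng, 21))
        ests = [
            SequenceRecord("e1", "", random_rna(rng, 80) + q.residues + random_rna(rng, 80)),
            SequenceRecord("e2", "", random_rna(rng, 80) + q.residues + random_rna(rng, 80)),
        ]
        hits = [h for h in scan([q], ests, 0) if h.strand == "+"]
        assert len(collapse_redundant(hits, ests)) == 2

    def test_clusters_by_identity(self, rng):
        q = make_query("q1", random_rna(rng, 21))
        body = random_rna(rng, 100) + q.residues + random_rna(rng, 100)
        # three near-copies at ~96% identity and one diverged relative
        def mutate(seq, n):
            out = list(seq)
            # never touch the planted mature, so every copy still hits
            positions = rng.choice(100, size=n, replace=False)
            for p in positions:
                out[p] = {"A": "C", "C": "A", "G": "U", "U": "G"}[out[p]]
            return "".join(out)

        ests = [
            SequenceRecord("c1", "", body),
            SequenceRecord("c2", "", mutate(body, 8)),
            SequenceRecord("c3", "", mutate(body, 8)),
            SequenceRecord("c4", "", mutate(body, 70)),
        ]
        hits = [h for h in scan([q], ests, 4) if h.strand == "+"]
        reps = collapse_redundant(hits, ests, identity_threshold=0.95)
        rep_ids = {h.est_id for h in reps}
        assert "c4" in rep_ids
        assert len(rep_ids) == 2

    def test_empty_hits(self):
        assert collapse_redundant([], []) == []
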