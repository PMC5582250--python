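import numpy as np
import pytest

from mirhunt import folding
from mirhunt.io_formats import RunConfig, SequenceRecord, ValidationError, reverse_complement
from mirhunt.screen import find_tandem_repeats, structural_criteria
from mirhunt.synthetic import (
    PlantSpec,
    benchmark_collection,
    make_est_collection,
    make_precursor,
    make_target_transcripts,
)

from conftest import random_rna


class TestMakePrecursor:
    def test_perfect_hairpin_dimensions_and_full_pairing(self, mature_record):
        spec = PlantSpec(query_id=mature_record.id, n_mutations=0,
                         duplex_mismatches=0, loop_len=8)
        rec, truth = make_precursor(mature_record, spec, rng_seed=3)
        assert len(rec.residues) == 21 + 8 + 21 + 2
        structure = folding.fold(rec.residues)
        partner = structure.partner_array()
        mature = partner[truth.mature_start:truth.mature_end]
        assert (mature >= 0).all()  # every mature position paired

    def test_hamming_distance_to_query_is_exact(self, mature_record):
        for n_mut in range(5):
            spec = PlantSpec(query_id=mature_record.id, n_mutations=n_mut)
            _, truth = make_precursor(mature_record, spec, rng_seed=n_mut)
            d = sum(a != b for a, b in
                    zip(truth.mature_seq, mature_record.residues))
            assert d == n_mut

    def test_same_seed_is_identical(self, mature_record):
        spec = PlantSpec(query_id=mature_record.id, n_mutations=2,
                         duplex_mismatches=2)
        a = make_precursor(mature_record, spec, rng_seed=42)
        b = make_precursor(mature_record, spec, rng_seed=42)
        assert a[0].residues == b[0].residues and a[1] == b[1]

    def test_invalid_spec_rejected(self, mature_record):
        with pytest.raises(ValidationError):
            make_precursor(
                mature_record,
                PlantSpec(query_id=mature_record.id, loop_len=2), 0)
        with pytest.raises(ValidationError):
            make_precursor(
                mature_record,
                PlantSpec(query_id=mature_record.id, n_mutations=9), 0)

    def test_planted_precursors_pass_structural_screen(self, rng):
        # over many random in-threshold specs the construction must yield
        # hairpins whose folded structure satisfies the structural criteria
        cfg = RunConfig()
        failures = 0
        for k in range(50):
            mature = SequenceRecord(f"syn-miR{k}", "", random_rna(rng, int(rng.integers(20, 23))))
            spec = PlantSpec(
                query_id=mature.id,
                n_mutations=int(rng.integers(0, 5)),
                arm="5p" if rng.integers(2) == 0 else "3p",
                loop_len=int(rng.integers(8, 17)),
                duplex_mismatches=int(rng.integers(0, 4)),
            )
            _, truth = make_precursor(mature, spec, rng_seed=1000 + k)
            structure = folding.fold(truth.core_seq)
            feats = folding.extract_hairpin(
                structure, (truth.mature_start, truth.mature_end))
            if not all(structural_criteria(feats, cfg).values()):
                failures += 1
        assert failures == 0


class TestMakeEstCollection:
    def test_single_plant_no_background(self, mature_record):
        spec = PlantSpec(query_id=mature_record.id)
        ests, truth = make_est_collection(0, [spec], 0, 0, 1, [mature_record])
        assert len(ests) == 1 and len(truth) == 1
        t = truth[0]
        planted_window = ests[0].residues[t.mature_start:t.mature_end]
        assert planted_window == t.plant.mature_seq

    def test_background_gc_within_binomial_bound(self, mature_record):
        ests, _ = make_est_collection(100, [], 0, 0, 2, [],
                                      background_gc=40.0)
        residues = "".join(e.residues for e in ests)
        gc = 100 * sum(c in "GC" for c in residues) / len(residues)
        assert abs(gc - 40.0) < 3.0

    def test_minus_strand_plant_contains_reverse_complement(self, mature_record):
        spec = PlantSpec(query_id=mature_record.id, strand="-", n_mutations=0)
        ests, truth = make_est_collection(0, [spec], 0, 0, 3, [mature_record])
        t = truth[0]
        assert t.strand == "-"
        window = ests[0].residues[t.mature_start:t.mature_end]
        assert reverse_complement(window) == t.plant.mature_seq

    def test_decoys_have_their_signals(self, mature_record):
        from mirhunt.coding import is_protein_coding
        ests, truth = make_est_collection(0, [], 3, 3, 4, [])
        kinds = {t.est_id: t.kind for t in truth}
        for est in ests:
            if kinds[est.id] == "coding":
                assert is_protein_coding(est, 80)[0]
            elif kinds[est.id] == "repeat":
                runs = find_tandem_repeats(est.residues, min_span=24)
                assert runs, "repeat decoy must contain a >=24 nt tandem run"

    def test_truth_table_is_complete(self):
        queries, ests, truth, specs = benchmark_collection(5, n_plants=6,
                                                           n_background=10,
                                                           n_coding_decoys=2,
                                                           n_repeat_decoys=2)
        assert sum(t.kind == "precursor" for t in truth) == 6
        assert sum(t.kind == "coding" for t in truth) == 2
        assert sum(t.kind == "repeat" for t in truth) == 2
        assert len(ests) == 20
        est_ids = {e.id for e in ests}
        assert all(t.est_id in est_ids for t in truth)


class TestMakeTargetTranscripts:
    def test_perfect_site_truth_zero(self, mature_record):
        records, truths = make_target_transcripts(
            mature_record, [(0, 0, 0, False)], rng_seed=1)
        (t,) = truths
        assert t.expectation == 0.0 and t.mode == "cleavage"
        site = records[0].residues[t.site_start - 1:t.site_end]
        assert site == reverse_complement(mature_record.residues)

    def test_mismatch_plus_wobble_outside_seed(self, mature_record):
        _, truths = make_target_transcripts(
            mature_record, [(1, 1, 0, False)], rng_seed=2)
        assert truths[0].expectation == 1.5
        assert all(p not in range(2, 14) for p in truths[0].mirna_positions)

    def test_seed_mismatch_doubled(self, mature_record):
        _, truths = make_target_transcripts(
            mature_record, [(1, 0, 0, True)], rng_seed=3)
        assert truths[0].expectation == 2.0
        assert all(p in range(2, 14) for p in truths[0].mirna_positions)

    def test_deterministic(self, mature_record):
        a = make_target_transcripts(mature_record, [(1, 1, 0, False)], 7)
        b = make_target_transcripts(mature_record, [(1, 1, 0, False)], 7)
        assert a[0][0].residues == b[0][0].residues and a[1] == b[1]
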