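"""Generators: determinism, planted-truth structure, sampling statistics."""

import numpy as np
import pytest

from editmir import (
    make_reference,
    plant_seed_windows,
    plant_sites,
    simulate_pileup,
    simulate_small_rna,
)
from editmir.errors import (
    CapacityError,
    CatalogMismatchError,
    InfeasiblePlantError,
    InvalidParameterError,
    ReferenceMismatchError,
)
from editmir.seed_scan import MiRNA, scan_window

from conftest import random_mirna_catalog


class TestMakeReference:
    def test_deterministic_under_seed(self):
        assert make_reference(1, 1000, 0.5, 7) == make_reference(1, 1000, 0.5, 7)

    def test_zero_gc_is_at_only(self):
        ref = make_reference(2, 201, 0.0, 1)
        assert len(ref) == 2
        for seq in ref.values():
            assert set(seq) <= {"A", "T"}

    def test_gc_fraction_close_to_requested(self):
        # binomial sampling: 3 SD of the mean GC at n=10000 is under 0.02
        seq = make_reference(1, 10000, 0.41, 3)["chr1"]
        gc = sum(b in "GC" for b in seq) / len(seq)
        assert abs(gc - 0.41) <= 0.02

    @pytest.mark.parametrize("args", [(0, 1000, 0.5), (1, 0, 0.5), (1, 100, 0.5), (1, 1000, 1.5)])
    def test_invalid_parameters_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            make_reference(*args, rng_seed=0)


class TestPlantSites:
    def test_sites_disjoint_and_counted(self):
        ref = make_reference(1, 2000, 0.5, 0)
        truth = plant_sites(ref, 10, 5, (0.2, 0.8), 1)
        coords = [(e.seq, e.pos) for e in truth.edit_sites] + [
            (s.seq, s.pos) for s in truth.snp_sites
        ]
        assert len(truth.edit_sites) == 10 and len(truth.snp_sites) == 5
        assert len(set(coords)) == len(coords)

    def test_transcript_sense_reference_base_is_A(self):
        ref = make_reference(2, 1500, 0.41, 3)
        truth = plant_sites(ref, 25, 0, (0.1, 0.9), 4)
        for e in truth.edit_sites:
            base = ref[e.seq][e.pos - 1]
            assert base == ("A" if e.strand == "+" else "T")
            assert 100 < e.pos <= len(ref[e.seq]) - 100
            assert 0.1 <= e.fraction <= 0.9

    def test_empty_request_gives_empty_truth(self):
        ref = make_reference(1, 500, 0.5, 0)
        truth = plant_sites(ref, 0, 0, (0, 1), 1)
        assert truth.edit_sites == [] and truth.snp_sites == []

    def test_capacity_error_without_A_positions(self):
        with pytest.raises(CapacityError):
            plant_sites({"chr1": "C" * 500}, 1, 0, (0.2, 0.8), 1)


class TestSimulatePileup:
    def test_noiseless_pileup_is_all_reference(self):
        ref = make_reference(1, 300, 0.5, 2)
        truth = plant_sites(ref, 0, 0, (0, 1), 0)
        pileup = simulate_pileup(ref, truth, 40, 0.0, 3)
        for row in pileup.itertuples():
            assert getattr(row, f"count_{row.ref}") == row.depth

    def test_full_fraction_edit_forces_all_G(self):
        from editmir.synthetic import PlantedEdit, SyntheticTruth

        ref = {"chr1": "C" * 150 + "A" + "C" * 150}
        truth = SyntheticTruth(edit_sites=[PlantedEdit("chr1", 151, "+", 1.0)])
        pileup = simulate_pileup(ref, truth, (50, 50), 0.0, 1)
        row = pileup[pileup["pos"] == 151].iloc[0]
        assert row["count_G"] == 50 and row["count_A"] == 0 and row["depth"] == 50

    def test_half_fraction_edit_near_half_G(self):
        from editmir.synthetic import PlantedEdit, SyntheticTruth

        ref = {"chr1": "C" * 150 + "A" + "C" * 150}
        truth = SyntheticTruth(edit_sites=[PlantedEdit("chr1", 151, "+", 0.5)])
        pileup = simulate_pileup(ref, truth, (1000, 1000), 0.0, 1)
        row = pileup[pileup["pos"] == 151].iloc[0]
        # binomial: 3 SD of the fraction at depth 1000 is ~0.047
        assert abs(row["count_G"] / row["depth"] - 0.5) <= 0.05

    def test_reverse_strand_edit_reported_as_T_to_C(self):
        from editmir.synthetic import PlantedEdit, SyntheticTruth

        ref = {"chr1": "G" * 150 + "T" + "G" * 150}
        truth = SyntheticTruth(edit_sites=[PlantedEdit("chr1", 151, "-", 1.0)])
        pileup = simulate_pileup(ref, truth, (40, 40), 0.0, 1)
        row = pileup[pileup["pos"] == 151].iloc[0]
        assert row["count_C"] == 40 and row["count_T"] == 0

    def test_unknown_sequence_name_rejected(self):
        from editmir.synthetic import PlantedEdit, SyntheticTruth

        ref = make_reference(1, 300, 0.5, 2)
        truth = SyntheticTruth(edit_sites=[PlantedEdit("chrX", 150, "+", 0.5)])
        with pytest.raises(ReferenceMismatchError):
            simulate_pileup(ref, truth, 30, 0.0, 0)


class TestPlantSeedWindows:
    def test_created_window_is_single_base_consequence(self, catalog):
        pairs, truth = plant_seed_windows(catalog, 1, 0, 0, rng_seed=4)
        (match,) = truth.planted_matches
        pair = pairs[0]
        mir = {m.name: m for m in catalog}[match.mirna]
        assert match.state == "edited"
        assert pair.edited[match.offset : match.offset + 7] == mir.seed_rc
        assert pair.unedited[match.offset : match.offset + 7] != mir.seed_rc
        # the two states differ exactly at the center
        diffs = [i for i, (a, b) in enumerate(zip(pair.unedited, pair.edited)) if a != b]
        assert diffs == [pair.center]

    def test_seed_without_G_cannot_be_created(self):
        no_g = MiRNA(name="mir-noG", accession="X", mature="AAAAAAAAAAAAAAAAAAAAAA")
        assert no_g.seed_rc == "TTTTTTT"
        with pytest.raises(InfeasiblePlantError):
            plant_seed_windows([no_g], 1, 0, 0, rng_seed=1)

    def test_scan_recovers_planted_matches_exactly(self, catalog):
        pairs, truth = plant_seed_windows(catalog, 3, 2, 5, rng_seed=9)
        planted = {(m.window_id, m.mirna, m.offset, m.state) for m in truth.planted_matches}
        seen = set()
        by_seed = {m.seed_rc: m.name for m in catalog}
        lo_hi = lambda c: (c - 6, c)
        for pair in pairs:
            lo, hi = lo_hi(pair.center)
            for seed, name in by_seed.items():
                for state, seq in (("unedited", pair.unedited), ("edited", pair.edited)):
                    for o in scan_window(seq, seed):
                        if lo <= o <= hi:
                            seen.add((pair.window_id, name, o, state))
        assert seen == planted
        assert sum(m.state == "edited" for m in truth.planted_matches) == 3
        assert sum(m.state == "unedited" for m in truth.planted_matches) == 2


class TestSimulateSmallRNA:
    def test_error_free_reads_match_matures(self, catalog):
        reads = simulate_small_rna(catalog, {catalog[0].name: 5}, 0.0, 1)
        assert len(reads) == 5
        assert all(seq == catalog[0].mature_dna for _, seq in reads)

    def test_total_read_count_is_sum_of_abundances(self, catalog):
        reads = simulate_small_rna(
            catalog, {catalog[0].name: 100, catalog[1].name: 0}, 0.0, 2
        )
        assert len(reads) == 100

    def test_error_rate_gives_expected_mismatch_load(self, catalog):
        mir = catalog[0]
        reads = simulate_small_rna(catalog, {mir.name: 10000}, 0.02, 3)
        template = mir.mature_dna
        mm = np.mean(
            [sum(a != b for a, b in zip(seq, template)) for _, seq in reads]
        )
        # per-read mismatches ~ Binomial(22, 0.02): mean 0.44, SE of mean ~0.007
        assert abs(mm - 0.44) <= 0.07

    def test_unknown_mirna_in_abundances_rejected(self, catalog):
        with pytest.raises(CatalogMismatchError):
            simulate_small_rna(catalog, {"mir-unknown": 1}, 0.0, 1)


def test_generators_fully_deterministic():
    ref1 = make_reference(2, 1200, 0.41, 11)
    ref2 = make_reference(2, 1200, 0.41, 11)
    t1 = plant_sites(ref1, 8, 4, (0.2, 0.9), 12)
    t2 = plant_sites(ref2, 8, 4, (0.2, 0.9), 12)
    assert t1.edit_sites == t2.edit_sites and t1.snp_sites == t2.snp_sites
    p1 = simulate_pileup(ref1, t1, 30, 0.01, 13)
    p2 = simulate_pileup(ref2, t2, 30, 0.01, 13)
    assert p1.equals(p2)
    cat = random_mirna_catalog(6, seed=5)
    w1, m1 = plant_seed_windows(cat, 2, 2, 2, rng_seed=14)
    w2, m2 = plant_seed_windows(cat, 2, 2, 2, rng_seed=14)
    assert w1 == w2 and m1.planted_matches == m2.planted_matches
    r1 = simulate_small_rna(cat, {cat[0].name: 10}, 0.05, 15)
    assert r1 == simulate_small_rna(cat, {cat[0].name: 10}, 0.05, 15)
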