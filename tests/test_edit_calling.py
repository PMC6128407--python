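"""Edit-site filters: substitution type, SNP mask, depth and fraction thresholds."""

import numpy as np
import pandas as pd
import pytest

from editmir import (
    EditSite,
    call_edits,
    edit_fraction_summary,
    load_snp_mask,
    make_reference,
    merge_site_sets,
    plant_sites,
    simulate_pileup,
)
from editmir.errors import (
    ConflictError,
    EmptyGroupError,
    InvalidParameterError,
    MalformedRecordError,
)


def pileup_row(seq="chr1", pos=100, ref="A", depth=None, **counts):
    base = {"count_A": 0, "count_C": 0, "count_G": 0, "count_T": 0}
    base.update(counts)
    if depth is None:
        depth = sum(base.values())
    return {"seq": seq, "pos": pos, "ref": ref, "depth": depth, **base}


def make_pileup(rows):
    return pd.DataFrame(rows)


class TestCallEdits:
    def test_boundary_site_at_thresholds_is_retained(self):
        # depth exactly 30, fraction exactly 0.10: both thresholds inclusive
        pileup = make_pileup([pileup_row(ref="A", count_A=27, count_G=3)])
        sites = call_edits(pileup)
        assert len(sites) == 1
        site = sites[0]
        assert site.strand == "+" and site.change == "A>G"
        assert site.depth == 30 and site.edited_reads == 3
        assert site.edited_fraction == pytest.approx(0.10)

    def test_below_minimum_depth_rejected(self):
        pileup = make_pileup([pileup_row(ref="A", count_G=29)])  # 29/29 edited
        assert call_edits(pileup) == []

    def test_non_AG_TC_substitutions_removed(self):
        pileup = make_pileup([pileup_row(ref="C", count_C=50, count_T=50)])
        assert call_edits(pileup) == []

    def test_masked_position_rejected(self):
        row = pileup_row(ref="T", count_T=30, count_C=30)
        assert len(call_edits(make_pileup([row]))) == 1
        assert call_edits(make_pileup([row]), snp_mask={("chr1", 100)}) == []

    def test_reverse_strand_site_is_T_to_C(self):
        sites = call_edits(make_pileup([pileup_row(ref="T", count_T=20, count_C=20)]))
        assert sites[0].strand == "-" and sites[0].change == "T>C"

    def test_other_alt_bases_do_not_count_as_edited(self):
        # A reference with big T pile: not an edit signal
        pileup = make_pileup([pileup_row(ref="A", count_A=50, count_T=50)])
        assert call_edits(pileup) == []
        # G is the edited base; the stray T inflates depth only
        pileup = make_pileup([pileup_row(ref="A", count_A=10, count_G=10, count_T=80)])
        sites = call_edits(pileup)
        assert sites[0].edited_reads == 10 and sites[0].depth == 100

    def test_unknown_reference_base_rejected(self):
        with pytest.raises(MalformedRecordError):
            call_edits(make_pileup([pileup_row(ref="N", count_A=40)]))

    def test_negative_counts_rejected(self):
        with pytest.raises(MalformedRecordError):
            call_edits(make_pileup([pileup_row(ref="A", count_A=40, count_G=-1)]))

    def test_called_set_is_subset_of_input_positions(self):
        ref = make_reference(1, 3000, 0.45, 21)
        truth = plant_sites(ref, 30, 10, (0.05, 0.95), 22)
        pileup = simulate_pileup(ref, truth, (20, 80), 0.001, 23)
        sites = call_edits(pileup, truth.snp_mask())
        positions = set(zip(pileup["seq"], pileup["pos"]))
        assert all((s.seq, s.pos) in positions for s in sites)
        for s in sites:
            assert s.change == ("A>G" if s.strand == "+" else "T>C")
            assert s.depth >= 30 and s.edited_fraction >= 0.10

    def test_raising_thresholds_never_adds_sites(self):
        ref = make_reference(1, 3000, 0.45, 31)
        truth = plant_sites(ref, 40, 0, (0.02, 0.95), 32)
        pileup = simulate_pileup(ref, truth, (10, 200), 0.0, 33)
        keys = lambda sites: {s.key for s in sites}
        base = keys(call_edits(pileup, min_depth=20, min_fraction=0.05))
        for depth, fraction in [(20, 0.10), (30, 0.05), (30, 0.10), (60, 0.30)]:
            stricter = keys(call_edits(pileup, min_depth=depth, min_fraction=fraction))
            assert stricter <= base


class TestSnpMask:
    def test_vcf_record_masks_its_position(self, tmp_path):
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\n"
        )
        assert load_snp_mask(vcf) == {("chr1", 100)}

    def test_bed_interval_expands_to_1_based_positions(self, tmp_path):
        bed = tmp_path / "snps.bed"
        bed.write_text("chr1\t99\t100\n")
        assert load_snp_mask(bed) == {("chr1", 100)}

    def test_empty_mask_file_disables_filter(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        mask = load_snp_mask(bed)
        assert mask == set()
        pileup = make_pileup([pileup_row(ref="A", count_A=27, count_G=3)])
        assert len(call_edits(pileup, mask)) == 1

    def test_malformed_bed_line_reports_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t1\nchr1\toops\n")
        with pytest.raises(Exception) as err:
            load_snp_mask(bed)
        assert "line 2" in str(err.value)


def site(seq="chr1", pos=100, strand="+", labels=(), depth=50, edited=25):
    return EditSite(
        seq=seq,
        pos=pos,
        strand=strand,
        change="A>G" if strand == "+" else "T>C",
        depth=depth,
        edited_reads=edited,
        labels=frozenset(labels),
    )


class TestMergeSiteSets:
    def test_union_keeps_labels_of_every_contributor(self):
        s1, s2, s3 = site(pos=10), site(pos=20), site(pos=30)
        merged = merge_site_sets({"MCF-7": [s1, s2], "MDA-MB-231": [s2, s3]})
        assert len(merged) == 3
        by_pos = {s.pos: s for s in merged}
        assert by_pos[20].labels == {"MCF-7", "MDA-MB-231"}
        assert by_pos[10].labels == {"MCF-7"}

    def test_merge_is_idempotent(self):
        sites = [site(pos=10), site(pos=20)]
        once = merge_site_sets({"a": sites})
        twice = merge_site_sets({"a": once})
        assert [s.key for s in once] == [s.key for s in twice]

    def test_disjoint_lists_concatenate(self):
        a = [site(pos=p) for p in range(10, 20)]
        b = [site(pos=p) for p in range(100, 112)]
        assert len(merge_site_sets({"a": a, "b": b})) == 22

    def test_conflicting_strands_at_same_coordinate_rejected(self):
        with pytest.raises(ConflictError):
            merge_site_sets({"a": [site(pos=10, strand="+")], "b": [site(pos=10, strand="-")]})


class TestEditFractionSummary:
    def test_mean_of_two_fractions(self):
        sites = [site(labels=["x"], edited=40, depth=100), site(pos=9, labels=["x"], edited=60, depth=100)]
        assert edit_fraction_summary(sites) == {"x": pytest.approx(0.5)}

    def test_single_site_mean_is_its_fraction(self):
        sites = [site(labels=["MCF-7"], edited=518, depth=1000)]
        assert edit_fraction_summary(sites)["MCF-7"] == pytest.approx(0.518)

    def test_uniform_fractions_average_near_center(self):
        rng = np.random.default_rng(8)
        sites = [
            site(pos=1000 + i, labels=["s"], depth=1000,
                 edited=int(1000 * rng.uniform(0.1, 0.9)))
            for i in range(1000)
        ]
        mean = edit_fraction_summary(sites)["s"]
        assert abs(mean - 0.5) <= 0.03  # 3 SD of a Uniform(0.1,0.9) mean at n=1000

    def test_missing_label_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            edit_fraction_summary([site(labels=["a"])], labels=["b"])


def test_strand_change_consistency_enforced_on_construction():
    with pytest.raises(InvalidParameterError):
        EditSite(seq="chr1", pos=1, strand="+", change="T>C", depth=30, edited_reads=3)
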