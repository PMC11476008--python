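"""Region projection, NHR insertion detection, correspondences, leaders."""

import pytest

from splicetrace.alignment_projection import Msa
from splicetrace.errors import (
    AnnotationError,
    BoundsError,
    UndefinedFractionError,
)
from splicetrace.gene_models import ProteinRecord
from splicetrace.orf_annotation import TranscriptRecord
from splicetrace.region_analysis import (
    RegionSet,
    default_region_set,
    detect_insertions,
    detect_leader,
    difference_concentration,
    project_regions,
    region_conservation,
    residue_correspondence,
)


def simple_rs(reference="ref", **regions):
    return RegionSet(reference_id=reference, regions=regions)


class TestProjectRegions:
    def test_ungapped_reference(self):
        msa = Msa(ids=["ref", "t"], rows=["M" * 30] * 2)
        spans = project_regions(msa, simple_rs(loop=(5, 10)))
        assert spans == {"loop": (5, 10)}

    def test_reference_gaps_widen_span(self):
        ref = "MMMM" + "--" + "M" * 26
        msa = Msa(ids=["ref", "t"], rows=[ref, "M" * len(ref)])
        spans = project_regions(msa, simple_rs(loop=(3, 8)))
        assert spans == {"loop": (3, 10)}

    def test_region_beyond_reference(self):
        msa = Msa(ids=["ref"], rows=["M" * 10])
        with pytest.raises(BoundsError):
            project_regions(msa, simple_rs(loop=(5, 99)))

    def test_empty_region_set(self):
        msa = Msa(ids=["ref"], rows=["M" * 10])
        assert project_regions(msa, simple_rs()) == {}

    def test_packaged_defaults_load(self):
        rs = default_region_set()
        assert set(rs.regions) >= {"FLAG", "CF_loop", "regulatory_loop",
                                   "PP_loop", "R5P_loop"}
        assert [p for p, _ in rs.residue_sets["catalytic"]] == \
            [171, 194, 196, 200, 225]


class TestDetectInsertions:
    def make_msa(self, ins_len, region=(10, 20), gap_at=15):
        """Target carries ins_len extra residues inside the region window."""
        L = 40
        ref = "A" * gap_at + "-" * ins_len + "A" * (L - gap_at)
        tgt = "A" * gap_at + "I" * ins_len + "A" * (L - gap_at)
        return Msa(ids=["ref", "tgt"], rows=[ref, tgt])

    def test_identical_target_no_calls(self):
        msa = Msa(ids=["ref", "tgt"], rows=["A" * 40] * 2)
        assert detect_insertions(msa, simple_rs(loop=(10, 20))) == []

    def test_known_length_recovered(self):
        msa = self.make_msa(25)
        (call,) = detect_insertions(msa, simple_rs(CF_loop=(10, 20)),
                                    min_insertion=10)
        assert call.region_name == "CF_loop" and call.length == 25
        assert call.flank_anchored

    def test_regulatory_window_call(self):
        msa = self.make_msa(25, gap_at=15)
        rs = simple_rs(regulatory_loop=(12, 18))
        (call,) = detect_insertions(msa, rs, min_insertion=10)
        assert call.region_name == "regulatory_loop" and call.length == 25

    def test_short_insertion_below_threshold_ignored(self):
        msa = self.make_msa(5)
        assert detect_insertions(msa, simple_rs(loop=(10, 20)),
                                 min_insertion=10) == []

    def test_gap_merge_joins_split_runs(self):
        ref = "A" * 10 + "-" * 6 + "AA" + "-" * 6 + "A" * 20
        tgt = "A" * 10 + "I" * 6 + "AA" + "I" * 6 + "A" * 20
        msa = Msa(ids=["ref", "tgt"], rows=[ref, tgt])
        (call,) = detect_insertions(msa, simple_rs(loop=(8, 20)),
                                    min_insertion=10, gap_merge=2)
        assert call.length == 12


class TestResidueCorrespondence:
    def test_target_equals_reference(self):
        msa = Msa(ids=["ref", "t"], rows=["MDKRNT" * 5] * 2)
        rs = RegionSet(reference_id="ref",
                       residue_sets={"catalytic": [(2, "D"), (3, "K")]})
        table = residue_correspondence(msa, rs, "catalytic", ["t"])
        assert table["conserved"].all()

    def test_gapped_target_column(self):
        msa = Msa(ids=["ref", "t"], rows=["MDKR", "M-KR"])
        rs = RegionSet(reference_id="ref", residue_sets={"s": [(2, "D")]})
        row = residue_correspondence(msa, rs, "s", ["t"]).iloc[0]
        assert row.target_position is None and not row.conserved

    def test_shifted_target_position_reported(self):
        """A target with an N-terminal insertion reports its own numbering,
        mirroring the D171->S177-style offset between paralogs."""
        ref = "------MADKRNTW"
        tgt = "QQQQQQMASKRNTW"  # 6 extra residues; D (ref pos 3) -> S
        msa = Msa(ids=["ref", "t"], rows=[ref, tgt])
        rs = RegionSet(reference_id="ref", residue_sets={"s": [(3, "D")]})
        row = residue_correspondence(msa, rs, "s", ["t"]).iloc[0]
        assert row.target_position == 9 and row.target_residue == "S"
        assert not row.conserved

    def test_reference_mismatch_warns(self):
        msa = Msa(ids=["ref", "t"], rows=["MAKR", "MAKR"])
        rs = RegionSet(reference_id="ref", residue_sets={"s": [(2, "D")]})
        with pytest.warns(UserWarning):
            residue_correspondence(msa, rs, "s", ["t"])


class TestRegionConservation:
    def test_identity_and_full_gap(self):
        msa = Msa(ids=["ref", "same", "gapped"],
                  rows=["A" * 20, "A" * 20, "A" * 5 + "-" * 10 + "A" * 5])
        rcs = region_conservation(msa, simple_rs(loop=(6, 15)),
                                  ["same", "gapped"])
        (rc,) = rcs
        assert rc.per_target["same"] == 1.0
        assert rc.per_target["gapped"] == 0.0

    def test_three_substitutions_in_ten(self):
        ref = "A" * 20
        tgt = "A" * 5 + "VVV" + "A" * 12
        msa = Msa(ids=["ref", "t"], rows=[ref, tgt])
        (rc,) = region_conservation(msa, simple_rs(loop=(1, 10)), ["t"])
        assert rc.per_target["t"] == pytest.approx(0.7)


class TestDifferenceConcentration:
    def test_identical_pair_is_undefined(self):
        a = ProteinRecord(id="a", residues="MKVA" * 30)
        with pytest.raises(UndefinedFractionError):
            difference_concentration(a, ProteinRecord(id="b", residues=a.residues))

    def test_constructed_fraction(self):
        base = list("MKVAWDERTYLPSCHG" * 10)  # 160 aa
        b = base.copy()
        for pos in (10, 40, 80, 120):  # 3 of 4 substitutions inside [1,95]
            b[pos] = "W" if b[pos] != "W" else "Y"
        res = difference_concentration(
            ProteinRecord(id="a", residues="".join(base)),
            ProteinRecord(id="b", residues="".join(b)), window=(1, 95))
        assert res.total_differences == 4
        assert res.fraction == pytest.approx(0.75)

    def test_indel_run_counts_once(self):
        import numpy as np

        rng = np.random.default_rng(0)
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                      for i in rng.integers(0, 20, 120))
        a = ProteinRecord(id="a", residues=seq)
        b = ProteinRecord(id="b", residues=seq[:60] + seq[85:])
        res = difference_concentration(a, b, window=(1, 95))
        assert res.total_differences == 1
        assert res.in_window == 1

    def test_mask_excludes_region(self):
        base = "MKVAWDERTY" * 12
        mutated = list(base[:50] + "GGGGGGGGGGGG" + base[62:])  # 12 at 51..62
        mutated[99] = "W"  # one difference outside the masked window
        rs = RegionSet(reference_id="a", regions={"NHR": (51, 62)})
        am = ProteinRecord(id="a", residues=base)
        bm = ProteinRecord(id="b", residues="".join(mutated))
        masked = difference_concentration(am, bm, window=(1, 95),
                                          mask=["NHR"], rs=rs)
        assert masked.total_differences == 1 and masked.in_window == 0
        unmasked = difference_concentration(am, bm, window=(1, 95))
        assert unmasked.total_differences == 13
        assert unmasked.in_window == 12

    def test_totals_symmetric(self):
        a = ProteinRecord(id="a", residues="MKVAWDERTY" * 12)
        resid = list(a.residues)
        resid[30] = "G"
        b = ProteinRecord(id="b", residues="".join(resid[:70] + resid[90:]))
        ab = difference_concentration(a, b)
        ba = difference_concentration(b, a)
        assert ab.total_differences == ba.total_differences


class TestDetectLeader:
    CDS = "ATGGCTGCTGCTTAA"

    def test_no_upstream_atg(self):
        tx = TranscriptRecord(id="t", residues="CCCCCC" + self.CDS)
        assert detect_leader(tx, 6) == []

    def test_twenty_nine_residue_leader(self):
        """An upstream ATG 87 nt (29 codons) before the canonical start."""
        leader = "ATG" + "GCC" * 28
        tx = TranscriptRecord(id="t", residues="TAA" + leader + self.CDS)
        (lp,) = detect_leader(tx, 3 + len(leader))
        assert lp.leader_aa == 29
        assert lp.leader_sequence == "M" + "A" * 28

    def test_upstream_atg_behind_stop_excluded(self):
        tx = TranscriptRecord(id="t", residues="ATGTAA" + self.CDS)
        assert detect_leader(tx, 6) == []

    def test_canonical_start_must_be_atg(self):
        tx = TranscriptRecord(id="t", residues="CCC" + self.CDS)
        with pytest.raises(AnnotationError):
            detect_leader(tx, 0)

    def test_invariant_under_5prime_stop_padding(self):
        leader = "ATG" + "GCC" * 11
        tx1 = TranscriptRecord(id="t", residues="TAA" + leader + self.CDS)
        tx2 = TranscriptRecord(id="t", residues="TGATAGTAA" + leader + self.CDS)
        l1 = detect_leader(tx1, 3 + len(leader))
        l2 = detect_leader(tx2, 9 + len(leader))
        assert [x.leader_aa for x in l1] == [x.leader_aa for x in l2] == [12]
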