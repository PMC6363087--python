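"""edit_classifier: alignment round trips, left alignment, site calls,
coding-effect prediction and the clone mode."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import affine_score_oracle
from polyamp.edit_classifier import (CdsEffect, Variant, align_global,
                                     apply_variants, call_site_edits_named,
                                     classify_clones, deletion_histogram,
                                     left_align, predict_coding_effect,
                                     summarize_sample, EditCall, _aligner)
from polyamp.guide_design import check_allele_compatibility
from polyamp.sequence_io import GeneModel, NucSeq
from polyamp.synthetic_data import (CUT1, CUT2, SimConfig, anchor_gene_model,
                                    simulate_locus)


def _mutate(rng, ref: str, n_edits: int) -> str:
    seq = list(ref)
    for _ in range(n_edits):
        op = rng.integers(3)
        i = int(rng.integers(0, len(seq)))
        if op == 0:
            seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1 + int(rng.integers(3))) % 4]
        elif op == 1 and len(seq) > 5:
            k = int(rng.integers(1, 5))
            del seq[i:i + k]
        else:
            ins = "".join("ACGT"[j] for j in rng.integers(0, 4, size=int(rng.integers(1, 5))))
            seq[i:i] = list(ins)
    return "".join(seq) or "A"


class TestAlignGlobal:
    def test_identical_sequences_empty(self):
        assert align_global("ACGTACGT", "ACGTACGT") == []

    def test_homopolymer_deletion_left_aligned(self):
        ref = "ACGTTTTTTACG"
        seq = "ACGTTTACG"  # 3 T's removed somewhere in the run
        variants = align_global(seq, ref)
        assert len(variants) == 1
        v = variants[0]
        assert v.type == "deletion" and len(v.ref) == 3
        # leftmost admissible placement: position 3 (start of the T run)
        assert v.position == 3
        # every placement in the run yields the same edited string
        for pos in range(3, 7):
            assert apply_variants(ref, [Variant(pos, "TTT", "")]) == seq

    @pytest.mark.parametrize("seed", range(40))
    def test_roundtrip_on_fuzzed_edits(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        seq = _mutate(rng, ref, int(rng.integers(1, 6)))
        variants = align_global(seq, ref)
        assert apply_variants(ref, variants) == seq

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 9))))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 9))))
        aligner_score = _aligner(None).align(a, b).score
        assert aligner_score == pytest.approx(affine_score_oracle(a, b))

    def test_left_align_insertion_in_repeat(self):
        ref = "AATTTTGG"
        original = Variant(6, "", "TT")  # insert TT after the T run
        v = left_align(original, ref)
        assert v.position < original.position
        assert apply_variants(ref, [v]) == apply_variants(ref, [original])
        # fully shifted: no further left shift produces the same string
        assert v.position == 0 or ref[v.position - 1] != v.alt[-1]


class TestSiteEdits:
    @pytest.fixture()
    def sites(self, default_locus):
        return {
            g.name: check_allele_compatibility(g, default_locus)["a1"]
            for g in default_locus.guides
        }

    def test_no_variants_wild_type(self, sites):
        status, dual = call_site_edits_named([], sites)
        assert status == {"sgRNA1": "wild-type", "sgRNA2": "wild-type"}
        assert dual is False

    def test_dual_cut_deletion_marks_both_sites(self, sites, anchor_seq):
        start, end = CUT1 - 5, CUT2 + 5
        v = Variant(start, anchor_seq[start:end], "")
        status, dual = call_site_edits_named([v], sites)
        assert status == {"sgRNA1": "edited", "sgRNA2": "edited"}
        assert dual is True

    def test_insertion_at_cut2_only(self, sites):
        v = Variant(CUT2, "", "G")
        status, dual = call_site_edits_named([v], sites)
        assert status == {"sgRNA1": "wild-type", "sgRNA2": "edited"}
        assert dual is False

    def test_two_separate_deletions_not_dual(self, sites, anchor_seq):
        v1 = Variant(CUT1 - 2, anchor_seq[CUT1 - 2:CUT1 + 2], "")
        v2 = Variant(CUT2 - 2, anchor_seq[CUT2 - 2:CUT2 + 2], "")
        status, dual = call_site_edits_named([v1, v2], sites)
        assert status == {"sgRNA1": "edited", "sgRNA2": "edited"}
        assert dual is False

    def test_missing_site_not_assessable(self, sites):
        sites = dict(sites) | {"sgRNA1": None}
        status, _ = call_site_edits_named([], sites)
        assert status["sgRNA1"] == "not_assessable"

    def test_edit_window_boundary(self, sites):
        # flank=10: a variant at cut-10 intersects, at cut-11 does not
        v_in = Variant(CUT1 - 10, "A", "T")
        status, _ = call_site_edits_named([v_in], sites, flank=10)
        assert status["sgRNA1"] == "edited"
        v_out = Variant(CUT1 - 11, "A", "T")
        status, _ = call_site_edits_named([v_out], sites, flank=10)
        assert status["sgRNA1"] == "wild-type"


class TestCodingEffect:
    def test_pinned_dual_cut_triple(self, default_locus):
        """187/193/188-nt genomic deletions over the 106-nt-intron model
        classify as 27-aa loss, 29-aa loss and frameshift with PTC."""
        ref = default_locus.alleles["a1"].seq
        gm = default_locus.gene_models["a1"]
        expected = {
            187: ("in_frame_deletion", 27),
            193: ("in_frame_deletion", 29),
            188: ("frameshift_with_PTC", None),
        }
        for size, (kind, n_aa) in expected.items():
            extra = size - (CUT2 - CUT1)
            start = CUT1 - extra // 2
            v = left_align(Variant(start, ref[start:start + size], ""), ref)
            eff = predict_coding_effect([v], ref, gm)
            assert eff.kind == kind, size
            if n_aa is not None:
                assert eff.n_aa == n_aa, size

    def test_3nt_exonic_deletion_one_aa(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        gm = default_locus.gene_models["a1"]
        # codon-aligned 3-nt deletion at codon 4 (locus 57..60)
        v = Variant(57, ref[57:60], "")
        eff = predict_coding_effect([v], ref, gm)
        assert eff == CdsEffect("in_frame_deletion", n_aa=1)

    def test_no_variants_none(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        assert predict_coding_effect([], ref, default_locus.gene_models["a1"]).kind == "none"

    def test_intronic_deletion_is_silent_none(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        gm = default_locus.gene_models["a1"]
        v = Variant(180, ref[180:184], "")  # intron 1 interior
        assert predict_coding_effect([v], ref, gm).kind == "none"

    def test_splice_donor_break_disrupts(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        gm = default_locus.gene_models["a1"]
        # delete 4 bases straddling the exon1/intron1 boundary (135)
        v = Variant(133, ref[133:137], "")
        assert predict_coding_effect([v], ref, gm).kind == "splice_disrupted"

    def test_start_codon_destroyed(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        gm = default_locus.gene_models["a1"]
        v = Variant(45, ref[45:48], "")  # remove ATG
        eff = predict_coding_effect([v], ref, gm)
        assert eff.kind in ("start_lost",)

    def test_frameshift_iff_net_cds_change_not_multiple_of_3(self, default_locus):
        """Over random exonic indel fixtures, frameshift classification is
        equivalent to (net CDS length change) mod 3 != 0."""
        ref = default_locus.alleles["a1"].seq
        gm = default_locus.gene_models["a1"]
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(1000):
            # exonic, interior to exon 2, away from splice sites
            size = int(rng.integers(1, 10))
            if rng.random() < 0.5:
                start = int(rng.integers(243, 318 - size))
                v = Variant(start, ref[start:start + size], "")
                delta = -size
            else:
                pos = int(rng.integers(243, 318))
                ins = "".join("ACGT"[j] for j in rng.integers(0, 4, size=size))
                v = Variant(pos, "", ins)
                delta = size
            eff = predict_coding_effect([left_align(v, ref)], ref, gm)
            if delta % 3 != 0:
                assert eff.kind in ("frameshift", "frameshift_with_PTC"), v
            else:
                assert eff.kind not in ("frameshift", "frameshift_with_PTC"), v
            checked += 1
        assert checked == 1000

    def test_substitution_effects(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        gm = default_locus.gene_models["a1"]
        # locus 62 is a 4-fold third codon position (CTG Leu)
        assert predict_coding_effect([Variant(62, ref[62], "C")], ref, gm).kind == "silent"
        # locus 69 first codon position (GAT Asp -> AAT Asn)
        assert predict_coding_effect([Variant(69, "G", "A")], ref, gm).kind == "missense"


class TestCloneMode:
    def test_wild_type_clone_no_variants(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        sites = {g.name: check_allele_compatibility(g, default_locus)["a1"]
                 for g in default_locus.guides}
        calls = classify_clones([NucSeq("wt", ref)], ref, sites)
        assert calls[0].variants == [] and not calls[0].dual_cut

    def test_dual_cut_clone_deletion_size(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        sites = {g.name: check_allele_compatibility(g, default_locus)["a1"]
                 for g in default_locus.guides}
        start = CUT1 - 6
        clone_seq = ref[:start] + ref[start + 189:]
        site5 = ref[:CUT2 - 3] + ref[CUT2 + 2:]  # 5-nt deletion at site 2
        calls = classify_clones(
            [NucSeq("dual", clone_seq), NucSeq("site2", site5)], ref, sites)
        dual, single = calls
        assert dual.dual_cut and dual.deletion_size == 189
        assert dual.site_status == {"sgRNA1": "edited", "sgRNA2": "edited"}
        assert not single.dual_cut and single.deletion_size == 5
        assert single.site_status == {"sgRNA1": "wild-type", "sgRNA2": "edited"}
        assert deletion_histogram(calls) == {5: 1, 189: 1}

    def test_foreign_clone_flagged(self, default_locus):
        ref = default_locus.alleles["a1"].seq
        rng = np.random.default_rng(5)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        calls = classify_clones([NucSeq("junk", junk)], ref, {})
        assert calls[0].foreign


class TestSummarize:
    def _call(self, assigned, variants, prev):
        return EditCall(variants=list(variants), site_status={}, dual_cut=False,
                        cds_effect=CdsEffect("none"), assigned=assigned,
                        prevalence=prev, cluster_id="c")

    def test_distinct_groups_counted(self):
        v1 = Variant(5, "A", "T")
        v2 = Variant(9, "C", "")
        calls = [
            self._call(("a1", "a2"), [v1], 0.4),
            self._call(("a3",), [v1], 0.3),
            self._call(("a3",), [v2], 0.2),
            self._call(("a3",), [v2], 0.1),  # same group, summed
        ]
        groups = summarize_sample(calls)
        assert len(groups) == 3
        assert groups[0].prevalence == pytest.approx(0.4)

    def test_group_count_invariant_to_order_and_scaling(self):
        v = Variant(5, "A", "T")
        calls = [self._call(("a1",), [v], 0.5), self._call(("a2",), [], 0.5)]
        n1 = len(summarize_sample(calls))
        n2 = len(summarize_sample(list(reversed(calls)) * 3))
        assert n1 == n2 == 2
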