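"""Consequence engine: codon rules, splice rules, frameshift translation,
strand symmetry, and agreement with the genome-reconstruction oracle."""

from __future__ import annotations

import numpy as np
import pytest

from brcascreen.consequence import (
    PLOF_CONSEQUENCES,
    Variant,
    classify_indel,
    classify_snv,
    classify_variant,
    lof_confidence,
)
from brcascreen.simulate import generate_transcripts

from conftest import build_plus_model, mirror_model, mirror_snv, oracle_coding_class


@pytest.fixture(scope="module")
def plus_model():
    return build_plus_model()


@pytest.fixture(scope="module")
def minus_model(plus_model):
    return mirror_model(plus_model)


class TestSNVRules:
    def test_tac_to_taa_is_stop_gained(self, plus_model):
        # TAC codon occupies CDS bases 3-5 -> genomic 10-12 on the toy model
        call = classify_snv(Variant("chrT", 12, "C", "A"), plus_model)
        assert call.consequence == "stop_gained" and call.is_plof
        assert lof_confidence(call, plus_model) == "high"

    def test_atg_to_ata_is_start_lost(self, plus_model):
        call = classify_snv(Variant("chrT", 9, "G", "A"), plus_model)
        assert call.consequence == "start_lost" and call.is_plof

    def test_synonymous_and_missense(self, plus_model):
        # codon 3 (a GCT) spans CDS bases 9-11 = genomic 36-38 (exon 2)
        pos = 38  # third codon position: GCT -> GCC (Ala->Ala)
        assert plus_model.base_at(pos) == "T"
        call = classify_snv(Variant("chrT", pos, "T", "C"), plus_model)
        assert call.consequence == "synonymous"
        # second codon position: GCT -> GTT (Ala->Val)
        call = classify_snv(Variant("chrT", 37, "C", "T"), plus_model)
        assert call.consequence == "missense"
        assert not call.is_plof

    def test_intronic_and_splice_sites(self, plus_model):
        donor1 = plus_model.exons[0][1] + 1
        acceptor1 = plus_model.exons[1][0] - 1
        assert classify_snv(Variant("chrT", donor1, "G", "A"), plus_model).consequence == "splice_donor"
        assert classify_snv(Variant("chrT", acceptor1, "G", "C"), plus_model).consequence == "splice_acceptor"
        mid_intron = donor1 + 8
        ref = plus_model.base_at(mid_intron)
        alt = "A" if ref != "A" else "G"
        assert classify_snv(Variant("chrT", mid_intron, ref, alt), plus_model).consequence == "intronic"

    def test_minus_strand_donor_on_high_side_of_exon(self, minus_model):
        # transcript-upstream exon of the mirrored model is the highest-
        # coordinate exon; its donor dinucleotide sits just BELOW it
        last_exon = minus_model.exons[-1]
        donor_pos = last_exon[0] - 1
        ref = minus_model.base_at(donor_pos)
        alt = "A" if ref != "A" else "T"
        call = classify_snv(Variant("chrT", donor_pos, ref, alt), minus_model)
        assert call.consequence == "splice_donor" and call.is_plof

    def test_ref_mismatch_is_an_error(self, plus_model):
        wrong = "A" if plus_model.base_at(12) != "A" else "C"
        with pytest.raises(ValueError, match="ref mismatch"):
            classify_snv(Variant("chrT", 12, wrong, "G"), plus_model)


class TestIndelRules:
    def test_one_bp_deletion_early_is_frameshift_premature_stop(self, plus_model):
        pos = 10  # anchor inside CDS, deletes CDS base at 11
        ref = plus_model.seq_slice(pos, pos + 1)
        call = classify_indel(Variant("chrT", pos, ref, ref[0]), plus_model)
        assert call.consequence == "frameshift_premature_stop" and call.is_plof

    def test_three_bp_deletion_is_inframe_not_plof(self, plus_model):
        pos = 40  # mid exon 2, fully coding
        ref = plus_model.seq_slice(pos, pos + 3)
        call = classify_indel(Variant("chrT", pos, ref, ref[0]), plus_model)
        assert call.consequence == "inframe_indel" and not call.is_plof

    def test_deleting_donor_dinucleotide_is_splice_donor(self, plus_model):
        exon1_end = plus_model.exons[0][1]
        ref = plus_model.seq_slice(exon1_end, exon1_end + 2)
        call = classify_indel(Variant("chrT", exon1_end, ref, ref[0]), plus_model)
        assert call.consequence == "splice_donor" and call.is_plof

    def test_exon_boundary_spanning_deletion_is_other(self, plus_model):
        exon1_end = plus_model.exons[0][1]
        pos = exon1_end - 2  # deletes 2 coding + 2 intronic... spans boundary
        ref = plus_model.seq_slice(pos, pos + 4)
        call = classify_indel(Variant("chrT", pos, ref, ref[0]), plus_model)
        assert call.consequence in ("other", "splice_donor")
        # removing the donor counts as splice ablation, else boundary warning
        if call.consequence == "other":
            assert "boundary" in call.note

    def test_insertion_in_cds_frameshift(self, plus_model):
        pos = 40
        ref = plus_model.base_at(pos)
        call = classify_indel(Variant("chrT", pos, ref, ref + "GG"), plus_model)
        assert call.consequence in ("frameshift_premature_stop", "other")

    def test_not_left_anchored_rejected(self, plus_model):
        pos = 40
        ref = plus_model.seq_slice(pos, pos + 1)
        bad_alt = "G" if ref[0] != "G" else "C"
        with pytest.raises(ValueError, match="left-anchored"):
            classify_indel(Variant("chrT", pos, ref, bad_alt), plus_model)


class TestLofConfidence:
    def test_stop_in_first_exon_is_high(self, plus_model):
        call = classify_snv(Variant("chrT", 12, "C", "A"), plus_model)
        assert lof_confidence(call, plus_model) == "high"

    def test_stop_near_last_junction_is_low(self, plus_model):
        # a frameshift whose premature stop lands in the final exon must be
        # demoted: truncations there escape nonsense-mediated decay
        last_exon = plus_model.exons[-1]
        pos = last_exon[0]
        ref = plus_model.seq_slice(pos, pos + 1)
        call = classify_indel(Variant("chrT", pos, ref, ref[0]), plus_model)
        if call.is_plof:
            assert lof_confidence(call, plus_model) == "low"

    def test_single_exon_transcript_always_low(self):
        from brcascreen.transcripts import TranscriptModel

        cds = "ATG" + "GCT" * 20 + "TAA"
        model = TranscriptModel(
            gene_id="ONEEXON", chrom="c", strand="+",
            exons=((1, len(cds) + 8),),
            cds_start=5, cds_end=4 + len(cds),
            ref_seq="TTTT" + cds + "GGGG",
        )
        model.validate()
        call = classify_snv(Variant("c", 13, model.base_at(13), "A"), model)
        if call.is_plof:
            assert lof_confidence(call, model) == "low"

    def test_rejects_non_plof(self, plus_model):
        call = classify_snv(Variant("chrT", 37, "C", "T"), plus_model)
        with pytest.raises(ValueError):
            lof_confidence(call, plus_model)


class TestOracleEquivalence:
    """Implementation (transcript-space edits) vs genome-reconstruction oracle."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_coding_snvs_agree(self, seed):
        models = generate_transcripts(2, seed)
        rng = np.random.default_rng(seed + 100)
        for model in models:
            cds_pos = model.cds_positions()
            for pos in rng.choice(cds_pos, size=60, replace=False):
                pos = int(pos)
                ref = model.base_at(pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = Variant(model.chrom, pos, ref, alt)
                assert classify_snv(v, model).consequence == oracle_coding_class(v, model), v

    @pytest.mark.parametrize("seed", [3, 4])
    def test_random_coding_deletions_agree(self, seed):
        models = generate_transcripts(2, seed)
        rng = np.random.default_rng(seed + 200)
        for model in models:
            cds_pos = np.sort(model.cds_positions())
            tried = 0
            for pos in rng.permutation(cds_pos):
                if tried >= 40:
                    break
                pos = int(pos)
                k = int(rng.integers(1, 4))
                # anchor + deleted run must be contiguous CDS in one exon
                run = [pos + i for i in range(k + 1)]
                if not all(model.in_cds(p) for p in run):
                    continue
                if not any(s <= run[0] and run[-1] <= e for s, e in model.exons):
                    continue
                ref = model.seq_slice(pos, pos + k)
                v = Variant(model.chrom, pos, ref, ref[0])
                got = classify_variant(v, model).consequence
                want = oracle_coding_class(v, model)
                assert got == want, v
                tried += 1
            assert tried >= 20

    @pytest.mark.parametrize("seed", [5, 6])
    def test_random_coding_insertions_agree(self, seed):
        models = generate_transcripts(2, seed)
        rng = np.random.default_rng(seed + 300)
        for model in models:
            cds_pos = np.sort(model.cds_positions())
            tried = 0
            for pos in rng.permutation(cds_pos):
                if tried >= 30:
                    break
                pos = int(pos)
                if not (model.in_cds(pos) and model.in_cds(pos + 1)):
                    continue
                if not any(s <= pos and pos + 1 <= e for s, e in model.exons):
                    continue
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                ref = model.base_at(pos)
                v = Variant(model.chrom, pos, ref, ref + ins)
                got = classify_variant(v, model).consequence
                want = oracle_coding_class(v, model)
                assert got == want, v
                tried += 1
            assert tried >= 15


class TestStrandSymmetry:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_mirrored_locus_gives_identical_classes(self, seed):
        models = generate_transcripts(2, seed)
        rng = np.random.default_rng(seed)
        for model in models:
            mirrored = mirror_model(model)
            lo = model.seq_start
            hi = model.seq_start + len(model.ref_seq) - 1
            positions = rng.integers(lo, hi + 1, size=120)
            for pos in positions:
                pos = int(pos)
                ref = model.base_at(pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = Variant(model.chrom, pos, ref, alt)
                mv = mirror_snv(model, v)
                assert (
                    classify_snv(v, model).consequence
                    == classify_snv(mv, mirrored).consequence
                ), (v, mv)


class TestInvariants:
    def test_plof_set_matches_consequence_labels(self, plus_model):
        rng = np.random.default_rng(9)
        for pos in rng.integers(1, len(plus_model.ref_seq) + 1, size=150):
            pos = int(pos)
            ref = plus_model.base_at(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            call = classify_snv(Variant("chrT", pos, ref, alt), plus_model)
            assert call.is_plof == (call.consequence in PLOF_CONSEQUENCES)

    def test_inframe_never_plof_random_models(self):
        models = generate_transcripts(2, 11)
        rng = np.random.default_rng(11)
        for model in models:
            for pos in np.sort(model.cds_positions())[:200]:
                pos = int(pos)
                if not all(model.in_cds(pos + i) for i in range(4)):
                    continue
                if not any(s <= pos and pos + 3 <= e for s, e in model.exons):
                    continue
                ref = model.seq_slice(pos, pos + 3)
                call = classify_indel(Variant(model.chrom, pos, ref, ref[0]), model)
                assert call.consequence == "inframe_indel"
                assert not call.is_plof
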