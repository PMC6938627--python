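"""Shared fixtures: hand-built transcript models and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from brcascreen.callset import CallSet
from brcascreen.consequence import Variant
from brcascreen.simulate import SimConfig, generate_cohort
from brcascreen.transcripts import TranscriptModel

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def build_plus_model() -> TranscriptModel:
    """Three-exon plus-strand model with known codon landmarks.

    CDS: ATG TAC (CTA ACT x15) GAT TTC TAA.  The TAC codon (CDS bases 3-5)
    can be made a stop by one substitution; the CTA-ACT filler has no
    in-frame stop but carries TAA in its +1 frame, so frameshifts truncate;
    the final junction sits 12 coding bases before the stop, leaving a long
    NMD-competent region.
    """
    utr5, utr3 = "TTAACC", "GGTTAA"
    cds = "ATG" + "TAC" + "CTAACT" * 15 + "GAT" + "TTC" + "TAA"
    mrna = utr5 + cds + utr3
    intron1 = "GT" + "C" * 16 + "AG"
    intron2 = "GT" + "A" * 16 + "AG"
    # exon splits in mRNA space: after 15 bases and after 99 bases
    e1, e2, e3 = mrna[:15], mrna[15:99], mrna[99:]
    ref = e1 + intron1 + e2 + intron2 + e3
    exons = (
        (1, 15),
        (15 + len(intron1) + 1, 15 + len(intron1) + len(e2)),
        (len(ref) - len(e3) + 1, len(ref)),
    )
    model = TranscriptModel(
        gene_id="TOYPLUS",
        chrom="chrT",
        strand="+",
        exons=exons,
        cds_start=len(utr5) + 1,
        cds_end=exons[2][0] + (len(cds) - (15 - len(utr5)) - len(e2)) - 1,
        ref_seq=ref,
    )
    model.validate()
    return model


def mirror_model(model: TranscriptModel) -> TranscriptModel:
    """Reverse-complement the locus and flip strand/coordinates."""
    T = len(model.ref_seq)
    m = TranscriptModel(
        gene_id=model.gene_id + "_mirror",
        chrom=model.chrom,
        strand="-" if model.strand == "+" else "+",
        exons=tuple(sorted((T - e + 1, T - s + 1) for s, e in model.exons)),
        cds_start=T - model.cds_end + 1,
        cds_end=T - model.cds_start + 1,
        ref_seq=revcomp(model.ref_seq),
        seq_start=model.seq_start,
    )
    m.validate()
    return m


def mirror_snv(model: TranscriptModel, v: Variant) -> Variant:
    T = len(model.ref_seq)
    return Variant(v.chrom, T - v.pos + 1, v.ref.translate(_COMP), v.alt.translate(_COMP))


# --------------------------------------------------------------------------
# independent consequence oracle: edit the genome, re-extract, translate


def _shift(coord: int, edit_after: int, net: int) -> int:
    return coord + net if coord > edit_after else coord


def oracle_coding_class(variant: Variant, model: TranscriptModel) -> str:
    """Classify a CDS-contained variant by full genomic reconstruction.

    Applies the edit to the raw locus sequence, shifts every exon/CDS
    coordinate beyond the edit, re-extracts the mutant spliced CDS, and
    compares translations.  Deliberately a different route from the
    transcript-space editing in the implementation.
    """
    seq = model.ref_seq
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    net = len(alt) - len(ref)
    if net == 0:
        mutant = seq[: pos - 1] + alt + seq[pos:]
        edit_after = len(seq) + 1  # no shifts
    elif net < 0:
        mutant = seq[:pos] + seq[pos + len(ref) - 1 :]
        edit_after = pos
    else:
        mutant = seq[:pos] + alt[1:] + seq[pos:]
        edit_after = pos
    exons = [(_shift(s, edit_after, net), _shift(e, edit_after, net)) for s, e in model.exons]
    cds_lo = _shift(model.cds_start, edit_after, net)
    cds_hi = _shift(model.cds_end, edit_after, net)

    def spliced_cds(sequence: str, exon_list, lo, hi) -> str:
        positions = [p for s, e in exon_list for p in range(s, e + 1) if lo <= p <= hi]
        bases = "".join(sequence[p - 1] for p in positions)
        return revcomp(bases) if model.strand == "-" else bases

    ref_cds = spliced_cds(seq, model.exons, model.cds_start, model.cds_end)
    mut_cds = spliced_cds(mutant, exons, cds_lo, cds_hi)
    ref_prot = str(Seq(ref_cds).translate())
    mut_prot = str(Seq(mut_cds[: 3 * (len(mut_cds) // 3)]).translate())
    if net == 0:
        if not mut_cds.startswith("ATG"):
            return "start_lost"
        stop_at = mut_prot.find("*")
        if stop_at != -1 and stop_at < len(ref_prot) - 1:
            return "stop_gained"
        if stop_at == -1:
            return "stop_lost"
        return "synonymous" if mut_prot == ref_prot else "missense"
    if abs(net) % 3 == 0:
        return "inframe_indel"
    stop_at = mut_prot.find("*")
    if stop_at != -1 and stop_at < len(ref_prot) - 1:
        return "frameshift_premature_stop"
    return "other"


# --------------------------------------------------------------------------
# cohort fixtures


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort with planted relatives, shared read-only."""
    config = SimConfig(
        n_samples=1200,
        seed=20,
        n_kinship_snps=3000,
        relative_pairs=(("duplicate", 4), ("first", 12), ("second", 12)),
    )
    callset, cohort, truth = generate_cohort(config)
    return config, callset, cohort, truth


@pytest.fixture()
def tiny_callset() -> CallSet:
    """Four samples x three sites with hand-set dosages and depths."""
    sites = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "pos": [100, 200, 300],
            "ref": ["A", "C", "G"],
            "alt": ["T", "G", "A"],
            "group_id": ["", "", ""],
        }
    )
    dosage = np.array(
        [[0, 1, 1, 2],
         [0, 0, -1, 1],
         [1, 1, 0, 0]],
        dtype=np.int8,
    )
    ad_ref = np.array(
        [[10, 5, 9, 0],
         [10, 10, 0, 6],
         [9, 8, 12, 11]],
        dtype=np.int32,
    )
    ad_alt = np.array(
        [[0, 5, 1, 12],
         [0, 0, 0, 5],
         [1, 2, 0, 0]],
        dtype=np.int32,
    )
    return CallSet(["A", "B", "C", "D"], sites, dosage, ad_ref, ad_alt)
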