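"""Rule-based consequence annotation and predicted loss-of-function calls.

Replaces a VEP+LOFTEE consensus with a deterministic, fully testable rule
engine over single canonical transcript models:

* coding SNVs are classified by comparing the reference and alternate codon
  in transcript orientation (stop_gained, start_lost, stop_lost, missense,
  synonymous);
* SNVs or indels hitting either of the two canonical intronic dinucleotides
  of any intron are splice_donor / splice_acceptor;
* frame-shifting indels are confirmed by actually translating the edited
  spliced CDS — they are pLOF only if a premature stop codon appears
  (frameshift_premature_stop); in-frame indels are never pLOF;
* a LOFTEE-style confidence flag demotes pLOF calls whose lesion lies in
  the final exon or within 50 coding bases of the last exon-exon junction
  (the canonical NMD-escape region).

Variants are VCF-style: 1-based position, left-anchored ref/alt alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from brcascreen.transcripts import TranscriptModel

PLOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "start_lost",
        "stop_lost",
        "splice_acceptor",
        "splice_donor",
        "frameshift_premature_stop",
    }
)

NMD_ESCAPE_WINDOW = 50  # coding bases upstream of the last junction


@dataclass(frozen=True)
class ConsequenceCall:
    key: str  # chrom:pos:ref:alt
    consequence: str
    is_plof: bool
    lesion_cds_index: int | None = None  # CDS coordinate of the damaging event
    note: str = ""


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_ref(variant: Variant, model: TranscriptModel) -> None:
    obs = model.seq_slice(variant.pos, variant.pos + len(variant.ref) - 1)
    if obs != variant.ref:
        raise ValueError(
            f"ref mismatch at {variant.chrom}:{variant.pos}: "
            f"variant says {variant.ref!r}, reference has {obs!r}"
        )


def _splice_sites(model: TranscriptModel) -> tuple[set[int], set[int]]:
    """Genomic positions of donor and acceptor dinucleotides of every intron.

    The donor is the intron end adjacent to the transcript-upstream exon,
    the acceptor the end adjacent to the downstream exon; on the minus
    strand these swap genomic sides.
    """
    donors: set[int] = set()
    acceptors: set[int] = set()
    for lo, hi in model.introns:
        if hi - lo + 1 < 2:
            continue
        low_pair = {lo, lo + 1}
        high_pair = {hi - 1, hi}
        if model.strand == "+":
            donors |= low_pair
            acceptors |= high_pair
        else:
            donors |= high_pair
            acceptors |= low_pair
    return donors, acceptors


def _splice_lesion_index(model: TranscriptModel, pos: int) -> int | None:
    """CDS index attributed to a splice lesion at intronic position ``pos``.

    Taken as the CDS index of the first coding base downstream (transcript
    order) of the damaged junction; for lesions past the last coding exon
    this clamps to the CDS end.
    """
    cp = model.cds_positions()
    if model.strand == "+":
        later = cp[cp > pos]
    else:
        later = cp[cp < pos]
    if len(later) == 0:
        return len(cp) - 1
    return int(len(cp) - len(later))


def classify_snv(variant: Variant, model: TranscriptModel) -> ConsequenceCall:
    """Classify a single-nucleotide variant against one transcript model."""
    _check_ref(variant, model)
    pos, alt = variant.pos, variant.alt
    donors, acceptors = _splice_sites(model)

    if model.in_cds(pos):
        cds = model.cds_sequence()
        idx = model.cds_index(pos)
        alt_base = alt if model.strand == "+" else _rc(alt)
        codon_i = idx // 3
        offset = idx % 3
        ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if codon_i == 0 and alt_codon != "ATG":
            cons = "start_lost"
        elif aa_ref == "*" and aa_alt != "*":
            cons = "stop_lost"
        elif aa_alt == "*" and aa_ref != "*":
            cons = "stop_gained"
        elif aa_alt == aa_ref:
            cons = "synonymous"
        else:
            cons = "missense"
        lesion = {"start_lost": 0, "stop_lost": len(cds) - 3}.get(cons, codon_i * 3)
        return ConsequenceCall(variant.key, cons, cons in PLOF_CONSEQUENCES,
                               lesion if cons in PLOF_CONSEQUENCES else None)

    if pos in donors or pos in acceptors:
        cons = "splice_donor" if pos in donors else "splice_acceptor"
        return ConsequenceCall(
            variant.key, cons, True, _splice_lesion_index(model, pos)
        )
    if model.in_exon(pos):
        return ConsequenceCall(variant.key, "other", False, note="UTR")
    if any(lo <= pos <= hi for lo, hi in model.introns):
        return ConsequenceCall(variant.key, "intronic", False)
    return ConsequenceCall(variant.key, "other", False, note="outside transcript")


def classify_indel(variant: Variant, model: TranscriptModel) -> ConsequenceCall:
    """Classify a left-anchored insertion or deletion."""
    _check_ref(variant, model)
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    if len(ref) == len(alt):
        raise ValueError("not an indel (use classify_snv for SNVs / MNVs unsupported)")
    if ref[0] != alt[0]:
        raise ValueError(f"indel {variant.key} is not left-anchored (anchor bases differ)")
    net = len(alt) - len(ref)
    donors, acceptors = _splice_sites(model)

    if net < 0:
        affected = set(range(pos + 1, pos + len(ref)))  # deleted genomic bases
    else:
        # insertion lands between pos and pos+1; it disrupts a dinucleotide
        # only if it separates its two bases
        affected = set()

    # splice ablation first: the dinucleotide no longer exists
    for sites, cons in ((donors, "splice_donor"), (acceptors, "splice_acceptor")):
        if affected & sites:
            return ConsequenceCall(
                variant.key, cons, True,
                _splice_lesion_index(model, min(affected & sites)),
            )
        if net > 0:
            # insertion between the two bases of one dinucleotide
            pair = {pos, pos + 1}
            if pair <= sites:
                return ConsequenceCall(
                    variant.key, cons, True, _splice_lesion_index(model, pos)
                )

    if net < 0:
        in_cds = [model.in_cds(p) for p in sorted(affected)]
        if not any(in_cds):
            if all(any(lo <= p <= hi for lo, hi in model.introns) for p in affected):
                return ConsequenceCall(variant.key, "intronic", False)
            return ConsequenceCall(variant.key, "other", False, note="non-coding indel")
        if not all(in_cds):
            return ConsequenceCall(
                variant.key, "other", False,
                note="indel spans a coding/non-coding boundary; not classified",
            )
        cds_idx = sorted(model.cds_index(p) for p in affected)
        if cds_idx != list(range(cds_idx[0], cds_idx[0] + len(cds_idx))):
            return ConsequenceCall(
                variant.key, "other", False,
                note="deleted bases not contiguous in CDS; not classified",
            )
        cds = model.cds_sequence()
        mutant = cds[: cds_idx[0]] + cds[cds_idx[-1] + 1 :]
        edit_at = cds_idx[0]
    else:
        inserted = alt[1:]
        # require the insertion point to sit strictly inside the CDS
        flank = (pos, pos + 1)
        if not (model.in_cds(flank[0]) and model.in_cds(flank[1])):
            if any(lo <= pos <= hi for lo, hi in model.introns):
                return ConsequenceCall(variant.key, "intronic", False)
            return ConsequenceCall(
                variant.key, "other", False,
                note="insertion at a coding boundary; not classified",
            )
        i0, i1 = model.cds_index(flank[0]), model.cds_index(flank[1])
        if abs(i0 - i1) != 1:
            return ConsequenceCall(
                variant.key, "other", False,
                note="insertion point not contiguous in CDS; not classified",
            )
        cds = model.cds_sequence()
        if model.strand == "+":
            mutant = cds[: i0 + 1] + inserted + cds[i0 + 1 :]
            edit_at = i0 + 1
        else:
            mutant = cds[: i1 + 1] + _rc(inserted) + cds[i1 + 1 :]
            edit_at = i1 + 1

    if abs(net) % 3 == 0:
        return ConsequenceCall(variant.key, "inframe_indel", False)

    # frameshift: confirmed only by translation of the edited CDS
    prot = str(Seq(mutant[: 3 * (len(mutant) // 3)]).translate())
    original_stop_codon = len(cds) // 3 - 1
    stop_at = prot.find("*")
    if stop_at != -1 and stop_at < original_stop_codon:
        return ConsequenceCall(
            variant.key, "frameshift_premature_stop", True,
            lesion_cds_index=_shifted_index(stop_at * 3, edit_at, net),
        )
    return ConsequenceCall(
        variant.key, "other", False, note="frameshift without premature stop"
    )


def _shifted_index(mutant_index: int, edit_at: int, net: int) -> int:
    """Map a mutant-CDS index back onto reference-CDS coordinates."""
    if mutant_index < edit_at:
        return mutant_index
    return max(edit_at, mutant_index - max(net, 0))


def classify_variant(variant: Variant, model: TranscriptModel) -> ConsequenceCall:
    """Dispatch to the SNV or indel classifier."""
    if variant.is_snv:
        return classify_snv(variant, model)
    return classify_indel(variant, model)


def lof_confidence(call: ConsequenceCall, model: TranscriptModel) -> str:
    """LOFTEE-style confidence for a pLOF call: ``high`` or ``low``.

    ``low`` when the lesion lies in the final exon or within 50 coding
    bases upstream of the last exon-exon junction — transcripts truncated
    there typically escape nonsense-mediated decay, so the call is a likely
    false positive for complete loss of function.
    """
    if not call.is_plof:
        raise ValueError("lof_confidence is defined only for pLOF calls")
    junction = model.last_junction_cds_index()
    if junction is None:  # single-exon transcript: no NMD at all
        return "low"
    lesion = call.lesion_cds_index
    if lesion is None:
        return "low"
    return "low" if lesion >= junction - NMD_ESCAPE_WINDOW else "high"


def consensus_plof(call: ConsequenceCall, model: TranscriptModel) -> bool:
    """High-confidence pLOF: the rule engine's stand-in for a two-caller consensus."""
    return call.is_plof and lof_confidence(call, model) == "high"
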