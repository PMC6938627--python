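"""Predicted loss-of-function annotation and expected-pathogenic classification.

A stop-gain, a frameshift and a missense variant are classified against a
toy two-gene transcript set; ClinVar-style assertions then partition the
variants, and the union of ClinVar pathogenic/likely-pathogenic with
high-confidence novel pLOF forms the "expected pathogenic" screening set.
"""

from brcascreen.classify import ClinVarRecord, classify_variants, load_clinvar
from brcascreen.consequence import Variant, classify_variant, consensus_plof, lof_confidence
from brcascreen.simulate import generate_transcripts

model = generate_transcripts(2, seed=3)[1]  # the plus-strand gene
cds = model.cds_positions()

# engineer a stop-gain: find a position whose substitution creates a stop
for pos in cds:
    ref = model.base_at(int(pos))
    for alt in "ACGT":
        if alt == ref:
            continue
        call = classify_variant(Variant(model.chrom, int(pos), ref, alt), model)
        if call.consequence == "stop_gained":
            break
    else:
        continue
    break

conf = lof_confidence(call, model)
print(f"{call.key}: {call.consequence}, pLOF={call.is_plof}, confidence={conf}")

# a 1-bp deletion early in the CDS frameshifts into a premature stop
for anchor in map(int, sorted(cds)[10:]):
    ref2 = model.seq_slice(anchor, anchor + 1)
    fs = classify_variant(Variant(model.chrom, anchor, ref2, ref2[0]), model)
    if fs.consequence == "frameshift_premature_stop":
        break
print(f"{fs.key}: {fs.consequence} (confirmed by translating the edited CDS)")

clinvar = load_clinvar([ClinVarRecord(call.key, "pathogenic", 3)])
consensus = {fs.key: consensus_plof(fs, model)}
out = classify_variants([call.key, fs.key], clinvar,
                        consequences={fs.key: fs}, consensus_flags=consensus)
for c in out:
    print(f"{c.key}: category={c.category}, expected_pathogenic={c.expected_pathogenic}")
print("expected pathogenic = ClinVar P/LP union high-confidence novel pLOF")
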