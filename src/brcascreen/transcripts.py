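"""Transcript models: exon structure, CDS bounds, strand, reference sequence.

One canonical transcript per gene, the substrate of the consequence engine.
Coordinates are genomic, 1-based, inclusive, relative to the bundled locus
reference sequence (``seq_start`` is the genomic coordinate of its first
base).  For minus-strand genes the coding sequence is read from the
reverse complement, high coordinate first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq


@dataclass(frozen=True)
class TranscriptModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # sorted, 1-based inclusive, genomic
    cds_start: int  # genomic, min coordinate of CDS
    cds_end: int  # genomic, max coordinate of CDS
    ref_seq: str
    seq_start: int = 1

    # ---- coordinate helpers -------------------------------------------------

    def base_at(self, pos: int) -> str:
        i = pos - self.seq_start
        if not (0 <= i < len(self.ref_seq)):
            raise ValueError(f"position {pos} outside locus [{self.seq_start}, "
                             f"{self.seq_start + len(self.ref_seq) - 1}]")
        return self.ref_seq[i]

    def seq_slice(self, start: int, end: int) -> str:
        """Genomic-orientation sequence for the inclusive interval."""
        return "".join(self.base_at(p) for p in range(start, end + 1))

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return self.cds_start <= pos <= self.cds_end and self.in_exon(pos)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons (sorted by coordinate)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in transcript (5'->3') order."""
        cached = self.__dict__.get("_cds_pos")
        if cached is None:
            pos = np.concatenate(
                [np.arange(s, e + 1) for s, e in self.exons]
            )
            pos = pos[(pos >= self.cds_start) & (pos <= self.cds_end)]
            cached = pos[::-1] if self.strand == "-" else pos
            object.__setattr__(self, "_cds_pos", cached)
        return cached

    def cds_sequence(self) -> str:
        cached = self.__dict__.get("_cds_seq")
        if cached is None:
            pos = self.cds_positions()
            asc = pos[::-1] if self.strand == "-" else pos
            bases = "".join(self.base_at(int(p)) for p in asc)
            cached = str(Seq(bases).reverse_complement()) if self.strand == "-" else bases
            object.__setattr__(self, "_cds_seq", cached)
        return cached

    def cds_index(self, pos: int) -> int:
        """0-based index of a genomic position within the spliced CDS."""
        cp = self.cds_positions()
        hits = np.flatnonzero(cp == pos)
        if len(hits) != 1:
            raise ValueError(f"position {pos} not in CDS of {self.gene_id}")
        return int(hits[0])

    def last_junction_cds_index(self) -> int | None:
        """CDS index of the first base of the final (3'-most) exon.

        None for single-exon transcripts.  Equals the count of coding bases
        upstream of the last exon-exon junction; the 50-nt NMD-escape rule
        measures from here.
        """
        if len(self.exons) < 2:
            return None
        last_exon = self.exons[-1] if self.strand == "+" else self.exons[0]
        cp = self.cds_positions()
        in_last = (cp >= last_exon[0]) & (cp <= last_exon[1])
        if not in_last.any():
            # CDS ends before the final exon: every coding base is upstream
            return len(cp)
        return int(np.flatnonzero(in_last)[0])

    # ---- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for (s, e) in self.exons:
            if s > e:
                raise ValueError("exon start > end")
            if s < self.seq_start or e > self.seq_start + len(self.ref_seq) - 1:
                raise ValueError("exon outside reference sequence")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap or are unsorted")
        if not (self.in_exon(self.cds_start) and self.in_exon(self.cds_end)):
            raise ValueError("CDS bounds must fall inside exons")
        cds = self.cds_sequence()
        if len(cds) % 3 != 0:
            raise ValueError("spliced CDS length not a multiple of 3")
        prot = str(Seq(cds).translate())
        if not cds.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if not prot.endswith("*"):
            raise ValueError("CDS does not end with a stop codon")
        if "*" in prot[:-1]:
            raise ValueError("CDS contains an internal stop codon")


# ---- tabular I/O -----------------------------------------------------------


def write_transcript_table(models: list[TranscriptModel], tsv_path: str, fasta_path: str) -> None:
    """Write exon table (GFF-like TSV) plus locus reference FASTA."""
    rows = []
    for m in models:
        for k, (s, e) in enumerate(m.exons, start=1):
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "chrom": m.chrom,
                    "strand": m.strand,
                    "exon_number": k,
                    "exon_start": s,
                    "exon_end": e,
                    "cds_start": m.cds_start,
                    "cds_end": m.cds_end,
                    "seq_start": m.seq_start,
                }
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for m in models:
            fh.write(f">{m.gene_id} chrom={m.chrom} seq_start={m.seq_start}\n")
            for i in range(0, len(m.ref_seq), 70):
                fh.write(m.ref_seq[i : i + 70] + "\n")


def read_transcript_table(tsv_path: str, fasta_path: str) -> list[TranscriptModel]:
    seqs: dict[str, str] = {}
    name = None
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line
    df = pd.read_csv(tsv_path, sep="\t")
    models = []
    for gene_id, g in df.groupby("gene_id", sort=False):
        g = g.sort_values("exon_number")
        m = TranscriptModel(
            gene_id=str(gene_id),
            chrom=str(g["chrom"].iloc[0]),
            strand=str(g["strand"].iloc[0]),
            exons=tuple(
                (int(s), int(e)) for s, e in zip(g["exon_start"], g["exon_end"])
            ),
            cds_start=int(g["cds_start"].iloc[0]),
            cds_end=int(g["cds_end"].iloc[0]),
            ref_seq=seqs[str(gene_id)],
            seq_start=int(g["seq_start"].iloc[0]),
        )
        m.validate()
        models.append(m)
    return models
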