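"""Genotype call-set container and VCF 4.2 round-trip.

A :class:`CallSet` holds a sites-by-samples dosage matrix together with
per-call allele depths (AD), which the QC stage needs for the heterozygous
allele-balance filter.  Multi-allelic sites are stored decomposed — one row
per alternate allele — sharing a ``group_id`` so downstream code can still
recognise them as one genomic site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "group_id"]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class CallSet:
    """Samples x variant sites with dosages {0,1,2,-1(missing)} and AD.

    Attributes
    ----------
    sample_ids : list of str
    sites : DataFrame with columns chrom, pos (1-based), ref, alt, group_id
    dosage : int8 array, shape (n_sites, n_samples); -1 encodes a missing call
    ad_ref, ad_alt : int32 arrays of per-call read depths (0 where absent)
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n_sites, n_samples = self.dosage.shape
        if n_sites != len(self.sites) or n_samples != len(self.sample_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sites)} sites x {len(self.sample_ids)} samples"
            )
        if (self.sites["pos"] < 1).any():
            raise ValueError("VCF positions are 1-based; pos must be >= 1")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def variant_keys(self) -> list[str]:
        return [
            variant_key(c, p, r, a)
            for c, p, r, a in zip(
                self.sites["chrom"], self.sites["pos"], self.sites["ref"], self.sites["alt"]
            )
        ]

    def subset_sites(self, mask: np.ndarray) -> "CallSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CallSet(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[idx],
            ad_ref=None if self.ad_ref is None else self.ad_ref[idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[idx],
        )

    def equals(self, other: "CallSet") -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        if not self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS]):
            return False
        if not np.array_equal(self.dosage, other.dosage):
            return False
        for a, b in ((self.ad_ref, other.ad_ref), (self.ad_alt, other.ad_alt)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


def write_vcf(callset: CallSet, path: str) -> None:
    """Write a plain-text VCF 4.2 with GT and AD FORMAT fields.

    Multi-allelic group membership is preserved in the MAGROUP INFO field.
    """
    contigs = list(dict.fromkeys(callset.sites["chrom"]))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=brcascreen",
        '##INFO=<ID=MAGROUP,Number=1,Type=String,Description="Multi-allelic site group id">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(callset.sample_ids)
    )
    has_ad = callset.ad_ref is not None and callset.ad_alt is not None
    fmt = "GT:AD" if has_ad else "GT"
    gt_lut = ["./.", "0/0", "0/1", "1/1"]  # index dosage+1
    if has_ad:
        # distinct (gt, ad_ref, ad_alt) triples are few; format each once
        key = (
            (callset.dosage.astype(np.int64) + 1) * 10**8
            + callset.ad_ref.astype(np.int64) * 10**4
            + callset.ad_alt.astype(np.int64)
        )
        uniq, inverse = np.unique(key, return_inverse=True)

        def _fmt(k: int) -> str:
            d, rest = divmod(int(k), 10**8)
            r, a = divmod(rest, 10**4)
            return "./.:.,." if d == 0 else f"{gt_lut[d]}:{r},{a}"

        calls = np.array([_fmt(k) for k in uniq])[inverse].reshape(callset.dosage.shape)
    else:
        calls = np.array(gt_lut)[callset.dosage.astype(np.int64) + 1]
    call_rows = calls.tolist()
    chroms = callset.sites["chrom"].tolist()
    poss = callset.sites["pos"].tolist()
    refs = callset.sites["ref"].tolist()
    alts = callset.sites["alt"].tolist()
    gids = callset.sites["group_id"].tolist()
    for i in range(callset.n_sites):
        info = f"MAGROUP={gids[i]}" if gids[i] else "."
        lines.append(
            f"{chroms[i]}\t{int(poss[i])}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t{info}\t{fmt}\t"
            + "\t".join(call_rows[i])
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> CallSet:
    """Read a VCF (one ALT per record) back into a :class:`CallSet`."""
    vf = VCF(path, gts012=True)
    sample_ids = list(vf.samples)
    rows = []
    dosage_rows = []
    ad_rows = []
    any_ad = False
    for rec in vf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"expected decomposed records (one ALT) at {rec.CHROM}:{rec.POS}"
            )
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "group_id": rec.INFO.get("MAGROUP") or "",
            }
        )
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 3 = unknown
        gt[gt == 3] = MISSING
        dosage_rows.append(gt)
        ad = rec.format("AD")
        if ad is not None:
            any_ad = True
            ad = np.asarray(ad, dtype=np.int32)
            ad[ad < 0] = 0  # missing-call sentinel
            ad_rows.append(ad)
        else:
            ad_rows.append(np.zeros((len(sample_ids), 2), dtype=np.int32))
    vf.close()
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = (
        np.vstack(dosage_rows)
        if dosage_rows
        else np.empty((0, len(sample_ids)), dtype=np.int8)
    )
    if any_ad and ad_rows:
        ad = np.stack(ad_rows)
        ad_ref, ad_alt = ad[:, :, 0], ad[:, :, 1]
    else:
        ad_ref = ad_alt = None
    return CallSet(
        sample_ids=sample_ids,
        sites=sites,
        dosage=dosage,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )
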