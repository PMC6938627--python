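"""Kinship estimation, unrelated-subset selection, admixture binning.

Kinship uses the KING-robust between-family estimator,

    phi_hat = (N_het,het - 2 * N_opposite-homozygote) / (N_het(i) + N_het(j)),

whose heterozygosity-sum denominator keeps it unbiased under population
structure and admixture — the reason it is the field standard for diverse
biobanks.  Degrees follow the powers-of-two midpoint convention
(> 2^-5/2 duplicate, (2^-7/2, 2^-5/2] first, (2^-9/2, 2^-7/2] second).

The unrelated subset is built greedily and deterministically: retain the
sample with the fewest second-degree-or-closer partners, drop its
partners, repeat (ties broken toward the lexicographically smaller id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from brcascreen.callset import MISSING, CallSet

# conventional roundings of 2^(-3/2), 2^(-5/2), 2^(-7/2) — the published
# inference cutoffs of the KING software
DUP_THRESHOLD = 0.354
FIRST_THRESHOLD = 0.177
SECOND_THRESHOLD = 0.0884
MIN_CO_GENOTYPED = 200

ADMIXTURE_BINS = ("0-20%", ">20-40%", ">40-60%", ">60%")


@dataclass(frozen=True)
class KinshipPair:
    sample_i: str
    sample_j: str
    phi: float
    degree: str


def estimate_kinship(
    callset: CallSet, i: int | str, j: int | str, min_sites: int = MIN_CO_GENOTYPED
) -> float | None:
    """KING-robust kinship for one sample pair; None if too few shared sites."""
    if isinstance(i, str):
        i = callset.sample_ids.index(i)
    if isinstance(j, str):
        j = callset.sample_ids.index(j)
    gi = callset.dosage[:, i]
    gj = callset.dosage[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    if int(ok.sum()) < min_sites:
        warnings.warn(
            f"pair ({callset.sample_ids[i]}, {callset.sample_ids[j]}): only "
            f"{int(ok.sum())} co-genotyped sites (< {min_sites}); kinship undefined",
            stacklevel=2,
        )
        return None
    gi, gj = gi[ok], gj[ok]
    n_het_i = int(np.sum(gi == 1))
    n_het_j = int(np.sum(gj == 1))
    if n_het_i + n_het_j == 0:
        return None
    n_het_het = int(np.sum((gi == 1) & (gj == 1)))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    return (n_het_het - 2.0 * n_opp) / (n_het_i + n_het_j)


def infer_degree(phi: float) -> str:
    if phi > DUP_THRESHOLD:
        return "duplicate/MZ"
    if phi > FIRST_THRESHOLD:
        return "first"
    if phi > SECOND_THRESHOLD:
        return "second"
    return "unrelated"


def related_pairs(
    callset: CallSet,
    min_phi: float = SECOND_THRESHOLD,
    min_sites: int = MIN_CO_GENOTYPED,
    block: int = 2048,
) -> list[KinshipPair]:
    """All sample pairs with kinship above ``min_phi``, block-wise.

    Counts are assembled from indicator-matrix products so memory stays at
    one ``block x block`` tile at a time.
    """
    D = callset.dosage
    valid = (D != MISSING).astype(np.float32)
    het = (D == 1).astype(np.float32)
    hom0 = (D == 0).astype(np.float32)
    hom2 = (D == 2).astype(np.float32)
    n = callset.n_samples
    ids = callset.sample_ids
    out: list[KinshipPair] = []
    for a0 in range(0, n, block):
        a1 = min(a0 + block, n)
        for b0 in range(a0, n, block):
            b1 = min(b0 + block, n)
            n_hh = het[:, a0:a1].T @ het[:, b0:b1]
            n_opp = hom0[:, a0:a1].T @ hom2[:, b0:b1] + hom2[:, a0:a1].T @ hom0[:, b0:b1]
            het_i = het[:, a0:a1].T @ valid[:, b0:b1]
            het_j = valid[:, a0:a1].T @ het[:, b0:b1]
            shared = valid[:, a0:a1].T @ valid[:, b0:b1]
            denom = het_i + het_j
            with np.errstate(divide="ignore", invalid="ignore"):
                phi = (n_hh - 2.0 * n_opp) / denom
            ok = (shared >= min_sites) & (denom > 0) & (phi > min_phi)
            for ia, ib in zip(*np.nonzero(ok)):
                gi, gj = a0 + int(ia), b0 + int(ib)
                if gi >= gj:
                    continue
                p = float(phi[ia, ib])
                out.append(KinshipPair(ids[gi], ids[gj], p, infer_degree(p)))
    out.sort(key=lambda kp: (kp.sample_i, kp.sample_j))
    return out


def select_unrelated(
    sample_ids: list[str], pairs: list[tuple[str, str]] | list[KinshipPair]
) -> list[str]:
    """Greedy unrelated subset: no retained pair at second degree or closer.

    Repeatedly retains the sample with the fewest remaining related
    partners and drops all of that sample's partners; ties go to the
    lexicographically smaller id (so of a tied pair the smaller id
    survives).  Deterministic, and near-optimal on the sparse relatedness
    graphs biobanks produce.
    """
    edges: dict[str, set[str]] = {s: set() for s in sample_ids}
    for p in pairs:
        a, b = (p.sample_i, p.sample_j) if isinstance(p, KinshipPair) else p
        if a not in edges or b not in edges:
            raise ValueError(f"pair ({a}, {b}) references unknown sample(s)")
        if a == b:
            continue
        edges[a].add(b)
        edges[b].add(a)
    remaining = set(sample_ids)
    retained: set[str] = set()
    while remaining:
        keep = min(remaining, key=lambda s: (len(edges[s] & remaining), s))
        retained.add(keep)
        remaining.discard(keep)
        remaining -= edges[keep]
    return sorted(retained)


def bin_admixture(
    proportions: pd.Series | dict[str, float]
) -> pd.DataFrame:
    """Bin per-sample proportions of one ancestry component.

    Half-open bins: [0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 1].
    """
    if isinstance(proportions, dict):
        proportions = pd.Series(proportions)
    vals = proportions.astype(float)
    if ((vals < 0) | (vals > 1)).any():
        bad = vals[(vals < 0) | (vals > 1)]
        raise ValueError(f"admixture proportions outside [0,1]: {bad.to_dict()}")

    def label(x: float) -> str:
        if x <= 0.2:
            return ADMIXTURE_BINS[0]
        if x <= 0.4:
            return ADMIXTURE_BINS[1]
        if x <= 0.6:
            return ADMIXTURE_BINS[2]
        return ADMIXTURE_BINS[3]

    return pd.DataFrame(
        {
            "sample_id": vals.index,
            "proportion": vals.values,
            "bin": [label(x) for x in vals],
        }
    ).reset_index(drop=True)
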