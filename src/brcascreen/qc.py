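"""Site-level genotype QC: missingness, het allele balance, exact HWE.

Three independent filters, mirroring standard exome call-set QC:

* per-site call missingness > ``max_missingness`` (default 0.02) fails;
* mean alternate-allele read fraction among heterozygous carriers outside
  the open interval (``ab_low``, ``ab_high``) = (0.3, 0.8) fails;
* Hardy-Weinberg exact-test p-value below ``hwe_alpha`` (default 1e-6) in
  ANY ancestry stratum with at least ``min_stratum_n`` genotyped samples
  fails.  Stratification matters in an admixed cohort: pooling strata with
  different allele frequencies creates a Wahlund excess of homozygotes that
  can mask (or mimic) genotyping artifacts.

All inequalities are strict, so a site sitting exactly on a threshold
passes.  The HWE test is the exact conditional test on heterozygote counts
(Wigginton-style): given the minor-allele count, sum the probabilities of
every heterozygote count no more probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special

from brcascreen.callset import MISSING, CallSet

#: Minimum genotyped samples for a stratum to be HWE-tested.
DEFAULT_MIN_STRATUM_N = 50


@dataclass(frozen=True)
class QCThresholds:
    max_missingness: float = 0.02
    ab_low: float = 0.3
    ab_high: float = 0.8
    hwe_alpha: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.ab_low < self.ab_high <= 1.0):
            raise ValueError("require 0 <= ab_low < ab_high <= 1")
        if not (0.0 <= self.max_missingness <= 1.0):
            raise ValueError("max_missingness must be in [0,1]")
        if not (0.0 <= self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must be in [0,1)")


@dataclass
class SiteQCReport:
    """Per-site metrics, pass/fail flags and per-filter removal counts."""

    table: pd.DataFrame
    removed_counts: dict[str, int]
    retained: int
    removed: int
    notes: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.retained + self.removed


def site_missingness(callset: CallSet, site_index: int) -> float:
    """Fraction of missing calls at one site."""
    row = callset.dosage[site_index]
    return float(np.mean(row == MISSING))


def het_allele_balance(callset: CallSet, site_index: int) -> float | None:
    """Mean alt-read fraction over het carriers at one site.

    Returns None (undefined) when the site has no heterozygous carrier with
    nonzero total depth; such sites pass the AB filter by default.
    """
    if callset.ad_ref is None or callset.ad_alt is None:
        return None
    het = callset.dosage[site_index] == 1
    ref = callset.ad_ref[site_index][het].astype(float)
    alt = callset.ad_alt[site_index][het].astype(float)
    tot = ref + alt
    ok = tot > 0
    if not ok.any():
        return None
    return float(np.mean(alt[ok] / tot[ok]))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg p-value from genotype counts.

    Conditional on the observed allele counts, heterozygote counts with the
    parity of the minor-allele count follow an exact distribution; the
    p-value is the total probability of counts no more probable than the
    observed one.  Computed by the numerically stable ratio recurrence.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor-allele copies
    if rare == 0:
        return 1.0

    # possible het counts share the parity of the minor-allele count
    h = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_r = (rare - h) // 2  # rare homozygotes
    hom_c = n - h - hom_r  # common homozygotes
    # log P(h) up to the shared constant, in log space to avoid overflow
    logp = h * math.log(2.0) - (
        scipy.special.gammaln(h + 1)
        + scipy.special.gammaln(hom_r + 1)
        + scipy.special.gammaln(hom_c + 1)
    )
    logz = scipy.special.logsumexp(logp)
    log_obs = logp[np.flatnonzero(h == n_het)[0]]
    take = logp <= log_obs + 1e-9
    return float(min(1.0, math.exp(scipy.special.logsumexp(logp[take]) - logz)))


def _genotype_counts(dosage_row: np.ndarray) -> tuple[int, int, int]:
    return (
        int(np.sum(dosage_row == 0)),
        int(np.sum(dosage_row == 1)),
        int(np.sum(dosage_row == 2)),
    )


def apply_site_filters(
    callset: CallSet,
    thresholds: QCThresholds | None = None,
    strata: dict[str, str] | None = None,
    min_stratum_n: int = DEFAULT_MIN_STRATUM_N,
) -> tuple[CallSet, SiteQCReport]:
    """Apply the three site filters independently and report each.

    Parameters
    ----------
    strata : mapping sample id -> ancestry stratum label.  Unlabeled samples
        form their own "NA" stratum, which is never HWE-tested.
    """
    thresholds = thresholds or QCThresholds()
    strata = strata or {}
    n_sites = callset.n_sites
    rows = []
    if n_sites == 0:
        report = SiteQCReport(
            table=pd.DataFrame(
                columns=[
                    "key",
                    "missingness",
                    "mean_het_ab",
                    "min_hwe_p",
                    "hwe_stratum",
                    "multiallelic",
                    "pass",
                    "reasons",
                ]
            ),
            removed_counts={"missingness": 0, "allele_balance": 0, "hwe": 0},
            retained=0,
            removed=0,
        )
        return callset, report

    labels = np.array([strata.get(s, "NA") for s in callset.sample_ids])
    stratum_masks = {
        lab: labels == lab for lab in np.unique(labels) if lab != "NA"
    }

    keys = callset.variant_keys
    group_sizes = callset.sites["group_id"].map(
        callset.sites["group_id"].value_counts()
    )
    keep = np.ones(n_sites, dtype=bool)
    counts = {"missingness": 0, "allele_balance": 0, "hwe": 0}
    for i in range(n_sites):
        reasons = []
        miss = site_missingness(callset, i)
        if miss > thresholds.max_missingness:
            reasons.append("missingness")
        ab = het_allele_balance(callset, i)
        if ab is not None and (ab < thresholds.ab_low or ab > thresholds.ab_high):
            reasons.append("allele_balance")
        min_p, min_stratum = np.nan, ""
        row = callset.dosage[i]
        for lab, mask in stratum_masks.items():
            sub = row[mask]
            sub = sub[sub != MISSING]
            if len(sub) < min_stratum_n:
                continue
            p = hwe_exact_p(*_genotype_counts(sub))
            if math.isnan(min_p) or p < min_p:
                min_p, min_stratum = p, lab
        if not math.isnan(min_p) and min_p < thresholds.hwe_alpha:
            reasons.append("hwe")
        for r in reasons:
            counts[r] += 1
        ok = not reasons
        keep[i] = ok
        multi = bool(callset.sites.iloc[i]["group_id"]) and group_sizes.iloc[i] > 1
        rows.append(
            {
                "key": keys[i],
                "missingness": miss,
                "mean_het_ab": ab,
                "min_hwe_p": min_p,
                "hwe_stratum": min_stratum,
                "multiallelic": multi,
                "pass": ok,
                "reasons": ";".join(reasons),
            }
        )
    table = pd.DataFrame(rows)
    notes = []
    n_multi_flag = int(table["multiallelic"].sum())
    if n_multi_flag:
        notes.append(
            f"{n_multi_flag} decomposed multi-allelic records retained pending "
            "manual pileup review of pathogenic carriers (not automated)"
        )
    report = SiteQCReport(
        table=table,
        removed_counts=counts,
        retained=int(keep.sum()),
        removed=int((~keep).sum()),
        notes=notes,
    )
    return callset.subset_sites(keep), report
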