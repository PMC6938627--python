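"""Site QC: missingness, het allele balance, exact HWE, combined filters."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brcascreen.callset import MISSING, CallSet
from brcascreen.qc import (
    QCThresholds,
    apply_site_filters,
    het_allele_balance,
    hwe_exact_p,
    site_missingness,
)


def _callset(dosage, ad_ref=None, ad_alt=None, sample_prefix="S"):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    sites = pd.DataFrame(
        {
            "chrom": ["1"] * n_sites,
            "pos": np.arange(1, n_sites + 1),
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
            "group_id": [""] * n_sites,
        }
    )
    return CallSet(
        [f"{sample_prefix}{i}" for i in range(n_samples)],
        sites,
        dosage,
        None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32),
    )


class TestMissingness:
    @pytest.mark.parametrize(
        "n_missing,expected,passes",
        [(0, 0.0, True), (3, 0.03, False), (2, 0.02, True)],
    )
    def test_thresholds_are_strict(self, n_missing, expected, passes):
        row = np.zeros(100, dtype=np.int8)
        row[:n_missing] = MISSING
        cs = _callset(row[None, :])
        assert site_missingness(cs, 0) == pytest.approx(expected)
        _, report = apply_site_filters(cs, QCThresholds())
        assert bool(report.table["pass"][0]) is passes


class TestAlleleBalance:
    def test_single_balanced_het(self):
        cs = _callset([[1]], ad_ref=[[5]], ad_alt=[[5]])
        assert het_allele_balance(cs, 0) == pytest.approx(0.5)

    def test_mean_over_hets_fails_low(self):
        cs = _callset([[1, 1, 0]], ad_ref=[[9, 8, 10]], ad_alt=[[1, 2, 0]])
        assert het_allele_balance(cs, 0) == pytest.approx(0.15)
        _, report = apply_site_filters(cs, QCThresholds())
        assert report.table["reasons"][0] == "allele_balance"

    def test_boundary_mean_passes(self):
        # mean exactly 0.3: strict inequality keeps the site
        cs = _callset([[1, 1]], ad_ref=[[7, 7]], ad_alt=[[3, 3]])
        assert het_allele_balance(cs, 0) == pytest.approx(0.3)
        _, report = apply_site_filters(cs, QCThresholds())
        assert bool(report.table["pass"][0])

    def test_no_het_carriers_is_undefined_and_passes(self):
        cs = _callset([[0, 2]], ad_ref=[[10, 0]], ad_alt=[[0, 10]])
        assert het_allele_balance(cs, 0) is None
        _, report = apply_site_filters(cs, QCThresholds())
        assert bool(report.table["pass"][0])


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration over all het counts (independent route)."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0
    common = 2 * n - rare

    def prob(h: int) -> Fraction:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return Fraction(
            math.factorial(n) * 2**h * math.factorial(rare) * math.factorial(common),
            math.factorial(hom_r)
            * math.factorial(h)
            * math.factorial(hom_c)
            * math.factorial(2 * n),
        )

    probs = {h: prob(h) for h in range(rare % 2, min(rare, common) + 1, 2)}
    observed = probs[n_het]
    return float(sum(v for v in probs.values() if v <= observed))


class TestHWEExact:
    def test_monomorphic_site_is_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0

    def test_balanced_case_matches_enumeration(self):
        assert hwe_exact_p(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-12)

    def test_extreme_heterozygote_excess_fails_filter(self):
        p = hwe_exact_p(0, 100, 0)
        assert p == pytest.approx(hwe_oracle(0, 100, 0), abs=1e-12)
        assert p < 1e-6

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 5, 5)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=120),
        st.integers(min_value=0, max_value=120),
        st.integers(min_value=0, max_value=120),
    )
    def test_matches_enumeration_oracle(self, a, b, c):
        if a + b + c == 0 or a + b + c > 200:
            return
        assert hwe_exact_p(a, b, c) == pytest.approx(hwe_oracle(a, b, c), abs=1e-12)


class TestApplySiteFilters:
    def test_extreme_thresholds_are_identity(self, small_cohort):
        _, callset, cohort, _ = small_cohort
        sub = callset.subset_sites(np.arange(80))
        thresholds = QCThresholds(max_missingness=1.0, ab_low=0.0, ab_high=1.0, hwe_alpha=0.0)
        filtered, report = apply_site_filters(sub, thresholds)
        assert filtered.equals(sub)
        assert report.removed == 0

    def test_double_failure_listed_once_with_two_reasons(self):
        # 1 het with skewed depths among 100 samples, plus 3 missing calls
        row = np.zeros(100, dtype=np.int8)
        row[0] = 1
        row[1:4] = MISSING
        ar = np.zeros((1, 100), dtype=np.int32)
        aa = np.zeros((1, 100), dtype=np.int32)
        ar[0, 0], aa[0, 0] = 9, 1
        cs = _callset(row[None, :], ar, aa)
        filtered, report = apply_site_filters(cs, QCThresholds())
        assert filtered.n_sites == 0
        assert report.removed == 1
        assert set(report.table["reasons"][0].split(";")) == {"missingness", "allele_balance"}

    def test_sample_permutation_invariance(self, small_cohort):
        _, callset, cohort, _ = small_cohort
        sub = callset.subset_sites(np.arange(60))
        strata = dict(zip(cohort.samples["sample_id"], cohort.samples["self_reported"]))
        rng = np.random.default_rng(5)
        perm = rng.permutation(sub.n_samples)
        permuted = CallSet(
            [sub.sample_ids[i] for i in perm],
            sub.sites,
            sub.dosage[:, perm],
            sub.ad_ref[:, perm],
            sub.ad_alt[:, perm],
        )
        f1, _ = apply_site_filters(sub, QCThresholds(), strata)
        f2, _ = apply_site_filters(permuted, QCThresholds(), strata)
        assert f1.variant_keys == f2.variant_keys

    def test_idempotence_and_conservation(self, small_cohort):
        _, callset, cohort, _ = small_cohort
        strata = dict(zip(cohort.samples["sample_id"], cohort.samples["self_reported"]))
        filtered, report = apply_site_filters(callset, QCThresholds(), strata)
        assert report.retained + report.removed == callset.n_sites
        again, report2 = apply_site_filters(filtered, QCThresholds(), strata)
        assert report2.removed == 0
        assert again.equals(filtered)

    def test_empty_callset(self):
        cs = _callset(np.empty((0, 4), dtype=np.int8))
        filtered, report = apply_site_filters(cs, QCThresholds())
        assert filtered.n_sites == 0 and report.total == 0

    def test_stratification_detects_admixed_artifact(self):
        # two strata with opposite fixed alleles: pooled they mimic a
        # heterozygote deficit, stratified each is monomorphic and clean;
        # a within-stratum het excess is only visible stratified
        n = 60
        stratum = {f"S{i}": ("X" if i < n else "Y") for i in range(2 * n)}
        row = np.array([1] * n + [0] * n, dtype=np.int8)  # all-het in X only
        cs = _callset(row[None, :])
        _, pooled = apply_site_filters(cs, QCThresholds())
        _, strat = apply_site_filters(cs, QCThresholds(), stratum)
        assert bool(pooled.table["pass"][0])  # unstratified: no stratum tested
        assert strat.table["reasons"][0] == "hwe"
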