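"""Site-level genotype QC on a generated call set.

Three filters run independently: call missingness > 2%, mean heterozygous
allele balance outside (0.3, 0.8), and a Hardy-Weinberg exact-test p below
1e-6 in any self-reported ancestry stratum with >= 50 genotyped samples.
"""

from brcascreen.qc import QCThresholds, apply_site_filters, hwe_exact_p
from brcascreen.simulate import SimConfig, generate_cohort

callset, cohort, _ = generate_cohort(
    SimConfig(n_samples=3000, seed=7, ab_bad_site_fraction=0.08, relative_pairs=())
)
strata = dict(zip(cohort.samples["sample_id"], cohort.samples["self_reported"]))
filtered, report = apply_site_filters(callset, QCThresholds(), strata)

print(f"input sites: {report.total}; retained: {report.retained}; "
      f"removed: {report.removed}")
for reason, count in report.removed_counts.items():
    print(f"  removed by {reason}: {count}")
print("a site failing several filters is removed once but every reason is logged")

# the exact test itself: a site with only heterozygotes is wildly off HWE
print(f"HWE exact p for (0 hom-ref, 100 het, 0 hom-alt): {hwe_exact_p(0, 100, 0):.2e}"
      " -> fails the 1e-6 screen")
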