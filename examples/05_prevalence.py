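"""Carrier prevalence with '1 in N' formatting, Wilson CIs and Yates tests.

The numbers here are the published-table style of output: a rate, its
"1 in N" rendering (round half away from zero), and a Wilson score
interval, which stays sensible at very small proportions.
"""

from brcascreen.prevalence import prevalence, wilson_ci, yates_chi2

r = prevalence(218, 30223, group="all participants")
print(f"{r.group}: {r.carriers}/{r.n} = {r.rate:.2%} -> {r.render_one_in_n()} "
      f"(95% CI {r.ci_low:.2%}-{r.ci_high:.2%})")

r = prevalence(8, 1116, group="half-integer rounding")
print(f"{r.group}: N/carriers = {1116 / 8} -> {r.render_one_in_n()}")

lo, hi = wilson_ci(78, 688)
print(f"uncertain/conflicting rate 78/688: {78 / 688:.1%} "
      f"(Wilson 95% CI {lo:.1%}-{hi:.1%})")

res = yates_chi2(53, 84, 5, 76)
print(f"clinical testing, female vs male (53/137 vs 5/81): "
      f"chi2={res.chi2:.1f}, p={res.p_value:.1e} (Yates-corrected, df=1)")
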