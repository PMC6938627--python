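"""Parameter-recovery benchmark: can the pipeline recover a known odds ratio?

Generates replicate synthetic cohorts at a fixed carrier odds ratio for
HBOC-related cancer, pushes each through the real analysis path —
consequence annotation, ClinVar classification, carrier-status derivation,
ICD-based case definition, covariate-adjusted logistic regression — and
summarises the fitted odds ratios.  The mean fitted OR across replicates
is the calibration statistic: it should sit within sampling error of the
generating value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from brcascreen.association import DEFAULT_HBOC_CODES, define_cases, fit_logistic
from brcascreen.classify import classify_variants, derive_carrier_status, load_clinvar
from brcascreen.consequence import Variant, classify_variant, consensus_plof
from brcascreen.simulate import clinvar_frame, generate_cohort, recovery_config


@dataclass
class RecoveryResult:
    true_or: float
    mean_or: float
    fitted_ors: list[float]
    ci_covered: int  # replicates whose 95% CI contains the truth
    n_replicates: int
    n_samples: int


def fit_cohort_odds_ratio(callset, cohort, truth, transcripts) -> tuple[float, bool]:
    """Adjusted carrier OR for HBOC cancer on one cohort, via the full path.

    Returns (odds ratio, truth-in-CI flag).
    """
    by_chrom = {m.chrom: m for m in transcripts}
    panel_mask = np.array([c in by_chrom for c in callset.sites["chrom"]])
    panel = callset.subset_sites(panel_mask)
    consensus = {}
    consequences = {}
    for c, p, r, a in zip(panel.sites["chrom"], panel.sites["pos"],
                          panel.sites["ref"], panel.sites["alt"]):
        model = by_chrom[c]
        call = classify_variant(Variant(c, int(p), r, a), model)
        consequences[call.key] = call
        consensus[call.key] = consensus_plof(call, model)
    clinvar = load_clinvar(clinvar_frame(truth))
    classifications = classify_variants(
        panel.variant_keys, clinvar, consequences, consensus
    )
    statuses = derive_carrier_status(panel, classifications)
    status = pd.Series({s.sample_id: s.status for s in statuses})

    samples = cohort.samples.set_index("sample_id")
    keep = status.isin(["variant_positive", "variant_negative"])
    ids = status.index[keep]
    x = (status[keep] == "variant_positive").astype(float).to_numpy()
    case_flags = define_cases(cohort.icd, DEFAULT_HBOC_CODES)
    y = np.array([float(case_flags.get(s, False)) for s in ids])
    covs = samples.loc[ids, ["age", "female", "pc1", "pc2", "pc3", "pc4", "pc5"]].copy()
    covs["age"] = (covs["age"] - covs["age"].mean()) / covs["age"].std()
    result = fit_logistic(y, x, covs, outcome_label="HBOC-related cancer")
    if not result.converged:
        raise RuntimeError("logistic fit did not converge on a recovery replicate")
    return result.odds_ratio, (result.ci_low, result.ci_high)


def odds_ratio_recovery(
    n_replicates: int = 20,
    n_samples: int = 25_000,
    true_or: float = 5.6,
    carrier_freq: float = 0.0075,
    baseline_case_rate: float = 0.08,
    seed: int = 0,
) -> RecoveryResult:
    """Mean fitted adjusted OR over replicate cohorts at a known truth."""
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    ors: list[float] = []
    covered = 0
    for ss in child_seeds:
        rep_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        config = recovery_config(
            n_samples=n_samples, seed=rep_seed, true_or=true_or,
            carrier_freq=carrier_freq, baseline_case_rate=baseline_case_rate,
        )
        callset, cohort, truth = generate_cohort(config)
        or_hat, (lo, hi) = fit_cohort_odds_ratio(
            callset, cohort, truth, cohort.transcripts
        )
        ors.append(or_hat)
        if lo <= true_or <= hi:
            covered += 1
    return RecoveryResult(
        true_or=true_or,
        mean_or=float(np.mean(ors)),
        fitted_ors=ors,
        ci_covered=covered,
        n_replicates=n_replicates,
        n_samples=n_samples,
    )
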