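"""Case-control logistic regression and phecode PheWAS.

Cases are samples carrying any ICD-9/10 code from a configurable
HBOC-related cancer code set (breast, ovarian, prostate, pancreatic,
melanoma); controls carry none.  Odds ratios come from maximum-likelihood
logistic regression (Newton/IRLS, tolerance 1e-8, at most 50 iterations)
with Wald confidence intervals, adjusting for age, sex and five ancestry
covariates.  The PheWAS fits one model per phecode carried by at least
``min_carriers`` exposed samples and applies a Bonferroni threshold of
alpha / number of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

#: Default HBOC-related cancer code set (personal history).  Shipped as an
#: editable starting point, not an authoritative clinical list.
DEFAULT_HBOC_CODES: frozenset[tuple[str, str]] = frozenset(
    {
        ("ICD-9", "174.9"),   # malignant neoplasm of female breast
        ("ICD-9", "175.9"),   # malignant neoplasm of male breast
        ("ICD-9", "183.0"),   # malignant neoplasm of ovary
        ("ICD-9", "185"),     # malignant neoplasm of prostate
        ("ICD-9", "157.9"),   # malignant neoplasm of pancreas
        ("ICD-9", "172.9"),   # malignant melanoma of skin
        ("ICD-9", "V10.3"),   # personal history, breast cancer
        ("ICD-10", "C50.9"),  # malignant neoplasm of breast
        ("ICD-10", "C56.9"),  # malignant neoplasm of ovary
        ("ICD-10", "C61"),    # malignant neoplasm of prostate
        ("ICD-10", "C25.9"),  # malignant neoplasm of pancreas
        ("ICD-10", "C43.9"),  # malignant melanoma of skin
        ("ICD-10", "Z85.3"),  # personal history, breast cancer
    }
)


@dataclass(frozen=True)
class PheWASConfig:
    min_carriers: int = 5
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "female", "pc1", "pc2", "pc3", "pc4", "pc5")

    def __post_init__(self) -> None:
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")


@dataclass
class AssociationResult:
    outcome: str
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n_cases: int
    n_controls: int
    n_exposed_cases: int
    converged: bool


def define_cases(
    icd: pd.DataFrame, code_set: frozenset[tuple[str, str]] | set[tuple[str, str]]
) -> pd.Series:
    """Case flags from an ICD long table (sample_id, system, code).

    Returns a boolean Series indexed by every sample that appears in the
    table; callers mark absent samples as controls.
    """
    if not code_set:
        raise ValueError("HBOC code set must be non-empty")
    pairs = set(zip(icd["system"], icd["code"]))
    unknown_systems = {s for s, _ in pairs} - {"ICD-9", "ICD-10"}
    if unknown_systems:
        raise ValueError(f"unknown code systems: {sorted(unknown_systems)}")
    hit = icd.apply(lambda r: (r["system"], r["code"]) in code_set, axis=1)
    flags = icd.assign(hit=hit).groupby("sample_id")["hit"].any()
    return flags


def fit_logistic(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    outcome_label: str = "outcome",
    maxiter: int = 50,
    tol: float = 1e-8,
) -> AssociationResult:
    """Adjusted logistic regression; OR, Wald CI and p for the exposure term."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0} or set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("outcome and exposure must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    if len(np.unique(x)) < 2:
        raise ValueError("exposure is constant")
    cols = [x]
    names = ["exposure"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cols += [cov[c].to_numpy(dtype=float) for c in cov.columns]
        names += [str(c) for c in cov.columns]
    X = sm.add_constant(np.column_stack(cols), prepend=True)
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    n_exposed_cases = int((y * x).sum())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=False, warn_convergence=False
            )
        converged = bool(fit.mle_retvals.get("converged", False))
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
            converged = False  # quasi-separation: SE blows up
    except Exception:
        converged = False
    if not converged:
        return AssociationResult(
            outcome_label, None, None, None, None, n_cases, n_controls, n_exposed_cases, False
        )
    z = norm.ppf(0.975)
    p = 2 * norm.sf(abs(beta / se))
    return AssociationResult(
        outcome_label,
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
        float(p),
        n_cases,
        n_controls,
        n_exposed_cases,
        True,
    )


def load_phecode_map(map_df: pd.DataFrame) -> dict[tuple[str, str], str]:
    """ICD -> phecode map from a CSV-style frame (system, code, phecode)."""
    required = {"system", "code", "phecode"}
    if not required <= set(map_df.columns):
        raise ValueError(f"phecode map needs columns {sorted(required)}")
    bad = map_df[
        map_df["system"].isna() | map_df["code"].isna() | map_df["phecode"].isna()
    ]
    if len(bad):
        raise ValueError(f"malformed phecode map rows at index {list(bad.index)}")
    return {
        (str(r["system"]), str(r["code"])): str(r["phecode"])
        for _, r in map_df.iterrows()
    }


def map_phecodes(
    icd: pd.DataFrame, phecode_map: dict[tuple[str, str], str]
) -> tuple[dict[str, set[str]], int]:
    """Collapse per-sample ICD codes to phecode sets.

    Returns (sample_id -> phecode set, count of unmapped code observations).
    """
    out: dict[str, set[str]] = {}
    unmapped = 0
    for sid, system, code in zip(icd["sample_id"], icd["system"], icd["code"]):
        ph = phecode_map.get((system, code))
        if ph is None:
            unmapped += 1
            continue
        out.setdefault(sid, set()).add(ph)
    return out, unmapped


def run_phewas(
    sample_ids: list[str],
    exposure: np.ndarray,
    phecodes: dict[str, set[str]],
    covariates: pd.DataFrame | None = None,
    config: PheWASConfig | None = None,
) -> tuple[list[AssociationResult], float | None]:
    """One adjusted logistic fit per eligible phecode, Bonferroni threshold.

    A phecode is eligible when present in at least ``config.min_carriers``
    exposed (variant-positive) samples.  Returns results sorted by p-value
    and the Bonferroni-adjusted significance threshold (None if no test ran).
    """
    config = config or PheWASConfig()
    exposure = np.asarray(exposure, dtype=float)
    all_codes = sorted(set().union(*phecodes.values())) if phecodes else []
    exposed_ids = {s for s, e in zip(sample_ids, exposure) if e == 1}
    eligible = [
        code
        for code in all_codes
        if sum(1 for s in exposed_ids if code in phecodes.get(s, ())) >= config.min_carriers
    ]
    if not eligible:
        return [], None
    threshold = config.alpha / len(eligible)
    results = []
    for code in eligible:
        y = np.array([1.0 if code in phecodes.get(s, ()) else 0.0 for s in sample_ids])
        try:
            res = fit_logistic(y, exposure, covariates, outcome_label=code)
        except ValueError:
            res = AssociationResult(code, None, None, None, None,
                                    int(y.sum()), int(len(y) - y.sum()),
                                    int((y * exposure).sum()), False)
        results.append(res)
    results.sort(key=lambda r: (r.p_value is None, r.p_value))
    return results, threshold


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "outcome": [r.outcome for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "n_cases": [r.n_cases for r in results],
            "n_controls": [r.n_controls for r in results],
            "n_exposed_cases": [r.n_exposed_cases for r in results],
            "converged": [r.converged for r in results],
        }
    )
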