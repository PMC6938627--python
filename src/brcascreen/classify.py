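"""ClinVar cross-referencing, the expected-pathogenic set, carrier status.

The screening set — "expected pathogenic" — is the union of

* variants with a ClinVar pathogenic or likely-pathogenic assertion, and
* variants absent from ClinVar whose consequence is high-confidence pLOF.

A pLOF variant that IS asserted in ClinVar keeps its ClinVar category.
Review stars are retained descriptively and never used as a filter.
ClinVar "conflicting interpretations" remains its own category but is
pooled with "uncertain significance" for all rate computations
(uncertain/conflicting), replacing case-by-case curator review with a
deterministic rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from brcascreen.callset import CallSet
from brcascreen.consequence import ConsequenceCall

CLINVAR_ASSERTIONS = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain_significance",
    "conflicting",
    "likely_benign",
    "benign",
)

_ASSERTION_TO_CATEGORY = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "uncertain_significance": "uncertain",
    "conflicting": "conflicting",
    "likely_benign": "likely_benign",
    "benign": "benign",
}

CATEGORIES = (
    "pathogenic",
    "likely_pathogenic",
    "conflicting",
    "uncertain",
    "likely_benign",
    "benign",
    "novel",
)

#: carrier-status labels in precedence order
STATUSES = ("variant_positive", "uncertain_conflicting", "novel_only", "variant_negative")


@dataclass(frozen=True)
class ClinVarRecord:
    key: str
    assertion: str
    stars: int = 0

    def __post_init__(self) -> None:
        if self.assertion not in CLINVAR_ASSERTIONS:
            raise ValueError(f"unknown assertion {self.assertion!r}")
        if not (0 <= self.stars <= 4):
            raise ValueError("review stars must be 0..4")


def load_clinvar(records: pd.DataFrame | list[ClinVarRecord]) -> dict[str, ClinVarRecord]:
    """Index ClinVar-style records by variant key, rejecting duplicates."""
    if isinstance(records, pd.DataFrame):
        records = [
            ClinVarRecord(r["key"], r["assertion"], int(r.get("stars", 0)))
            for _, r in records.iterrows()
        ]
    out: dict[str, ClinVarRecord] = {}
    for rec in records:
        if rec.key in out:
            raise ValueError(f"duplicate ClinVar record for {rec.key}")
        out[rec.key] = rec
    return out


@dataclass
class VariantClassification:
    key: str
    category: str
    expected_pathogenic: bool
    plof_consensus: bool
    stars: int | None = None
    founder_populations: list[str] = field(default_factory=list)

    @property
    def uncertain_conflicting(self) -> bool:
        return self.category in ("uncertain", "conflicting")


@dataclass
class CarrierStatus:
    sample_id: str
    status: str
    expected_pathogenic_keys: list[str] = field(default_factory=list)


def classify_variants(
    variant_keys: list[str],
    clinvar: dict[str, ClinVarRecord],
    consequences: dict[str, ConsequenceCall] | None = None,
    consensus_flags: dict[str, bool] | None = None,
) -> list[VariantClassification]:
    """Assign each variant exactly one category and the expected-pathogenic flag.

    Parameters
    ----------
    consequences : consequence calls for variants absent from ClinVar
        (required for every such variant).
    consensus_flags : variant key -> high-confidence pLOF consensus flag.
        When omitted, derived from ``consequences`` alone is not possible
        (confidence needs the transcript), so callers normally pass the
        output of :func:`brcascreen.consequence.consensus_plof`.
    """
    consequences = consequences or {}
    consensus_flags = consensus_flags or {}
    missing = [
        k for k in variant_keys if k not in clinvar and k not in consequences
    ]
    if missing:
        raise ValueError(
            "variants with neither a ClinVar record nor a consequence call: "
            + ", ".join(missing)
        )
    out = []
    for key in variant_keys:
        if key in clinvar:
            rec = clinvar[key]
            category = _ASSERTION_TO_CATEGORY[rec.assertion]
            consensus = bool(consensus_flags.get(key, False))
            expected = category in ("pathogenic", "likely_pathogenic")
            stars = rec.stars
        else:
            category = "novel"
            consensus = bool(consensus_flags.get(key, False))
            expected = consensus
            stars = None
        out.append(
            VariantClassification(
                key=key,
                category=category,
                expected_pathogenic=expected,
                plof_consensus=consensus,
                stars=stars,
            )
        )
    return out


def derive_carrier_status(
    callset: CallSet, classifications: list[VariantClassification]
) -> list[CarrierStatus]:
    """Per-sample screening status from the filtered call set.

    Precedence: carrying any expected-pathogenic variant makes a sample
    variant_positive; otherwise any uncertain/conflicting variant makes it
    uncertain_conflicting; otherwise any novel variant makes it novel_only;
    otherwise variant_negative.  A sample with expected-pathogenic variants
    in two genes is one positive sample carrying both keys.
    """
    by_key = {c.key: c for c in classifications}
    keys = callset.variant_keys
    uncovered = [k for k in keys if k not in by_key]
    if uncovered:
        raise ValueError(f"classifications missing for: {', '.join(uncovered)}")
    carried = callset.dosage >= 1
    expected = np.array([by_key[k].expected_pathogenic for k in keys])
    uncertain = np.array([by_key[k].uncertain_conflicting for k in keys])
    novel = np.array([by_key[k].category == "novel" for k in keys])
    out = []
    for j, sid in enumerate(callset.sample_ids):
        col = carried[:, j]
        if (col & expected).any():
            status = "variant_positive"
            carried_keys = [keys[i] for i in np.flatnonzero(col & expected)]
        elif (col & uncertain).any():
            status, carried_keys = "uncertain_conflicting", []
        elif (col & novel).any():
            status, carried_keys = "novel_only", []
        else:
            status, carried_keys = "variant_negative", []
        out.append(CarrierStatus(sid, status, carried_keys))
    return out


@dataclass(frozen=True)
class FounderVariantEntry:
    key: str
    hgvs_c: str
    populations: tuple[str, ...]
    haplotype_evidence: bool = True


def load_founder_table(df: pd.DataFrame) -> dict[str, FounderVariantEntry]:
    """Founder reference TSV: key, cDNA HGVS, semicolon-joined populations."""
    out: dict[str, FounderVariantEntry] = {}
    for _, r in df.iterrows():
        if r["key"] in out:
            raise ValueError(f"duplicate founder entry for {r['key']}")
        out[r["key"]] = FounderVariantEntry(
            key=r["key"],
            hgvs_c=str(r.get("hgvs_c", "")),
            populations=tuple(str(r["populations"]).split(";")),
            haplotype_evidence=bool(r.get("haplotype_evidence", True)),
        )
    return out


def match_founders(
    classifications: list[VariantClassification],
    founder_table: dict[str, FounderVariantEntry],
) -> list[VariantClassification]:
    """Annotate classifications with founder populations by exact key match."""
    for c in classifications:
        entry = founder_table.get(c.key)
        if entry is None:
            continue
        if c.category in ("benign", "likely_benign"):
            warnings.warn(
                f"founder-table variant {c.key} is classified {c.category}; "
                "annotating anyway",
                stacklevel=2,
            )
        c.founder_populations = list(entry.populations)
    return classifications


def classifications_frame(classifications: list[VariantClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "key": [c.key for c in classifications],
            "category": [c.category for c in classifications],
            "expected_pathogenic": [c.expected_pathogenic for c in classifications],
            "plof_consensus": [c.plof_consensus for c in classifications],
            "stars": [c.stars for c in classifications],
            "founder_populations": [
                ";".join(c.founder_populations) for c in classifications
            ],
        }
    )


def carrier_frame(statuses: list[CarrierStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in statuses],
            "status": [s.status for s in statuses],
            "expected_pathogenic_keys": [
                ";".join(s.expected_pathogenic_keys) for s in statuses
            ],
        }
    )
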