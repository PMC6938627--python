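"""Synthetic biobank generator with known ground truth.

Emulates the structure of a diverse, EHR-linked exome cohort so that every
downstream stage — QC, annotation, classification, kinship pruning,
prevalence, association — can be exercised and calibrated without access
to protected individual-level data:

* ~0.7% of samples carry an "expected pathogenic" variant overall, with
  founder variants concentrated in designated ancestry communities (the
  Ashkenazi-Jewish-like group reaches ~2.1% through three founder alleles,
  a Puerto-Rican-like group carries a single recurrent stop-gain);
* the probability of carrying an uncertain/conflicting ClinVar variant
  rises linearly with one admixture component (African-like), from ~4%
  at zero to ~11% above 60%;
* carrier status raises the odds of HBOC-related cancer diagnosis codes at
  a configurable odds ratio (default 5.6) on top of modest age and sex
  effects;
* duplicate / first- / second-degree relative pairs are planted by allele
  copying, and a block of common "array-like" SNPs is emitted so kinship
  can actually be estimated (the rare gene-panel variants alone carry no
  relatedness information);
* heterozygous calls receive binomial read depths, with a configurable
  fraction of sites skewed to exercise the allele-balance filter.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from brcascreen.callset import MISSING, CallSet, write_vcf
from brcascreen.consequence import Variant, classify_variant, lof_confidence
from brcascreen.transcripts import TranscriptModel, write_transcript_table

ADMIXTURE_COMPONENTS = ("AFR", "EUR", "AMR", "EAS", "SAS")

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


@dataclass(frozen=True)
class AncestryGroup:
    label: str
    fraction: float
    self_reported: str
    dirichlet_alpha: tuple[float, ...]
    background_carrier_freq: float


@dataclass(frozen=True)
class FounderSpec:
    name: str
    group: str  # target ancestry community
    carrier_freq: float  # within the target group
    populations: tuple[str, ...]
    gene_index: int = 0  # which toy gene carries it


DEFAULT_ANCESTRY_GROUPS: tuple[AncestryGroup, ...] = (
    AncestryGroup("African American and African", 0.240, "African American/African",
                  (8.0, 2.0, 0.5, 0.25, 0.25), 0.0045),
    AncestryGroup("Ashkenazi Jewish", 0.140, "European",
                  (0.2, 12.0, 0.3, 0.25, 0.25), 0.0020),
    AncestryGroup("Non-Ashkenazi Jewish European", 0.190, "European",
                  (0.3, 12.0, 0.4, 0.3, 0.3), 0.0097),
    AncestryGroup("Filipino and other Southeast Asian", 0.020, "East/Southeast Asian",
                  (0.25, 0.5, 0.5, 10.0, 1.0), 0.0120),
    AncestryGroup("Puerto Rican", 0.180, "Hispanic/Latino",
                  (3.0, 5.0, 2.0, 0.3, 0.3), 0.0015),
    AncestryGroup("Dominican", 0.065, "Hispanic/Latino",
                  (5.0, 3.5, 1.5, 0.25, 0.25), 0.0021),
    AncestryGroup("Ecuadorian", 0.015, "Hispanic/Latino",
                  (1.5, 3.0, 6.0, 0.4, 0.3), 0.0048),
    AncestryGroup("Other Central and South American", 0.040, "Hispanic/Latino",
                  (2.0, 5.0, 4.0, 0.4, 0.3), 0.0071),
    AncestryGroup("Other", 0.110, "Other",
                  (2.0, 6.0, 1.0, 1.0, 1.0), 0.0050),
)

DEFAULT_FOUNDER_SPECS: tuple[FounderSpec, ...] = (
    FounderSpec("FND-AJ-1", "Ashkenazi Jewish", 0.009, ("Ashkenazi Jewish",), 0),
    FounderSpec("FND-AJ-2", "Ashkenazi Jewish", 0.006, ("Ashkenazi Jewish",), 0),
    FounderSpec("FND-AJ-3", "Ashkenazi Jewish", 0.004, ("Ashkenazi Jewish",), 1),
    FounderSpec("FND-PR-1", "Puerto Rican", 0.0014, ("Puerto Rican",), 1),
    FounderSpec("FND-KF-1", "Non-Ashkenazi Jewish European", 0.0006,
                ("Korean", "Finnish"), 1),
)

#: (phecode, description, baseline rate) for the non-cancer phenome panel
DEFAULT_PHECODE_PANEL: tuple[tuple[str, str, float], ...] = (
    ("401.1", "essential hypertension", 0.25),
    ("250.2", "type 2 diabetes", 0.15),
    ("272.11", "hypercholesterolemia", 0.18),
    ("278.1", "obesity", 0.14),
    ("280.1", "iron deficiency anemia", 0.06),
    ("296.22", "major depressive disorder", 0.08),
    ("300.1", "anxiety disorder", 0.09),
    ("327.3", "sleep apnea", 0.05),
    ("495", "asthma", 0.10),
    ("530.11", "gastroesophageal reflux disease", 0.12),
    ("535", "gastritis", 0.04),
    ("585.3", "chronic kidney disease stage 3", 0.05),
    ("714.1", "rheumatoid arthritis", 0.02),
    ("716.9", "arthropathy NOS", 0.07),
    ("740.1", "osteoarthritis", 0.09),
    ("743.1", "osteoporosis", 0.04),
)

#: HBOC cancer phecodes with their ICD-9/10 source codes
HBOC_PHECODES: tuple[tuple[str, str, tuple[tuple[str, str], ...]], ...] = (
    ("174.1", "malignant neoplasm of female breast",
     (("ICD-9", "174.9"), ("ICD-9", "175.9"), ("ICD-9", "V10.3"),
      ("ICD-10", "C50.9"), ("ICD-10", "Z85.3"))),
    ("184.11", "malignant neoplasm of ovary",
     (("ICD-9", "183.0"), ("ICD-10", "C56.9"))),
    ("185", "malignant neoplasm of prostate",
     (("ICD-9", "185"), ("ICD-10", "C61"))),
    ("157", "malignant neoplasm of pancreas",
     (("ICD-9", "157.9"), ("ICD-10", "C25.9"))),
    ("172.11", "malignant melanoma of skin",
     (("ICD-9", "172.9"), ("ICD-10", "C43.9"))),
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_samples: int = 30223
    seed: int = 0
    ancestry_groups: tuple[AncestryGroup, ...] = DEFAULT_ANCESTRY_GROUPS
    founder_specs: tuple[FounderSpec, ...] = DEFAULT_FOUNDER_SPECS
    background_pathogenic_freq: float | None = None  # overrides per-group freq
    uncertain_base_rate: float = 0.041
    uncertain_rate_slope: float = 0.10  # per unit AFR admixture
    novel_rate: float = 0.012  # novel missense/other carriers (per-sample)
    novel_plof_freq: float = 3e-5  # per novel pLOF variant; near-singleton
    true_or: float = 5.6
    baseline_case_rate: float = 0.08
    beta_age: float = 0.3  # per SD of age
    beta_sex: float = 0.5  # female vs male
    beta_pc: float = 0.1
    sex_female_frac: float = 0.593
    missingness_rate: float = 0.005
    depth_mean: float = 36.0
    ab_bad_site_fraction: float = 0.02
    ab_bad_mean: float = 0.15
    relative_pairs: tuple[tuple[str, int], ...] = (
        ("duplicate", 10), ("first", 150), ("second", 150),
    )
    phecode_panel: tuple[tuple[str, str, float], ...] = DEFAULT_PHECODE_PANEL
    n_kinship_snps: int = 5000  # null sd(phi) ~ 0.013, clear of the 2nd-degree cut
    n_background_pathogenic: int = 20
    n_uncertain: int = 15
    n_benign: int = 10
    n_novel_plof: int = 4
    n_novel_missense: int = 6

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        total = sum(g.fraction for g in self.ancestry_groups)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ancestry fractions sum to {total}, not 1")
        labels = {g.label for g in self.ancestry_groups}
        for spec in self.founder_specs:
            if spec.group not in labels:
                raise ValueError(f"founder target group {spec.group!r} not in ancestry_groups")
            if not (0.0 <= spec.carrier_freq <= 1.0):
                raise ValueError("founder carrier_freq must be in [0,1]")
        for f in (
            self.uncertain_base_rate, self.novel_rate, self.baseline_case_rate,
            self.missingness_rate, self.ab_bad_site_fraction, self.sex_female_frac,
        ):
            if not (0.0 <= f <= 1.0):
                raise ValueError("frequencies must be in [0,1]")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")


def recovery_config(n_samples: int = 25_000, seed: int = 0, true_or: float = 5.6,
                    carrier_freq: float = 0.0075, baseline_case_rate: float = 0.08) -> SimConfig:
    """Conditions for the odds-ratio parameter-recovery benchmark.

    Uniform carrier frequency across groups (no founder enrichment), no
    planted relatives, minimal kinship panel — relatedness is not part of
    the quantity being recovered.
    """
    return SimConfig(
        n_samples=n_samples,
        seed=seed,
        background_pathogenic_freq=carrier_freq,
        founder_specs=(),
        novel_plof_freq=0.0,  # novel pLOF would add to the carrier fraction
        true_or=true_or,
        baseline_case_rate=baseline_case_rate,
        relative_pairs=(),
        n_kinship_snps=50,
    )


@dataclass
class CohortTable:
    """Per-sample metadata plus the ICD long table."""

    samples: pd.DataFrame  # sample_id, age, female, sex, self_reported, community, admix_*, pc1..5
    icd: pd.DataFrame  # sample_id, system, code


@dataclass
class GroundTruth:
    carrier_flags: np.ndarray  # bool per sample, pre-missingness
    case_flags: np.ndarray  # bool per sample (HBOC-cancer outcome)
    variant_truth: pd.DataFrame  # key, class, clinvar_assertion, founder_populations
    kinship_pairs: list[tuple[str, str, str, float]]  # (id1, id2, degree, phi)
    true_coefficients: dict[str, float]


# --------------------------------------------------------------------------
# transcripts


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_NON_STOP_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + "".join(_NON_STOP_CODONS[i] for i in body) + stop


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_transcripts(n_genes: int, seed: int) -> list[TranscriptModel]:
    """Toy multi-exon gene models; odd indices plus-strand, even minus-strand.

    Each model has >= 3 exons, 5'/3' UTRs, GT..AG introns and a valid CDS
    (starts ATG, ends with a stop, no internal stop, length % 3 == 0).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    models = []
    for gi in range(n_genes):
        strand = "-" if gi % 2 == 0 else "+"  # gene 0 minus-strand (BRCA1-like)
        n_exons = int(rng.integers(4, 7))
        n_codons = int(rng.integers(120, 220))
        cds = _random_cds(rng, n_codons)
        utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 80))))
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 80))))
        mrna = utr5 + cds + utr3
        # split the mRNA into exons, every exon >= 12 bases; pin the final
        # junction 20-60 coding bases before the stop so the transcript
        # keeps a large NMD-competent region (high-confidence pLOF space)
        last_cut = len(utr5) + len(cds) - int(rng.integers(20, 61))
        while True:
            others = sorted(
                rng.choice(np.arange(12, last_cut - 12), size=n_exons - 2, replace=False)
            )
            cuts = [int(c) for c in others] + [last_cut]
            if all(b - a >= 12 for a, b in zip([0] + cuts, cuts + [len(mrna)])):
                break
        bounds = list(zip([0] + cuts, cuts + [len(mrna)]))  # transcript-space, 0-based half-open
        introns = [
            "GT" + "".join(rng.choice(list("ACGT"), size=int(rng.integers(26, 76)))) + "AG"
            for _ in range(n_exons - 1)
        ]
        # transcript-orientation genomic layout
        pieces = []
        exon_tx: list[tuple[int, int]] = []  # 1-based inclusive, transcript-oriented genome
        cursor = 1
        for k, (a, b) in enumerate(bounds):
            pieces.append(mrna[a:b])
            exon_tx.append((cursor, cursor + (b - a) - 1))
            cursor += b - a
            if k < len(introns):
                pieces.append(introns[k])
                cursor += len(introns[k])
        genome_tx = "".join(pieces)
        cds_tx = (len(utr5) + 1, len(utr5) + len(cds))  # transcript coords of CDS
        # map transcript coords to genomic via exon offsets
        def tx2g(t: int) -> int:
            off = 0
            for (a, b), (gs, ge) in zip(bounds, exon_tx):
                if a < t <= b:
                    return gs + (t - a) - 1
            raise AssertionError("transcript coordinate outside exons")
        cds_g = (tx2g(cds_tx[0]), tx2g(cds_tx[1]))
        if strand == "+":
            ref_seq = genome_tx
            exons = exon_tx
            cds_start, cds_end = cds_g
        else:
            T = len(genome_tx)
            ref_seq = _rc(genome_tx)
            exons = sorted((T - e + 1, T - s + 1) for s, e in exon_tx)
            cds_start, cds_end = sorted((T - cds_g[0] + 1, T - cds_g[1] + 1))
        model = TranscriptModel(
            gene_id=f"GENE{gi + 1}",
            chrom=f"chr{17 - 4 * (gi % 2)}",  # chr17-like / chr13-like alternation
            strand=strand,
            exons=tuple(exons),
            cds_start=cds_start,
            cds_end=cds_end,
            ref_seq=ref_seq,
        )
        model.validate()
        models.append(model)
    return models


# --------------------------------------------------------------------------
# variant panel


def _snv_candidates(model: TranscriptModel, rng: np.random.Generator,
                    wanted: str, count: int, used: set[int],
                    require_high: bool = False) -> list[Variant]:
    """Sample coding SNVs of a wanted consequence class from a model."""
    out: list[Variant] = []
    cds_pos = model.cds_positions()
    order = rng.permutation(len(cds_pos))
    for idx in order:
        if len(out) >= count:
            break
        pos = int(cds_pos[idx])
        if pos in used:
            continue
        ref = model.base_at(pos)
        for alt in rng.permutation(list("ACGT")):
            if alt == ref:
                continue
            v = Variant(model.chrom, pos, ref, str(alt))
            call = classify_variant(v, model)
            if call.consequence != wanted:
                continue
            if require_high and (not call.is_plof or lof_confidence(call, model) != "high"):
                continue
            out.append(v)
            used.add(pos)
            break
    if len(out) < count:
        raise RuntimeError(f"could not place {count} {wanted} SNVs in {model.gene_id}")
    return out


def _frameshift_candidates(model: TranscriptModel, rng: np.random.Generator,
                           count: int, used: set[int]) -> list[Variant]:
    out: list[Variant] = []
    cds_pos = model.cds_positions()
    order = rng.permutation(len(cds_pos))
    for idx in order:
        if len(out) >= count:
            break
        pos = int(cds_pos[idx])
        anchor = pos - 1 if model.strand == "+" else pos - 1
        if anchor in used or pos in used or not model.in_cds(anchor):
            continue
        ref = model.base_at(anchor) + model.base_at(anchor + 1)
        v = Variant(model.chrom, anchor, ref, ref[0])  # 1-bp deletion
        try:
            call = classify_variant(v, model)
        except ValueError:
            continue
        if call.consequence == "frameshift_premature_stop" and lof_confidence(call, model) == "high":
            out.append(v)
            used.add(anchor)
            used.add(pos)
    if len(out) < count:
        raise RuntimeError(f"could not place {count} frameshift indels in {model.gene_id}")
    return out


@dataclass
class _PanelVariant:
    variant: Variant
    gene_index: int
    sim_class: str  # founder / background_pathogenic / uncertain / benign / novel_plof / novel_missense
    clinvar_assertion: str | None
    stars: int | None
    founder: FounderSpec | None = None
    group_id: str = ""


def _build_panel(config: SimConfig, models: list[TranscriptModel],
                 rng: np.random.Generator) -> list[_PanelVariant]:
    used: dict[int, set[int]] = {i: set() for i in range(len(models))}
    panel: list[_PanelVariant] = []

    def pick_gene(k: int) -> int:
        return k % len(models)

    # founder variants: alternate stop-gain SNVs and frameshifts
    for k, spec in enumerate(config.founder_specs):
        g = spec.gene_index % len(models)
        if k % 2 == 0:
            v = _snv_candidates(models[g], rng, "stop_gained", 1, used[g], require_high=True)[0]
        else:
            v = _frameshift_candidates(models[g], rng, 1, used[g])[0]
        panel.append(_PanelVariant(v, g, "founder", "pathogenic", 3, founder=spec))

    # background ClinVar pathogenic / likely pathogenic (mix of pLOF and missense)
    for k in range(config.n_background_pathogenic):
        g = pick_gene(k)
        if k % 2 == 0:
            v = _snv_candidates(models[g], rng, "stop_gained", 1, used[g], require_high=True)[0]
        else:
            v = _snv_candidates(models[g], rng, "missense", 1, used[g])[0]
        assertion = "pathogenic" if k % 3 else "likely_pathogenic"
        panel.append(_PanelVariant(v, g, "background_pathogenic", assertion, 2 + (k % 2)))

    # uncertain / conflicting missense
    for k in range(config.n_uncertain):
        g = pick_gene(k)
        v = _snv_candidates(models[g], rng, "missense", 1, used[g])[0]
        assertion = "uncertain_significance" if k % 3 else "conflicting"
        panel.append(_PanelVariant(v, g, "uncertain", assertion, k % 2))

    # benign / likely benign (synonymous + missense); one multi-allelic pair
    for k in range(config.n_benign):
        g = pick_gene(k)
        wanted = "synonymous" if k % 2 else "missense"
        v = _snv_candidates(models[g], rng, wanted, 1, used[g])[0]
        assertion = "benign" if k % 2 else "likely_benign"
        panel.append(_PanelVariant(v, g, "benign", assertion, 1))
    # turn the last benign site into a multi-allelic pair when possible
    last = panel[-1]
    m = models[last.gene_index]
    for alt in "ACGT":
        if alt in (last.variant.ref, last.variant.alt):
            continue
        v2 = Variant(last.variant.chrom, last.variant.pos, last.variant.ref, alt)
        gid = f"MA_{last.variant.chrom}_{last.variant.pos}"
        last.group_id = gid
        panel.append(
            _PanelVariant(v2, last.gene_index, "benign", "likely_benign", 1, group_id=gid)
        )
        break

    # novel pLOF (absent from ClinVar): stop gains and frameshifts
    for k in range(config.n_novel_plof):
        g = pick_gene(k)
        if k % 2 == 0:
            v = _snv_candidates(models[g], rng, "stop_gained", 1, used[g], require_high=True)[0]
        else:
            v = _frameshift_candidates(models[g], rng, 1, used[g])[0]
        panel.append(_PanelVariant(v, g, "novel_plof", None, None))

    # novel missense (absent from ClinVar, not expected pathogenic)
    for k in range(config.n_novel_missense):
        g = pick_gene(k)
        v = _snv_candidates(models[g], rng, "missense", 1, used[g])[0]
        panel.append(_PanelVariant(v, g, "novel_missense", None, None))

    return panel


# --------------------------------------------------------------------------
# cohort generation


def _carrier_prob_matrix(config: SimConfig, panel: list[_PanelVariant],
                         group_idx: np.ndarray, afr: np.ndarray) -> np.ndarray:
    """Per-variant x per-sample carrier probability."""
    n = len(group_idx)
    groups = config.ancestry_groups
    probs = np.zeros((len(panel), n))
    n_bg = max(1, config.n_background_pathogenic)
    n_unc = max(1, config.n_uncertain)
    n_novel_mis = max(1, config.n_novel_missense)
    bg_freq_by_group = np.array([
        config.background_pathogenic_freq
        if config.background_pathogenic_freq is not None
        else g.background_carrier_freq
        for g in groups
    ])
    uncertain_p = np.clip(
        config.uncertain_base_rate + config.uncertain_rate_slope * afr, 0.0, 1.0
    )
    for i, pv in enumerate(panel):
        if pv.sim_class == "founder":
            gi = next(k for k, g in enumerate(groups) if g.label == pv.founder.group)
            p = np.where(group_idx == gi, pv.founder.carrier_freq, 1e-5)
        elif pv.sim_class == "background_pathogenic":
            p = bg_freq_by_group[group_idx] / n_bg
        elif pv.sim_class == "uncertain":
            p = uncertain_p / n_unc
        elif pv.sim_class == "benign":
            p = np.full(n, 0.02)
        elif pv.sim_class == "novel_plof":
            p = np.full(n, config.novel_plof_freq)
        else:  # novel_missense
            p = np.full(n, config.novel_rate / n_novel_mis)
        probs[i] = p
    return probs


def generate_cohort(config: SimConfig) -> tuple[CallSet, CohortTable, GroundTruth]:
    """Generate genotypes, metadata and EHR codes with known ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:06d}" for i in range(n)]

    groups = config.ancestry_groups
    fractions = np.array([g.fraction for g in groups])
    group_idx = rng.choice(len(groups), size=n, p=fractions)

    admix = np.empty((n, len(ADMIXTURE_COMPONENTS)))
    for gi, g in enumerate(groups):
        mask = group_idx == gi
        if mask.any():
            admix[mask] = rng.dirichlet(g.dirichlet_alpha, size=int(mask.sum()))
    afr = admix[:, 0]

    age = rng.uniform(18, 90, size=n)
    female = (rng.random(n) < config.sex_female_frac).astype(int)
    pcs = np.empty((n, 5))
    for k in range(4):
        comp = admix[:, k]
        pcs[:, k] = (comp - comp.mean()) / (comp.std() + 1e-12) + 0.1 * rng.standard_normal(n)
    pcs[:, 4] = rng.standard_normal(n)

    models = generate_transcripts(2, seed=int(rng.integers(2**31 - 1)))
    panel = _build_panel(config, models, rng)
    probs = _carrier_prob_matrix(config, panel, group_idx, afr)

    # genotypes via explicit alleles (HWE within group); q = 1 - sqrt(1-p)
    q = 1.0 - np.sqrt(1.0 - np.clip(probs, 0.0, 1.0))
    a1 = (rng.random(q.shape) < q).astype(np.int8)
    a2 = (rng.random(q.shape) < q).astype(np.int8)

    # common array-like SNPs for kinship, no population structure
    m_kin = config.n_kinship_snps
    maf = rng.uniform(0.05, 0.5, size=m_kin)
    k1 = (rng.random((m_kin, n)) < maf[:, None]).astype(np.int8)
    k2 = (rng.random((m_kin, n)) < maf[:, None]).astype(np.int8)

    A1 = np.vstack([a1, k1])
    A2 = np.vstack([a2, k2])

    # plant relatives within group, on fresh (so far unused) sample pairs
    kin_truth: list[tuple[str, str, str, float]] = []
    taken = np.zeros(n, dtype=bool)
    phi_of = {"duplicate": 0.5, "first": 0.25, "second": 0.125}
    for degree, count in config.relative_pairs:
        if degree not in phi_of:
            raise ValueError(f"unknown relative degree {degree!r}")
        for _ in range(count):
            gi = rng.choice(len(groups), p=fractions)
            pool = np.flatnonzero((group_idx == gi) & ~taken)
            if len(pool) < 2:
                continue
            a, b = rng.choice(pool, size=2, replace=False)
            taken[a] = taken[b] = True
            if degree == "duplicate":
                A1[:, b] = A1[:, a]
                A2[:, b] = A2[:, a]
            else:
                from_parent = rng.random(A1.shape[0]) < 0.5
                transmitted = np.where(from_parent, A1[:, a], A2[:, a])
                if degree == "first":
                    A1[:, b] = transmitted
                else:  # second degree: transmitted allele survives with prob 1/2
                    keep = rng.random(A1.shape[0]) < 0.5
                    A1[:, b] = np.where(keep, transmitted, A1[:, b])
            kin_truth.append(
                (sample_ids[int(a)], sample_ids[int(b)], degree, phi_of[degree])
            )

    dosage = (A1 + A2).astype(np.int8)
    n_sites = dosage.shape[0]

    # expected-pathogenic ground truth (pre-missingness)
    expected_rows = np.array([
        pv.sim_class in ("founder", "background_pathogenic", "novel_plof")
        for pv in panel
    ])
    carrier = (dosage[: len(panel)][expected_rows] >= 1).any(axis=0)

    # read depths: binomial alt reads around 0.5, skewed at "bad" sites.
    # Stochastic depths only for the gene panel — the AB filter never looks
    # at the kinship block, which gets flat nominal coverage.
    n_panel = len(panel)
    depth = np.full(dosage.shape, int(round(config.depth_mean)), dtype=np.int32)
    depth[:n_panel] = np.maximum(
        rng.poisson(config.depth_mean, size=(n_panel, n)), 1
    )
    bad_sites = rng.random(n_panel) < config.ab_bad_site_fraction
    ab = np.full(n_panel, 0.5)
    ab[bad_sites] = config.ab_bad_mean
    alt_reads = np.where(dosage == 1, depth // 2, 0)
    alt_reads[:n_panel] = rng.binomial(depth[:n_panel], ab[:, None])
    ad_alt = np.where(dosage == 1, alt_reads, np.where(dosage == 2, depth, 0))
    ad_ref = depth - ad_alt

    # missingness
    miss = rng.random(dosage.shape) < config.missingness_rate
    dosage = np.where(miss, MISSING, dosage).astype(np.int8)
    ad_ref = np.where(miss, 0, ad_ref).astype(np.int32)
    ad_alt = np.where(miss, 0, ad_alt).astype(np.int32)

    # site table
    rows = []
    for pv in panel:
        v = pv.variant
        rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "group_id": pv.group_id})
    for s in range(m_kin):
        rows.append({"chrom": "chrKIN", "pos": s + 1, "ref": "A", "alt": "G", "group_id": ""})
    sites = pd.DataFrame(rows)
    callset = CallSet(sample_ids=sample_ids, sites=sites, dosage=dosage,
                      ad_ref=ad_ref, ad_alt=ad_alt)

    # outcome model: centered covariates so the intercept is the baseline rate
    z_age = (age - age.mean()) / age.std()
    logit = (
        math.log(config.baseline_case_rate / (1 - config.baseline_case_rate))
        + math.log(config.true_or) * carrier.astype(float)
        + config.beta_age * z_age
        + config.beta_sex * (female - female.mean())
        + config.beta_pc * (pcs[:, 0] + pcs[:, 1])
    )
    p_case = 1.0 / (1.0 + np.exp(-logit))
    case = rng.random(n) < p_case

    icd = _assign_icd_codes(config, rng, sample_ids, case, female)

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "age": np.round(age, 1),
        "female": female,
        "sex": np.where(female == 1, "F", "M"),
        "self_reported": [groups[i].self_reported for i in group_idx],
        "community": [groups[i].label for i in group_idx],
        **{f"admix_{c.lower()}": np.round(admix[:, k], 6)
           for k, c in enumerate(ADMIXTURE_COMPONENTS)},
        **{f"pc{k + 1}": np.round(pcs[:, k], 6) for k in range(5)},
    })

    variant_truth = pd.DataFrame({
        "key": [pv.variant.key for pv in panel],
        "class": [pv.sim_class for pv in panel],
        "clinvar_assertion": [pv.clinvar_assertion or "" for pv in panel],
        "stars": [pv.stars if pv.stars is not None else -1 for pv in panel],
        "founder_populations": [
            ";".join(pv.founder.populations) if pv.founder else "" for pv in panel
        ],
    })
    truth = GroundTruth(
        carrier_flags=carrier,
        case_flags=case,
        variant_truth=variant_truth,
        kinship_pairs=kin_truth,
        true_coefficients={
            "intercept": math.log(config.baseline_case_rate / (1 - config.baseline_case_rate)),
            "carrier": math.log(config.true_or),
            "age_sd": config.beta_age,
            "female": config.beta_sex,
            "pc": config.beta_pc,
        },
    )
    cohort = CohortTable(samples=samples, icd=icd)
    # stash the models so write_outputs can emit them without regenerating
    cohort.transcripts = models  # type: ignore[attr-defined]
    return callset, cohort, truth


def _assign_icd_codes(config: SimConfig, rng: np.random.Generator,
                      sample_ids: list[str], case: np.ndarray,
                      female: np.ndarray) -> pd.DataFrame:
    """HBOC codes for cases (sex-aware mix) plus the background phenome panel."""
    female_sites = ["174.1", "184.11", "157", "172.11"]
    female_w = [0.6, 0.2, 0.1, 0.1]
    male_sites = ["185", "174.1", "157", "172.11"]
    male_w = [0.6, 0.1, 0.15, 0.15]
    codes_by_phecode = {ph: list(codes) for ph, _, codes in HBOC_PHECODES}
    rows: list[tuple[str, str, str]] = []
    for j in np.flatnonzero(case):
        sites, w = (female_sites, female_w) if female[j] else (male_sites, male_w)
        ph = sites[int(rng.choice(len(sites), p=w))]
        system, code = codes_by_phecode[ph][int(rng.integers(len(codes_by_phecode[ph])))]
        rows.append((sample_ids[j], system, code))
    n = len(sample_ids)
    for ph, _desc, rate in config.phecode_panel:
        hit = np.flatnonzero(rng.random(n) < rate)
        pick = rng.integers(2, size=len(hit))  # ICD-9 vs ICD-10 dialect
        for j, d in zip(hit, pick):
            system = "ICD-9" if d == 0 else "ICD-10"
            rows.append((sample_ids[int(j)], system, f"{'P9' if d == 0 else 'P10'}-{ph}"))
    return pd.DataFrame(rows, columns=["sample_id", "system", "code"])


def phecode_map_frame(config: SimConfig | None = None) -> pd.DataFrame:
    """The ICD -> phecode map matching the generator's code panel."""
    config = config or SimConfig()
    rows = []
    for ph, desc, codes in HBOC_PHECODES:
        for system, code in codes:
            rows.append({"system": system, "code": code, "phecode": ph, "description": desc})
    for ph, desc, _rate in config.phecode_panel:
        rows.append({"system": "ICD-9", "code": f"P9-{ph}", "phecode": ph, "description": desc})
        rows.append({"system": "ICD-10", "code": f"P10-{ph}", "phecode": ph, "description": desc})
    return pd.DataFrame(rows)


def clinvar_frame(truth: GroundTruth) -> pd.DataFrame:
    """ClinVar-style assertion table for every simulated classified variant."""
    df = truth.variant_truth
    present = df[df["clinvar_assertion"] != ""]
    return pd.DataFrame({
        "key": present["key"].values,
        "assertion": present["clinvar_assertion"].values,
        "stars": present["stars"].values,
    })


def founder_frame(truth: GroundTruth) -> pd.DataFrame:
    df = truth.variant_truth
    f = df[df["founder_populations"] != ""]
    return pd.DataFrame({
        "key": f["key"].values,
        "hgvs_c": [f"c.{i + 1}sim" for i in range(len(f))],
        "populations": f["founder_populations"].values,
        "haplotype_evidence": True,
    })


# --------------------------------------------------------------------------
# output writing


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(callset: CallSet, cohort: CohortTable, truth: GroundTruth,
                  outdir: str, overwrite: bool = False,
                  transcripts: list[TranscriptModel] | None = None,
                  config: SimConfig | None = None) -> dict:
    """Emit VCF, TSVs, transcript table, phecode map and a checksum manifest."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "icd": os.path.join(outdir, "icd.tsv"),
        "clinvar": os.path.join(outdir, "clinvar.tsv"),
        "founder": os.path.join(outdir, "founder.tsv"),
        "transcripts": os.path.join(outdir, "transcripts.tsv"),
        "reference": os.path.join(outdir, "reference.fasta"),
        "phecode_map": os.path.join(outdir, "phecode_map.csv"),
    }
    if not overwrite:
        existing = [p for p in paths.values() if os.path.exists(p)]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite without overwrite=True: {existing}"
            )
    models = transcripts or getattr(cohort, "transcripts", None)
    if models is None:
        raise ValueError("transcript models required (pass transcripts=...)")
    write_vcf(callset, paths["vcf"])
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    cohort.icd.to_csv(paths["icd"], sep="\t", index=False)
    clinvar_frame(truth).to_csv(paths["clinvar"], sep="\t", index=False)
    founder_frame(truth).to_csv(paths["founder"], sep="\t", index=False)
    write_transcript_table(models, paths["transcripts"], paths["reference"])
    phecode_map_frame(config).to_csv(paths["phecode_map"], index=False)
    manifest = {
        "files": {name: {"path": p, "sha256": _sha256(p)} for name, p in paths.items()},
        "n_samples": callset.n_samples,
        "n_sites": callset.n_sites,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
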