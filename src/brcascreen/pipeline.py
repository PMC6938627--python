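"""Staged pipeline: simulate -> qc -> annotate -> classify -> prune ->
prevalence -> associate -> report.

Each stage reads and writes declared files under one run directory and the
run manifest records sha256 checksums of every input and output, the seed,
the package version and the fully defaulted configuration — a run is
re-executable from its manifest alone.  Stage toggles let a stage be
skipped; downstream stages then consume the rawest available upstream file
and the skip is recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from brcascreen import __version__
from brcascreen.association import (
    DEFAULT_HBOC_CODES,
    PheWASConfig,
    association_frame,
    define_cases,
    fit_logistic,
    load_phecode_map,
    map_phecodes,
    run_phewas,
)
from brcascreen.callset import read_vcf, write_vcf
from brcascreen.classify import (
    carrier_frame,
    classifications_frame,
    classify_variants,
    derive_carrier_status,
    load_clinvar,
    load_founder_table,
    match_founders,
)
from brcascreen.consequence import Variant, classify_variant, lof_confidence
from brcascreen.prevalence import group_rates, prevalence, prevalence_frame
from brcascreen.qc import QCThresholds, apply_site_filters
from brcascreen.relatedness import bin_admixture, related_pairs, select_unrelated
from brcascreen.simulate import SimConfig, generate_cohort, write_outputs
from brcascreen.transcripts import read_transcript_table

STAGES = (
    "simulate", "qc", "annotate", "classify", "prune",
    "prevalence", "associate", "report",
)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    sim: SimConfig = field(default_factory=SimConfig)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    phewas: PheWASConfig = field(default_factory=PheWASConfig)
    input_dir: str | None = None  # pre-existing inputs when not simulating

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("sim", {})
        qc_kwargs = raw.pop("qc_thresholds", {})
        phewas_kwargs = raw.pop("phewas", {})
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        if "seed" in raw and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = raw["seed"]
        if "covariates" in phewas_kwargs:
            phewas_kwargs["covariates"] = tuple(phewas_kwargs["covariates"])
        return cls(
            stages=stages,
            sim=SimConfig(**sim_kwargs),
            qc_thresholds=QCThresholds(**qc_kwargs),
            phewas=PheWASConfig(**phewas_kwargs),
            **raw,
        )

    def defaults_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "stages": dict(self.stages),
            "sim": _dataclass_to_jsonable(self.sim),
            "qc_thresholds": dataclasses.asdict(self.qc_thresholds),
            "phewas": dataclasses.asdict(self.phewas),
            "input_dir": self.input_dir,
        }


def _dataclass_to_jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _dataclass_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _require(stage: str, path: str) -> str:
    if not os.path.exists(path):
        raise StageError(stage, f"missing upstream output {path}; re-run its stage")
    return path


# --------------------------------------------------------------------------
# input validation


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema checks on the staged inputs; returns a list of issues."""
    issues: list[str] = []
    indir = config.input_dir or os.path.join(config.outdir, "sim")
    if config.stages.get("simulate", True) and config.input_dir is None:
        return issues  # inputs will be generated
    required = {
        "cohort.vcf": None,
        "samples.tsv": ["sample_id", "age", "female", "self_reported", "community"],
        "icd.tsv": ["sample_id", "system", "code"],
        "clinvar.tsv": ["key", "assertion", "stars"],
        "founder.tsv": ["key", "populations"],
        "transcripts.tsv": ["gene_id", "chrom", "strand", "exon_start", "exon_end"],
        "phecode_map.csv": ["system", "code", "phecode"],
    }
    for name, cols in required.items():
        path = os.path.join(indir, name)
        if not os.path.exists(path):
            issues.append(f"{name}: file missing ({path})")
            continue
        if cols is None:
            continue
        sep = "," if name.endswith(".csv") else "\t"
        try:
            df = pd.read_csv(path, sep=sep)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            issues.append(f"{name}: unreadable ({exc})")
            continue
        for c in cols:
            if c not in df.columns:
                issues.append(f"{name}: missing column {c!r}")
        bad = df[df.isna().any(axis=1)]
        for idx in bad.index[:10]:
            issues.append(f"{name}: line {idx + 2}: incomplete row")
    vcf_path = os.path.join(indir, "cohort.vcf")
    if os.path.exists(vcf_path):
        header = []
        with open(vcf_path) as fh:
            for line in fh:
                if not line.startswith("##"):
                    break
                header.append(line)
        if not any("ID=AD" in h for h in header):
            issues.append(
                "cohort.vcf: no AD FORMAT field; allele-balance filter cannot run"
            )
        samples_path = os.path.join(indir, "samples.tsv")
        if os.path.exists(samples_path):
            try:
                cs = read_vcf(vcf_path)
                meta_ids = set(pd.read_csv(samples_path, sep="\t")["sample_id"])
                orphans = [s for s in cs.sample_ids if s not in meta_ids]
                if orphans:
                    issues.append(
                        f"cohort.vcf: samples absent from samples.tsv: {orphans[:10]}"
                    )
            except Exception as exc:  # noqa: BLE001
                issues.append(f"cohort.vcf: unreadable ({exc})")
    return issues


# --------------------------------------------------------------------------
# stages


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the run manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.defaults_dict(),
        "stages": {},
    }
    sim_dir = config.input_dir or os.path.join(config.outdir, "sim")
    paths = {
        "vcf": os.path.join(sim_dir, "cohort.vcf"),
        "samples": os.path.join(sim_dir, "samples.tsv"),
        "icd": os.path.join(sim_dir, "icd.tsv"),
        "clinvar": os.path.join(sim_dir, "clinvar.tsv"),
        "founder": os.path.join(sim_dir, "founder.tsv"),
        "transcripts": os.path.join(sim_dir, "transcripts.tsv"),
        "reference": os.path.join(sim_dir, "reference.fasta"),
        "phecode_map": os.path.join(sim_dir, "phecode_map.csv"),
        "filtered_vcf": os.path.join(config.outdir, "filtered.vcf"),
        "qc_report": os.path.join(config.outdir, "qc_report.tsv"),
        "consequences": os.path.join(config.outdir, "consequences.tsv"),
        "classifications": os.path.join(config.outdir, "classifications.tsv"),
        "carrier_status": os.path.join(config.outdir, "carrier_status.tsv"),
        "kinship_pairs": os.path.join(config.outdir, "kinship_pairs.tsv"),
        "unrelated": os.path.join(config.outdir, "unrelated_ids.txt"),
        "prevalence_dir": config.outdir,
        "casecontrol": os.path.join(config.outdir, "casecontrol.tsv"),
        "phewas": os.path.join(config.outdir, "phewas.tsv"),
        "phewas_meta": os.path.join(config.outdir, "phewas_meta.json"),
        "report": os.path.join(config.outdir, "report.md"),
    }

    def record(stage: str, inputs: list[str], outputs: list[str], **extra) -> None:
        manifest["stages"][stage] = {
            "inputs": {p: _sha256(p) for p in inputs if os.path.exists(p)},
            "outputs": {p: _sha256(p) for p in outputs if os.path.exists(p)},
            **extra,
        }

    enabled = {s: bool(config.stages.get(s, True)) for s in STAGES}

    if enabled["simulate"]:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        callset, cohort, truth = generate_cohort(sim)
        write_outputs(callset, cohort, truth, sim_dir, overwrite=True, config=sim)
        record("simulate", [], [paths[k] for k in
                                ("vcf", "samples", "icd", "clinvar", "founder",
                                 "transcripts", "reference", "phecode_map")])
    elif config.input_dir is None:
        raise StageError("simulate", "stage disabled but no input_dir given")
    else:
        manifest["stages"]["simulate"] = {"skipped": True, "input_dir": config.input_dir}

    samples = pd.read_csv(_require("qc", paths["samples"]), sep="\t")

    if enabled["qc"]:
        callset = read_vcf(_require("qc", paths["vcf"]))
        strata = dict(zip(samples["sample_id"], samples["self_reported"]))
        filtered, report = apply_site_filters(callset, config.qc_thresholds, strata)
        write_vcf(filtered, paths["filtered_vcf"])
        report.table.to_csv(paths["qc_report"], sep="\t", index=False)
        record("qc", [paths["vcf"], paths["samples"]],
               [paths["filtered_vcf"], paths["qc_report"]],
               removed_counts=report.removed_counts,
               retained=report.retained, removed=report.removed,
               notes=report.notes)
        analysis_vcf = paths["filtered_vcf"]
    else:
        manifest["stages"]["qc"] = {"skipped": True}
        analysis_vcf = paths["vcf"]  # classification consumes the raw call set

    callset = read_vcf(_require("annotate", analysis_vcf))
    models = read_transcript_table(
        _require("annotate", paths["transcripts"]), _require("annotate", paths["reference"])
    )
    by_chrom = {m.chrom: m for m in models}

    if enabled["annotate"]:
        rows = []
        for c, p, r, a in zip(callset.sites["chrom"], callset.sites["pos"],
                              callset.sites["ref"], callset.sites["alt"]):
            model = by_chrom.get(c)
            if model is None:
                rows.append({"key": f"{c}:{p}:{r}:{a}", "consequence": "no_transcript",
                             "is_plof": False, "lof_confidence": "n/a",
                             "plof_consensus": False})
                continue
            call = classify_variant(Variant(c, int(p), r, a), model)
            conf = lof_confidence(call, model) if call.is_plof else "n/a"
            rows.append({"key": call.key, "consequence": call.consequence,
                         "is_plof": call.is_plof, "lof_confidence": conf,
                         "plof_consensus": call.is_plof and conf == "high"})
        pd.DataFrame(rows).to_csv(paths["consequences"], sep="\t", index=False)
        record("annotate", [analysis_vcf, paths["transcripts"], paths["reference"]],
               [paths["consequences"]])

    if enabled["classify"]:
        cons_df = pd.read_csv(_require("classify", paths["consequences"]), sep="\t")
        clinvar = load_clinvar(pd.read_csv(paths["clinvar"], sep="\t"))
        consensus = dict(zip(cons_df["key"], cons_df["plof_consensus"]))
        # gene-panel variants only: sites without a transcript are background SNPs
        annotated = cons_df[cons_df["consequence"] != "no_transcript"]["key"].tolist()
        placeholder = {k: None for k in annotated}
        classifications = classify_variants(
            annotated, clinvar, consequences=placeholder, consensus_flags=consensus
        )
        founder = load_founder_table(pd.read_csv(paths["founder"], sep="\t"))
        classifications = match_founders(classifications, founder)
        classifications_frame(classifications).to_csv(
            paths["classifications"], sep="\t", index=False
        )
        panel_keys = set(annotated)
        panel_mask = np.array([k in panel_keys for k in callset.variant_keys])
        statuses = derive_carrier_status(callset.subset_sites(panel_mask), classifications)
        carrier_frame(statuses).to_csv(paths["carrier_status"], sep="\t", index=False)
        record("classify",
               [paths["consequences"], paths["clinvar"], paths["founder"], analysis_vcf],
               [paths["classifications"], paths["carrier_status"]])

    if enabled["prune"]:
        pairs = related_pairs(callset)
        pd.DataFrame(
            [{"sample_i": p.sample_i, "sample_j": p.sample_j,
              "phi": p.phi, "degree": p.degree} for p in pairs]
        ).to_csv(paths["kinship_pairs"], sep="\t", index=False)
        unrelated = select_unrelated(callset.sample_ids,
                                     [(p.sample_i, p.sample_j) for p in pairs])
        with open(paths["unrelated"], "w") as fh:
            fh.write("\n".join(unrelated) + "\n")
        record("prune", [analysis_vcf], [paths["kinship_pairs"], paths["unrelated"]],
               n_related_pairs=len(pairs), n_unrelated=len(unrelated))

    carrier_df = None
    unrelated_ids = None
    if os.path.exists(paths["carrier_status"]):
        carrier_df = pd.read_csv(paths["carrier_status"], sep="\t")
    if os.path.exists(paths["unrelated"]):
        unrelated_ids = open(paths["unrelated"]).read().split()

    prevalence_files = []
    if enabled["prevalence"]:
        if carrier_df is None:
            raise StageError("prevalence", "carrier_status.tsv missing; run classify")
        samples = samples.copy()
        bins = bin_admixture(
            pd.Series(samples["admix_afr"].values, index=samples["sample_id"])
        )
        samples["admixture_bin"] = samples["sample_id"].map(
            dict(zip(bins["sample_id"], bins["bin"]))
        )
        overall = prevalence(
            int((carrier_df["status"] == "variant_positive").sum()), len(carrier_df),
            group="all",
        )
        rows = [overall]
        if unrelated_ids is not None:
            sub = carrier_df[carrier_df["sample_id"].isin(set(unrelated_ids))]
            rows.append(prevalence(
                int((sub["status"] == "variant_positive").sum()), len(sub),
                group="unrelated subset",
            ))
        path = os.path.join(paths["prevalence_dir"], "prevalence_overall.tsv")
        prevalence_frame(rows).to_csv(path, sep="\t", index=False)
        prevalence_files.append(path)
        for grouping, fname in (
            ("self-reported", "prevalence_self_reported.tsv"),
            ("genetic community", "prevalence_community.tsv"),
            ("admixture bin", "prevalence_admixture_bins.tsv"),
        ):
            results, _excluded = group_rates(
                carrier_df, samples, grouping, unrelated_ids=unrelated_ids
            )
            path = os.path.join(paths["prevalence_dir"], fname)
            prevalence_frame(results).to_csv(path, sep="\t", index=False)
            prevalence_files.append(path)
        record("prevalence", [paths["carrier_status"], paths["samples"]],
               prevalence_files)

    if enabled["associate"]:
        if carrier_df is None:
            raise StageError("associate", "carrier_status.tsv missing; run classify")
        icd = pd.read_csv(paths["icd"], sep="\t")
        merged = samples.merge(carrier_df, on="sample_id")
        if unrelated_ids is not None:
            merged = merged[merged["sample_id"].isin(set(unrelated_ids))]
        # variant-positive vs variant-negative (uncertain/novel carriers excluded)
        cc = merged[merged["status"].isin(["variant_positive", "variant_negative"])]
        case_flags = define_cases(icd, DEFAULT_HBOC_CODES)
        y = cc["sample_id"].map(lambda s: float(case_flags.get(s, False))).to_numpy()
        x = (cc["status"] == "variant_positive").astype(float).to_numpy()
        covs = cc[list(config.phewas.covariates)].astype(float)
        covs["age"] = (covs["age"] - covs["age"].mean()) / covs["age"].std()
        try:
            result = fit_logistic(y, x, covs, outcome_label="HBOC-related cancer")
        except ValueError:
            # degenerate cohort (no carriers or no cases): record, don't crash
            from brcascreen.association import AssociationResult

            result = AssociationResult(
                "HBOC-related cancer", None, None, None, None,
                int(y.sum()), int(len(y) - y.sum()), int((y * x).sum()), False,
            )
        association_frame([result]).to_csv(paths["casecontrol"], sep="\t", index=False)
        phemap = load_phecode_map(pd.read_csv(paths["phecode_map"]))
        phecodes, unmapped = map_phecodes(icd, phemap)
        results, threshold = run_phewas(
            cc["sample_id"].tolist(), x, phecodes, covs, config.phewas
        )
        association_frame(results).to_csv(paths["phewas"], sep="\t", index=False)
        with open(paths["phewas_meta"], "w") as fh:
            json.dump({"n_tests": len(results), "bonferroni_threshold": threshold,
                       "alpha": config.phewas.alpha,
                       "min_carriers": config.phewas.min_carriers,
                       "unmapped_codes": unmapped}, fh, indent=2)
        record("associate",
               [paths["carrier_status"], paths["samples"], paths["icd"],
                paths["phecode_map"]],
               [paths["casecontrol"], paths["phewas"], paths["phewas_meta"]])

    if enabled["report"]:
        _write_report(paths, manifest)
        record("report", [], [paths["report"]])

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    with open(os.path.join(config.outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_report(paths: dict, manifest: dict) -> None:
    lines = ["# Screening run report", ""]
    qc = manifest["stages"].get("qc", {})
    if "removed_counts" in qc:
        lines += ["## Site QC", "",
                  f"- retained {qc['retained']} sites, removed {qc['removed']}"]
        lines += [f"- removed by {k}: {v}" for k, v in qc["removed_counts"].items()]
        lines.append("")
    for title, key in (
        ("Prevalence (overall)", "prevalence_overall.tsv"),
        ("Prevalence by self-reported ancestry", "prevalence_self_reported.tsv"),
        ("Prevalence by genetic community", "prevalence_community.tsv"),
        ("Prevalence by admixture bin", "prevalence_admixture_bins.tsv"),
    ):
        path = os.path.join(paths["prevalence_dir"], key)
        if os.path.exists(path):
            df = pd.read_csv(path, sep="\t")
            lines += [f"## {title}", "", "```\n" + df.to_string(index=False) + "\n```", ""]
    if os.path.exists(paths["casecontrol"]):
        df = pd.read_csv(paths["casecontrol"], sep="\t")
        lines += ["## HBOC-related cancer case-control", "",
                  "```\n" + df.to_string(index=False) + "\n```", ""]
    if os.path.exists(paths["phewas"]):
        df = pd.read_csv(paths["phewas"], sep="\t").head(10)
        lines += ["## PheWAS (top 10)", "", "```\n" + df.to_string(index=False) + "\n```", ""]
    with open(paths["report"], "w") as fh:
        fh.write("\n".join(lines) + "\n")
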