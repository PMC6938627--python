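"""Synthetic-cohort generator: determinism, calibration, transcripts, outputs."""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from brcascreen.callset import read_vcf
from brcascreen.simulate import (
    AncestryGroup,
    FounderSpec,
    SimConfig,
    clinvar_frame,
    generate_cohort,
    generate_transcripts,
    write_outputs,
)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        groups = (
            AncestryGroup("a", 0.6, "A", (1, 1, 1, 1, 1), 0.01),
            AncestryGroup("b", 0.3, "B", (1, 1, 1, 1, 1), 0.01),
        )
        with pytest.raises(ValueError, match="sum"):
            SimConfig(n_samples=10, ancestry_groups=groups, founder_specs=()).validate()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            SimConfig(n_samples=1).validate()

    def test_founder_group_must_exist(self):
        spec = (FounderSpec("f", "Atlantis", 0.01, ("Atlantis",)),)
        with pytest.raises(ValueError, match="Atlantis"):
            SimConfig(n_samples=10, founder_specs=spec).validate()

    def test_negative_or_rejected(self):
        with pytest.raises(ValueError, match="true_or"):
            SimConfig(n_samples=10, true_or=-2).validate()


class TestTranscriptGeneration:
    def test_both_strands_emitted(self):
        models = generate_transcripts(2, seed=0)
        assert {m.strand for m in models} == {"+", "-"}

    @pytest.mark.parametrize("seed", range(8))
    def test_models_valid_no_internal_stop_sorted_exons(self, seed):
        for m in generate_transcripts(2, seed):
            m.validate()  # CDS %3, ATG start, stop end, no internal stop
            assert len(m.exons) >= 3
            prot = str(Seq(m.cds_sequence()).translate())
            assert "*" not in prot[:-1] and prot[-1] == "*"
            for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
                assert e1 < s2  # sorted, non-overlapping
            assert m.exons[0][0] >= m.seq_start
            assert m.exons[-1][1] <= m.seq_start + len(m.ref_seq) - 1

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            generate_transcripts(0, seed=1)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        config = SimConfig(n_samples=300, seed=9, n_kinship_snps=120,
                           relative_pairs=(("duplicate", 2),))
        out = []
        for run in ("a", "b"):
            callset, cohort, truth = generate_cohort(config)
            d = tmp_path / run
            manifest = write_outputs(callset, cohort, truth, str(d), config=config)
            out.append((callset, truth, manifest))
        cs1, t1, m1 = out[0]
        cs2, t2, m2 = out[1]
        assert cs1.equals(cs2)
        assert np.array_equal(t1.carrier_flags, t2.carrier_flags)
        assert t1.kinship_pairs == t2.kinship_pairs
        assert t1.variant_truth.equals(t2.variant_truth)
        shas = lambda m: {k: v["sha256"] for k, v in m["files"].items()}
        assert shas(m1) == shas(m2)

    def test_checksums_change_with_seed(self, tmp_path):
        shas = []
        for seed in (1, 2):
            config = SimConfig(n_samples=120, seed=seed, n_kinship_snps=60,
                               relative_pairs=())
            callset, cohort, truth = generate_cohort(config)
            m = write_outputs(callset, cohort, truth, str(tmp_path / str(seed)),
                              config=config)
            shas.append(m["files"]["vcf"]["sha256"])
        assert shas[0] != shas[1]


class TestCalibration:
    def test_founder_group_carrier_rate_in_binomial_band(self):
        # one group carrying a 2% founder allele, 4000 samples
        groups = (AncestryGroup("AJ-like", 1.0, "European", (0.2, 12, 0.3, 0.25, 0.25), 0.0),)
        config = SimConfig(
            n_samples=4000,
            seed=3,
            ancestry_groups=groups,
            founder_specs=(FounderSpec("f1", "AJ-like", 0.02, ("AJ-like",)),),
            background_pathogenic_freq=0.0,
            novel_plof_freq=0.0,
            relative_pairs=(),
            n_kinship_snps=50,
        )
        _, _, truth = generate_cohort(config)
        rate = truth.carrier_flags.mean()
        half_width = 1.96 * math.sqrt(0.02 * 0.98 / 4000)
        assert abs(rate - 0.02) <= half_width

    def test_null_effect_gives_or_near_one(self):
        from brcascreen.recovery import fit_cohort_odds_ratio
        from brcascreen.simulate import recovery_config

        config = recovery_config(n_samples=10_000, seed=5, true_or=1.0,
                                 carrier_freq=0.02)
        callset, cohort, truth = generate_cohort(config)
        or_hat, (lo, hi) = fit_cohort_odds_ratio(callset, cohort, truth,
                                                 cohort.transcripts)
        assert lo <= 1.0 <= hi

    def test_duplicates_concordant_and_carrier_flags_match_genotypes(self):
        config = SimConfig(n_samples=400, seed=6, n_kinship_snps=200,
                           relative_pairs=(("duplicate", 3),),
                           missingness_rate=0.0)
        callset, cohort, truth = generate_cohort(config)
        ids = callset.sample_ids
        for a, b, degree, phi in truth.kinship_pairs:
            assert degree == "duplicate" and phi == 0.5
            ga = callset.dosage[:, ids.index(a)]
            gb = callset.dosage[:, ids.index(b)]
            assert np.array_equal(ga, gb)
        # with no missingness, emitted genotypes imply exactly the flags
        truth_df = truth.variant_truth
        expected_keys = set(
            truth_df.loc[
                truth_df["class"].isin(["founder", "background_pathogenic", "novel_plof"]),
                "key",
            ]
        )
        mask = np.array([k in expected_keys for k in callset.variant_keys])
        derived = (callset.dosage[mask] >= 1).any(axis=0)
        assert np.array_equal(derived, truth.carrier_flags)

    def test_uncertain_rate_rises_with_admixture_component(self):
        config = SimConfig(n_samples=9000, seed=8, n_kinship_snps=50,
                           relative_pairs=())
        callset, cohort, truth = generate_cohort(config)
        unc_keys = set(
            truth.variant_truth.loc[truth.variant_truth["class"] == "uncertain", "key"]
        )
        mask = np.array([k in unc_keys for k in callset.variant_keys])
        has_unc = (callset.dosage[mask] == 1).any(axis=0)
        afr = cohort.samples["admix_afr"].to_numpy()
        low, high = afr <= 0.2, afr > 0.6
        assert has_unc[high].mean() > has_unc[low].mean()


class TestWriteOutputs:
    def test_vcf_round_trip(self, tmp_path):
        config = SimConfig(n_samples=150, seed=12, n_kinship_snps=80, relative_pairs=())
        callset, cohort, truth = generate_cohort(config)
        write_outputs(callset, cohort, truth, str(tmp_path), config=config)
        back = read_vcf(str(tmp_path / "cohort.vcf"))
        assert callset.equals(back)

    def test_clinvar_table_complete_and_unique(self, tmp_path):
        config = SimConfig(n_samples=80, seed=13, n_kinship_snps=50, relative_pairs=())
        callset, cohort, truth = generate_cohort(config)
        write_outputs(callset, cohort, truth, str(tmp_path), config=config)
        emitted = pd.read_csv(tmp_path / "clinvar.tsv", sep="\t")
        classified = truth.variant_truth[truth.variant_truth["clinvar_assertion"] != ""]
        assert sorted(emitted["key"]) == sorted(classified["key"])
        assert emitted["key"].is_unique

    def test_refuses_overwrite_without_flag(self, tmp_path):
        config = SimConfig(n_samples=60, seed=14, n_kinship_snps=40, relative_pairs=())
        callset, cohort, truth = generate_cohort(config)
        write_outputs(callset, cohort, truth, str(tmp_path), config=config)
        with pytest.raises(FileExistsError):
            write_outputs(callset, cohort, truth, str(tmp_path), config=config)
        write_outputs(callset, cohort, truth, str(tmp_path), overwrite=True, config=config)

    def test_manifest_is_valid_json_with_checksums(self, tmp_path):
        config = SimConfig(n_samples=60, seed=15, n_kinship_snps=40, relative_pairs=())
        callset, cohort, truth = generate_cohort(config)
        write_outputs(callset, cohort, truth, str(tmp_path), config=config)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert set(manifest["files"]) >= {"vcf", "samples", "icd", "clinvar",
                                          "founder", "transcripts"}
        for entry in manifest["files"].values():
            assert len(entry["sha256"]) == 64
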