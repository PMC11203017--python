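import json

import numpy as np
import pandas as pd
import pytest

from cdsevol.codon_usage import count_codons, gc_partition, profile_set, rscu
from cdsevol.genetics import STOP_CODONS, SYN_FAMILIES
from cdsevol.selection import count_differences
from cdsevol.seqio import validate_cds
from cdsevol.synthetic import (
    PREFERRED_CODON,
    PRESETS,
    SyntheticConfig,
    gen_annotation_tables,
    gen_cds_cohort,
    gen_diverged_pair,
    gen_pair_cohort,
    simulate_preset,
)


class TestConfig:
    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SyntheticConfig(gc3_target=1.5).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(omega=-0.1).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(third_base_mode="weird").validate()
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=5, n_specific=6).validate()

    def test_to_dict_roundtrips(self):
        cfg = SyntheticConfig(seed=4, omega=0.3)
        assert SyntheticConfig(**cfg.to_dict()) == cfg


class TestGenCdsCohort:
    def test_all_sequences_validate_cleanly(self):
        cohort, truth = gen_cds_cohort(SyntheticConfig(seed=1, n_genes=30, len_codons=60))
        checked = validate_cds(cohort, min_codons=10)
        assert all(s.valid for s in checked)
        assert len(truth) == 30
        assert set(truth["gene_id"]) == set(cohort.ids)

    def test_sequences_start_with_atg_and_end_with_stop(self):
        cohort, _ = gen_cds_cohort(SyntheticConfig(seed=2, n_genes=10, len_codons=40))
        for s in cohort:
            assert s.seq[:3] == "ATG"
            assert s.seq[-3:] in STOP_CODONS

    def test_deterministic(self):
        cfg = SyntheticConfig(seed=5, n_genes=10, len_codons=50)
        a, ta = gen_cds_cohort(cfg)
        b, tb = gen_cds_cohort(cfg)
        assert [s.seq for s in a] == [s.seq for s in b]
        pd.testing.assert_frame_equal(ta, tb)

    def test_gc3_target_controls_composition(self):
        lo, _ = gen_cds_cohort(SyntheticConfig(seed=6, n_genes=40, len_codons=200,
                                               gc3_target=0.2))
        hi, _ = gen_cds_cohort(SyntheticConfig(seed=6, n_genes=40, len_codons=200,
                                               gc3_target=0.8))

        def mean_gc3(cohort):
            vals = [gc_partition(s)[3] for s in validate_cds(cohort, min_codons=10)]
            return float(np.mean(vals))

        g_lo, g_hi = mean_gc3(lo), mean_gc3(hi)
        assert g_lo < 0.35 and g_hi > 0.65

    def test_selection_shifts_usage_toward_preferred_codons(self):
        sel, _ = gen_cds_cohort(SyntheticConfig(seed=7, n_genes=30, len_codons=200,
                                                selection_strength=2.0))
        from cdsevol.codon_usage import CodonCountTable

        pooled: dict[str, int] = {}
        total = 0
        for s in validate_cds(sel, min_codons=10):
            ct = count_codons(s)
            total += ct.n_codons
            for c, k in ct.counts.items():
                pooled[c] = pooled.get(c, 0) + k
        r = rscu(CodonCountTable(gene_id="pooled", counts=pooled, n_codons=total))
        # preferred codons of multi-codon families should dominate (RSCU > 1)
        over = [
            r[PREFERRED_CODON[aa]] > 1.0
            for aa, fam in SYN_FAMILIES.items()
            if len(fam) > 1 and not np.isnan(r[PREFERRED_CODON[aa]])
        ]
        assert np.mean(over) > 0.9

    def test_null_cohort_enc_near_expectation(self):
        cohort, _ = gen_cds_cohort(SyntheticConfig(seed=8, n_genes=60, len_codons=300))
        prof = profile_set(validate_cds(cohort, min_codons=10))
        ratios = prof["enc_ratio"].dropna()
        assert abs(float(ratios.median()) - 1.0) < 0.05


class TestGenDivergedPair:
    def test_zero_divergence_identical(self):
        anc, _ = gen_cds_cohort(SyntheticConfig(seed=9, n_genes=1, len_codons=100, n_specific=0))
        a, b, truth = gen_diverged_pair(anc.sequences[0], omega=0.5, t=0.0, seed=0)
        assert a.seq == b.seq
        assert truth["syn_subs_a"] == truth["nonsyn_subs_a"] == 0

    def test_omega_zero_only_synonymous_changes(self):
        anc, _ = gen_cds_cohort(SyntheticConfig(seed=10, n_genes=1, len_codons=200, n_specific=0))
        a, b, truth = gen_diverged_pair(anc.sequences[0], omega=0.0, t=0.3, seed=1)
        assert truth["nonsyn_subs_a"] == truth["nonsyn_subs_b"] == 0
        assert truth["syn_subs_a"] + truth["syn_subs_b"] > 0
        n_diff = sum(
            count_differences(x, y)[1]
            for x, y in zip(a.codons(), b.codons())
            if x != y
        )
        assert n_diff == 0.0

    def test_no_stop_codons_created(self):
        anc, _ = gen_cds_cohort(SyntheticConfig(seed=11, n_genes=1, len_codons=150, n_specific=0))
        a, b, _ = gen_diverged_pair(anc.sequences[0], omega=2.0, t=0.5, seed=2)
        for s in (a, b):
            assert not any(c in STOP_CODONS for c in s.codons())

    def test_divergence_scale_calibrated(self):
        # realized synonymous subs per synonymous site should track t
        rng = np.random.default_rng(12)
        anc_set, _ = gen_cds_cohort(SyntheticConfig(seed=12, n_genes=30, len_codons=300))
        t = 0.2
        rates = []
        for anc in anc_set:
            _, _, truth = gen_diverged_pair(anc, omega=0.1, t=t, rng=rng)
            total_syn = truth["syn_subs_a"] + truth["syn_subs_b"]
            rates.append(total_syn / truth["s_sites_ancestor"])
        assert float(np.mean(rates)) == pytest.approx(t, rel=0.15)

    def test_deterministic_with_seed(self):
        anc, _ = gen_cds_cohort(SyntheticConfig(seed=13, n_genes=1, len_codons=80, n_specific=0))
        a1, b1, t1 = gen_diverged_pair(anc.sequences[0], omega=0.4, t=0.2, seed=7)
        a2, b2, t2 = gen_diverged_pair(anc.sequences[0], omega=0.4, t=0.2, seed=7)
        assert a1.seq == a2.seq and b1.seq == b2.seq and t1 == t2


class TestGenPairCohort:
    def test_shapes_and_ids(self):
        fa, cb, truth = gen_pair_cohort(
            SyntheticConfig(seed=14, n_genes=5, len_codons=60, n_specific=0)
        )
        assert len(fa.sequences) == len(cb.sequences) == len(truth) == 5
        assert all(t.endswith("_a") for t in truth["id_a"])
        assert all(t.endswith("_b") for t in truth["id_b"])


class TestGenAnnotationTables:
    def test_exactly_n_specific_satisfy_rule(self):
        cfg = SyntheticConfig(seed=15, n_genes=120, len_codons=40, n_specific=7)
        cohort, _ = gen_cds_cohort(cfg)
        ann, _, truth = gen_annotation_tables(cfg, cohort)
        rule = (
            (ann["pfam_hit"].astype(bool) | ann["interpro_hit"].astype(bool))
            & ~ann["nr_hit"].astype(bool)
            & (ann["og_comparator1"].astype(str) == "")
            & (ann["og_comparator2"].astype(str) == "")
        )
        assert set(ann.loc[rule, "gene_id"]) == set(truth["specific_genes"])
        assert len(truth["specific_genes"]) == 7

    def test_planted_term_is_denser_in_study_set(self):
        cfg = SyntheticConfig(seed=16, n_genes=400, len_codons=40, n_specific=0,
                              enrichment_fold=5.0)
        cohort, _ = gen_cds_cohort(cfg)
        _, go_map, truth = gen_annotation_tables(cfg, cohort)
        term = truth["planted_terms"][0]
        study = set(truth["study_genes"])
        hits = set(go_map.loc[go_map["go_id"] == term, "gene_id"])
        in_rate = len(hits & study) / len(study)
        out_rate = len(hits - study) / (cfg.n_genes - len(study))
        assert in_rate > 2 * out_rate


class TestPresets:
    @pytest.mark.parametrize("preset", PRESETS)
    def test_presets_write_expected_files(self, preset, tmp_path):
        out = tmp_path / preset
        manifest = simulate_preset(preset, out, seed=3)
        assert (out / "manifest.json").exists()
        for fname in manifest["files"].values():
            assert (out / fname).exists()
        on_disk = json.loads((out / "manifest.json").read_text())
        assert on_disk["preset"] == preset and on_disk["seed"] == 3

    def test_unknown_preset_errors(self, tmp_path):
        with pytest.raises(ValueError):
            simulate_preset("nope", tmp_path)
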