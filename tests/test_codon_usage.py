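import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdsevol import codon_usage as cu
from cdsevol.genetics import DEGENERACY, CODON_TO_AA, SENSE_CODONS, SYN_FAMILIES
from cdsevol.seqio import CdsSet, validate_cds
from cdsevol.synthetic import SyntheticConfig, gen_cds_cohort

from conftest import make_cds, random_valid_cds
from oracles import enc_oracle


def table(counts, gene="g"):
    return cu.CodonCountTable(gene_id=gene, counts=counts, n_codons=sum(counts.values()))


class TestCountCodons:
    def test_simple(self):
        t = cu.count_codons(make_cds("ATGAAAAAA"))
        assert t.counts == {"ATG": 1, "AAA": 2} and t.n_codons == 3

    def test_n_codons_skipped(self):
        t = cu.count_codons(make_cds("ATGANAAAA"))
        assert t.counts == {"ATG": 1, "AAA": 1} and t.n_codons == 2

    def test_invalid_cds_errors(self):
        with pytest.raises(ValueError, match="g1"):
            cu.count_codons(make_cds("", valid=False))


class TestRscu:
    def test_two_fold_skew(self):
        r = cu.rscu(table({"TTT": 4}))
        assert r["TTT"] == pytest.approx(2.0) and r["TTC"] == pytest.approx(0.0)

    def test_four_fold(self):
        r = cu.rscu(table({"GGA": 2, "GGC": 1, "GGG": 1}))
        assert (r["GGA"], r["GGC"], r["GGG"], r["GGT"]) == (2.0, 1.0, 1.0, 0.0)

    def test_equal_usage_gives_one(self):
        counts = {c: 3 for c in SENSE_CODONS}
        r = cu.rscu(table(counts))
        assert all(v == pytest.approx(1.0) for v in r.values())

    def test_unobserved_amino_acid_is_missing(self):
        r = cu.rscu(table({"ATG": 5}))
        assert math.isnan(r["TTT"])
        assert r["ATG"] == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.dictionaries(st.sampled_from(SENSE_CODONS), st.integers(0, 50), min_size=1))
    def test_family_sums_equal_degeneracy(self, counts):
        counts = {c: v for c, v in counts.items() if v > 0}
        if not counts:
            return
        r = cu.rscu(table(counts))
        for aa, codons in SYN_FAMILIES.items():
            if sum(counts.get(c, 0) for c in codons) == 0:
                continue
            assert sum(r[c] for c in codons) == pytest.approx(DEGENERACY[aa])


class TestEnc:
    def test_uniform_usage_approaches_61(self):
        value, _, flags = cu.enc(table({c: 1000 for c in SENSE_CODONS}))
        assert value == pytest.approx(61.0, abs=0.2)

    def test_single_codon_per_amino_acid_is_20(self):
        counts = {SYN_FAMILIES[aa][0]: 100 for aa in SYN_FAMILIES}
        value, _, _ = cu.enc(table(counts))
        assert value == pytest.approx(20.0, abs=1e-9)

    def test_ile_class_imputed(self):
        counts = {c: 20 for c in SENSE_CODONS if CODON_TO_AA[c] != "I"}
        value, class_f, flags = cu.enc(table(counts))
        assert "class_imputed" in flags
        assert not math.isnan(value)

    def test_undefined_when_class_missing(self):
        value, _, flags = cu.enc(table({"TTT": 5, "TTC": 5}))  # only 2-fold data
        assert math.isnan(value) and "enc_undefined" in flags

    def test_bounds_on_random_tables(self, rng):
        for _ in range(50):
            counts = {c: int(rng.integers(2, 30)) for c in SENSE_CODONS}
            value, _, _ = cu.enc(table(counts))
            assert 20.0 <= value <= 61.0

    def test_matches_bruteforce_oracle(self, rng):
        for i in range(200):
            gene = random_valid_cds(rng, int(rng.integers(60, 400)), f"g{i}")
            t = cu.count_codons(gene)
            mine, _, _ = cu.enc(t)
            ref = enc_oracle(t.counts)
            if math.isnan(ref):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-9)


class TestExpectedEnc:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form(self, s, expected):
        assert cu.expected_enc(s) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            cu.expected_enc(1.2)

    def test_maximal_near_half_and_above_endpoints(self):
        grid = np.linspace(0, 1, 101)
        vals = [cu.expected_enc(s) for s in grid]
        assert max(vals) == pytest.approx(cu.expected_enc(0.5), abs=0.6)
        assert all(v >= cu.expected_enc(0.0) - 1e-12 for v in vals[:51])
        assert all(v >= cu.expected_enc(1.0) - 1e-12 for v in vals[50:])


class TestGcPartition:
    def test_all_gc(self):
        assert cu.gc_partition(make_cds("GGGGGG")) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_counted(self):
        gc, gc1, gc2, gc3, gc12 = cu.gc_partition(make_cds("ATGAAA"))
        assert (gc1, gc2, gc3, gc12) == (0.0, 0.0, 0.5, 0.0)

    def test_n_excluded(self):
        gc, *_ = cu.gc_partition(make_cds("NNNAAA"))
        assert gc == 0.0

    def test_ratio_sign_matches_gc3_vs_gc12(self, rng):
        for i in range(30):
            gene = random_valid_cds(rng, 100, f"g{i}")
            p = cu.profile(gene)
            if p.gc12 > 0 and not math.isnan(p.gc3_gc12_ratio):
                assert (p.gc3_gc12_ratio > 1) == (p.gc3 > p.gc12)


class TestProfileSet:
    def test_single_gene_consistency(self, rng):
        gene = random_valid_cds(rng, 150, "solo")
        df = cu.profile_set(CdsSet("t", [gene]))
        assert len(df) == 1
        row = df.iloc[0]
        enc_val, _, _ = cu.enc(cu.count_codons(gene))
        assert row["enc"] == pytest.approx(enc_val)
        assert row["exp_enc"] == pytest.approx(
            cu.expected_enc(cu.gc3_synonymous(cu.count_codons(gene)))
        )

    def test_short_gene_flagged(self, rng):
        gene = random_valid_cds(rng, 40, "short")
        df = cu.profile_set(CdsSet("t", [gene]))
        assert "short_gene" in df.iloc[0]["flags"]

    def test_no_valid_genes_errors(self):
        with pytest.raises(ValueError):
            cu.profile_set(CdsSet("t", [make_cds("AT", valid=False)]))

    def test_null_cohort_tracks_expected_curve(self):
        cohort, _ = gen_cds_cohort(SyntheticConfig(seed=42, n_genes=60, len_codons=300))
        df = cu.profile_set(validate_cds(cohort))
        assert abs(df["enc_ratio"].median() - 1.0) < 0.05

    def test_selected_cohort_falls_below_curve(self):
        cohort, _ = gen_cds_cohort(
            SyntheticConfig(seed=43, n_genes=60, len_codons=300, selection_strength=2.0)
        )
        df = cu.profile_set(validate_cds(cohort))
        assert df["enc_ratio"].median() < 0.9


class TestRscuMatrix:
    def test_shape_and_columns(self, random_gene_set):
        m = cu.rscu_matrix(random_gene_set)
        assert m.shape == (20, 59)
        assert "ATG" not in m.columns and "TGG" not in m.columns
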