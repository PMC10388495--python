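import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset, make_harmonized
from mrkit.errors import HarmonizationError, NoInstrumentsError
from mrkit.gwas_io import LdMatrix
from mrkit.instruments import f_statistics, harmonize, ld_clump, select_by_pvalue


class TestSelectByPvalue:
    def test_strict_threshold_filter(self, rng):
        j = 100
        p = np.concatenate([rng.uniform(1e-12, 4e-8, 12), rng.uniform(1e-5, 1, 88)])
        ds = make_dataset([f"rs{i}" for i in range(j)], np.full(j, 0.1), np.full(j, 0.01),
                          pvalue=p)
        sel = select_by_pvalue(ds)
        assert len(sel) == 12
        assert sel.meta["p_threshold_used"] == 5e-8
        assert not sel.meta["threshold_relaxed"]

    def test_relaxation_kicks_in(self, rng):
        # 2 below 5e-8, 10 below 5e-6 -> relaxed selection keeps all 10
        p = np.concatenate([
            [1e-9, 2e-9],
            np.linspace(1e-7, 4e-6, 8),
            np.linspace(1e-3, 0.9, 10),
        ])
        ds = make_dataset([f"rs{i}" for i in range(20)], np.full(20, 0.1),
                          np.full(20, 0.01), pvalue=p)
        sel = select_by_pvalue(ds, min_instruments=3)
        assert len(sel) == 10
        assert sel.meta["threshold_relaxed"]
        assert sel.meta["p_threshold_used"] == 5e-6

    def test_no_instruments_errors(self):
        ds = make_dataset(["rs1", "rs2"], [0.1, 0.1], [0.1, 0.1], pvalue=[0.5, 0.9])
        with pytest.raises(NoInstrumentsError):
            select_by_pvalue(ds)

    def test_bad_thresholds_rejected(self):
        ds = make_dataset(["rs1"], [0.1], [0.01], pvalue=[1e-9])
        with pytest.raises(ValueError):
            select_by_pvalue(ds, threshold=5e-6, relaxed_threshold=5e-8)


class TestLdClump:
    def test_correlated_close_pair_keeps_best(self):
        ds = make_dataset(["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01],
                          pvalue=[1e-10, 1e-9], chrom=["1", "1"], pos=[1000, 6000])
        ld = LdMatrix(["rsA", "rsB"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        out = ld_clump(ds, ld)
        assert out.snp_ids == ["rsA"]

    def test_different_chromosomes_both_kept(self):
        ds = make_dataset(["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01],
                          pvalue=[1e-10, 1e-9], chrom=["1", "2"], pos=[1000, 1000])
        ld = LdMatrix(["rsA", "rsB"], np.eye(2))
        assert len(ld_clump(ds, ld)) == 2

    def test_independent_snps_noop(self):
        ds = make_dataset(["rsA", "rsB", "rsC"], [0.1] * 3, [0.01] * 3,
                          pvalue=[1e-8, 1e-10, 1e-9], chrom=["1"] * 3,
                          pos=[1000, 2000, 3000])
        ld = LdMatrix(["rsA", "rsB", "rsC"], np.eye(3))
        out = ld_clump(ds, ld)
        assert sorted(out.snp_ids) == ["rsA", "rsB", "rsC"]
        # input order preserved regardless of p ordering
        assert out.snp_ids == ["rsA", "rsB", "rsC"]

    def test_conjunction_far_apart_in_ld_kept(self):
        # r2 above threshold but outside the window: both kept
        ds = make_dataset(["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01],
                          pvalue=[1e-10, 1e-9], chrom=["1", "1"],
                          pos=[1000, 1000 + 10_001_000])
        ld = LdMatrix(["rsA", "rsB"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert len(ld_clump(ds, ld)) == 2

    def test_missing_snp_in_ld_errors(self):
        ds = make_dataset(["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01], pvalue=[1e-10, 1e-9])
        ld = LdMatrix(["rsA"], np.eye(1))
        with pytest.raises(NoInstrumentsError, match="rsB"):
            ld_clump(ds, ld)

    def test_distance_only_fallback_warns(self, caplog):
        ds = make_dataset(["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01],
                          pvalue=[1e-10, 1e-9], chrom=["1", "1"], pos=[1000, 6000])
        with caplog.at_level("WARNING"):
            out = ld_clump(ds, None)
        assert out.snp_ids == ["rsA"]
        assert any("distance-only" in r.message for r in caplog.records)

    def test_clump_output_subset_with_no_close_ld_pairs(self, rng):
        j = 30
        ds = make_dataset([f"rs{i}" for i in range(j)], np.full(j, 0.1),
                          np.full(j, 0.01), pvalue=rng.uniform(1e-12, 1e-8, j),
                          chrom=[str(i % 5 + 1) for i in range(j)],
                          pos=rng.integers(1, 2_000_000_000, j))
        m = np.eye(j)
        # random LD structure
        for _ in range(40):
            a, b = rng.integers(0, j, 2)
            if a != b:
                m[a, b] = m[b, a] = rng.uniform(0, 1)
        ld = LdMatrix([f"rs{i}" for i in range(j)], m)
        out = ld_clump(ds, ld)
        assert set(out.snp_ids) <= set(ds.snp_ids)
        pos = dict(zip(ds.snp_ids, ds.table["pos"]))
        chrom = dict(zip(ds.snp_ids, ds.table["chrom"]))
        for a in out.snp_ids:
            for b in out.snp_ids:
                if a < b and chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= 1e7:
                    assert ld.lookup(a, b) < 0.001


class TestHarmonize:
    def test_allele_swap_flips_sign(self):
        exp = make_dataset(["rs1"], [0.1], [0.01], ea="A", oa="G")
        out = make_dataset(["rs1"], [0.05], [0.02], ea="G", oa="A")
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(-0.05)
        assert h.provenance.loc[0, "action"] == "flipped"

    def test_palindrome_intermediate_removed(self):
        exp = make_dataset(["rs1", "rs2"], [0.1, 0.1], [0.01, 0.01],
                           ea=["A", "A"], oa=["T", "G"], eaf=[0.50, 0.50])
        out = make_dataset(["rs1", "rs2"], [0.05, 0.05], [0.02, 0.02],
                           ea=["A", "A"], oa=["T", "G"], eaf=[0.50, 0.50])
        h = harmonize(exp, out, palindrome_band=0.08)
        assert list(h.snp_ids) == ["rs2"]
        assert h.removed.loc[0, "reason"] == "palindromic_intermediate_eaf"

    def test_palindrome_extreme_eaf_kept(self):
        exp = make_dataset(["rs1"], [0.1], [0.01], ea="A", oa="T", eaf=0.10)
        out = make_dataset(["rs1"], [0.05], [0.02], ea="A", oa="T", eaf=0.10)
        h = harmonize(exp, out, palindrome_band=0.08)
        assert h.n_snps == 1

    def test_palindrome_missing_eaf_removed(self):
        exp = make_dataset(["rs1"], [0.1], [0.01], ea="A", oa="T", eaf=np.nan)
        out = make_dataset(["rs1"], [0.05], [0.02], ea="A", oa="T", eaf=np.nan)
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)  # only SNP removed -> empty set error

    def test_strand_complement_kept(self):
        exp = make_dataset(["rs1"], [0.1], [0.01], ea="A", oa="G")
        out = make_dataset(["rs1"], [0.05], [0.02], ea="T", oa="C")
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(0.05)
        assert h.provenance.loc[0, "action"] == "strand"

    def test_strand_complement_plus_swap_flips(self):
        exp = make_dataset(["rs1"], [0.1], [0.01], ea="A", oa="G")
        out = make_dataset(["rs1"], [0.05], [0.02], ea="C", oa="T")
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(-0.05)

    def test_irreconcilable_removed(self):
        exp = make_dataset(["rs1", "rs2"], [0.1, 0.1], [0.01, 0.01],
                           ea=["A", "A"], oa=["G", "G"])
        out = make_dataset(["rs1", "rs2"], [0.05, 0.05], [0.02, 0.02],
                           ea=["A", "A"], oa=["C", "G"])
        h = harmonize(exp, out)
        assert list(h.snp_ids) == ["rs2"]
        assert h.removed.loc[0, "reason"] == "allele_mismatch"

    def test_empty_intersection_errors(self):
        exp = make_dataset(["rs1"], [0.1], [0.01])
        out = make_dataset(["rs2"], [0.05], [0.02])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_accounting_identity(self, rng):
        # kept + removed equals the intersection size
        j = 40
        ids = [f"rs{i}" for i in range(j)]
        eas = rng.choice(["A", "C"], j)
        oas = np.where(eas == "A", rng.choice(["G", "T"], j), "G")
        exp = make_dataset(ids, rng.normal(0, 0.1, j), np.full(j, 0.01),
                           ea=list(eas), oa=list(oas), eaf=list(rng.uniform(0.05, 0.95, j)))
        out = make_dataset(ids[5:], rng.normal(0, 0.1, j - 5), np.full(j - 5, 0.02),
                           ea=list(eas[5:]), oa=list(oas[5:]),
                           eaf=list(rng.uniform(0.05, 0.95, j - 5)))
        h = harmonize(exp, out)
        assert h.n_snps + len(h.removed) == j - 5

    def test_idempotent(self):
        # re-harmonizing an already-aligned pair changes nothing
        exp = make_dataset(["rs1", "rs2"], [0.1, -0.2], [0.01, 0.01],
                           ea=["A", "C"], oa=["G", "T"], eaf=[0.2, 0.3])
        out = make_dataset(["rs1", "rs2"], [0.05, 0.07], [0.02, 0.02],
                           ea=["G", "T"], oa=["A", "C"], eaf=[0.8, 0.7])
        h1 = harmonize(exp, out)
        aligned = make_dataset(
            list(h1.snp_ids), list(h1.Gamma), list(h1.se_Gamma),
            ea=list(h1.effect_allele), oa=list(h1.other_allele), eaf=list(h1.eaf),
        )
        h2 = harmonize(exp, aligned)
        np.testing.assert_allclose(h2.Gamma, h1.Gamma)
        assert (h2.provenance["action"] == "kept").all()

    def test_freq_source_outcome(self):
        exp = make_dataset(["rs1"], [0.1], [0.01], ea="A", oa="T", eaf=0.5)
        out = make_dataset(["rs1"], [0.05], [0.02], ea="A", oa="T", eaf=0.1)
        # exposure eaf is intermediate but outcome governs -> kept
        h = harmonize(exp, out, freq_source="outcome")
        assert h.n_snps == 1


class TestFStatistics:
    def test_strong_instrument(self):
        h = make_harmonized([0.1], [0.05], se_gamma=[0.01])
        st = f_statistics(h)
        assert st.f_stat[0] == pytest.approx(100.0)
        assert not st.weak_flags[0]

    def test_weak_boundary(self):
        h = make_harmonized([0.03], [0.05], se_gamma=[0.01])
        st = f_statistics(h)
        assert st.f_stat[0] == pytest.approx(9.0)
        assert st.weak_flags[0]

    def test_zero_gamma(self):
        h = make_harmonized([0.0, 0.1], [0.05, 0.05], se_gamma=[0.01, 0.01])
        st = f_statistics(h)
        assert st.f_stat[0] == 0.0
        assert st.mean_f == pytest.approx((0 + 100) / 2)
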