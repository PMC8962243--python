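"""Summary-statistics parsing, z/p conversion, harmonization, inflation."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosstrait import sumstats as ss

CM = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2", "z": "Z", "p": "P"}


def _tsv(text):
    return io.StringIO("\n".join(line.strip() for line in text.strip().splitlines()))


# ---------------------------------------------------------------------------
# conversions


class TestConversions:
    def test_z_zero_gives_p_one(self):
        assert ss.p_from_z(0.0) == 1.0

    @pytest.mark.parametrize(
        "z,expected",
        [(-7.86, 3.84e-15), (5.73, 1.00e-8)],  # published z/p pairs
    )
    def test_reported_pairs_to_three_sig_figs(self, z, expected):
        p = ss.p_from_z(z)
        assert p == pytest.approx(expected, rel=5e-3)

    def test_deep_tail_log10(self):
        # frozen from a 50-digit mpmath evaluation of log10(2*Phi(-40))
        assert ss.log10p_from_z(40.0) == pytest.approx(-349.13597646368186, abs=1e-6)

    def test_tail_matches_high_precision_oracle(self):
        mpmath = pytest.importorskip("mpmath")
        mpmath.mp.dps = 50
        rng = np.random.default_rng(42)
        z = rng.uniform(-38, 38, 300)
        p = ss.p_from_z(z)
        exact = np.array([float(2 * mpmath.ncdf(-abs(float(v)))) for v in z])
        assert np.max(np.abs(p - exact) / exact) <= 1e-12

    def test_quantile(self):
        assert abs(ss.z_from_p(0.05)) == pytest.approx(1.95996, abs=5e-6)
        assert ss.z_from_p(1.0) == 0.0

    def test_roundtrip_published_value(self):
        z = ss.z_from_p(3.84e-15, sign=-1)
        assert z == pytest.approx(-7.86, abs=0.005)

    def test_roundtrip_wide_range(self):
        rng = np.random.default_rng(1)
        p = 10 ** rng.uniform(-300, 0, 10_000)
        back = ss.p_from_z(ss.z_from_p(p))
        assert np.max(np.abs(back - p) / p) <= 1e-10

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_z_rejected(self, bad):
        with pytest.raises(ss.SumstatsError):
            ss.p_from_z(bad)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_bad_p_rejected(self, bad):
        with pytest.raises(ss.SumstatsError):
            ss.z_from_p(bad)


class TestGcCorrect:
    def test_exact_normal_quantiles_give_lambda_one(self):
        grid = (np.arange(1, 1001) - 0.5) / 1000
        z = ss.z_from_p(grid)  # |z| quantiles of the null
        _, lam = ss.gc_correct(z)
        assert lam == pytest.approx(1.0, abs=0.01)

    def test_scaling_property(self):
        grid = (np.arange(1, 1001) - 0.5) / 1000
        z = ss.z_from_p(grid)
        zc, lam = ss.gc_correct(z * np.sqrt(2))
        assert lam == pytest.approx(2.0, abs=0.02)
        assert np.allclose(zc, z * np.sqrt(2) / np.sqrt(lam))

    def test_deflation_not_applied_without_force(self):
        z = np.full(200, 0.1)
        zc, lam = ss.gc_correct(z)
        assert lam < 1 and np.array_equal(zc, z)

    def test_degenerate_zero_input(self):
        zc, lam = ss.gc_correct(np.zeros(200))
        assert lam == 1.0 and np.array_equal(zc, np.zeros(200))


# ---------------------------------------------------------------------------
# reading


class TestReadSumstats:
    def test_wellformed(self):
        df = ss.read_sumstats(
            _tsv(
                """SNP CHR BP A1 A2 Z P
                rs1 1 100 A G 2.0 0.0455
                rs2 2 200 C T -1.0 0.3173
                rs3 3 300 G A 0.5 0.6171"""
            ),
            CM,
        )
        assert len(df) == 3
        assert not df["zp_inconsistent"].any()

    def test_z_from_beta_se(self):
        df = ss.read_sumstats(
            _tsv(
                """SNP A1 A2 BETA SE
                rs1 A G 0.1 0.05"""
            ),
            {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "BETA", "se": "SE"},
        )
        assert df.loc[0, "z"] == pytest.approx(2.0)
        assert df.loc[0, "p"] == pytest.approx(ss.p_from_z(2.0))

    def test_missing_association_source_is_config_error(self):
        with pytest.raises(ss.ColumnConfigError):
            ss.read_sumstats(
                _tsv("SNP A1 A2\nrs1 A G"),
                {"snp": "SNP", "a1": "A1", "a2": "A2"},
            )

    def test_unparseable_rows_skipped_and_counted(self):
        df = ss.read_sumstats(
            _tsv(
                """SNP A1 A2 Z
                rs1 A G xx
                rs2 C T 1.0"""
            ),
            {"snp": "SNP", "a1": "A1", "a2": "A2", "z": "Z"},
        )
        assert len(df) == 1
        assert df.attrs["dropped"]["bad_numeric"] == 1

    def test_zero_p_clamped(self):
        df = ss.read_sumstats(
            _tsv("SNP A1 A2 Z P\nrs1 A G 50 0"),
            {"snp": "SNP", "a1": "A1", "a2": "A2", "z": "Z", "p": "P"},
        )
        assert df.loc[0, "p"] == ss.TINY_P
        assert df.attrs["dropped"]["p_clamped"] == 1

    def test_inconsistent_zp_flagged(self):
        df = ss.read_sumstats(
            _tsv("SNP A1 A2 Z P\nrs1 A G 2.0 0.5"),
            {"snp": "SNP", "a1": "A1", "a2": "A2", "z": "Z", "p": "P"},
        )
        assert df.loc[0, "zp_inconsistent"]


# ---------------------------------------------------------------------------
# harmonization


def _frame(rows):
    return pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "a1", "a2", "z", "p"]
    )


class TestHarmonize:
    def test_allele_swap_negates_z2(self):
        prim = _frame([("rs1", "1", 1, "A", "G", 1.5, 0.13)])
        sec = _frame([("rs1", "1", 1, "G", "A", 1.5, 0.13)])
        out = ss.harmonize_pair(prim, sec)
        assert out.frame.loc[0, "z2"] == -1.5
        assert out.frame.loc[0, "allele_swapped"]

    def test_strand_complement_keeps_sign(self):
        prim = _frame([("rs1", "1", 1, "A", "G", 1.0, 0.3)])
        sec = _frame([("rs1", "1", 1, "T", "C", 2.0, 0.05)])
        out = ss.harmonize_pair(prim, sec)
        assert out.frame.loc[0, "z2"] == 2.0
        assert out.frame.loc[0, "strand_flipped"]

    def test_ambiguous_dropped_by_default(self):
        prim = _frame([("rs1", "1", 1, "A", "T", 1.0, 0.3),
                       ("rs2", "1", 2, "A", "G", 1.0, 0.3)])
        sec = _frame([("rs1", "1", 1, "A", "T", 1.0, 0.3),
                      ("rs2", "1", 2, "A", "G", 1.0, 0.3)])
        out = ss.harmonize_pair(prim, sec)
        assert out.frame["snp"].tolist() == ["rs2"]
        assert out.meta["ambiguous_dropped"] == 1

    def test_mismatched_alleles_dropped_and_counted(self):
        prim = _frame([("rs1", "1", 1, "A", "G", 1.0, 0.3)])
        sec = _frame([("rs1", "1", 1, "A", "C", 1.0, 0.3)])
        out = ss.harmonize_pair(prim, sec)
        assert len(out.frame) == 0
        assert out.meta["allele_mismatch_dropped"] == 1

    def test_empty_intersection_is_error(self):
        prim = _frame([("rs1", "1", 1, "A", "G", 1.0, 0.3)])
        sec = _frame([("rs9", "1", 1, "A", "G", 1.0, 0.3)])
        with pytest.raises(ss.SumstatsError):
            ss.harmonize_pair(prim, sec)

    @settings(deadline=None, max_examples=50)
    @given(z=st.floats(-10, 10, allow_nan=False, allow_subnormal=False))
    def test_swap_involution(self, z):
        """Applying the allele-swap sign rule twice restores z2."""
        prim = _frame([("rs1", "1", 1, "A", "G", 0.0, 1.0)])

        def swapped_z2(v):
            sec = _frame([("rs1", "1", 1, "G", "A", v, ss.p_from_z(v))])
            return ss.harmonize_pair(prim, sec).frame.loc[0, "z2"]

        once = swapped_z2(z)
        assert once == -z
        assert swapped_z2(once) == z

    def test_role_swap_gives_same_variant_set(self, paired_from_simulation, tmp_path):
        paired, _, _ = paired_from_simulation(tmp_path, n_variants=500, seed=5)
        # swapping trait roles: harmonize(secondary, primary)
        f = paired.frame
        prim = f[["snp", "chrom", "pos", "a1", "a2", "z1", "p1"]].rename(
            columns={"z1": "z", "p1": "p"})
        sec = f[["snp", "chrom", "pos", "a1", "a2", "z2", "p2"]].rename(
            columns={"z2": "z", "p2": "p"})
        swapped = ss.harmonize_pair(sec, prim)
        assert set(swapped.frame["snp"]) == set(f["snp"])

    def test_mhc_exclusion_window(self):
        prim = _frame([
            ("rs1", "6", 25_000_000, "A", "G", 1.0, 0.3),
            ("rs2", "6", 35_000_000, "A", "G", 1.0, 0.3),
            ("rs3", "6", 35_000_001, "A", "G", 1.0, 0.3),
            ("rs4", "1", 30_000_000, "A", "G", 1.0, 0.3),
        ])
        paired = ss.harmonize_pair(prim, prim)
        kept = ss.exclude_mhc(paired)
        assert kept.frame["snp"].tolist() == ["rs3", "rs4"]
        assert kept.meta["mhc_excluded"] == 2
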