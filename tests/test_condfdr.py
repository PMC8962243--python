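"""condFDR/conjFDR estimation and conditional Q-Q enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crosstrait as ct
from crosstrait import condfdr as cf

from conftest import brute_force_condfdr


def _paired(p1, p2):
    return pd.DataFrame(
        {"snp": [f"v{i}" for i in range(len(p1))], "p1": p1, "p2": p2}
    )


class TestExactCondFdr:
    def test_worked_example(self, small_paired):
        fdr, flags = cf.cond_fdr(small_paired, direction=1)
        # B: stratum p2<=0.5 holds {A,B,C}; only B has p1<=0.001
        assert fdr[1] == pytest.approx(0.001 / (1 / 3), abs=1e-15)
        # D: full stratum, empirical cdf at 0.9 is 1
        assert fdr[3] == pytest.approx(0.9, abs=1e-15)
        assert not flags.any()

    def test_single_variant_gets_own_p(self):
        fdr, _ = cf.cond_fdr(_paired([0.037], [0.2]), direction=1)
        assert fdr[0] == pytest.approx(0.037, abs=1e-15)

    @pytest.mark.parametrize("n,seed", [(1000, 0), (1000, 1), (5000, 2)])
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        # mixture with ties to exercise <= handling
        p1 = np.round(10 ** rng.uniform(-6, 0, n), 4)
        p2 = np.round(10 ** rng.uniform(-6, 0, n), 4)
        p1[p1 == 0] = 1e-4
        p2[p2 == 0] = 1e-4
        fdr, _ = cf.cond_fdr(_paired(p1, p2), direction=1)
        assert np.max(np.abs(fdr - brute_force_condfdr(p1, p2))) <= 1e-12

    def test_direction_two_swaps_roles(self):
        rng = np.random.default_rng(3)
        p1, p2 = rng.random(200), rng.random(200)
        f2, _ = cf.cond_fdr(_paired(p1, p2), direction=2)
        f1_swapped, _ = cf.cond_fdr(_paired(p2, p1), direction=1)
        assert np.array_equal(f2, f1_swapped)


class TestConjFdr:
    def test_max_and_symmetry(self):
        assert cf.conj_fdr([0.003], [0.008])[0] == 0.008
        assert cf.conj_fdr([0.008], [0.003])[0] == 0.008
        x = np.random.default_rng(0).random(50)
        assert np.array_equal(cf.conj_fdr(x, x), x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cf.conj_fdr([0.1, 0.2], [0.1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=30))
    def test_dominates_both_directions(self, pairs):
        a = np.array([x for x, _ in pairs])
        b = np.array([y for _, y in pairs])
        c = cf.conj_fdr(a, b)
        assert np.all(c >= a) and np.all(c >= b)


class TestSelectSignificant:
    def test_strict_boundary(self):
        frame = pd.DataFrame({"snp": list("abc"), "conj_fdr": [0.009, 0.01, 0.02]})
        sel = cf.select_significant(frame, 0.01)
        assert sel["snp"].tolist() == ["a"]

    def test_empty_input(self):
        sel = cf.select_significant(pd.DataFrame({"snp": [], "conj_fdr": []}), 0.01)
        assert len(sel) == 0

    def test_threshold_must_be_interior(self):
        with pytest.raises(ValueError):
            cf.select_significant(pd.DataFrame({"snp": ["a"], "conj_fdr": [0.5]}), 1.0)


class TestConditionalCdf:
    def test_hand_counted_empirical_cdf(self):
        # singleton blocks, one iteration, all-SNP stratum only
        paired = _paired([0.02, 0.001, 0.5, 0.9], [0.5, 0.5, 0.5, 0.5])
        cdf = cf.build_conditional_cdf(paired, None, cf.QQConfig(), direction=1)
        # empirical cdf of p1 at the variants' own values: 0.5, 0.25, 0.75, 1.0
        f = cdf.evaluate(-np.log10([0.02, 0.001, 0.5, 0.9]), np.zeros(4))
        # knots at 0.1 spacing: evaluate at exact -log10 p1 of each variant
        # against direct counting
        expect = np.array([2 / 4, 1 / 4, 3 / 4, 4 / 4])
        assert np.all(np.abs(f - expect) <= 0.25)  # grid-interpolated estimate
        # and the exact mode reproduces the counts precisely
        fdr, _ = cf.cond_fdr(paired, direction=1)
        assert np.allclose(fdr, [0.02 / 0.5, 0.001 / 0.25, 0.5 / 0.75, 0.9])

    def test_deterministic_given_seed(self, paired_from_simulation, tmp_path):
        paired, ld, _ = paired_from_simulation(tmp_path, n_variants=2000, seed=1)
        blocks = ct.ld_blocks(ld, paired.frame["snp"], 0.1)
        cfg = cf.QQConfig(pruning_iterations=5, seed=9)
        a = cf.build_conditional_cdf(paired, blocks, cfg)
        b = cf.build_conditional_cdf(paired, blocks, cfg)
        assert np.array_equal(a.fhat, b.fhat, equal_nan=True)

    def test_monotone_in_p1_and_bounded(self, paired_from_simulation, tmp_path):
        paired, ld, _ = paired_from_simulation(tmp_path, n_variants=2000, seed=2)
        blocks = ct.ld_blocks(ld, paired.frame["snp"], 0.1)
        cdf = cf.build_conditional_cdf(paired, blocks, cf.QQConfig(pruning_iterations=10))
        valid = cdf.fhat[:, cdf.valid]
        assert np.nanmin(valid) >= 0 and np.nanmax(valid) <= 1
        # increasing -log10 p1 means decreasing p1, so F must not increase
        assert np.all(np.diff(valid, axis=0) <= 1e-12)
        # stratum denominators shrink as conditioning strengthens
        den = cdf.denominators[cdf.valid]
        assert np.all(np.diff(den) <= 1e-9)

    def test_lookup_close_to_exact_without_pruning(self, paired_from_simulation, tmp_path):
        paired, _, _ = paired_from_simulation(tmp_path, n_variants=5000, seed=3)
        cdf = cf.build_conditional_cdf(paired, None, cf.QQConfig(), direction=1)
        lookup, _ = cf.cond_fdr(paired, cdf, 1)
        exact, _ = cf.cond_fdr(paired, None, 1)
        rel = np.abs(lookup - exact) / np.maximum(exact, 1e-6)
        assert np.median(rel) <= 0.02
        # in the discovery region the lookup may only err conservatively
        calls = exact < 0.2
        assert np.max(exact[calls] - lookup[calls]) <= 0.02


class TestConditionalQQ:
    def test_null_curves_hug_the_diagonal(self):
        rng = np.random.default_rng(12)
        n = 100_000
        paired = _paired(rng.random(n), rng.random(n))
        qq = cf.conditional_qq(paired, None, cf.QQConfig())
        for t, e in qq.enrichment.items():
            assert abs(e) <= 0.05, f"stratum {t} enrichment {e}"

    def test_pleiotropic_mixture_orders_strata(self, paired_from_simulation, tmp_path):
        paired, ld, _ = paired_from_simulation(tmp_path, n_variants=50_000, seed=4)
        blocks = ct.ld_blocks(ld, paired.frame["snp"], 0.1)
        qq = cf.conditional_qq(paired, blocks, cf.QQConfig(pruning_iterations=20))
        e = qq.enrichment
        assert e[0.0] == 0.0
        assert e[0.0] < e[1.0] < e[2.0] < e[3.0]

    def test_stratum_identical_to_full_set(self):
        rng = np.random.default_rng(5)
        n = 2000
        paired = _paired(rng.random(n), np.full(n, 0.9))
        # threshold 0 stratum == all SNPs; compare the two curves directly
        qq = cf.conditional_qq(paired, None, cf.QQConfig(strata_thresholds=(0.04,)))
        all_curve = qq.curves[qq.curves["stratum"] == 0.0]
        # p2 = 0.9 for everyone -> stratum -log10 p2 >= 0.04 also holds everyone
        strat = qq.curves[qq.curves["stratum"] == 0.04]
        merged = all_curve.merge(strat, on="nominal_log10p")
        assert np.allclose(merged["empirical_log10p_x"], merged["empirical_log10p_y"])

    def test_small_strata_omitted(self):
        rng = np.random.default_rng(6)
        paired = _paired(rng.random(500), rng.random(500))
        qq = cf.conditional_qq(paired, None, cf.QQConfig(strata_thresholds=(1.0, 6.0)))
        assert 6.0 not in set(qq.curves["stratum"])


class TestCalibration:
    def test_null_condfdr_is_conservative_small(self):
        """No pleiotropy + independent traits: FDP among condFDR<0.05 calls <= 0.05.

        Scaled-down check (the full 200-replicate version runs in the
        acceptance suite)."""
        fdps = []
        for rep in range(5):
            s1, s2, _, truth = ct.simulate_sumstats_pair(
                n_variants=30_000, pi=(0.92, 0.04, 0.04, 0.0),
                block_sizes=1, seed=100 + rep,
            )
            paired = _paired(s1["P"], s2["P"])
            cdf = cf.build_conditional_cdf(paired, None, cf.QQConfig(), direction=1)
            f12, _ = cf.cond_fdr(paired, cdf, 1)
            calls = f12 < 0.05
            null1 = truth.frame["delta1"].to_numpy() == 0
            fdps.append((calls & null1).sum() / max(calls.sum(), 1))
        mc_se = np.std(fdps, ddof=1) / np.sqrt(len(fdps))
        assert np.mean(fdps) <= 0.05 + 3 * mc_se

    def test_conjfdr_outpowers_bh_on_max_p(self):
        """conjFDR<0.01 finds more true pleiotropic variants than BH on max(p1,p2)."""
        from crosstrait.expression import bh_adjust

        conj_tp = bh_tp = 0
        for rep in range(3):
            s1, s2, ld, truth = ct.simulate_sumstats_pair(n_variants=20_000, seed=600 + rep)
            paired = pd.DataFrame({"snp": s1["SNP"], "p1": s1["P"], "p2": s2["P"]})
            pleio = (truth.frame["component"] == "pleiotropic").to_numpy()
            blocks = ct.ld_blocks(ld, s1["SNP"], 0.1)
            res = cf.compute_condfdr_result(paired, blocks, cf.QQConfig(pruning_iterations=50))
            conj_tp += ((res.frame["conj_fdr"].to_numpy() < 0.01) & pleio).sum()
            bh_tp += ((bh_adjust(np.maximum(paired["p1"], paired["p2"])) < 0.01) & pleio).sum()
        assert conj_tp >= bh_tp
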