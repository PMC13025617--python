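"""f4 statistics, jackknife machinery, regression and sex-bias tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from admixchron.fstats import (
    BlockPartition,
    F4Regression,
    f4,
    jackknife,
    jackknife_from_loo,
    sex_bias_z,
    symmetry_scan,
)
from admixchron.io import allele_frequencies
from admixchron.simulate import SimConfig, simulate_cohort
from conftest import random_dataset


class TestJackknife:
    def test_constant_blocks_give_zero_se(self):
        est, se = jackknife([3.3] * 6, [1, 2, 3, 1, 2, 3])
        assert est == pytest.approx(3.3)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_equal_weights_match_hand_enumerated_delete_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        est, se = jackknife(vals, np.ones(4))
        # classic delete-one jackknife by explicit enumeration
        loo = np.array([vals[np.arange(4) != j].mean() for j in range(4)])
        se_classic = np.sqrt((4 - 1) / 4 * ((loo - loo.mean()) ** 2).sum())
        assert est == pytest.approx(vals.mean())
        assert se == pytest.approx(se_classic, rel=1e-12)

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=12),
        st.floats(0.5, 8.0),
    )
    def test_weight_scale_invariance(self, vals, factor):
        w = np.arange(1.0, len(vals) + 1.0)
        est1, se1 = jackknife(vals, w)
        est2, se2 = jackknife(vals, w * factor)
        assert est1 == pytest.approx(est2, rel=1e-10, abs=1e-12)
        assert se1 == pytest.approx(se2, rel=1e-10, abs=1e-12)

    def test_fewer_than_two_blocks_rejected(self):
        with pytest.raises(ValueError, match="2 blocks"):
            jackknife([1.0], [5.0])
        with pytest.raises(ValueError, match="2 blocks"):
            jackknife([1.0, 2.0], [5.0, 0.0])

    def test_matches_analytic_se_of_mean_on_iid_blocks(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 200)
        _, se = jackknife(vals, np.ones(200))
        analytic = vals.std(ddof=1) / np.sqrt(200)
        assert abs(se - analytic) / analytic < 0.10

    def test_loo_variant_agrees_with_block_variant(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 30)
        w = rng.uniform(0.5, 2.0, 30)
        est, se = jackknife(vals, w)
        n = w.sum()
        loo = (n * est - w * vals) / (n - w)
        assert jackknife_from_loo(est, loo, w) == pytest.approx(se, rel=1e-10)


class TestF4:
    def test_identical_final_pair_is_exactly_zero(self):
        ds = random_dataset(np.random.default_rng(2), n_variants=80)
        res = f4(ds, "pop0", "pop1", "pop2", "pop2")
        assert res.estimate == 0.0
        assert res.z == 0.0

    def test_matches_brute_force_per_site_loop(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n_variants=500, n_samples=12, n_pops=4)
        freqs = allele_frequencies(ds)
        res = f4(ds, "pop0", "pop1", "pop2", "pop3")
        total, count = 0.0, 0
        for v in range(ds.n_variants):
            ps = [freqs[(f"pop{k}", "freq")].iloc[v] for k in range(4)]
            if any(np.isnan(p) for p in ps):
                continue
            total += (ps[0] - ps[1]) * (ps[2] - ps[3])
            count += 1
        assert res.n_snps == count
        assert res.estimate == pytest.approx(total / count, abs=1e-12)

    def test_antisymmetry_identities(self):
        ds = random_dataset(np.random.default_rng(4), n_variants=120)
        blocks = BlockPartition.contiguous(ds)
        freqs = allele_frequencies(ds)
        base = f4(ds, "pop0", "pop1", "pop2", "pop3", blocks, freqs)
        swap_cd = f4(ds, "pop0", "pop1", "pop3", "pop2", blocks, freqs)
        swap_ab = f4(ds, "pop1", "pop0", "pop2", "pop3", blocks, freqs)
        assert base.estimate == pytest.approx(-swap_cd.estimate, abs=1e-15)
        assert base.estimate == pytest.approx(-swap_ab.estimate, abs=1e-15)
        assert base.se == pytest.approx(swap_cd.se, rel=1e-10)

    def test_additivity_over_middle_population(self):
        # f4(A,B;C,D) = f4(A,B;C,E) + f4(A,B;E,D) on complete data
        ds = random_dataset(
            np.random.default_rng(5), n_variants=200, n_samples=10, n_pops=5,
            missing=0.0,
        )
        freqs = allele_frequencies(ds)
        blocks = BlockPartition.contiguous(ds)
        f_cd = f4(ds, "pop0", "pop1", "pop2", "pop3", blocks, freqs)
        f_ce = f4(ds, "pop0", "pop1", "pop2", "pop4", blocks, freqs)
        f_ed = f4(ds, "pop0", "pop1", "pop4", "pop3", blocks, freqs)
        assert f_cd.estimate == pytest.approx(
            f_ce.estimate + f_ed.estimate, abs=1e-14
        )

    def test_no_usable_snps_errors(self):
        ds = random_dataset(np.random.default_rng(6), n_variants=20)
        ds.calls[:, (ds.samples["population"] == "pop0").to_numpy()] = -1
        with pytest.raises(ValueError, match="no usable|all-missing"):
            f4(ds, "pop0", "pop1", "pop2", "pop3")


class TestSymmetryScan:
    def test_target_equal_baseline_z_zero(self):
        ds = random_dataset(np.random.default_rng(7), n_variants=60)
        tab = symmetry_scan(ds, ["pop0"], "pop0", "pop2", "pop3")
        assert tab["z"].iloc[0] == 0.0
        assert tab["estimate"].iloc[0] == 0.0

    def test_detects_excess_papuan_affinity(self):
        # target has 5% more Papuan ancestry than the baseline cohort
        base_cfg = dict(n_snps_per_chrom=5000, n_chroms=10, n_admixed=12,
                        missing_rate=0.02)
        ds_hi, _ = simulate_cohort(
            SimConfig(**base_cfg, alpha_autosome=0.45, seed=100)
        )
        ds_lo, _ = simulate_cohort(
            SimConfig(**base_cfg, alpha_autosome=0.40, seed=100)
        )
        # same source frequencies (same seed drives the frequency draw),
        # so the two admixed cohorts are comparable populations
        import pandas as pd

        lo = ds_lo.restrict(
            sample_filter=(ds_lo.samples["population"] == "Admixed").to_numpy()
        )
        lo.samples["population"] = "Baseline"
        lo.samples["id"] = ["B" + s for s in lo.samples["id"]]
        merged = type(ds_hi)(
            ds_hi.variants,
            pd.concat([ds_hi.samples, lo.samples], ignore_index=True),
            np.hstack([ds_hi.calls, lo.calls]),
            pseudo_haploid=True,
        )
        tab = symmetry_scan(
            merged.restrict(chromosome_class="autosomes"),
            ["Admixed"], "Baseline", "Papuan", "Outgroup0",
        )
        assert tab["z"].iloc[0] > 2.0

    def test_null_z_is_standard_normal(self):
        # unadmixed targets vs a baseline from the same population:
        # |Z| > 1.96 in at most ~5% of replicates (binomial bound at 10%)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = SimConfig(
                n_snps_per_chrom=400, n_chroms=5, n_admixed=6,
                alpha_autosome=0.0, alpha_X=0.0, include_x=False,
                n_source1=6, missing_rate=0.0, seed=10_000 + rep,
            )
            ds, _ = simulate_cohort(cfg)
            tab = symmetry_scan(
                ds, ["Admixed"], "EastAsian", "Papuan", "Outgroup0"
            )
            if abs(tab["z"].iloc[0]) > 1.96:
                hits += 1
        assert hits <= 0.10 * n_rep


class TestF4Regression:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.5 * x - 0.7
        fit = F4Regression(x, y, sy=np.full(4, 0.1)).fit()
        assert fit.slope == pytest.approx(2.5, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.7, abs=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_matches_closed_form_normal_equations(self):
        x = np.array([0.1, 0.5, 1.1, 2.0, 3.3])
        y = np.array([0.2, 0.9, 1.8, 3.1, 5.4])
        sy = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        fit = F4Regression(x, y, sy).fit()
        W = np.diag(1.0 / sy**2)
        M = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(M.T @ W @ M, M.T @ W @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        # weighted residuals of the fitted points sum to zero
        assert (fit.weights * fit.residuals).sum() == pytest.approx(0.0, abs=1e-9)

    def test_downweighting_outlier_moves_fit_toward_rest(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 10.0])  # last point is an outlier
        sy = np.ones(5) * 0.2
        fit_full = F4Regression(x, y, sy).fit()
        sy_down = sy.copy()
        sy_down[-1] *= 10
        fit_down = F4Regression(x, y, sy_down).fit()
        assert abs(fit_down.slope - 1.0) < abs(fit_full.slope - 1.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            F4Regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [0.1] * 3)

    def test_jackknife_residual_se_from_f4_results(self, autosomal):
        freqs = allele_frequencies(autosomal)
        blocks = BlockPartition.contiguous(autosomal)
        pops = ["Outgroup0", "OutEastAsian", "OutPapuan", "Outgroup1"]
        xs = [
            f4(autosomal, "EastAsian", p, "Papuan", "Outgroup1", blocks, freqs)
            for p in pops[:3]
        ]
        ys = [
            f4(autosomal, "Admixed", p, "Papuan", "Outgroup1", blocks, freqs)
            for p in pops[:3]
        ]
        fit = F4Regression.from_f4_results(xs, ys).fit()
        assert np.isfinite(fit.residual_se).all()
        assert (fit.residual_se > 0).all()
        # residual Z should be well-behaved (no catastrophic scaling)
        assert np.abs(fit.residual_z).max() < 50


class TestSexBias:
    def test_identical_fits_give_zero(self):
        assert sex_bias_z((0.4, 0.01), (0.4, 0.01)) == 0.0

    def test_arithmetic_example(self):
        z = sex_bias_z((0.40, 0.01), (0.36, 0.02))
        assert z == pytest.approx(0.04 / np.sqrt(0.0005), rel=1e-12)
        assert z == pytest.approx(1.789, abs=1e-3)

    def test_zero_ses_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sex_bias_z((0.4, 0.0), (0.3, 0.0))

    def test_detects_simulated_male_biased_admixture(self, cohort):
        # alpha_auto=0.40 vs alpha_X=0.30 in the shared cohort
        from admixchron.qpadm import QpAdm

        ds, _ = cohort
        rights = ["Outgroup0", "OutEastAsian", "OutPapuan", "Outgroup1"]
        auto = ds.restrict(chromosome_class="autosomes")
        x = ds.restrict(chromosome_class="X")
        fit_a = QpAdm(auto, "Admixed", ["EastAsian", "Papuan"], rights).fit()
        fit_x = QpAdm(x, "Admixed", ["EastAsian", "Papuan"], rights).fit()
        z = sex_bias_z(fit_a, fit_x, source="Papuan")
        assert z > 1.8
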