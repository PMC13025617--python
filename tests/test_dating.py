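"""Ancestry-covariance decay curves and the exponential date fit."""

import numpy as np
import pytest

from admixchron.dating import (
    AdmixtureDecay,
    DecayCurve,
    ancestry_covariance_curve,
    fit_exponential,
    merge_targets,
)
from admixchron.simulate import SimConfig, simulate_cohort


def _targets(ds, pop="Admixed"):
    return list(ds.samples.loc[ds.samples["population"] == pop, "id"])


def synthetic_curve(n, A=0.01, c=0.0, binsize=0.001, maxdis=0.5, n_chroms=6,
                    noise=0.0, seed=0):
    """A DecayCurve assembled directly from the model equation."""
    rng = np.random.default_rng(seed)
    centres = (np.arange(int(maxdis / binsize)) + 0.5) * binsize
    per_num, per_den, per_pairs = {}, {}, {}
    for k in range(n_chroms):
        vals = A * np.exp(-n * centres) + c
        if noise:
            vals = vals + rng.normal(0, noise, centres.size)
        per_num[str(k + 1)] = vals
        per_den[str(k + 1)] = np.ones_like(vals)
        per_pairs[str(k + 1)] = np.full(centres.size, 100)
    num = sum(per_num.values())
    den = sum(per_den.values())
    return DecayCurve(centres, num / den, sum(per_pairs.values()),
                      per_num, per_den, per_pairs, binsize, maxdis, 0.4)


class TestCurve:
    def test_unadmixed_target_is_flat_near_zero(self):
        import pandas as pd

        cfg = SimConfig(
            n_snps_per_chrom=1500, n_chroms=10, alpha_autosome=0.0,
            alpha_X=0.0, include_x=False, missing_rate=0.0, seed=50,
        )
        ds, truth = simulate_cohort(cfg)
        # noise-free source frequencies isolate the admixture-LD signal;
        # sample-estimated frequencies add a constant offset that the
        # affine fit term absorbs (checked in TestFitExponential)
        sf = truth["source_freqs"]
        freqs = pd.DataFrame(
            {
                (pop, "freq"): sf[pop].to_numpy()
                for pop in ("EastAsian", "Papuan")
            }
        )
        freqs.columns = pd.MultiIndex.from_tuples(freqs.columns)
        curve = ancestry_covariance_curve(
            ds, _targets(ds), "EastAsian", "Papuan", binsize=0.005, maxdis=0.3,
            alpha=0.0, freqs=freqs,
        )
        # every bin within a few jackknife SDs of zero
        loo = np.vstack([curve.leave_one_out(c) for c in curve.chromosomes])
        se = loo.std(axis=0, ddof=1) * np.sqrt(len(curve.chromosomes) - 1)
        ok = se > 0
        assert (np.abs(curve.values[ok]) < 4 * se[ok]).mean() > 0.95

    def test_admixed_curve_decays_at_rate_n(self, autosomal):
        curve = ancestry_covariance_curve(
            autosomal, _targets(autosomal), "EastAsian", "Papuan",
            binsize=0.002, maxdis=0.3,
        )
        sel = (curve.bin_centres >= 0.01) & (curve.bin_centres <= 0.1)
        d = curve.bin_centres[sel]
        v = curve.values[sel]
        assert (v[d < 0.03].mean()) > (v[d > 0.07].mean()) > 0
        # log-linear slope ~ -n (truth n = 30)
        pos = v > 0
        slope = np.polyfit(d[pos], np.log(v[pos]), 1)[0]
        assert -45 < slope < -15

    def test_concatenated_curve_is_weighted_chromosome_combination(self, autosomal):
        curve = ancestry_covariance_curve(
            autosomal, _targets(autosomal)[:5], "EastAsian", "Papuan",
            binsize=0.005, maxdis=0.2,
        )
        num = sum(curve.per_chrom_num.values())
        den = sum(curve.per_chrom_den.values())
        with np.errstate(invalid="ignore"):
            recomposed = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        np.testing.assert_allclose(curve.values, recomposed, equal_nan=True)
        # and each per-chromosome component is itself a valid curve piece
        assert set(curve.chromosomes) == {str(c) for c in range(1, 23)}

    def test_alpha_estimated_close_to_truth(self, autosomal):
        curve = ancestry_covariance_curve(
            autosomal, _targets(autosomal), "EastAsian", "Papuan",
            binsize=0.01, maxdis=0.1,
        )
        assert 0.25 < curve.alpha_used < 0.55

    def test_no_pairs_within_maxdis_errors(self, tiny_ds):
        with pytest.raises(ValueError):
            ancestry_covariance_curve(
                tiny_ds, ["i1"], "P1", "P2", binsize=0.0001, maxdis=0.0002
            )


class TestFitExponential:
    def test_noiseless_inversion_recovers_parameters(self):
        curve = synthetic_curve(n=25.0, A=0.01, c=0.0)
        fit = fit_exponential(curve, mindis=0.005)
        assert fit.n_generations == pytest.approx(25.0, abs=1e-3)
        assert fit.amplitude == pytest.approx(0.01, rel=1e-3)
        assert fit.se_generations == pytest.approx(0.0, abs=1e-6)

    def test_affine_term_absorbed(self):
        curve = synthetic_curve(n=40.0, A=0.008, c=0.002)
        fit = fit_exponential(curve, mindis=0.005)
        assert fit.n_generations == pytest.approx(40.0, abs=1e-2)
        assert fit.affine == pytest.approx(0.002, abs=1e-5)

    def test_flat_curve_has_no_decay_signal(self):
        curve = synthetic_curve(n=30.0, A=0.0, c=0.001)
        with pytest.raises(ValueError, match="decay signal|amplitude"):
            fit_exponential(curve, mindis=0.005)

    def test_recovery_on_simulated_cohort(self, autosomal):
        model = AdmixtureDecay(
            autosomal, _targets(autosomal), "EastAsian", "Papuan",
            binsize=0.001, maxdis=0.5,
        )
        fit = model.fit(mindis=0.005)
        upper, lower = fit.ci95()
        assert lower <= 30 <= upper
        assert fit.se_generations > 0

    def test_monotone_in_true_admixture_time(self):
        fitted = []
        for n_true in (10.0, 30.0, 60.0):
            cfg = SimConfig(
                n_snps_per_chrom=1500, n_chroms=16,
                admixture_generations=n_true, include_x=False,
                missing_rate=0.02, seed=60,
            )
            ds, _ = simulate_cohort(cfg)
            fit = AdmixtureDecay(
                ds, _targets(ds), "EastAsian", "Papuan",
                binsize=0.002, maxdis=0.5,
            ).fit(mindis=0.005)
            fitted.append(fit.n_generations)
        assert fitted[0] < fitted[1] < fitted[2]

    def test_amplitude_scales_with_alpha_variance(self):
        amps = {}
        for alpha in (0.1, 0.5):
            cfg = SimConfig(
                n_snps_per_chrom=1500, n_chroms=12, alpha_autosome=alpha,
                include_x=False, missing_rate=0.0, seed=61,
            )
            ds, _ = simulate_cohort(cfg)
            fit = AdmixtureDecay(
                ds, _targets(ds), "EastAsian", "Papuan",
                binsize=0.002, maxdis=0.4,
            ).fit(mindis=0.005)
            amps[alpha] = fit.amplitude
        assert amps[0.5] > amps[0.1]

    def test_too_few_bins_rejected(self):
        curve = synthetic_curve(n=30.0, maxdis=0.02, binsize=0.005)
        with pytest.raises(ValueError, match="bins"):
            fit_exponential(curve, mindis=0.015)


class TestMergeTargets:
    def test_singleton_group_equals_single_sample_curve(self, autosomal):
        sid = _targets(autosomal)[0]
        groups = merge_targets(autosomal, {"solo": [sid]})
        c1 = ancestry_covariance_curve(
            autosomal, groups["solo"], "EastAsian", "Papuan",
            binsize=0.01, maxdis=0.1,
        )
        c2 = ancestry_covariance_curve(
            autosomal, [sid], "EastAsian", "Papuan", binsize=0.01, maxdis=0.1,
        )
        np.testing.assert_allclose(c1.values, c2.values, equal_nan=True)

    def test_merging_samples_shrinks_jackknife_se(self, autosomal):
        ts = _targets(autosomal)
        fits = []
        for members in (ts[:2], ts):
            fit = AdmixtureDecay(
                autosomal, members, "EastAsian", "Papuan",
                binsize=0.002, maxdis=0.4,
            ).fit(mindis=0.005)
            fits.append(fit)
        assert fits[1].se_generations < fits[0].se_generations

    def test_pair_count_accounting(self, autosomal):
        ts = _targets(autosomal)[:4]
        kwargs = dict(binsize=0.01, maxdis=0.1)
        whole = ancestry_covariance_curve(
            autosomal, ts, "EastAsian", "Papuan", **kwargs
        )
        # pair positions are the same; the n_pairs counter tracks bins with
        # at least one doubly-called individual, so the merged run can only
        # gain usable pairs
        part = ancestry_covariance_curve(
            autosomal, ts[:1], "EastAsian", "Papuan", **kwargs
        )
        assert (whole.n_pairs >= part.n_pairs).all()

    def test_empty_group_rejected(self, autosomal):
        with pytest.raises(ValueError, match="empty"):
            merge_targets(autosomal, {"bad": []})

    def test_unknown_sample_rejected(self, autosomal):
        with pytest.raises(KeyError):
            merge_targets(autosomal, {"bad": ["ghost"]})
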