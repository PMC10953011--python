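"""Apparent and global fits, F-test model comparison, and inhibition detection."""

import warnings

import numpy as np
import pytest
from scipy import stats

from nitrokin.datasets import RateDataset
from nitrokin.fitting import (
    ModelVariant,
    NonIdentifiableError,
    compare_models,
    detect_inhibition,
    fit_apparent_mm,
    fit_global,
    format_fit_table,
)
from nitrokin.rate_laws import KineticParameters, rate_grid
from nitrokin.synth import DesignConfig, default_designs, simulate_rates

A_GRID = tuple(270.0 / 2**k for k in reversed(range(7)))
B_GRID = tuple(290.0 / 2**k for k in reversed(range(7)))


def noiseless_design(**overrides) -> DesignConfig:
    base = dict(
        a_grid=A_GRID,
        b_grid=B_GRID,
        fixed_a=75.0,
        fixed_b=100.0,
        inhibitor_levels=(0.0, 200.0, 500.0, 1000.0, 2000.0),
        replicates=1,
        noise_cv=0.0,
    )
    base.update(overrides)
    return DesignConfig(**base)


class TestApparentFit:
    def test_noiseless_round_trip(self):
        """Exact Michaelis-Menten data returns the generating Vmax and Km."""
        vmax, km = 19.380, 20.930
        s = np.array([5.0, 10, 20, 40, 80, 160, 320])
        v = vmax * s / (km + s)
        fit = fit_apparent_mm(s, v)
        assert fit.vmax_app == pytest.approx(vmax, rel=1e-6)
        assert fit.km_app == pytest.approx(km, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_all_zero_rates_rejected(self):
        s = np.array([5.0, 10, 20, 40])
        with pytest.raises(NonIdentifiableError):
            fit_apparent_mm(s, np.zeros_like(s))

    def test_single_concentration_rejected(self):
        with pytest.raises(NonIdentifiableError):
            fit_apparent_mm(np.full(6, 20.0), np.full(6, 5.0))


class TestGlobalFit:
    def test_noiseless_recovery_both_variant(self, fumarate_params):
        dataset = simulate_rates(fumarate_params, noiseless_design())
        fit = fit_global(dataset, ModelVariant.BOTH)
        assert fit.converged
        for name, truth in [("kcat", 25.0), ("km_a", 27.0), ("km_b", 29.0),
                            ("ki_a", 960.0), ("ki_b", 145.0)]:
            assert getattr(fit.params, name) == pytest.approx(truth, rel=1e-3)

    def test_noiseless_recovery_from_perturbed_starts(self, fumarate_params):
        dataset = simulate_rates(fumarate_params, noiseless_design())
        rng = np.random.default_rng(11)
        for _ in range(5):
            factors = rng.uniform(0.5, 1.5, size=5)
            init = KineticParameters(
                25 * factors[0], 27 * factors[1], 29 * factors[2],
                960 * factors[3], 145 * factors[4],
            )
            fit = fit_global(dataset, ModelVariant.BOTH, init=init)
            assert fit.params.kcat == pytest.approx(25.0, rel=1e-3)
            assert fit.params.ki_b == pytest.approx(145.0, rel=1e-3)

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_every_variant_round_trips(self, variant):
        """Data generated under each variant is recovered to < 0.1 %."""
        rng = np.random.default_rng(hash(variant.value) % 2**31)
        for _ in range(5):
            kcat = rng.uniform(5, 80)
            km_a = rng.uniform(5, 120)
            km_b = rng.uniform(5, 120)
            ki = dict(
                ki_a=rng.uniform(100, 5000) if "ki_a" in variant.param_names else None,
                ki_b=rng.uniform(100, 5000) if "ki_b" in variant.param_names else None,
            )
            truth = KineticParameters(kcat, km_a, km_b, **ki)
            design = noiseless_design(
                a_grid=tuple(10 * km_a / 2**k for k in reversed(range(7))),
                b_grid=tuple(10 * km_b / 2**k for k in reversed(range(7))),
                fixed_a=2 * km_a,
                fixed_b=2 * km_b,
            )
            dataset = simulate_rates(truth, design)
            perturbed = KineticParameters(
                kcat * rng.uniform(0.5, 1.5),
                km_a * rng.uniform(0.5, 1.5),
                km_b * rng.uniform(0.5, 1.5),
                ki_a=(ki["ki_a"] * rng.uniform(0.5, 1.5)) if ki["ki_a"] else None,
                ki_b=(ki["ki_b"] * rng.uniform(0.5, 1.5)) if ki["ki_b"] else None,
            )
            fit = fit_global(dataset, variant, init=perturbed)
            for name in variant.param_names:
                assert getattr(fit.params, name) == pytest.approx(
                    getattr(truth, name), rel=1e-3
                ), f"{variant.value}:{name}"

    def test_noiseless_no_inhibition_rss_zero(self, nfsb_params):
        design = noiseless_design(inhibitor_levels=(0.0,))
        dataset = simulate_rates(nfsb_params, design)
        fit = fit_global(dataset, ModelVariant.NO_INHIBITION)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_ki_without_inhibitor_data_is_nonidentifiable(self, nfsb_params):
        dataset = simulate_rates(nfsb_params, noiseless_design(inhibitor_levels=(0.0,)))
        with pytest.raises(NonIdentifiableError):
            fit_global(dataset, ModelVariant.BOTH)

    def test_concentration_rescale_invariance(self, fumarate_params):
        """Fitting in mM with matching parameter rescale leaves kcat unchanged."""
        dataset = simulate_rates(fumarate_params, noiseless_design())
        scaled = RateDataset(
            dataset.data.assign(
                A_uM=dataset.a / 1000, B_uM=dataset.b / 1000, I_uM=dataset.i / 1000
            ),
            dataset.metadata,
        )
        init = KineticParameters(30.0, 0.020, 0.040, 1.0, 0.2)
        fit = fit_global(scaled, ModelVariant.BOTH, init=init)
        assert fit.params.kcat == pytest.approx(25.0, rel=1e-3)
        assert fit.params.km_a == pytest.approx(0.027, rel=1e-3)

    def test_noisy_fit_kcat_bias_is_small(self, fumarate_params):
        """Median kcat error stays < 2 % at 5 % multiplicative noise."""
        errors = []
        for seed in range(60):
            design = noiseless_design(noise_cv=0.05, replicates=3, seed=seed)
            dataset = simulate_rates(fumarate_params, design)
            fit = fit_global(dataset, ModelVariant.BOTH)
            errors.append(abs(fit.params.kcat - 25.0) / 25.0)
        assert np.median(errors) < 0.02

    def test_optimizer_beats_exhaustive_grid(self):
        """LM optimum RSS <= best RSS over a 20^3 log-spaced parameter grid."""
        rng = np.random.default_rng(5)
        for _ in range(4):
            truth = KineticParameters(
                rng.uniform(10, 60), rng.uniform(10, 80), rng.uniform(10, 80)
            )
            design = noiseless_design(inhibitor_levels=(0.0,), noise_cv=0.05,
                                      replicates=2, seed=int(rng.integers(2**31)))
            dataset = simulate_rates(truth, design)
            fit = fit_global(dataset, ModelVariant.NO_INHIBITION)
            grid_rss = _grid_min_rss(dataset, truth)
            assert fit.rss <= grid_rss * (1 + 1e-9)


def _grid_min_rss(dataset, truth, n=20):
    """Independent brute-force oracle: exhaustive RSS over a log grid
    bracketing the generating parameters."""
    best = np.inf
    kcats = np.geomspace(truth.kcat / 4, truth.kcat * 4, n)
    kmas = np.geomspace(truth.km_a / 4, truth.km_a * 4, n)
    kmbs = np.geomspace(truth.km_b / 4, truth.km_b * 4, n)
    a, b, v = dataset.a, dataset.b, dataset.v
    for kcat in kcats:
        for km_a in kmas:
            for km_b in kmbs:
                model = kcat * a * b / (km_a * b + km_b * a + a * b)
                rss = float(np.sum((model - v) ** 2))
                best = min(best, rss)
    return best


class TestCompareModels:
    def _fit_pair(self, fumarate_params, noise_cv=0.05, seed=0):
        design = noiseless_design(noise_cv=noise_cv, replicates=3, seed=seed)
        dataset = simulate_rates(fumarate_params, design)
        reduced = fit_global(dataset, ModelVariant.NO_INHIBITION)
        full = fit_global(dataset, ModelVariant.BOTH)
        return reduced, full

    def test_f_statistic_formula(self, fumarate_params):
        """F and p match the extra-sum-of-squares definition computed directly."""
        reduced, full = self._fit_pair(fumarate_params)
        cmp = compare_models(reduced, full)
        ddf = reduced.df - full.df
        f_expected = ((reduced.rss - full.rss) / ddf) / (full.rss / full.df)
        assert cmp.f_stat == pytest.approx(f_expected, rel=1e-12)
        assert cmp.p_value == pytest.approx(stats.f.sf(f_expected, ddf, full.df), rel=1e-9)
        assert cmp.selected is ModelVariant.BOTH

    def test_reference_f_value(self):
        """RSS_r = 2 RSS_f with df_f = 40, ddf = 1 gives F = 40, p ~ 1.7e-7."""
        assert stats.f.sf(40.0, 1, 40) == pytest.approx(1.653e-07, rel=1e-3)

    def test_identical_rss_keeps_reduced(self, fumarate_params):
        reduced, full = self._fit_pair(fumarate_params, noise_cv=0.0)
        # noiseless data generated under BOTH: reduced fits worse, full is exact
        cmp = compare_models(reduced, full)
        assert cmp.selected is ModelVariant.BOTH
        # degenerate case: full model no better than the reduced one
        import dataclasses

        tie = compare_models(reduced, dataclasses.replace(full, rss=reduced.rss))
        assert tie.f_stat == 0.0
        assert tie.p_value == 1.0

    def test_non_nested_pair_rejected(self, fumarate_params):
        design = noiseless_design(noise_cv=0.02, replicates=2, seed=3)
        dataset = simulate_rates(fumarate_params, design)
        fit_a = fit_global(dataset, ModelVariant.COMPETITIVE_VS_A)
        fit_b = fit_global(dataset, ModelVariant.COMPETITIVE_VS_B)
        with pytest.raises(ValueError):
            compare_models(fit_a, fit_b)


class TestDetectInhibition:
    def test_noiseless_fumarate_selects_both(self, fumarate_params):
        dataset = simulate_rates(fumarate_params, noiseless_design())
        report = detect_inhibition(dataset)
        assert report.selected is ModelVariant.BOTH

    def test_succinate_like_selects_vs_b(self, succinate_params):
        design = DesignConfig(
            a_grid=tuple(580.0 / 2**k for k in reversed(range(7))),
            b_grid=tuple(690.0 / 2**k for k in reversed(range(7))),
            fixed_a=30.0,
            fixed_b=100.0,
            inhibitor_levels=(0.0, 5000.0, 10000.0, 20000.0, 30000.0),
            replicates=3,
            noise_cv=0.02,
            seed=123,
        )
        report = detect_inhibition(simulate_rates(succinate_params, design))
        assert report.selected is ModelVariant.COMPETITIVE_VS_B
        assert report.best_fit.params.ki_b == pytest.approx(4300.0, rel=0.2)

    def test_nfsb_like_selects_no_inhibition(self, nfsb_params):
        design = default_designs(replicates=3, noise_cv=0.03, seed=7)["nfsb"]
        report = detect_inhibition(simulate_rates(nfsb_params, design))
        assert report.selected is ModelVariant.NO_INHIBITION

    def test_noiseless_uninhibited_p_near_one(self, nfsb_params):
        design = default_designs(replicates=1, noise_cv=0.0, seed=0)["nfsb"]
        report = detect_inhibition(simulate_rates(nfsb_params, design))
        assert report.selected is ModelVariant.NO_INHIBITION
        for cmp in report.comparisons:
            assert cmp.p_value == pytest.approx(1.0)

    def test_requires_control_and_positive_level(self, nfsb_params):
        design = noiseless_design(inhibitor_levels=(0.0,))
        dataset = simulate_rates(nfsb_params, design)
        with pytest.raises(NonIdentifiableError):
            detect_inhibition(dataset)


def test_format_fit_table_contains_headline_numbers(fumarate_params):
    dataset = simulate_rates(fumarate_params, noiseless_design(noise_cv=0.02,
                                                               replicates=3, seed=1))
    fit = fit_global(dataset, ModelVariant.BOTH)
    table = format_fit_table(fit)
    assert "kcat" in table and "Ki NADPH" in table
    # kcat/Km for the nitrofurazone arm prints near 25/27 = 0.93
    assert any(line.startswith("kcat/Km NFZ") for line in table.splitlines())
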