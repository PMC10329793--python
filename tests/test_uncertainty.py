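"""Three-class Monte Carlo: classification, rate mixtures, propagation."""

import math

import numpy as np
import pytest

import ufcarbon as uf
from ufcarbon.types import UncertaintyClass
from ufcarbon.uncertainty import _combine, zeroed


class TestClassifyRu:
    def test_ru_without_cities_is_proxy(self, ru_by_id, cities):
        klass, w = uf.classify_ru(ru_by_id[9], cities)
        assert klass is UncertaintyClass.PROXY

    def test_partial_ru_weights_sum_to_one(self, ru_by_id, cities):
        klass, w = uf.classify_ru(ru_by_id[10], cities)
        assert klass is UncertaintyClass.PARTIAL
        assert w["covered"] == pytest.approx(202986 / 531700)
        assert w["covered"] + w["partial"] == pytest.approx(1.0)

    def test_oversized_assessment_capped_at_full_coverage(self, ru_by_id, cities):
        # the assessed area exceeds the stratum's defined urban area
        klass, w = uf.classify_ru(ru_by_id[16], cities)
        assert klass is UncertaintyClass.CITY_COVERED
        assert w["covered"] == 1.0


@pytest.fixture(scope="module")
def variability(cities, rus, ru_densities):
    return uf.compute_variability(cities, rus, ru_densities)


@pytest.fixture(scope="module")
def mc(rus, cities, ru_densities):
    cfg = uf.UncertaintyConfig(iterations=4000, seed=3)
    return uf.run_monte_carlo(rus, cities, ru_densities, cfg)


class TestRateDistributions:

    def test_reference_ru_is_the_city_richest(self, variability):
        assert variability.reference_ru == 10
        assert variability.inter_city_storage > 0
        assert variability.inter_ru_storage > 0

    def test_mixture_mean_equals_assigned_density(
        self, rus, cities, ru_densities, variability
    ):
        for ru in rus:
            dist = uf.build_rate_distribution(
                ru, "storage", cities, rus, ru_densities, variability
            )
            assert dist.mean == pytest.approx(
                ru_densities[ru.ru_id].storage_density, rel=1e-9
            )

    def test_proxy_sd_is_quadrature_of_components(
        self, rus, cities, ru_densities, variability, ru_by_id, city_by_name
    ):
        # Atlantic proxy RU: surrogate-city SE + inter-city SD + inter-RU SD
        dist = uf.build_rate_distribution(
            ru_by_id[14], "storage", cities, rus, ru_densities, variability
        )
        hal = city_by_name["Halifax"]
        at = hal.assessment_area * ru_by_id[16].canopy_fraction
        expected = math.sqrt(
            (hal.carbon_storage_se / at) ** 2
            + variability.inter_city_storage**2
            + variability.inter_ru_storage**2
        )
        [(label, w, mean, sd)] = dist.components
        assert (label, w) == ("proxy", 1.0)
        assert sd == pytest.approx(expected, rel=1e-9)

    def test_quadrature_matches_summed_normal_draws(self):
        sds = [1.5, 2.0, 0.7]
        rng = np.random.default_rng(0)
        total = sum(rng.normal(0, s, 200_000) for s in sds)
        assert total.std() == pytest.approx(_combine(sds, "quadrature"), rel=0.02)

    def test_forest_model_proxy_has_inter_ru_sd_only(
        self, rus, cities, ru_densities, variability, ru_by_id
    ):
        dist = uf.build_rate_distribution(
            ru_by_id[6], "seq", cities, rus, ru_densities, variability
        )
        [(_, _, _, sd)] = dist.components
        assert sd == pytest.approx(variability.inter_ru_seq)

    def test_zero_inter_city_sd_gives_point_mass_partial(self, ru_by_id, cities, rus, ru_densities):
        flat = uf.Variability(0.0, 0.0, 0.0, 0.0, reference_ru=10)
        dist = uf.build_rate_distribution(
            ru_by_id[10], "seq", cities, rus, ru_densities, flat
        )
        partial = [c for c in dist.components if c[0] == "partial"]
        assert partial and partial[0][3] == 0.0


class TestMonteCarlo:
    def test_zero_uncertainty_collapses_to_deterministic(
        self, rus, cities, ru_densities, accounts
    ):
        cfg = zeroed(uf.UncertaintyConfig(iterations=500, seed=0))
        res = uf.run_monte_carlo(rus, cities, ru_densities, cfg)
        _, nat = accounts
        b = res.national["seq_gross"]
        assert b.p2_5 == pytest.approx(nat.seq_gross, rel=1e-9)
        assert b.p97_5 == pytest.approx(nat.seq_gross, rel=1e-9)
        assert b.mean == pytest.approx(nat.seq_gross, rel=1e-9)

    def test_seed_determinism_bit_exact(self, rus, cities, ru_densities):
        cfg = uf.UncertaintyConfig(iterations=1500, seed=11)
        a = uf.run_monte_carlo(rus, cities, ru_densities, cfg)
        b = uf.run_monte_carlo(rus, cities, ru_densities, cfg)
        assert a.national["storage"] == b.national["storage"]
        assert a.per_ru[10]["seq_gross"] == b.per_ru[10]["seq_gross"]

    def test_percentiles_bracket_mean(self, mc):
        for q, b in mc.national.items():
            assert b.p2_5 <= b.mean <= b.p97_5

    def test_proxy_bounds_wider_than_city_covered(self, mc):
        widths = {
            ru_id: mc.per_ru[ru_id]["seq_gross"].rel_high
            - mc.per_ru[ru_id]["seq_gross"].rel_low
            for ru_id in mc.per_ru
        }
        proxy = [widths[r] for r, k in mc.classes.items() if k is UncertaintyClass.PROXY]
        covered = [
            widths[r] for r, k in mc.classes.items() if k is UncertaintyClass.CITY_COVERED
        ]
        assert min(proxy) > max(covered)

    def test_mean_preserved_under_area_skew_alone(self, rus, cities, ru_densities, accounts):
        # only the triangular area factor active: the Monte-Carlo mean should
        # sit at the deterministic value times the triangular mean factor
        cfg = uf.UncertaintyConfig(
            iterations=60_000,
            seed=5,
            model_uncertainty=0.0,
            canopy_uncertainty=0.0,
            include_rate_uncertainty=False,
        )
        res = uf.run_monte_carlo(rus, cities, ru_densities, cfg)
        _, nat = accounts
        expected = nat.seq_gross * cfg.triangular_mean_factor
        draws_sd = (res.national["seq_gross"].p97_5 - res.national["seq_gross"].p2_5) / 4
        mc_se = draws_sd / math.sqrt(cfg.iterations)
        assert abs(res.national["seq_gross"].mean - expected) < 3 * mc_se

    def test_truncation_rate_reported(self, mc):
        assert 0.0 <= mc.truncation_rate < 0.1

    def test_too_few_iterations_rejected(self):
        with pytest.raises(uf.ValidationError):
            uf.UncertaintyConfig(iterations=1)

    def test_canopy_semantics_both_run(self, rus, cities, ru_densities):
        for sem in ("relative", "absolute"):
            cfg = uf.UncertaintyConfig(iterations=200, seed=1, canopy_semantics=sem)
            res = uf.run_monte_carlo(rus, cities, ru_densities, cfg)
            assert res.national["storage"].mean > 0
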