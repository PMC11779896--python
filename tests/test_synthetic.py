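"""Ground-truth structure and reproducibility of the synthetic generator."""

import logging

import numpy as np
import pytest

from buffercrops import (
    BinSpec,
    ClimateParams,
    CROPS,
    SynthConfig,
    aggregate_bins,
    bin_proxy,
    cross_region_correlation,
    gen_climate,
    gen_contexts,
    gen_manor,
    gen_stations,
    ground_truth,
    regional_mean_precip,
)
from buffercrops import io as bcio
from buffercrops.synthetic import _ar1_series


class TestGenClimate:
    def test_noise_free_limit_equals_trend(self):
        params = ClimateParams(mean=2.0, ar_coef=0.0, noise_sd=0.0,
                               segments=((500, 1000, 1.0),))
        years = np.arange(100, 1801)
        vals = _ar1_series(params, years, np.random.default_rng(0))
        assert np.all(vals[(years >= 500) & (years < 1000)] == 3.0)
        assert np.all(vals[years < 500] == 2.0)

    def test_same_seed_identical(self):
        cfg = SynthConfig(seed=9)
        v1, c1 = gen_climate(cfg)
        v2, c2 = gen_climate(cfg)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_stationary_mean_recovered(self):
        params = ClimateParams(mean=5.0, ar_coef=0.6, noise_sd=0.3)
        years = np.arange(100, 1801)
        vals = _ar1_series(params, years, np.random.default_rng(3))
        # effective SE of the mean of an AR(1): sd/sqrt(n) * sqrt((1+phi)/(1-phi))
        stat_sd = 0.3 / np.sqrt(1 - 0.6**2)
        se = stat_sd / np.sqrt(len(years)) * np.sqrt((1 + 0.6) / (1 - 0.6))
        assert abs(vals.mean() - 5.0) <= 3 * se

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClimateParams(mean=0, ar_coef=1.0, noise_sd=0.1)


class TestGenContexts:
    def test_zero_couplings_give_symmetric_shares(self):
        cfg = SynthConfig(
            seed=5, n_contexts_per_bin=40,
            crop_intercepts=(0.0,) * 5,
            coupling_temp=(0.0,) * 5, coupling_precip=(0.0,) * 5,
        )
        contexts = gen_contexts(cfg, gen_climate(cfg))
        shares = np.array(
            [[c.percentages()[crop] / 100 for crop in CROPS] for c in contexts]
        )
        mean = shares.mean(axis=0)
        n_total = len(contexts) * cfg.n_seeds_per_context
        se = np.sqrt(0.2 * 0.8 / n_total)
        assert np.all(np.abs(mean - 0.2) <= 4 * se)

    def test_thermophilic_coupling_shows_in_warm_bins(self):
        signs = 0
        for rep in range(20):
            cfg = SynthConfig(seed=700 + rep)
            varve, cit = gen_climate(cfg)
            contexts = gen_contexts(cfg, (varve, cit))
            spec = BinSpec()
            series = aggregate_bins(contexts, spec)
            binned_t = dict(
                (b, v) for b, v, _ in bin_proxy(cit, spec).bins
            )
            temps = np.array([binned_t[b.bin_start] for b in series.bins])
            millet = np.array([b.mean_percent["millet"] for b in series.bins])
            warm = temps > np.median(temps)
            signs += millet[warm].mean() > millet[~warm].mean()
        assert signs >= 18

    def test_degenerate_span_gives_point_dates(self):
        cfg = SynthConfig(seed=2, span_halfwidth=(0, 0))
        contexts = gen_contexts(cfg, gen_climate(cfg))
        assert all(c.date_early == c.date_late for c in contexts)

    def test_reproducible(self):
        cfg = SynthConfig(seed=11)
        climate = gen_climate(cfg)
        a = gen_contexts(cfg, climate)
        b = gen_contexts(cfg, climate)
        assert a == b


class TestGenManor:
    def test_millet_mention_rate_near_one_third(self):
        cfg = SynthConfig(seed=8, n_records_per_century={16: 300, 17: 300, 18: 300})
        records = gen_manor(cfg)
        rate = np.mean([r.present["millet"] for r in records])
        se = np.sqrt((1 / 3) * (2 / 3) / len(records))
        assert abs(rate - 1 / 3) <= 3 * se

    def test_rye_dominates_mean_shares(self):
        from buffercrops import century_summary

        records = gen_manor(SynthConfig(seed=8))
        for s in century_summary(records):
            assert s.mean_share["rye"] > 0.4
            assert s.mean_share["oat"] > 0.2

    def test_oat_shift_moves_mean_share(self):
        base = SynthConfig(seed=8, n_records_per_century={16: 200, 17: 200, 18: 200})
        shifted = base.with_oat_shift(0.15)
        from buffercrops import century_summary

        s_base = {s.century: s for s in century_summary(gen_manor(base))}
        s_shift = {s.century: s for s in century_summary(gen_manor(shifted))}
        delta = s_shift[18].mean_share["oat"] - s_base[18].mean_share["oat"]
        assert 0.08 <= delta <= 0.22

    def test_reproducible(self):
        cfg = SynthConfig(seed=14)
        assert gen_manor(cfg) == gen_manor(cfg)


class TestGenStations:
    def test_two_regions_of_fifteen(self):
        stations = gen_stations(SynthConfig(seed=1))
        regions = {s.region for s in stations}
        assert regions == {"proxy_region", "study_region"}
        assert sum(s.region == "proxy_region" for s in stations) == 15

    def test_configured_region_correlation_recovered(self):
        rs = []
        for rep in range(25):
            cfg = SynthConfig(seed=900 + rep, station_noise_sd=0.0)
            stations = gen_stations(cfg)
            a = regional_mean_precip(stations, "proxy_region")
            b = regional_mean_precip(stations, "study_region")
            rs.append(cross_region_correlation(a, b)[0])
        assert abs(np.mean(rs) - 0.82) <= 0.05

    def test_wartime_gaps_leave_regional_mean_defined(self):
        stations = gen_stations(SynthConfig(seed=4))
        mean = regional_mean_precip(stations, "proxy_region")
        years = dict(mean.pairs())
        for y in range(1914, 1919):
            assert y in years


class TestValidators:
    def test_generated_tables_pass_readers_without_warnings(self, tmp_path, caplog):
        cfg = SynthConfig(seed=3, missing_rate=0.0)
        varve, cit = gen_climate(cfg)
        contexts = gen_contexts(cfg, (varve, cit))
        manors = gen_manor(cfg)
        bcio.write_arch_table(contexts, tmp_path / "arch.csv")
        bcio.write_proxy_series(varve, tmp_path / "varve.csv")
        bcio.write_manor_table(manors, tmp_path / "manor.csv")
        with caplog.at_level(logging.WARNING, logger="buffercrops.io"):
            back_ctx = bcio.read_arch_table(tmp_path / "arch.csv")
            back_proxy = bcio.read_proxy_series(tmp_path / "varve.csv")
            back_manor = bcio.read_manor_table(tmp_path / "manor.csv")
        assert not caplog.records
        assert len(back_ctx) == len(contexts)
        assert len(back_proxy) == len(varve)
        assert len(back_manor) == len(manors)

    def test_ground_truth_sidecar_names_coupled_signs(self):
        gt = ground_truth(SynthConfig(seed=0))
        assert gt["expected_coupled_signs"]["millet~cit_temperature"] == 1
        assert gt["expected_coupled_signs"]["buckwheat~cit_temperature"] == -1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(missing_rate=1.5)
        with pytest.raises(ValueError):
            SynthConfig(mention_prob={"rye": 2.0})
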