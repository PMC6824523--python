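"""Concentration inversion, blank algebra and time averaging."""

import numpy as np
import pytest

from uncsampler import quantify as q
from uncsampler.config import EfficiencyCurve


def occasion(oid="o1", surface="PC", role="sample", hours=24.0, location="lab"):
    return q.SamplingOccasion(
        occasion_id=oid, location=location, surface=surface, role=role, duration_h=hours
    )


def particle(mass_ng, d_ae):
    return q.SizedParticle(
        pixel_count=1, area_um2=1.0, d_pa_um=1.0, d_ve_um=1.0, d_ae_um=d_ae, mass_ng=mass_ng
    )


def result(oid, pm25, pm10):
    return q.ConcentrationResult(occasion_id=oid, pm25_mg_m3=pm25, pm10_mg_m3=pm10)


class TestPmWeight:
    def test_sharp_cut_boundary_inclusive(self, cfg):
        assert q.pm_weight(2.5, cfg, "pm2.5") == 1.0
        assert q.pm_weight(10.0, cfg, "pm10") == 1.0

    def test_sharp_cut_above(self, cfg):
        assert q.pm_weight(3.0, cfg, "pm2.5") == 0.0
        assert q.pm_weight(3.0, cfg, "pm10") == 1.0

    @pytest.mark.parametrize("convention", ["sharp", "smooth"])
    @pytest.mark.parametrize("fraction", ["pm2.5", "pm10"])
    def test_weights_non_increasing(self, cfg, convention, fraction):
        c = cfg.with_(pm_convention=convention)
        d = np.geomspace(0.1, 30, 300)
        w = q.pm_weight(d, c, fraction)
        assert np.all(np.diff(w) <= 0)
        assert np.all((w >= 0) & (w <= 1))


class TestStubConcentration:
    def test_empty_particle_list_zero(self, cfg):
        res = q.stub_concentration([], 1.0, occasion(), cfg)
        assert res.pm25_mg_m3 == 0.0
        assert res.pm10_mg_m3 == 0.0
        assert res.counts == {"pm2.5": 0, "pm10": 0}

    def test_single_particle_hand_formula(self, cfg):
        """One 3.2e-3 ng particle over 1 mm², 24 h: the hand-evaluated
        single-term flux inversion (unit efficiency, V_dep forced to the
        particle's computed value)."""
        p = particle(mass_ng=3.2e-3, d_ae=2.0)
        from uncsampler import physics as ph

        v_dep = float(ph.deposition_velocity(2.0, cfg))
        res = q.stub_concentration([p], 1.0, occasion(hours=24.0), cfg)
        expected = (3.2e-3 * 1e-6) / v_dep / (1.0 * 1e-6 * 24 * 3600.0)
        assert res.pm25_mg_m3 == pytest.approx(expected, rel=1e-12)
        assert res.pm10_mg_m3 == pytest.approx(expected, rel=1e-12)

    def test_halving_duration_doubles_concentration(self, cfg):
        p = particle(mass_ng=1e-2, d_ae=2.0)
        c24 = q.stub_concentration([p], 1.0, occasion(hours=24.0), cfg)
        c12 = q.stub_concentration([p], 1.0, occasion(hours=12.0), cfg)
        assert c12.pm10_mg_m3 == pytest.approx(2 * c24.pm10_mg_m3, rel=1e-12)

    def test_inverse_linearity_in_area(self, cfg):
        p = particle(mass_ng=1e-2, d_ae=2.0)
        c1 = q.stub_concentration([p], 1.0, occasion(), cfg)
        c2 = q.stub_concentration([p], 2.0, occasion(), cfg)
        assert c1.pm10_mg_m3 == pytest.approx(2 * c2.pm10_mg_m3, rel=1e-12)

    def test_pm25_le_pm10_sharp(self, cfg):
        rng = np.random.default_rng(0)
        parts = [particle(rng.uniform(1e-4, 1e-1), rng.uniform(0.3, 12.0)) for _ in range(100)]
        res = q.stub_concentration(parts, 1.0, occasion(), cfg)
        assert res.pm25_mg_m3 <= res.pm10_mg_m3

    def test_zero_efficiency_particle_rejected(self, cfg):
        dead = cfg.with_(efficiency_curve=EfficiencyCurve([1.0, 5.0], [1.0, 0.0]))
        p = particle(mass_ng=1e-2, d_ae=8.0)  # η = 0 above 5 µm
        with pytest.raises(ValueError, match="zero efficiency"):
            q.stub_concentration([p], 1.0, occasion(), dead)

    def test_low_count_warning(self, cfg):
        p = particle(mass_ng=1e-2, d_ae=2.0)
        res = q.stub_concentration([p], 1.0, occasion(), cfg)
        assert any("counting-statistics" in w for w in res.warnings)

    def test_config_id_stamped(self, cfg):
        res = q.stub_concentration([], 1.0, occasion(), cfg)
        assert res.config_id == cfg.config_id


class TestBlankCorrection:
    def setup_campaign(self):
        occasions = [
            occasion("s1", "PC"),
            occasion("s2", "PC"),
            occasion("b1", "PC", role="field_blank"),
            occasion("b2", "PC", role="field_blank"),
            occasion("t1", "PC", role="transport_blank"),
            occasion("s3", "CT"),
            occasion("b3", "CT", role="field_blank"),
        ]
        results = [
            result("s1", 0.010, 0.050),
            result("s2", 0.020, 0.080),
            result("b1", 0.002, 0.004),
            result("b2", 0.004, 0.008),
            result("t1", 0.001, 0.002),
            result("s3", 0.010, 0.040),
            result("b3", 0.001, 0.001),
        ]
        return results, occasions

    def test_subtracts_per_surface_field_blank_mean(self):
        results, occasions = self.setup_campaign()
        corrected, stats = q.blank_correct(results, occasions)
        by_id = {r.occasion_id: r for r in corrected}
        # PC blank means: pm2.5 = 0.003, pm10 = 0.006
        assert by_id["s1"].pm25_mg_m3 == pytest.approx(0.007)
        assert by_id["s1"].pm10_mg_m3 == pytest.approx(0.044)
        # CT blank mean subtracted from CT only
        assert by_id["s3"].pm25_mg_m3 == pytest.approx(0.009)
        assert all(r.blank_corrected for r in corrected)

    def test_negative_values_retained(self):
        occasions = [occasion("s", "PC"), occasion("b", "PC", role="field_blank")]
        results = [result("s", 0.010, 0.010), result("b", 0.012, 0.005)]
        corrected, _ = q.blank_correct(results, occasions)
        by_id = {r.occasion_id: r for r in corrected}
        assert by_id["s"].pm25_mg_m3 == pytest.approx(-0.002)

    def test_corrected_blanks_average_zero(self):
        results, occasions = self.setup_campaign()
        corrected, _ = q.blank_correct(results, occasions)
        occ = {o.occasion_id: o for o in occasions}
        for surface in ("PC", "CT"):
            blanks = [
                r for r in corrected
                if occ[r.occasion_id].surface == surface and occ[r.occasion_id].role == "field_blank"
            ]
            assert abs(np.mean([r.pm25_mg_m3 for r in blanks])) < 1e-15
            assert abs(np.mean([r.pm10_mg_m3 for r in blanks])) < 1e-15

    def test_all_zero_blanks_leave_results_unchanged(self):
        occasions = [occasion("s", "PC"), occasion("b", "PC", role="field_blank")]
        results = [result("s", 0.010, 0.020), result("b", 0.0, 0.0)]
        corrected, _ = q.blank_correct(results, occasions)
        by_id = {r.occasion_id: r for r in corrected}
        assert by_id["s"].pm25_mg_m3 == 0.010
        assert by_id["s"].pm10_mg_m3 == 0.020

    def test_disabled_mode_passes_through_with_stats(self):
        results, occasions = self.setup_campaign()
        passed, stats = q.blank_correct(results, occasions, enabled=False)
        assert [r.pm25_mg_m3 for r in passed] == [r.pm25_mg_m3 for r in results]
        assert any(s.fraction == "pm2.5" and s.surface == "PC" for s in stats)

    def test_toggling_shifts_by_exactly_blank_mean(self):
        results, occasions = self.setup_campaign()
        corrected, _ = q.blank_correct(results, occasions)
        uncorrected, _ = q.blank_correct(results, occasions, enabled=False)
        occ = {o.occasion_id: o for o in occasions}
        blank_mean_pc = np.mean([0.002, 0.004])
        for c, u in zip(corrected, uncorrected):
            if occ[c.occasion_id].surface == "PC":
                assert u.pm25_mg_m3 - c.pm25_mg_m3 == pytest.approx(blank_mean_pc, abs=1e-15)

    def test_missing_field_blank_rejected(self):
        occasions = [occasion("s", "PC")]
        results = [result("s", 0.01, 0.02)]
        with pytest.raises(ValueError, match="no field blank"):
            q.blank_correct(results, occasions)

    def test_transport_blanks_never_subtracted(self):
        """Transport blanks appear in the statistics but do not move the
        correction."""
        occasions = [
            occasion("s", "PC"),
            occasion("b", "PC", role="field_blank"),
            occasion("t", "PC", role="transport_blank"),
        ]
        results = [result("s", 0.010, 0.020), result("b", 0.002, 0.002), result("t", 0.5, 0.5)]
        corrected, stats = q.blank_correct(results, occasions)
        by_id = {r.occasion_id: r for r in corrected}
        assert by_id["s"].pm25_mg_m3 == pytest.approx(0.008)
        assert any("transport_blank" in s.fraction for s in stats)


class TestTimeWeightedMean:
    def test_single_occasion_identity(self):
        occ = [occasion("a", hours=7.0)]
        res = [result("a", 0.5, 1.5)]
        tw = q.time_weighted_mean(res, occ)
        assert tw["pm2.5"] == 0.5
        assert tw["pm10"] == 1.5

    def test_duration_weighting(self):
        occ = [occasion("a", hours=8.0), occasion("b", hours=16.0)]
        res = [result("a", 1.0, 1.0), result("b", 3.0, 3.0)]
        tw = q.time_weighted_mean(res, occ)
        assert tw["pm2.5"] == pytest.approx(7.0 / 3.0, rel=1e-12)

    def test_split_invariance(self):
        whole = q.time_weighted_mean(
            [result("a", 2.0, 2.0), result("b", 5.0, 5.0)],
            [occasion("a", hours=10.0), occasion("b", hours=10.0)],
        )
        split = q.time_weighted_mean(
            [result("a1", 2.0, 2.0), result("a2", 2.0, 2.0), result("b", 5.0, 5.0)],
            [occasion("a1", hours=4.0), occasion("a2", hours=6.0), occasion("b", hours=10.0)],
        )
        assert split["pm10"] == pytest.approx(whole["pm10"], rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q.time_weighted_mean([], [])


class TestRatio:
    def test_equal_means_100(self):
        assert q.sampler_vs_reference_ratio(0.07, 0.07) == pytest.approx(100.0)

    def test_half_is_50(self):
        assert q.sampler_vs_reference_ratio(0.05, 0.10) == pytest.approx(50.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            q.sampler_vs_reference_ratio(0.05, 0.0)


class TestOccasionModel:
    def test_duration_from_timestamps(self):
        from datetime import datetime

        occ = q.SamplingOccasion(
            occasion_id="x", location="mine", surface="CT",
            start=datetime(2016, 5, 10, 8, 0), end=datetime(2016, 5, 10, 20, 30),
        )
        assert occ.duration_h == pytest.approx(12.5)

    def test_end_before_start_rejected(self):
        from datetime import datetime

        with pytest.raises(ValueError):
            q.SamplingOccasion(
                occasion_id="x", location="mine", surface="CT",
                start=datetime(2016, 5, 10, 8, 0), end=datetime(2016, 5, 10, 7, 0),
            )
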