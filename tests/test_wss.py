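"""WSS indices: analytic oracles, thresholds, area-weighted summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulsewss as pw
from pulsewss.synthetic import SyntheticWSSSpec, make_random_wss_field
from pulsewss.wss import IndexMaps


def field_from(m, a, phi=0.0, mode="aligned", n_times=200):
    m = np.atleast_1d(np.asarray(m, float))
    spec = SyntheticWSSSpec(n_elements=m.size, steady_magnitudes=m,
                            oscillation_amplitudes=a, phase_offsets=phi,
                            direction_mode=mode)
    times = np.arange(n_times) / n_times
    return pw.make_wss_field(spec, times=times)


class TestTawssOsi:
    def test_constant_field(self):
        f = field_from(m=[0.5], a=[0.0])
        assert pw.tawss(f) == pytest.approx(0.5)
        assert pw.osi(f) == pytest.approx(0.0)

    def test_pure_sinusoid_oracles(self):
        # analytic: mean |sin| = 2/pi, zero mean vector -> OSI = 1/2
        f = field_from(m=[0.0], a=[1.0])
        assert pw.tawss(f) == pytest.approx(2.0 / np.pi, rel=1e-3)
        assert pw.osi(f) == pytest.approx(0.5, abs=1e-12)

    def test_offset_sinusoid_stays_unidirectional(self):
        # |2 + sin| = 2 + sin: TAWSS = 2, OSI = 0
        f = field_from(m=[2.0], a=[1.0])
        assert pw.tawss(f) == pytest.approx(2.0, rel=1e-12)
        assert pw.osi(f) == pytest.approx(0.0, abs=1e-12)

    def test_zero_field_is_flagged_undefined(self):
        f = field_from(m=[0.0], a=[0.0])
        assert pw.tawss(f) == 0.0
        assert np.isnan(pw.osi(f))[0]

    def test_generator_ground_truth_recovered(self):
        spec = SyntheticWSSSpec(n_elements=50, seed=7)
        f = pw.make_wss_field(spec)
        maps = pw.compute_maps(f)
        known = ~np.isnan(f.expected["tawss"])
        assert known.any()
        assert np.allclose(maps.tawss[known], f.expected["tawss"][known],
                           rtol=1e-3)
        assert np.allclose(maps.osi[known], f.expected["osi"][known],
                           atol=1e-9)


class TestRrt:
    @pytest.mark.parametrize("t,o,expected", [
        (0.5, 0.0, 2.0),
        (1.0, 0.25, 2.0),
    ])
    def test_reciprocal_identity(self, t, o, expected):
        assert pw.rrt(np.array([t]), np.array([o]))[0] == pytest.approx(
            expected)

    def test_infinite_flag_at_half_osi(self):
        assert np.isinf(pw.rrt(np.array([1.0]), np.array([0.5])))[0]

    def test_undefined_flag_at_zero_tawss(self):
        assert np.isnan(pw.rrt(np.array([0.0]), np.array([0.1])))[0]


class TestProperties:
    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_osi_bounded_on_random_fields(self, seed):
        f = make_random_wss_field(n_elements=20, n_times=32, seed=seed)
        o = pw.osi(f)
        assert np.all((o >= 0.0) & (o <= 0.5))

    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(0, 1000))
    def test_scaling_covariance(self, c, seed):
        f = make_random_wss_field(n_elements=10, n_times=32, seed=seed)
        scaled = pw.SurfaceWSSField(element_ids=f.element_ids,
                                    areas=f.areas, times=f.times,
                                    wss=c * f.wss, period=f.period)
        m1, m2 = pw.compute_maps(f), pw.compute_maps(scaled)
        assert np.allclose(m2.tawss, c * m1.tawss, rtol=1e-10)
        assert np.allclose(m2.osi, m1.osi, atol=1e-10)
        assert np.allclose(m2.rrt, m1.rrt / c, rtol=1e-8)

    def test_time_refinement_changes_band_limited_indices_little(self):
        coarse = field_from(m=[0.4, 0.0, 1.3], a=[0.2, 0.7, 1.0],
                            phi=0.8, n_times=200)
        fine = field_from(m=[0.4, 0.0, 1.3], a=[0.2, 0.7, 1.0],
                          phi=0.8, n_times=400)
        mc, mf = pw.compute_maps(coarse), pw.compute_maps(fine)
        assert np.allclose(mc.tawss, mf.tawss, rtol=1e-3)
        assert np.allclose(mc.osi, mf.osi, atol=1e-3)
        stable = mc.osi < 0.49  # RRT diverges at OSI = 1/2
        assert np.allclose(mc.rrt[stable], mf.rrt[stable], rtol=1e-3)


class TestThresholdsAndSummary:
    def test_all_low_tawss_is_full_area(self):
        maps = IndexMaps(tawss=np.full(4, 0.3), osi=np.zeros(4),
                         rrt=np.full(4, 1.0))
        p_t, p_o, p_r = pw.threshold_percentages(maps, np.ones(4))
        assert (p_t, p_o, p_r) == (100.0, 0.0, 0.0)

    def test_half_area_high_osi(self):
        maps = IndexMaps(tawss=np.ones(2), osi=np.array([0.4, 0.1]),
                         rrt=np.ones(2))
        _, p_o, _ = pw.threshold_percentages(maps, np.array([1.0, 1.0]))
        assert p_o == 50.0

    def test_infinite_rrt_counts_as_high(self):
        maps = IndexMaps(tawss=np.ones(2), osi=np.array([0.5, 0.0]),
                         rrt=np.array([np.inf, 1.0]))
        _, _, p_r = pw.threshold_percentages(maps, np.array([3.0, 1.0]))
        assert p_r == 75.0

    def test_planted_area_fractions_recovered_exactly(self):
        # 30% of area below the TAWSS threshold by construction
        m = np.where(np.arange(10) < 3, 0.2, 1.0)
        f = field_from(m=m, a=np.zeros(10))
        maps = pw.compute_maps(f)
        p_t, _, _ = pw.threshold_percentages(maps, f.areas)
        assert p_t == pytest.approx(30.0)

    def test_area_weighted_average(self):
        maps = IndexMaps(tawss=np.array([0.0, 1.0]), osi=np.zeros(2),
                         rrt=np.ones(2))
        s = pw.summarize(maps, np.array([1.0, 3.0]))
        assert s.tawss_ave == pytest.approx(0.75)
        assert (s.tawss_min, s.tawss_max) == (0.0, 1.0)

    def test_uniform_map_collapses(self):
        maps = IndexMaps(tawss=np.full(5, 0.7), osi=np.full(5, 0.1),
                         rrt=np.full(5, 1.0 / (0.8 * 0.7)))
        s = pw.summarize(maps, np.ones(5))
        assert s.tawss_ave == s.tawss_min == s.tawss_max == 0.7

    def test_summary_against_brute_force_loop(self, rng):
        n = 100
        f = make_random_wss_field(n_elements=n, n_times=32, seed=3)
        maps = pw.compute_maps(f)
        s = pw.summarize(maps, f.areas)
        # independent oracle: explicit loops
        num = den = 0.0
        for i in range(n):
            num += f.areas[i] * maps.tawss[i]
            den += f.areas[i]
        assert s.tawss_ave == pytest.approx(num / den, rel=1e-12)
        assert s.tawss_min == min(maps.tawss)
        assert s.osi_max == max(maps.osi)

    def test_unweighted_mode(self):
        maps = IndexMaps(tawss=np.array([0.0, 1.0]), osi=np.zeros(2),
                         rrt=np.ones(2))
        s = pw.summarize(maps, np.array([1.0, 3.0]), area_weighted=False)
        assert s.tawss_ave == pytest.approx(0.5)

    def test_mismatched_lengths_rejected(self):
        maps = IndexMaps(tawss=np.ones(3), osi=np.zeros(3), rrt=np.ones(3))
        with pytest.raises(ValueError, match="matching lengths"):
            pw.summarize(maps, np.ones(4))
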