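"""Top-fraction masks, %CBV arithmetic, and region x time inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusimap.containers import RegionMask, SaliencyMap
from fusimap.region_stats import (
    dice,
    percent_change_series,
    region_time_anova,
    sensitivity_sweep,
    threshold_top_fraction,
)
from fusimap.containers import CBVSeries

from conftest import series_from_frames


class TestThreshold:
    def test_exact_count_on_91x128(self):
        rng = np.random.default_rng(0)
        m = SaliencyMap("drug", rng.random((91, 128)), "cam")
        mask = threshold_top_fraction(m, 0.15)
        assert mask.n_true == 1747  # round(0.15 * 11648)

    def test_order_statistics_oracle(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        mask = threshold_top_fraction(SaliencyMap("drug", vals, "cam"), 0.5)
        assert set(vals[mask.mask]) == set(range(51, 101))

    def test_indicator_fixed_point(self):
        rng = np.random.default_rng(1)
        base = threshold_top_fraction(SaliencyMap("drug", rng.random((20, 20)), "cam"), 0.2)
        again = threshold_top_fraction(
            SaliencyMap("drug", base.mask.astype(float), "cam"), 0.2
        )
        assert np.array_equal(base.mask, again.mask)

    def test_constant_map_selects_first_k_indices(self):
        mask = threshold_top_fraction(SaliencyMap("drug", np.ones((4, 5)), "cam"), 0.25)
        expected = np.zeros(20, dtype=bool)
        expected[:5] = True
        assert np.array_equal(mask.mask.ravel(), expected)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nesting_of_fractions(self, seed):
        rng = np.random.default_rng(seed)
        m = SaliencyMap("drug", rng.random((12, 14)), "cam")
        small = threshold_top_fraction(m, 0.1).mask
        big = threshold_top_fraction(m, 0.3).mask
        assert np.all(big[small])  # mask(f1) subset of mask(f2) for f1 < f2


class TestPercentChange:
    def _mask(self, shape=(6, 8)):
        m = np.zeros(shape, dtype=bool)
        m[:3, :4] = True
        return RegionMask(mask=m, fraction=0.25)

    def test_constant_series_zero_everywhere(self):
        s = series_from_frames(np.full((30, 6, 8), 4.0), injection=20, baseline=(10, 20))
        cbv = percent_change_series(s, self._mask())
        assert np.allclose(cbv.in_region, 0)
        assert np.allclose(cbv.out_region, 0)

    def test_thirteen_percent_drop(self):
        frames = np.full((30, 6, 8), 100.0)
        frames[-1][:3, :4] = 87.0
        s = series_from_frames(frames, injection=20, baseline=(10, 20))
        cbv = percent_change_series(s, self._mask())
        assert cbv.in_region[-1] == pytest.approx(-13.0)
        assert cbv.out_region[-1] == pytest.approx(0.0)

    def test_baseline_mean_is_zero_by_construction(self):
        rng = np.random.default_rng(0)
        s = series_from_frames(rng.random((40, 6, 8)) + 1, injection=30, baseline=(20, 30))
        cbv = percent_change_series(s, self._mask())
        assert abs(cbv.in_region[20:30].mean()) < 1e-9
        assert abs(cbv.out_region[20:30].mean()) < 1e-9

    def test_uniform_frames_make_in_equal_out(self):
        t = np.linspace(1, 2, 30)
        frames = np.tile(t[:, None, None], (1, 6, 8))
        s = series_from_frames(frames, injection=20, baseline=(10, 20))
        cbv = percent_change_series(s, self._mask())
        assert np.allclose(cbv.in_region, cbv.out_region)

    def test_area_weighted_combination_recovers_whole_image(self):
        rng = np.random.default_rng(1)
        frames = rng.random((40, 6, 8)) + 1
        s = series_from_frames(frames, injection=30, baseline=(20, 30))
        mask = self._mask()
        cbv = percent_change_series(s, mask)
        f = mask.mask.mean()
        start, end = 20, 30
        m_in = frames.reshape(40, -1)[:, mask.mask.ravel()].mean(axis=1)
        m_out = frames.reshape(40, -1)[:, ~mask.mask.ravel()].mean(axis=1)
        b_in, b_out = m_in[start:end].mean(), m_out[start:end].mean()
        whole = frames.mean(axis=(1, 2))
        b_whole = whole[start:end].mean()
        whole_pct = 100 * (whole - b_whole) / b_whole
        combined = 100 * (
            (f * b_in * (1 + cbv.in_region / 100) + (1 - f) * b_out * (1 + cbv.out_region / 100))
            - b_whole
        ) / b_whole
        assert np.allclose(combined, whole_pct, atol=1e-9)

    def test_zero_baseline_rejected(self):
        frames = np.zeros((30, 6, 8))
        frames[25:] = 1.0
        s = series_from_frames(frames, injection=20, baseline=(10, 20))
        with pytest.raises(ValueError):
            percent_change_series(s, self._mask())


def _cbv(in_arr, out_arr, aid="a", group="drug"):
    return CBVSeries(
        animal_id=aid,
        in_region=np.asarray(in_arr, dtype=float),
        out_region=np.asarray(out_arr, dtype=float),
        baseline_window=(0, 60),
        group=group,
    )


class TestRegionAnova:
    def test_exact_null_in_equals_out(self):
        rng = np.random.default_rng(0)
        cbvs = []
        for i in range(5):
            x = np.repeat(rng.normal(0, 1, 6), 60)
            cbvs.append(_cbv(x, x, aid=f"a{i}"))
        res = region_time_anova(cbvs, window_frames=60, start=0)
        assert res["region"]["p"] == pytest.approx(1.0)
        assert res["region:time"]["p"] == pytest.approx(1.0)

    def test_planted_divergence_detected(self):
        """A -15% in-region ramp against flat out-region at n = 10 animals."""
        rng = np.random.default_rng(1)
        t = np.linspace(0, -15, 360)
        cbvs = []
        for i in range(10):
            noise = rng.normal(0, 1.0, 360)
            cbvs.append(_cbv(t + noise, rng.normal(0, 1.0, 360), aid=f"a{i}"))
        res = region_time_anova(cbvs, window_frames=60, start=0)
        assert res["region:time"]["p"] < 0.001

    def test_type_i_error_calibrated(self):
        """Null in/out series -> interaction rejected in ~5% of 500 replicates."""
        rng = np.random.default_rng(7)
        from fusimap.stats import rm_anova_two_way

        y = rng.normal(0, 1, (500, 6, 2, 8))  # (rep, animal, region, time-bin)
        res = rm_anova_two_way(y)
        rate = float(np.mean(res["A:B"]["p"] < 0.05))
        assert 0.03 <= rate <= 0.07

    def test_too_few_animals_rejected(self):
        cbvs = [_cbv(np.zeros(120), np.zeros(120), aid=f"a{i}") for i in range(2)]
        with pytest.raises(ValueError):
            region_time_anova(cbvs, window_frames=60, start=0)


class TestSensitivitySweep:
    def _setup(self):
        rng = np.random.default_rng(3)
        grid = rng.random((10, 12))
        m = SaliencyMap("drug", grid, "cam")
        frames = rng.random((120, 10, 12)) + 1
        s = series_from_frames(frames, injection=60, baseline=(40, 60))
        return m, [s]

    def test_single_fraction_matches_direct_pipeline(self):
        m, cohort = self._setup()
        sweep = sensitivity_sweep(m, cohort, [0.15], window_frames=30)
        direct_mask = threshold_top_fraction(m, 0.15)
        assert np.array_equal(sweep[0]["mask"].mask, direct_mask.mask)
        direct = percent_change_series(cohort[0], direct_mask)
        assert sweep[0]["final_in_pct"] == pytest.approx(direct.in_region[-30:].mean())

    def test_masks_nest_across_fractions(self):
        m, cohort = self._setup()
        sweep = sensitivity_sweep(m, cohort, [0.1, 0.2, 0.4], window_frames=30)
        for lo, hi in zip(sweep, sweep[1:]):
            assert np.all(hi["mask"].mask[lo["mask"].mask])


class TestDice:
    def test_identical_masks_give_one(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.zeros((5, 5), dtype=bool)
        a[0, 0] = True
        b[4, 4] = True
        assert dice(a, b) == 0.0
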