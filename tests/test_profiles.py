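"""Profile primitives against brute-force oracles and closed-form positions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import brentq

from hhquant import (
    CH_CI,
    CH_PTC,
    APProfile,
    NoResponseError,
    align_profiles,
    extract_profile,
    find_landmarks,
    normalize_profile,
    smooth,
)
from hhquant.simulate import GENOTYPES, SimParams, hill, simulate_disc_set, simulate_profile


def brute_force_smooth(values, window):
    """Independent windowed mean with shrinking edges (double loop)."""
    w = (window - 1) // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - w), min(len(values), i + w + 1)
        out[i] = sum(values[lo:hi]) / (hi - lo)
    return out


class TestExtract:
    def test_constant_image(self):
        img = np.full((10, 20), 7.0)
        prof = extract_profile(img, (2, 1, 15, 8))
        assert np.array_equal(prof.channels[CH_CI], np.full(15, 7.0))

    def test_two_row_column_means(self):
        img = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]])
        prof = extract_profile(img, (0, 0, 3, 2))
        assert np.array_equal(prof.channels[CH_CI], [2.0, 3.0, 4.0])

    def test_matches_per_column_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            img = rng.random((rng.integers(5, 60), rng.integers(5, 60)))
            ny, nx = img.shape
            w = int(rng.integers(2, nx + 1))
            h = int(rng.integers(1, ny + 1))
            x0 = int(rng.integers(0, nx - w + 1))
            y0 = int(rng.integers(0, ny - h + 1))
            prof = extract_profile(img, (x0, y0, w, h))
            oracle = [sum(img[y0 + r, x0 + c] for r in range(h)) / h for c in range(w)]
            assert np.allclose(prof.channels[CH_CI], oracle)

    def test_roi_bounds_and_empty(self):
        img = np.zeros((5, 5))
        with pytest.raises(IndexError):
            extract_profile(img, (3, 3, 4, 2))
        with pytest.raises(ValueError):
            extract_profile(img, (0, 0, 0, 2))


class TestSmooth:
    def test_single_spike_window5(self):
        out = smooth(np.array([0, 0, 0, 5, 0, 0, 0], dtype=float), 5)
        assert out[3] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_arrays(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(3, 120))
            vals = rng.normal(size=n)
            window = int(rng.choice([w for w in (1, 3, 5, 7, 9) if w <= n]))
            assert np.allclose(smooth(vals, window), brute_force_smooth(vals, window))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, st.integers(5, 80), elements=st.floats(-1e3, 1e3)),
        st.sampled_from([1, 3, 5]),
    )
    def test_bounded_by_extrema_and_constant_fixed(self, vals, window):
        out = smooth(vals, window)
        assert out.min() >= vals.min() - 1e-9 and out.max() <= vals.max() + 1e-9
        const = smooth(np.full(11, vals[0]), window)
        assert np.allclose(const, vals[0])

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            smooth(np.zeros(10), window)


class TestLandmarks:
    @staticmethod
    def ramp_profile():
        x = np.arange(9.0)
        y = np.where(x <= 4, 1.0, 1.0 + (x - 4) * 2.0)  # 1 flat, then ramp to 9 at x=8
        return APProfile("ramp", "t", x, {CH_PTC: y})

    def test_half_rise_on_linear_ramp(self):
        lm = find_landmarks(self.ramp_profile(), baseline_window=(0, 3))
        assert lm.x_half == 6.0
        assert lm.x_peak == 8.0
        assert lm.baseline == 1.0

    def test_flat_profile_raises_no_response(self):
        prof = APProfile("flat", "t", np.arange(20.0), {CH_PTC: np.ones(20)})
        with pytest.raises(NoResponseError):
            find_landmarks(prof, baseline_window=(0, 4))

    def test_ordering_invariant_on_simulated_discs(self):
        p = SimParams(noise_sd_frac=0.05, offset_sd=0, scale_sd_frac=0, seed=2)
        for d in simulate_disc_set(p, GENOTYPES["WT"], 10):
            sm = APProfile(d.disc_id, d.genotype, d.x, {CH_PTC: smooth(d.channels[CH_PTC], 5)})
            lm = find_landmarks(sm)
            assert lm.x_rise <= lm.x_half <= lm.x_peak

    def test_half_rise_matches_hill_inversion(self, clean_params):
        """Closed-form check: the 50%-rise position of the noise-free reporter
        is where Hill pathway activity crosses half of its baseline-to-peak span."""
        prof = simulate_profile(clean_params, GENOTYPES["WT"])
        lm = find_landmarks(prof, baseline_window=(-150, -110))
        K, n = clean_params.hill_act
        sel = (prof.x >= -150) & (prof.x <= -110)
        a_base = (prof.channels[CH_PTC][sel].mean() - clean_params.ptc_base) / clean_params.ptc_gain
        a_peak = hill(1.0, K, n)
        a_half = a_base + 0.5 * (a_peak - a_base)

        def f(x):
            return hill(np.exp(x / clean_params.lambda_hh), K, n) - a_half

        x_analytic = brentq(f, -150, 0)
        assert abs(lm.x_half - x_analytic) <= clean_params.grid_step


class TestAlign:
    @staticmethod
    def toy_profiles(shift_steps=0):
        x = np.arange(60.0)
        ptc = np.exp(-0.5 * ((x - 40) / 5) ** 2) * 10 + 1
        ci = np.linspace(5, 8, 60)
        base = APProfile("d0", "t", x, {CH_PTC: ptc, CH_CI: ci})
        shifted = APProfile("d1", "t", x + shift_steps, {CH_PTC: ptc, CH_CI: ci})
        return base, shifted

    def test_preshifted_copy_aligns_to_same_mean(self):
        base, shifted = self.toy_profiles(shift_steps=3)
        aligned = align_profiles([base, shifted], landmark_smooth_window=None, min_discs=2)
        overlap = aligned.n == 2
        for ch in (CH_PTC, CH_CI):
            stack = np.vstack([aligned.per_disc[d][ch] for d in ("d0", "d1")])
            assert np.nanmax(np.abs(stack[:, overlap] - aligned.mean[ch][overlap])) < 1e-9
        # reference landmark maps to grid 0
        peak_idx = np.nanargmax(aligned.mean[CH_PTC])
        assert abs(aligned.grid[peak_idx]) <= aligned.step

    def test_single_profile_mean_is_profile_and_sem_flagged(self):
        base, _ = self.toy_profiles()
        aligned = align_profiles([base], landmark_smooth_window=None, min_discs=1)
        inside = aligned.n == 1
        interp = np.interp(aligned.grid[inside] + aligned.shifts["d0"], base.x, base.channels[CH_CI])
        assert np.allclose(aligned.mean[CH_CI][inside], interp)
        assert np.all(np.isnan(aligned.sem[CH_CI][inside]))

    def test_translation_equivariance(self):
        base, _ = self.toy_profiles()
        moved = APProfile("d0", "t", base.x + 17.0, base.channels)
        a1 = align_profiles([base], landmark_smooth_window=None, min_discs=1)
        a2 = align_profiles([moved], landmark_smooth_window=None, min_discs=1)
        assert np.array_equal(a1.grid, a2.grid)
        for ch in base.channels:
            assert np.allclose(a1.mean[ch], a2.mean[ch], equal_nan=True)

    def test_recovers_true_generator_offsets(self):
        p = SimParams(offset_sd=5.0, noise_sd_frac=0.0, scale_sd_frac=0.0, seed=9)
        discs = simulate_disc_set(p, GENOTYPES["WT"], 3)
        aligned = align_profiles(discs)
        ref0 = aligned.shifts[discs[0].disc_id] - discs[0].meta["true_offset"]
        for d in discs:
            recovered = aligned.shifts[d.disc_id] - ref0
            assert abs(recovered - d.meta["true_offset"]) <= p.grid_step

    def test_sem_matches_brute_force(self):
        rng = np.random.default_rng(3)
        p = SimParams(noise_sd_frac=0.1, offset_sd=0.0, scale_sd_frac=0.0)
        discs = simulate_disc_set(p, GENOTYPES["WT"], 4, rng=rng)
        aligned = align_profiles(discs)
        full = aligned.n == 4
        stack = np.vstack([aligned.per_disc[d.disc_id][CH_CI] for d in discs])[:, full]
        n = stack.shape[0]
        sd = np.sqrt(np.sum((stack - stack.mean(axis=0)) ** 2, axis=0) / (n - 1))
        assert np.allclose(aligned.sem[CH_CI][full], sd / np.sqrt(n))

    def test_unusable_profiles_excluded_then_error(self):
        flat = APProfile("flat", "t", np.arange(30.0), {CH_PTC: np.ones(30), CH_CI: np.ones(30)})
        base, _ = self.toy_profiles()
        aligned = align_profiles([base, flat], landmark_smooth_window=None, min_discs=1)
        assert list(aligned.per_disc) == ["d0"]
        with pytest.raises(ValueError, match="no profile"):
            align_profiles([flat], landmark_smooth_window=None, min_discs=1)


class TestNormalize:
    def test_max_mode(self):
        assert np.allclose(normalize_profile(np.array([2.0, 4.0, 8.0])), [0.25, 0.5, 1.0])

    def test_idempotent_and_scale_invariant(self):
        vals = np.array([0.25, 0.5, 1.0])
        assert np.array_equal(normalize_profile(vals), vals)
        rng = np.random.default_rng(1)
        raw = rng.random(50) + 0.1
        assert np.allclose(normalize_profile(3.7 * raw), normalize_profile(raw))

    def test_anterior_plateau_mode_and_errors(self):
        x = np.arange(10.0)
        vals = np.arange(10.0) + 1
        out = normalize_profile(vals, "anterior_plateau", x=x, anterior_window=(0, 3))
        assert np.allclose(out, vals / vals[:4].mean())
        with pytest.raises(ValueError):
            normalize_profile(np.array([-1.0, -2.0]))
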