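"""Structure factor, peak scaling, collapse and assortment statistics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from t6phase.core_io import make_rng
from t6phase.fixtures import labyrinth_scaled_series, make_pattern
from t6phase.spatial_stats import (
    assortment,
    assortment_profile,
    assortment_summary,
    coarsening_fit,
    collapse_curves,
    peak,
    structure_factor,
    structure_factor_2d,
)


def brute_force_assortment(img: np.ndarray, h: int, focal: int = 1) -> tuple[float, float]:
    """Direct sliding-window evaluation of the assortment statistic.

    Independent of the convolution implementation: loops over every
    trimmed-interior pixel of the focal strain and counts genotypes in its
    (2h+1)^2 window by hand.
    """
    H, W = img.shape
    out = []
    for strain in (focal, -focal):
        occ = img != 0
        f_g = np.count_nonzero(img == strain) / np.count_nonzero(occ)
        ps = []
        for i in range(h, H - h):
            for j in range(h, W - h):
                if img[i, j] != strain:
                    continue
                win = img[i - h : i + h + 1, j - h : j + h + 1]
                n_g = np.count_nonzero(win == strain) - 1
                n_occ = np.count_nonzero(win != 0) - 1
                if n_occ > 0:
                    ps.append(n_g / n_occ)
        out.append((np.mean(ps) - f_g) / (1 - f_g))
    return out[0], out[1]


class TestStructureFactor:
    def test_stripe_peak_at_fundamental(self):
        """argmax is bin-exact at q = 2*pi/period; the full-band moment sits
        between the fundamental and the 1-D power-spectrum moment (a closed
        bound: odd square-wave harmonics pull the moment up, while the
        radial annulus average down-weights them by the annulus mode count)."""
        period = 16
        img = make_pattern("stripes", size=256, period=period)
        curve = structure_factor(img)
        q0 = 2 * np.pi / period
        dq = curve.meta["dq"]
        q_arg, _ = peak(curve, estimator="argmax")
        assert abs(q_arg - q0) <= dq / 2
        # 1-D oracle: the unbinned spectral moment is an upper bound for the
        # radially averaged one, the fundamental a lower bound
        wave = img[0].astype(float)
        power = np.abs(np.fft.fft(wave - wave.mean())) ** 2
        k = np.fft.fftfreq(wave.size) * 2 * np.pi
        keep = k > 0
        moment_1d = np.sum(np.abs(k[keep]) * power[keep]) / np.sum(power[keep])
        assert q0 - dq / 2 < curve.q_m < moment_1d

    def test_random_image_flat_spectrum(self):
        slopes = []
        from scipy import stats as sps

        for seed in range(10):
            img = make_pattern("random", size=256, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                curve = structure_factor(img)
            slopes.append(sps.linregress(np.log(curve.q), np.log(curve.S)).slope)
            assert curve.flat
        assert abs(np.mean(slopes)) < 0.1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="no fluctuations"):
            structure_factor(np.ones((64, 64)))

    def test_parseval_identity(self):
        img = make_pattern("labyrinth", size=64, seed=2).astype(float)
        s2d = structure_factor_2d(img)
        assert s2d[0, 0] == 0.0
        np.testing.assert_allclose(
            s2d.sum(), ((img - img.mean()) ** 2).sum(), rtol=1e-12
        )

    def test_rotation_and_translation_invariance(self):
        img = make_pattern("labyrinth", size=64, seed=5)
        base = structure_factor(img)
        for variant in (np.rot90(img), np.roll(img, 13, axis=0), np.roll(img, -7, axis=1)):
            other = structure_factor(variant)
            np.testing.assert_allclose(other.S, base.S, rtol=1e-10)

    def test_coarsening_run_gains_low_q_weight(self, ibm_coarsening_runs):
        grids = ibm_coarsening_runs[1]
        early = structure_factor(grids[50])
        late = structure_factor(grids[3200])
        low = early.q < 0.2
        assert late.S[low].sum() > 5 * early.S[low].sum()
        assert late.q_m < early.q_m


class TestPeak:
    def test_two_equal_peaks_average(self):
        curve = structure_factor(make_pattern("stripes", 256, period=16))
        q = np.linspace(0.1, 1.0, 32)
        S = np.zeros_like(q)
        S[5] = S[20] = 7.0
        curve.q, curve.S = q, S
        q_m, _ = peak(curve)
        assert q_m == pytest.approx((q[5] + q[20]) / 2)

    def test_too_few_bins_rejected(self):
        curve = structure_factor(make_pattern("stripes", 256, period=16))
        curve.q, curve.S = curve.q[:4], curve.S[:4]
        with pytest.raises(ValueError):
            peak(curve)

    def test_flat_curve_flagged_with_values(self):
        with pytest.warns(RuntimeWarning, match="no characteristic scale"):
            curve = structure_factor(make_pattern("random", 256, seed=0))
        assert curve.flat
        assert np.isfinite(curve.q_m) and np.isfinite(curve.S_qm)


class TestCoarseningFit:
    def test_self_similar_fixture_recovers_minus_two(self):
        imgs, ts = labyrinth_scaled_series(size=240, scales=(1, 2, 3, 4, 5), seed=3)
        for estimator in ("moment", "argmax"):
            fit = coarsening_fit(imgs, ts, estimator=estimator)
            assert fit.slope_S_vs_qm == pytest.approx(-2.0, abs=0.3)

    def test_too_few_snapshots_rejected(self):
        imgs, ts = labyrinth_scaled_series(size=64, scales=(1, 2), seed=0)
        with pytest.raises(ValueError, match="at least 5"):
            coarsening_fit(imgs, ts)

    def test_qm_decreases_with_time(self, ising_coarsening_runs):
        spins = ising_coarsening_runs[1]
        sweeps = sorted(spins)
        fit = coarsening_fit([spins[s] for s in sweeps], [float(s) for s in sweeps])
        assert (np.diff(fit.table["q_m"]) < 0).all()
        assert fit.slope_qm_vs_t < 0


class TestCollapse:
    def test_duplicated_curve_scores_zero(self):
        c = structure_factor(make_pattern("labyrinth", 64, seed=1))
        _, score = collapse_curves([c, c])
        assert score == 0.0

    def test_rescaling_improves_overlap(self, ibm_coarsening_runs):
        grids = ibm_coarsening_runs[1]
        curves = [structure_factor(grids[s]) for s in (400, 800, 1600, 3200)]
        _, raw = collapse_curves(curves, rescale=False)
        _, rescaled = collapse_curves(curves, rescale=True)
        assert rescaled < raw

    def test_ibm_and_ising_share_master_curve(self, ibm_coarsening_runs, ising_coarsening_runs):
        """Mixed-model rescaled curves overlap: same coarsening process."""
        curves = [structure_factor(ibm_coarsening_runs[1][s]) for s in (800, 1600, 3200)]
        curves += [structure_factor(ising_coarsening_runs[1][s]) for s in (80, 160, 320)]
        table, rescaled = collapse_curves(curves)
        _, raw = collapse_curves(curves, rescale=False)
        assert rescaled < 0.5 * raw


class TestAssortment:
    def test_random_5050_image_near_zero(self):
        vals = []
        for seed in range(1, 11):
            img = make_pattern("random", size=500, seed=seed)
            for h in range(1, 6):
                vals.append(assortment(img, h)[0])
        assert abs(np.mean(vals)) < 0.01

    def test_half_split_matches_brute_force_exactly(self):
        img = make_pattern("halves", 8)
        r_g, r_c = assortment(img, 1)
        bf_g, bf_c = brute_force_assortment(img, 1)
        assert r_g == pytest.approx(bf_g, abs=1e-12)
        assert r_c == pytest.approx(bf_c, abs=1e-12)
        assert r_g > 0.5

    def test_checkerboard_anti_assorted(self):
        # odd-sized board: the two labels have unequal global frequency and
        # every window is locally balanced, forcing r below 0
        n = 33
        img = np.where((np.add.outer(np.arange(n), np.arange(n)) % 2) == 0, 1, -1)
        r_g, r_c = assortment(img, 1)
        bf_g, bf_c = brute_force_assortment(img, 1)
        assert r_g == pytest.approx(bf_g, abs=1e-12)
        assert r_g < 0
        # even-sized board is perfectly balanced: exactly zero
        even = make_pattern("checkerboard", 64)
        assert assortment(even, 1) == (0.0, 0.0)

    @pytest.mark.parametrize("h", [1, 2, 3, 4])
    def test_kernel_equals_brute_force_on_structured_images(self, h):
        for kind, seed in (("random", 3), ("labyrinth", 4), ("halves", 0)):
            img = make_pattern(kind, size=64, seed=seed)
            r = assortment(img, h)
            bf = brute_force_assortment(img, h)
            assert r == pytest.approx(bf, abs=1e-12)

    def test_kernel_equals_brute_force_with_empties(self):
        rng = make_rng(9, "empties")
        img = rng.choice([-1, 0, 1], size=(48, 48), p=[0.45, 0.1, 0.45])
        for h in (1, 3):
            assert assortment(img, h) == pytest.approx(
                brute_force_assortment(img, h), abs=1e-12
            )

    def test_single_strain_image_rejected(self):
        with pytest.raises(ValueError, match="assortment undefined"):
            assortment(np.ones((32, 32), dtype=int), 1)

    def test_radius_bounds_enforced(self):
        img = make_pattern("random", 64, seed=1)
        with pytest.raises(ValueError):
            assortment(img, 0)
        with pytest.raises(ValueError):
            assortment(img, 17)  # > 64/4

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        img=hnp.arrays(np.int8, (16, 16), elements=st.sampled_from([-1, 0, 1])),
        h=st.integers(1, 3),
    )
    def test_bounds_and_label_swap_invariance(self, img, h):
        try:
            r_g, r_c = assortment(img, h)
        except ValueError:
            return  # degenerate image (single strain / empty interior)
        assert -1 <= r_g <= 1 and -1 <= r_c <= 1
        # swapping labels and the focal role leaves the profile unchanged
        r_g2, r_c2 = assortment(-img, h, focal=-1)
        assert r_g2 == pytest.approx(r_g, abs=1e-12)
        assert r_c2 == pytest.approx(r_c, abs=1e-12)


class TestAssortmentProfiles:
    def test_coarsened_snapshot_high_then_decaying(self, ibm_coarsening_runs):
        prof = assortment_profile(ibm_coarsening_runs[1][3200], h_max=20)
        assert prof.r_g[0] > 0.5
        assert prof.r_g[0] > prof.r_g[9] > prof.r_g[19]

    def test_split_image_decreasing_in_h(self):
        img = make_pattern("halves", 64)
        prof = assortment_profile(img, h_max=4)
        assert (np.diff(prof.r_g) < 0).all()
        for i, h in enumerate(prof.h):
            bf_g, _ = brute_force_assortment(img, int(h))
            assert prof.r_g[i] == pytest.approx(bf_g, abs=1e-12)

    def test_random_profile_flat_near_zero(self):
        img = make_pattern("random", 256, seed=8)
        prof = assortment_profile(img, h_max=8)
        assert np.abs(prof.r_g).max() < 0.05

    def test_summary_confidence_band_contains_mean(self):
        imgs = [make_pattern("random", 128, seed=s) for s in range(4)]
        table = assortment_summary(imgs, h_max=3)
        assert ((table["ci_low"] <= table["r_g"]) & (table["r_g"] <= table["ci_high"])).all()
        assert list(table["h"]) == [1, 2, 3]
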