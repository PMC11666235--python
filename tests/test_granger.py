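"""Tests of blockwise Granger causality and the directed asymmetry index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from specdag.factorization import wilson_factorize
from specdag.granger import all_pairs_gc, blockwise_gc, compute_dai, parametric_gc_spectrum
from specdag.spectral import CrossSpectralDensity, EpochSet, multitaper_csd, segment
from specdag.synthetic import Edge, NetworkSpec, analytic_csd, simulate_mvar


def _white_csd(n_parcels, comps=1, fs=128.0, n=256):
    nc = n_parcels * comps
    freqs = np.fft.rfftfreq(n, 1 / fs)
    S = analytic_csd(np.zeros((1, nc, nc)), np.eye(nc), fs, freqs)
    cp = np.array([f"P{p}" for p in range(n_parcels) for _ in range(comps)])
    return CrossSpectralDensity(S=S, freqs=freqs, fs=fs, n_fft=n, n_tapers=1,
                                smoothing_hz=0.0, n_epochs_averaged=1, channel_parcel=cp)


class TestBlockwiseGC:
    def test_independent_white_blocks_have_no_gc(self, rng):
        es = EpochSet(data=rng.standard_normal((500, 2, 256)), fs=64.0,
                      channel_parcel=np.array(["A", "B"]))
        fac = wilson_factorize(multitaper_csd(es, 2.0))
        gab, gba = blockwise_gc(fac, [0], [1])
        assert np.median(gab) < 0.01 and np.median(gba) < 0.01

    def test_partition_must_cover_all_channels(self):
        fac = wilson_factorize(_white_csd(3))
        with pytest.raises(ValueError, match="partition"):
            blockwise_gc(fac, [0], [1])

    def test_block_gc_bounds_scalar_gc_of_driving_pair(self):
        # only component 0 of A drives component 1 of B: the 3+3 block measure
        # at the coupling peak is at least the scalar measure on that pair
        spec = NetworkSpec(
            n_parcels=2, components_per_parcel=3,
            edges=[Edge(0, 1, 0.3, 16.0, 8.0, source_comp=0, target_comp=1)],
            fs=128.0, trial_length_s=60.0, n_trials=15, seed=9,
        )
        es = simulate_mvar(spec)
        epochs = segment(es, 4.0, 0.5)
        csd = multitaper_csd(epochs, 2.0)
        fac6 = wilson_factorize(csd)
        g_block, _ = blockwise_gc(fac6, np.arange(3), np.arange(3, 6))
        sub = csd.select_channels(np.array([0, 4]))  # A comp0, B comp1
        fac2 = wilson_factorize(sub)
        g_scalar, _ = blockwise_gc(fac2, [0], [1])
        pk = int(np.nanargmax(g_scalar))
        assert g_block[pk] >= 0.9 * g_scalar[pk]

    def test_integrated_gc_matches_time_domain_geweke(self, unidir_var2):
        # mean of F(f) over the full band approximates the time-domain measure
        # ln(var of restricted residuals / var of full-model residuals)
        spec, epochs, csd = unidir_var2
        fac = wilson_factorize(csd)
        gxy, _ = blockwise_gc(fac, [0], [1])
        x = epochs.data  # (n_ep, 2, n)
        p = 2

        def residual_var(y_idx, predictors):
            Y, X = [], []
            for ep in range(x.shape[0]):
                d = x[ep]
                Y.append(d[y_idx, p:])
                X.append(
                    np.vstack([d[j, p - k - 1 : d.shape[1] - k - 1] for j in predictors for k in range(p)])
                )
            Y = np.concatenate(Y)
            X = np.concatenate(X, axis=1)
            beta, *_ = np.linalg.lstsq(X.T, Y, rcond=None)
            r = Y - X.T @ beta
            return r.var()

        f_time = np.log(residual_var(1, [1]) / residual_var(1, [0, 1]))
        f_int = np.nanmean(gxy)
        assert abs(f_int - f_time) / f_time < 0.10

    def test_source_mixing_invariance_at_peak(self, rng):
        # nonsingular mixing of the SOURCE block's components leaves block GC
        # unchanged (checked at the coupling peak, 15% tolerance)
        spec = NetworkSpec(
            n_parcels=2, components_per_parcel=2,
            edges=[Edge(0, 1, 0.25, 16.0, 8.0)],
            fs=128.0, trial_length_s=60.0, n_trials=10, seed=4,
        )
        es = simulate_mvar(spec)
        csd = multitaper_csd(segment(es, 4.0, 0.5), 2.0)
        fac = wilson_factorize(csd)
        g0, _ = blockwise_gc(fac, [0, 1], [2, 3])
        M = np.array([[1.0, 0.6], [-0.4, 0.8]])
        T = np.eye(4)
        T[:2, :2] = M
        from dataclasses import replace

        csd_m = replace(csd, S=T[None] @ csd.S @ T.T[None])
        g1, _ = blockwise_gc(wilson_factorize(csd_m), [0, 1], [2, 3])
        pk = int(np.nanargmax(g0))
        assert abs(g1[pk] - g0[pk]) / g0[pk] < 0.15


class TestDAI:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0.3, 0.1, 0.5), (0.2, 0.2, 0.0), (0.2, 0.0, 1.0), (0.0, 0.2, -1.0)],
    )
    def test_stated_formula(self, a, b, expected):
        dai = compute_dai(np.array([a]), np.array([b]))
        assert dai[0] == pytest.approx(expected, abs=1e-15)

    @given(
        gc=hnp.arrays(
            np.float64,
            st.integers(2, 40),
            elements=st.floats(0.0, 10.0, allow_nan=False),
        ),
        gc2=hnp.arrays(
            np.float64,
            st.integers(2, 40),
            elements=st.floats(0.0, 10.0, allow_nan=False),
        ),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_antisymmetry_and_range(self, gc, gc2):
        n = min(len(gc), len(gc2))
        a, b = gc[:n], gc2[:n]
        d1 = compute_dai(a, b)
        d2 = compute_dai(b, a)
        valid = ~np.isnan(d1)
        np.testing.assert_array_equal(valid, ~np.isnan(d2))
        np.testing.assert_array_equal(d1[valid], -d2[valid])  # exact antisymmetry
        assert np.all(np.abs(d1[valid]) <= 1.0 + 1e-15)

    def test_degenerate_bins_are_nan_not_zero(self):
        dai = compute_dai(np.array([0.0, 0.3]), np.array([0.0, 0.1]))
        assert np.isnan(dai[0]) and dai[1] == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            compute_dai(np.array([0.1]), np.array([0.1]),
                        freqs_ab=np.array([1.0]), freqs_ba=np.array([2.0]))


class TestAllPairs:
    def test_fourteen_parcels_give_91_pairs(self):
        gcs = all_pairs_gc(_white_csd(14), fmax=40.0)
        assert len(gcs.pairs) == 91
        assert gcs.gc_ab.shape == (91, np.sum(_white_csd(14).freqs <= 40.0))
        assert not gcs.failures

    def test_two_parcels_match_direct_call(self):
        spec = NetworkSpec(n_parcels=2, components_per_parcel=1,
                           edges=[Edge(0, 1, 0.3, 16.0, 8.0)],
                           fs=128.0, trial_length_s=30.0, n_trials=6, seed=2)
        csd = multitaper_csd(segment(simulate_mvar(spec), 4.0, 0.5), 2.0)
        gcs = all_pairs_gc(csd, fmax=64.0)
        fac = wilson_factorize(csd)
        gab, gba = blockwise_gc(fac, [0], [1])
        keep = csd.freqs <= 64.0
        np.testing.assert_allclose(gcs.gc_ab[0], gab[keep], atol=1e-12)
        np.testing.assert_allclose(gcs.gc_ba[0], gba[keep], atol=1e-12)

    def test_parametric_and_nonparametric_agree_on_analytic_input(self):
        # white CSD has zero GC both ways in both routes
        gcs = all_pairs_gc(_white_csd(2), fmax=60.0)
        assert np.nanmax(gcs.gc_ab) < 1e-6
        pxy, pyx = parametric_gc_spectrum(
            np.zeros((1, 2, 2)), np.eye(2), 128.0, gcs.freqs, [0], [1]
        )
        assert np.nanmax(pxy) < 1e-12 and np.nanmax(pyx) < 1e-12
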