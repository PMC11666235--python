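"""Tests of the MVAR network generator: stationarity, determinism, band
placement of directed edges, envelope injection, cohort plumbing."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from specdag.spectral import multitaper_csd, segment
from specdag.synthetic import (
    Edge,
    NetworkSpec,
    ParticipantCohort,
    StabilityError,
    analytic_csd,
    make_cohort,
    make_envelope_driven_parcel,
    simulate_mvar,
)


def _spec(**kw):
    defaults = dict(n_parcels=2, components_per_parcel=1, fs=128.0, trial_length_s=30.0,
                    n_trials=4, seed=7)
    defaults.update(kw)
    return NetworkSpec(**defaults)


class TestSimulate:
    def test_independent_parcels_are_uncorrelated(self):
        es = simulate_mvar(_spec(edges=[], components_per_parcel=2))
        x = es.data.reshape(es.n_trials, es.n_channels, -1)
        r = []
        for tr in range(es.n_trials):
            c = np.corrcoef(x[tr])
            r.append(np.abs(c[:2, 2:]).max())  # cross-parcel entries only
        assert max(r) < 0.1

    def test_zero_strength_edge_is_noop(self):
        a = simulate_mvar(_spec(edges=[]))
        b = simulate_mvar(_spec(edges=[Edge(0, 1, 0.0, 10.0, 8.0)]))
        np.testing.assert_array_equal(a.data, b.data)

    def test_same_seed_bit_identical(self):
        a = simulate_mvar(_spec())
        b = simulate_mvar(_spec())
        np.testing.assert_array_equal(a.data, b.data)

    def test_target_spectrum_peaks_where_analytic_spectrum_does(self):
        # oscillatory A->B coupling at 10 Hz: the target's empirical spectrum
        # must show the local maximum the closed-form VAR spectrum predicts
        spec = _spec(edges=[Edge(0, 1, 0.3, 10.0, 4.0)], fs=256.0, trial_length_s=60.0,
                     n_trials=8)
        es = simulate_mvar(spec)
        csd = multitaper_csd(segment(es, 4.0, 0.5), 2.0)
        San = analytic_csd(spec.coefficients(), np.eye(2), spec.fs, csd.freqs)
        f_pred = csd.freqs[np.argmax(San[:, 1, 1].real)]
        assert abs(f_pred - 10.0) <= spec.edges[0].bw_hz  # sanity: peak near 10 Hz
        band = (csd.freqs > 2) & (csd.freqs < 20)
        f_emp = csd.freqs[band][np.argmax(csd.S[band, 1, 1].real)]
        assert abs(f_emp - f_pred) <= 1.0

    def test_unstable_coefficients_raise_with_radius(self):
        spec = _spec(edges=[Edge(0, 1, 1.2, 10.0, 1.0), Edge(1, 0, 1.2, 10.0, 1.0)])
        with pytest.raises(StabilityError, match="spectral radius"):
            simulate_mvar(spec)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            _spec(edges=[Edge(0, 1, 0.2, 80.0, 4.0)], fs=128.0)

    def test_conflicting_source_resonances_rejected(self):
        spec = _spec(edges=[Edge(0, 1, 0.2, 10.0, 8.0), Edge(0, 1, 0.2, 40.0, 8.0)])
        with pytest.raises(ValueError, match="resonance"):
            spec.coefficients()

    def test_covariance_stationarity_split_half(self):
        # log-power distributions of two trial halves agree (KS, alpha=0.01)
        es = simulate_mvar(_spec(edges=[Edge(0, 1, 0.25, 10.0, 8.0)], n_trials=8))
        half = es.n_trials // 2
        from dataclasses import replace

        c1 = multitaper_csd(segment(replace(es, data=es.data[:half]), 4.0, 0.5), 2.0)
        c2 = multitaper_csd(segment(replace(es, data=es.data[half:]), 4.0, 0.5), 2.0)
        for ch in range(es.n_channels):
            stat = ks_2samp(np.log(c1.S[:, ch, ch].real), np.log(c2.S[:, ch, ch].real))
            assert stat.pvalue > 0.01

    @pytest.mark.parametrize("n_trials", [20, 80])
    def test_spectrum_converges_to_analytic(self, n_trials):
        # relative L2 error of the multitaper spectrum vs the closed form
        # decreases with the number of trials
        errs = {}
        for nt in (n_trials, n_trials * 4):
            spec = _spec(edges=[Edge(0, 1, 0.25, 10.0, 8.0)], trial_length_s=4.0,
                         n_trials=nt, seed=3)
            es = simulate_mvar(spec)
            csd = multitaper_csd(es, 2.0)
            San = analytic_csd(spec.coefficients(), np.eye(2), spec.fs, csd.freqs)
            # compare away from the taper-smoothed peak: use broad-band L2
            errs[nt] = np.linalg.norm(csd.S[:, 1, 1].real - San[:, 1, 1].real) / np.linalg.norm(
                San[:, 1, 1].real
            )
        assert errs[n_trials * 4] < errs[n_trials]


class TestEnvelope:
    def test_snr_zero_leaves_parcel_independent(self):
        spec = _spec(edges=[], fs=256.0, trial_length_s=20.0, n_trials=2)
        es, env = make_envelope_driven_parcel(spec, lag_ms=130.0, snr=0.0)
        r = [abs(np.corrcoef(es.data[t, 0], env[t])[0, 1]) for t in range(2)]
        assert max(r) < 0.1

    def test_injected_lag_recovered_by_cross_correlation(self):
        spec = _spec(edges=[], fs=256.0, trial_length_s=30.0, n_trials=2)
        es, env = make_envelope_driven_parcel(spec, lag_ms=130.0, snr=4.0)
        expected = round(0.130 * 256)  # 33 samples
        for t in range(2):
            e = env[t] - env[t].mean()
            x = es.data[t, 0] - es.data[t, 0].mean()
            lags = np.arange(0, 100)
            cc = [np.dot(x[l:], e[: len(e) - l]) for l in lags]
            assert abs(int(lags[np.argmax(cc)]) - expected) <= 1

    def test_zero_lag_peaks_at_zero(self):
        spec = _spec(edges=[], fs=256.0, trial_length_s=20.0, n_trials=1)
        es, env = make_envelope_driven_parcel(spec, lag_ms=0.0, snr=9.0)
        e = env[0] - env[0].mean()
        x = es.data[0, 0] - es.data[0, 0].mean()
        lags = np.arange(0, 50)
        cc = [np.dot(x[l:], e[: len(e) - l]) for l in lags]
        assert int(np.argmax(cc)) == 0

    def test_lag_beyond_trial_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            make_envelope_driven_parcel(_spec(trial_length_s=1.0), lag_ms=2000.0)


class TestCohort:
    def test_zero_jitter_gives_identical_coefficients(self):
        base = _spec(edges=[Edge(0, 1, 0.2, 10.0, 8.0)], n_trials=1, trial_length_s=5.0)
        coh = ParticipantCohort(base=base, n_participants=3, between_participant_sd=0.0, seed=1)
        data = make_cohort(coh)
        coefs = [data.specs[(i, "speaking")].coefficients() for i in range(3)]
        np.testing.assert_array_equal(coefs[0], coefs[1])
        np.testing.assert_array_equal(coefs[0], coefs[2])
        # identical generating process, but different innovation draws
        assert not np.array_equal(
            data.epochs[(0, "speaking")].data, data.epochs[(1, "speaking")].data
        )

    def test_truth_table_one_row_per_edge(self):
        base = _spec(edges=[Edge(0, 1, 0.2, 10.0, 8.0)], n_trials=1, trial_length_s=5.0)
        coh = ParticipantCohort(base=base, n_participants=2, seed=1)
        truth = make_cohort(coh).truth
        assert len(truth) == 1
        row = truth.iloc[0]
        assert (row["source"], row["target"]) == (0, 1)
        assert row["f_low"] == 2.0 and row["f_high"] == 18.0

    def test_persistently_unstable_jitter_raises(self):
        base = _spec(edges=[Edge(0, 1, 0.25, 10.0, 8.0), Edge(1, 0, 0.25, 40.0, 8.0)],
                     n_trials=1, trial_length_s=2.0)
        assert base.spectral_radius() < 1.0
        coh = ParticipantCohort(base=base, n_participants=2, between_participant_sd=10.0,
                                seed=0, max_retries=3)
        with pytest.raises(StabilityError, match="retries"):
            make_cohort(coh)

    def test_conditions_share_layout_differ_in_strength(self):
        base = _spec(edges=[Edge(0, 1, 0.3, 10.0, 8.0)], n_trials=1, trial_length_s=5.0)
        coh = ParticipantCohort(
            base=base,
            n_participants=2,
            between_participant_sd=0.0,
            conditions={
                "speaking": (Edge(0, 1, 0.3, 10.0, 8.0),),
                "listening": (Edge(0, 1, 0.1, 10.0, 8.0),),
            },
            seed=1,
        )
        data = make_cohort(coh)
        assert set(data.truth["condition"]) == {"speaking", "listening"}
        assert data.epochs[(0, "speaking")].n_channels == data.epochs[(0, "listening")].n_channels
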