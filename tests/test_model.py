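"""Core model: rate law, ODE right-hand side, simulation, analytic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polya_rhythms import (ModelParameters, RhythmicProcess, Variant,
                           extract_features, lti_oracle, rhs, simulate,
                           steady_state)
from polya_rhythms.features import Quantity
from polya_rhythms.model import OMEGA


def make_params(k=(1.0, 1.0, 1.0, 1.0), A=(0.0, 0.0, 0.0, 0.0),
                phi=(0.0, 0.0, 0.0, 0.0), variant=Variant.FULL):
    return ModelParameters(
        RhythmicProcess(k[0], A[0], phi[0]), RhythmicProcess(k[1], A[1], phi[1]),
        RhythmicProcess(k[2], A[2], phi[2]), RhythmicProcess(k[3], A[3], phi[3]),
        variant=variant)


class TestRateLaw:
    @pytest.mark.parametrize("k,A,phi,t,expected", [
        (1.0, 0.0, 5.0, 13.0, 1.0),    # A=0 gives a constant rate
        (2.0, 0.5, 6.0, 6.0, 3.0),     # peak value k(1+A) at t=phi
        (1.0, 0.5, 6.0, 12.0, 1.0),    # quarter period later: cos = 0
    ])
    def test_pointwise_values(self, k, A, phi, t, expected):
        assert RhythmicProcess(k, A, phi).rate_at(t) == pytest.approx(expected)

    @given(k=st.floats(0.01, 10.0), A=st.floats(0.0, 1.0),
           phi=st.floats(0.0, 23.999), t=st.floats(-100.0, 100.0))
    @settings(max_examples=100, derandomize=True)
    def test_nonnegative_periodic_peak(self, k, A, phi, t):
        p = RhythmicProcess(k, A, phi)
        assert p.rate_at(t) >= 0.0
        assert p.rate_at(t) == pytest.approx(p.rate_at(t + 24.0), rel=1e-9, abs=1e-12)
        assert p.rate_at(t) <= p.rate_at(phi) + 1e-12  # max at the peak phase

    @pytest.mark.parametrize("bad", [dict(mean_rate=-1.0),
                                     dict(mean_rate=1.0, relative_amplitude=1.5),
                                     dict(mean_rate=1.0, peak_phase=24.0)])
    def test_invalid_process_rejected(self, bad):
        with pytest.raises(ValueError):
            RhythmicProcess(**bad)


class TestRhs:
    def test_constant_rates_steady_state_is_stationary(self):
        p = make_params()
        assert rhs(p, 3.7, (2.0, 1.0)) == pytest.approx((0.0, 0.0))
        assert steady_state(p) == pytest.approx((2.0, 1.0))

    def test_empty_state_only_transcription_acts(self):
        assert rhs(make_params(), 0.0, (0.0, 0.0)) == pytest.approx((1.0, 0.0))

    def test_no_polya_variant_drops_reflux_term(self):
        p = make_params(variant=Variant.NO_POLYA)
        # dL = 1 - 1*1 + 0 = 0 ; dS = 1*1 - 0 - 1*1 = 0 (L=S=1 is the
        # no-polyadenylation steady state at unit rates)
        assert rhs(p, 0.0, (1.0, 1.0)) == pytest.approx((0.0, 0.0))
        # polyadenylation term really is dropped: compare against FULL
        full = rhs(make_params(), 0.0, (1.0, 2.0))
        no_pol = rhs(p, 0.0, (1.0, 2.0))
        assert full[0] - no_pol[0] == pytest.approx(2.0)   # +kappa_polyA*S
        assert no_pol[1] - full[1] == pytest.approx(2.0)   # -kappa_polyA*S

    def test_steady_state_closed_form(self):
        p = make_params(k=(2.0, 0.08, 0.4, 0.3))
        L, S = steady_state(p)
        assert S == pytest.approx(2.0 / 0.08)
        assert L == pytest.approx(2.0 * (0.3 + 0.08) / (0.4 * 0.08))


class TestSimulate:
    def test_constant_rates_converge_to_fixed_point(self):
        traj = simulate(make_params())
        win = traj.times >= 700.0
        assert np.allclose(traj.L[win], 2.0, rtol=1e-6)
        assert np.allclose(traj.S[win], 1.0, rtol=1e-6)

    def test_positivity_in_window(self):
        p = make_params(k=(1.0, 0.05, 0.3, 0.5), A=(0.9, 0.9, 0.9, 0.9),
                        phi=(1.0, 7.0, 13.0, 19.0))
        traj = simulate(p)
        win = traj.times >= 700.0
        assert traj.L[win].min() > 0 and traj.S[win].min() > 0

    def test_window_shift_by_one_period_gives_same_features(self):
        p = make_params(k=(1.0, 0.1, 0.3, 0.3), A=(0.5, 0.4, 0.8, 0.3),
                        phi=(2.0, 9.0, 15.0, 21.0))
        traj = simulate(p, t_end=772.0)
        from polya_rhythms.features import features_from_grid, GRID_REL
        for q in Quantity:
            f1 = extract_features(traj, q)
            series = {Quantity.TOTAL: traj.L + traj.S,
                      Quantity.RATIO: traj.L / traj.S,
                      Quantity.LONG: traj.L}[q]
            shifted = np.interp(724.0 + GRID_REL, traj.times, series)
            f2 = features_from_grid(shifted, q)
            assert f1.relative_amplitude == pytest.approx(f2.relative_amplitude,
                                                          rel=1e-3, abs=1e-6)
            assert f1.mean_level == pytest.approx(f2.mean_level, rel=1e-3)

    def test_transcription_scale_invariance(self):
        """Doubling k_trsc doubles L and S pointwise; phases/amplitudes fixed."""
        base = dict(A=(0.5, 0.3, 0.7, 0.2), phi=(3.0, 10.0, 17.0, 22.0))
        p1 = make_params(k=(1.0, 0.1, 0.4, 0.3), **base)
        p2 = make_params(k=(2.0, 0.1, 0.4, 0.3), **base)
        t1, t2 = simulate(p1), simulate(p2)
        win = t1.times >= 700.0
        assert np.allclose(2.0 * t1.L[win], t2.L[win], rtol=1e-6)
        assert np.allclose(2.0 * t1.S[win], t2.S[win], rtol=1e-6)
        for q in Quantity:
            f1, f2 = extract_features(t1, q), extract_features(t2, q)
            assert abs(f1.peak_phase - f2.peak_phase) < 1e-6
            assert f1.relative_amplitude == pytest.approx(f2.relative_amplitude,
                                                          abs=1e-6)
        scale = extract_features(t2, Quantity.LONG).mean_level \
            / extract_features(t1, Quantity.LONG).mean_level
        assert scale == pytest.approx(2.0, rel=1e-6)


class TestLtiOracle:
    def test_rejects_other_rhythmic_processes(self):
        with pytest.raises(ValueError):
            lti_oracle(make_params(A=(0.5, 0.1, 0.0, 0.0)))

    def test_zero_amplitude_gives_flat_outputs_at_fixed_point(self):
        feats = lti_oracle(make_params(k=(1.0, 0.2, 0.5, 0.3)))
        L, S = steady_state(make_params(k=(1.0, 0.2, 0.5, 0.3)))
        assert feats["L"][0] == pytest.approx(L)
        assert feats["S"][0] == pytest.approx(S)
        assert feats["L+S"][0] == pytest.approx(L + S)
        assert all(f[1] == 0.0 for f in feats.values())

    def test_mean_equals_fixed_point_regardless_of_drive_amplitude(self):
        k = (1.0, 0.15, 0.35, 0.25)
        ref = steady_state(make_params(k=k))
        for A_trsc in (0.2, 0.9):
            feats = lti_oracle(make_params(k=k, A=(A_trsc, 0, 0, 0), phi=(8, 0, 0, 0)))
            assert feats["L"][0] == pytest.approx(ref[0])
            assert feats["S"][0] == pytest.approx(ref[1])

    @pytest.mark.parametrize("k,A_trsc,phi_trsc", [
        ((1.0, 0.1, 0.3, 0.3), 0.5, 6.0),
        ((1.0, 0.05, 0.8, 0.2), 0.9, 20.0),
        ((1.0, 0.3, 0.2, 0.6), 0.4, 0.0),
    ])
    def test_simulation_matches_frequency_response(self, k, A_trsc, phi_trsc):
        """Simulated features agree with the closed-form LTI solution to <1%."""
        p = make_params(k=k, A=(A_trsc, 0, 0, 0), phi=(phi_trsc, 0, 0, 0))
        traj = simulate(p)
        oracle = lti_oracle(p)
        for q, key in ((Quantity.LONG, "L"), (Quantity.TOTAL, "L+S")):
            f = extract_features(traj, q)
            mean, amp, phase = oracle[key]
            assert f.mean_level == pytest.approx(mean, rel=0.01)
            assert f.relative_amplitude == pytest.approx(amp, rel=0.01)
            dphi = abs(f.peak_phase - phase)
            assert min(dphi, 24.0 - dphi) < 0.15

    def test_oracle_phase_lags_drive_for_slow_turnover(self):
        """Output abundance peaks after the transcription drive (causality)."""
        p = make_params(k=(1.0, 0.1, 0.4, 0.3), A=(0.5, 0, 0, 0), phi=(6.0, 0, 0, 0))
        _, _, phase = lti_oracle(p)["L+S"]
        lag = (phase - 6.0) % 24.0
        assert 0.0 < lag < 12.0
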