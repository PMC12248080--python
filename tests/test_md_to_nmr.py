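"""Correlation functions, spectral densities and relaxation prediction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from taildyn import synthetic_data as sd
from taildyn.md_to_nmr import (
    CorrelationFunction,
    FieldParameters,
    InsufficientDataError,
    SpectralDensityModel,
    TumblingStateError,
    VectorTrajectory,
    WindowError,
    apply_tumbling,
    chunk_average,
    compare_to_experiment,
    fit_exponentials,
    nh_autocorrelation,
    predict_relaxation,
    relaxation_from_J,
    spectral_density,
    spectral_density_numeric,
)

FIELD = FieldParameters.at_field(600, 60.8)


def _vt(vectors, dt=0.1):
    return VectorTrajectory(vectors=vectors, frame_interval_ns=dt)


class TestAutocorrelation:
    def test_static_vector_is_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (500, 1, 1))
        corr = nh_autocorrelation(_vt(v))
        assert np.allclose(corr.values, 1.0, atol=1e-12)

    def test_iid_sphere_vectors_decorrelate_immediately(self, rng):
        v = rng.standard_normal((20_000, 1, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        corr = nh_autocorrelation(_vt(v), max_lag_ns=5.0)
        assert corr.values[0] == pytest.approx(1.0, abs=1e-9)
        # sphere average of P2 is 0; allow a 3-sigma sampling bound
        sigma = np.sqrt(0.2 / 20_000)
        assert np.max(np.abs(corr.values[1:])) < 3.5 * sigma

    def test_internal_motion_plateau_matches_order_parameter(self):
        vt = sd.gen_internal_motion(0.5, 1.0, 0.02, 80_000, 2, seed=11)
        corr = chunk_average(vt, 1, n_chunks=10)
        window = (corr.lags_ns >= 10) & (corr.lags_ns <= 40)
        assert corr.values[window].mean() == pytest.approx(0.5, abs=0.05)

    def test_lag_window_validation(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1, 1))
        with pytest.raises(WindowError):
            nh_autocorrelation(_vt(v), max_lag_ns=100 * 0.1)


class TestChunkAverage:
    def test_single_chunk_equals_plain_autocorrelation(self, rotational_vectors):
        res = rotational_vectors.residues[0]
        a = chunk_average(rotational_vectors, res, n_chunks=1, max_lag_ns=5.0)
        b = nh_autocorrelation(rotational_vectors, res, max_lag_ns=5.0)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_chunked_average_consistent_with_whole_trajectory(
        self, rotational_vectors
    ):
        res = rotational_vectors.residues[0]
        whole = nh_autocorrelation(rotational_vectors, res, max_lag_ns=5.0)
        chunked = chunk_average(
            rotational_vectors, res, n_chunks=20, max_lag_ns=5.0
        )
        assert np.max(np.abs(whole.values - chunked.values)) < 0.05

    def test_default_chunking_of_2us_trajectory_gives_100ns_chunks(self):
        v = np.tile([0.0, 0.0, 1.0], (2000, 1, 1))
        corr = chunk_average(_vt(v, dt=1.0), n_chunks=20)
        # chunk length 100 ns; default lag window is half of that
        assert corr.lags_ns[-1] == 50.0
        assert corr.n_chunks == 20

    def test_chunk_shorter_than_lag_window_rejected(self, rotational_vectors):
        with pytest.raises(WindowError):
            chunk_average(
                rotational_vectors,
                rotational_vectors.residues[0],
                n_chunks=20,
                max_lag_ns=1000.0,
            )


class TestApplyTumbling:
    def test_unit_correlation_becomes_tumbling_envelope(self):
        lags = np.arange(0, 101, dtype=float)
        corr = CorrelationFunction(lags_ns=lags, values=np.ones(101))
        out = apply_tumbling(corr, 163.4)
        assert np.allclose(out.values, np.exp(-lags / 163.4))
        assert out.tumbling_applied and out.tau_rot_ns == 163.4

    def test_infinite_tumbling_time_is_identity(self):
        lags = np.arange(0, 50, dtype=float)
        values = np.exp(-lags / 7.0)
        out = apply_tumbling(
            CorrelationFunction(lags_ns=lags, values=values), np.inf
        )
        assert np.allclose(out.values, values)

    def test_double_application_is_state_error(self):
        corr = CorrelationFunction(lags_ns=np.arange(5.0), values=np.ones(5))
        once = apply_tumbling(corr, 20.0)
        with pytest.raises(TumblingStateError):
            apply_tumbling(once, 20.0)

    def test_plateau_input_gives_model_free_product(self):
        lags = np.arange(0, 200, dtype=float)
        s2 = 0.8
        values = s2 + (1 - s2) * np.exp(-lags / 0.5)
        out = apply_tumbling(CorrelationFunction(lags_ns=lags, values=values), 20.0)
        expected = (s2 + (1 - s2) * np.exp(-lags / 0.5)) * np.exp(-lags / 20.0)
        assert np.allclose(out.values, expected)


class TestFitExponentials:
    def test_single_exponential_yields_one_dominant_term(self):
        lags = np.arange(0, 500, dtype=float) * 0.5
        corr = CorrelationFunction(
            lags_ns=lags,
            values=np.exp(-lags / 10.0),
            tumbling_applied=True,
            tau_rot_ns=163.4,
        )
        model = fit_exponentials(corr)
        dominant = np.argmax(model.amplitudes)
        assert model.amplitudes[dominant] == pytest.approx(1.0, abs=1e-3)
        assert model.timescales_ns[dominant] == pytest.approx(10.0, rel=1e-3)
        assert np.delete(model.amplitudes, dominant).sum() < 1e-3

    def test_known_mixture_recovered_within_2pc(self):
        lags = np.arange(0, 2001, dtype=float) * 0.5
        values = 0.3 * np.exp(-lags / 0.5) + 0.7 * np.exp(-lags / 163.4)
        corr = CorrelationFunction(
            lags_ns=lags, values=values, tumbling_applied=True, tau_rot_ns=163.4
        )
        model = fit_exponentials(corr)
        assert model.amplitudes == pytest.approx([0.3, 0.7], rel=0.02)
        assert model.timescales_ns == pytest.approx([0.5, 163.4], rel=0.02)

    def test_noise_perturbs_J0_by_under_5pc(self, rng):
        lags = np.arange(0, 2001, dtype=float) * 0.5
        clean = 0.3 * np.exp(-lags / 0.5) + 0.7 * np.exp(-lags / 163.4)
        noisy = np.clip(clean + rng.normal(0, 0.01, clean.size), -0.5, 1.0)
        noisy[0] = 1.0
        ref = fit_exponentials(
            CorrelationFunction(lags, clean, tumbling_applied=True, tau_rot_ns=163.4)
        )
        fit = fit_exponentials(
            CorrelationFunction(lags, noisy, tumbling_applied=True, tau_rot_ns=163.4)
        )
        assert spectral_density(fit, 0.0) == pytest.approx(
            spectral_density(ref, 0.0), rel=0.05
        )

    def test_amplitude_sum_constraint_enforced(self):
        model = fit_exponentials(
            CorrelationFunction(
                lags_ns=np.arange(0, 100, dtype=float),
                values=np.exp(-np.arange(0, 100) / 5.0),
            )
        )
        assert model.amplitudes.sum() <= 1.0 + 1e-3


class TestSpectralDensity:
    def test_lorentzian_values(self):
        model = SpectralDensityModel([1.0], [10.0])
        tau_s = 10e-9
        assert spectral_density(model, 0.0) == pytest.approx(0.4 * tau_s)
        assert spectral_density(model, 1.0 / tau_s) == pytest.approx(
            0.2 * tau_s
        )

    def test_numeric_cosine_transform_oracle_under_1pc(self):
        model = SpectralDensityModel([0.2, 0.3, 0.5], [0.5, 5.0, 163.4])
        omegas = np.linspace(0.0, 2 * FIELD.omega_H, 9)
        analytic = spectral_density(model, omegas)
        numeric = spectral_density_numeric(model, omegas)
        assert np.max(np.abs(numeric - analytic) / analytic) < 0.01

    def test_fit_evaluate_round_trip_at_canonical_frequencies(self):
        truth = SpectralDensityModel([0.25, 0.75], [1.0, 163.4])
        lags = np.arange(0, 2001, dtype=float) * 0.5
        corr = CorrelationFunction(
            lags_ns=lags,
            values=truth.correlation(lags),
            tumbling_applied=True,
            tau_rot_ns=163.4,
        )
        refit = fit_exponentials(corr)
        wN, wH = FIELD.omega_N, FIELD.omega_H
        for w in (0.0, wN, wH - wN, wH, wH + wN):
            assert spectral_density(refit, w) == pytest.approx(
                spectral_density(truth, w), rel=0.01
            )


class TestRelaxationFromJ:
    def test_rigid_rotor_at_ncp_tumbling_time_recovered(self):
        model = SpectralDensityModel([1.0], [163.4])
        rec = relaxation_from_J(model, FIELD)
        assert rec.tau_c_ns == pytest.approx(163.4, rel=0.05)
        assert rec.R2_per_s > rec.R1_per_s

    def test_zero_spectral_density_gives_zero_rates(self):
        model = SpectralDensityModel([0.0], [1.0])
        rec = relaxation_from_J(model, FIELD)
        assert rec.R1_per_s == 0.0 and rec.R2_per_s == 0.0

    def test_r2_monotone_in_tumbling_time(self):
        r2 = [
            relaxation_from_J(SpectralDensityModel([1.0], [tau]), FIELD).R2_per_s
            for tau in (50.0, 100.0, 163.4, 300.0)
        ]
        assert np.all(np.diff(r2) > 0)

    def test_r2_exceeds_r1_for_slow_models(self):
        for taus, amps in (
            ([0.5, 50.0], [0.3, 0.7]),
            ([1.0, 163.4], [0.5, 0.5]),
        ):
            if max(taus) * 1e-9 >= 1.0 / FIELD.omega_N:
                rec = relaxation_from_J(SpectralDensityModel(amps, taus), FIELD)
                assert rec.R2_per_s >= rec.R1_per_s


class TestFactorization:
    def test_internal_times_tumbling_equals_cosimulated_process(self):
        """C_total(t) factorises into C_internal(t) * exp(-t/tau_rot)."""
        s2, tau_e, tau_rot, dt, n = 0.8, 0.5, 20.0, 0.02, 50_000
        internal = sd.gen_internal_motion(s2, tau_e, dt, n, 2, seed=21)
        # co-simulate: accumulate an overall tumbling rotation and apply it
        rng = np.random.default_rng(99)
        sigma = np.sqrt(2.0 * dt / (6.0 * tau_rot))
        combined = np.empty_like(internal.vectors)
        R = np.eye(3)
        for k in range(n):
            combined[k] = internal.vectors[k] @ R.T
            R = Rotation.from_rotvec(rng.normal(0.0, sigma, 3)).as_matrix() @ R
        combined /= np.linalg.norm(combined, axis=-1, keepdims=True)
        vt = VectorTrajectory(vectors=combined, frame_interval_ns=dt)

        direct = chunk_average(vt, vt.residues[0], n_chunks=10, max_lag_ns=10.0)
        product = apply_tumbling(
            chunk_average(internal, 1, n_chunks=10, max_lag_ns=10.0), tau_rot
        )
        assert np.max(np.abs(direct.values - product.values)) < 0.06


class TestFullChain:
    def test_tau_recovery_through_complete_pipeline(self, rotational_vectors):
        """Free tumbling at 5 ns survives chunked C(t) -> fit -> Eq-2 route."""
        table, _ = predict_relaxation(
            rotational_vectors, FIELD, tau_rot_ns=None, n_chunks=20
        )
        good = np.abs(table["tau_c_ns"] / 5.0 - 1.0) < 0.10
        assert good.sum() >= 2  # of 3 vectors


class TestCompare:
    def test_perfect_and_anticorrelated_cases(self):
        a = {i: float(i) for i in range(1, 8)}
        b = {i: float(10 - i) for i in range(1, 8)}
        assert compare_to_experiment(a, a)[0] == pytest.approx(1.0)
        assert compare_to_experiment(a, b)[0] == pytest.approx(-1.0)

    def test_known_correlation_inside_fisher_interval(self, rng):
        n, rho = 30, 0.8
        cov = [[1, rho], [rho, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=n).T
        r, _ = compare_to_experiment(dict(enumerate(x)), dict(enumerate(y)))
        z, zr = np.arctanh(r), np.arctanh(rho)
        assert abs(z - zr) < 1.96 / np.sqrt(n - 3) + 1e-9

    def test_insufficient_overlap_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_to_experiment({1: 1.0, 2: 2.0}, {1: 1.0, 3: 3.0})

    def test_missing_data_excluded_pairwise(self):
        pred = {1: 1.0, 2: 2.0, 3: 3.0, 4: np.nan, 5: 5.0}
        obs = {1: 1.1, 2: 2.2, 3: 2.9, 4: 4.0, 5: 5.1}
        r, table = compare_to_experiment(pred, obs)
        assert len(table) == 4 and r > 0.99
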