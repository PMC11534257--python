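"""Envelope, channel and neuron attention mechanisms."""

import numpy as np
import pytest
from scipy.optimize import minimize

from fatiguefuse.attention import (
    SENetParams,
    SimamConfig,
    hilbert_envelope,
    lfam_apply,
    senet_apply,
    senet_excite,
    senet_squeeze,
    simam_apply,
    simam_energy,
)
from fatiguefuse.preprocess import zscore

FS = 2000.0


def simam_numeric_energy(channel, q, lam):
    """Independent oracle: minimize the separability objective
    (pooled statistics) numerically over the 2-D (w, b) plane."""
    x = np.asarray(channel, dtype=float)

    def objective(p):
        w, b = p
        return float(np.mean((-1.0 - (w * x + b)) ** 2) + (1.0 - (w * q + b)) ** 2 + lam * w * w)

    res = minimize(
        objective, [0.0, 0.0], method="Nelder-Mead",
        options=dict(xatol=1e-12, fatol=1e-14, maxiter=10000),
    )
    return res.fun


class TestHilbertEnvelope:
    def test_unit_sinusoid_envelope_is_one(self):
        t = np.arange(4000) / FS  # 100 cycles at 50 Hz
        env = hilbert_envelope(np.sin(2 * np.pi * 50 * t)).envelope
        interior = env[400:3600]
        np.testing.assert_allclose(interior, 1.0, atol=0.01)

    def test_zero_sequence(self):
        assert np.all(hilbert_envelope(np.zeros(100)).envelope == 0.0)

    def test_am_modulation_recovered(self):
        t = np.arange(20000) / FS
        carrier = (1 + 0.5 * np.cos(2 * np.pi * 1.0 * t)) * np.cos(2 * np.pi * 50 * t)
        env = hilbert_envelope(carrier).envelope
        true = 1 + 0.5 * np.cos(2 * np.pi * 1.0 * t)
        interior = slice(2000, 18000)
        assert np.max(np.abs(env[interior] - true[interior]) / true[interior]) < 0.02

    def test_envelope_dominates_signal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(8, 256))
            env = hilbert_envelope(x).envelope
            assert np.all(env >= np.abs(x) - 1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hilbert_envelope(np.array([1.0, 2.0]))


class TestLfam:
    def test_stationary_row_passes_through(self):
        t = np.arange(600)
        row = np.sin(2 * np.pi * 10 * t / 600)
        out = lfam_apply(row)
        z = zscore(row)
        interior = slice(60, 540)
        dev = np.sqrt(np.mean((out[interior] - z[interior]) ** 2))
        assert dev < 0.05 * np.sqrt(np.mean(z[interior] ** 2))

    def test_burst_amplified_relative_to_quiet(self):
        rng = np.random.default_rng(1)
        row = 0.2 * rng.standard_normal(600)
        row[280:320] += 3.0 * rng.standard_normal(40)  # localized burst
        out = lfam_apply(row)

        def ratio(x):
            burst = np.sqrt(np.mean(x[280:320] ** 2))
            quiet = np.sqrt(np.mean(np.concatenate([x[:280], x[320:]]) ** 2))
            return burst / quiet

        assert ratio(out) > ratio(row)

    def test_zero_row_stays_zero(self):
        out = lfam_apply(np.zeros((3, 60)))
        assert np.all(out == 0.0)

    def test_shape_preserved(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 60))
        assert lfam_apply(x).shape == (6, 60)


class TestSenet:
    def test_squeeze_is_channel_mean(self):
        assert senet_squeeze(np.array([[1.0, 2.0, 3.0]]))[0] == 2.0
        np.testing.assert_allclose(
            senet_squeeze(np.array([[0.0, 0.0], [4.0, 0.0]])), [0.0, 2.0]
        )
        np.testing.assert_allclose(senet_squeeze(np.full((2, 5), 7.0)), [7.0, 7.0])

    def test_zero_weights_give_half(self):
        params = SENetParams(W1=np.zeros((2, 4)), W2=np.zeros((4, 2)), r=2)
        np.testing.assert_allclose(senet_excite(np.ones(4), params), 0.5)

    def test_hand_evaluated_single_channel(self):
        params = SENetParams(W1=np.array([[1.0]]), W2=np.array([[1.0]]), r=1)
        # ReLU(-3) = 0 -> sigmoid(0) = 0.5
        np.testing.assert_allclose(senet_excite(np.array([-3.0]), params), [0.5])

    def test_weights_strictly_in_unit_interval(self):
        rng = np.random.default_rng(3)
        params = SENetParams.init(8, 2, rng)
        s = senet_excite(rng.standard_normal(8) * 10, params)
        assert np.all(s > 0) and np.all(s < 1)

    def test_apply_scales_channels(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((4, 16))
        params = SENetParams(W1=np.zeros((2, 4)), W2=np.zeros((4, 2)), r=2)
        np.testing.assert_allclose(senet_apply(x, params), 0.5 * x, atol=1e-12)
        assert np.all(senet_apply(np.zeros((4, 16)), params) == 0.0)

    def test_compose_squeeze_excite_by_hand(self):
        x = np.array([[1.0, 3.0]])  # mean 2
        params = SENetParams(W1=np.array([[0.5]]), W2=np.array([[2.0]]), r=1)
        s = 1 / (1 + np.exp(-2.0 * 1.0))  # sigmoid(W2 * relu(0.5*2))
        np.testing.assert_allclose(senet_apply(x, params), s * x, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        params = SENetParams.init(8, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            senet_excite(np.zeros(5), params)
        with pytest.raises(ValueError):
            SENetParams(W1=np.zeros((2, 4)), W2=np.zeros((3, 2)), r=2)

    def test_parameter_count_formula(self):
        params = SENetParams.init(100, 20, np.random.default_rng(0))
        assert params.n_params == 2 * 100 * (100 // 20) == 2 * 100**2 // 20


class TestSimam:
    def test_neuron_at_mean_has_energy_two(self):
        rng = np.random.default_rng(5)
        for lam in (1e-4, 0.3):
            x = rng.standard_normal(31)
            x = np.append(x, np.mean(x) * 32 - np.sum(x))  # force last neuron = mean
            E = simam_energy(x[None, :], SimamConfig(lam))
            assert E[0, -1] == pytest.approx(2.0, abs=1e-9)

    def test_three_point_example(self):
        E = simam_energy(np.array([[1.0, 2.0, 3.0]]), SimamConfig(1e-4))
        assert E[0, 2] == pytest.approx(1.14293, abs=1e-4)

    def test_constant_channel_energy_two(self):
        E = simam_energy(np.full((2, 10), 4.0))
        np.testing.assert_allclose(E, 2.0)

    def test_energy_positive(self):
        rng = np.random.default_rng(6)
        E = simam_energy(rng.standard_normal((5, 40)))
        assert np.all(E > 0)

    def test_closed_form_matches_numeric_minimization(self):
        """Closed-form energies match brute-force minimization of the
        separability objective on 100 random channels within 1e-6."""
        rng = np.random.default_rng(7)
        lam = 1e-4
        for _ in range(100):
            n = int(rng.integers(4, 65))
            ch = rng.standard_normal(n) * rng.uniform(0.5, 3.0)
            E = simam_energy(ch[None, :], SimamConfig(lam))[0]
            qi = int(rng.integers(0, n))
            assert abs(E[qi] - simam_numeric_energy(ch, ch[qi], lam)) < 1e-6

    def test_apply_constant_channel(self):
        x = np.full((1, 8), 3.0)
        w = 1 / (1 + np.exp(-0.5))  # sigmoid(1/2) since e* = 2
        np.testing.assert_allclose(simam_apply(x), w * x, atol=1e-12)
        assert w == pytest.approx(0.62246, abs=1e-5)

    def test_weight_monotone_in_distance_from_mean(self):
        x = np.array([[0.0, 0.5, 1.0, 2.0, 4.0]])
        out = simam_apply(x)
        weights = np.divide(out, x, out=np.zeros_like(x), where=x != 0)
        dist = np.abs(x - x.mean())
        order = np.argsort(dist[0, 1:]) + 1  # skip the zero entry
        assert np.all(np.diff(weights[0, order]) >= -1e-12)

    def test_zero_map(self):
        assert np.all(simam_apply(np.zeros((3, 9))) == 0.0)

    def test_shapes_preserved_by_all_mechanisms(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((6, 60))
        assert lfam_apply(x).shape == x.shape
        assert simam_apply(x).shape == x.shape
        params = SENetParams.init(6, 2, rng)
        assert senet_apply(x, params).shape == x.shape
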