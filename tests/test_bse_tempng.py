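"""Temporal-structure/non-Gaussianity extractor: objective, gradient,
optimizers, and the theorem-condition evaluators, all against brute-force
per-sample oracles."""

import math

import numpy as np
import pytest

from fecgbse import (
    DelayedPair,
    MixingMatrix,
    SignalMatrix,
    convergence_condition,
    delayed_pair,
    fixed_point_extract,
    generate_sources,
    global_vector,
    gradient_ascent_extract,
    make_nonlinearity,
    match_source,
    mix,
    objective,
    objective_gradient,
    benchmark_mixing_matrix,
    performance_index,
    stability_margin,
    whiten,
)
from fecgbse.bse_tempng import REFERENCE_W0_6CH
from fecgbse.exceptions import ParameterError, ShapeError

LOGCOSH = make_nonlinearity("logcosh")
QUARTIC = make_nonlinearity("quartic")


# ---------------------------------------------------------------- oracles

def _G(name, u):
    return math.log(math.cosh(u)) if name == "logcosh" else u**4 / 4


def _g(name, u):
    return math.tanh(u) if name == "logcosh" else u**3


def _gp(name, u):
    return 1 - math.tanh(u) ** 2 if name == "logcosh" else 3 * u**2


def objective_loop(w, pair, name):
    """Per-sample loop over the objective's defining expectation."""
    total = 0.0
    for t in range(pair.n_samples):
        y = float(w @ pair.current[:, t])
        ylag = float(w @ pair.lagged[:, t])
        total += _G(name, y) * _G(name, y * ylag)
    return total / pair.n_samples


def gradient_loop(w, pair, name):
    """Per-sample loop over the three expectation terms of the gradient."""
    acc = np.zeros_like(w)
    for t in range(pair.n_samples):
        xc = pair.current[:, t]
        xl = pair.lagged[:, t]
        y = float(w @ xc)
        ylag = float(w @ xl)
        u = y * ylag
        acc = acc + xc * _g(name, y) * _G(name, u)
        acc = acc + xc * ylag * _g(name, u) * _G(name, y)
        acc = acc + xl * y * _g(name, u) * _G(name, y)
    return acc / pair.n_samples


def stability_loop(s_i, s_j, tau, name):
    total = 0.0
    n = len(s_i) - tau
    for t in range(n):
        si, sit = s_i[t + tau], s_i[t]
        sj, sjt = s_j[t + tau], s_j[t]
        u = si * sit
        total += (
            _gp(name, si) * _G(name, u)
            + sit * _g(name, si) * _g(name, u)
            + 2 * si**2 * _gp(name, u) * _G(name, si)
            + 2 * u * sj * sjt * _gp(name, u) * _G(name, si)
            + 3 * si * sj * sjt * _g(name, si) * _g(name, u)
            - si * _g(name, si) * _G(name, u)
            - 2 * u * _g(name, u) * _G(name, si)
        )
    return total / n


def convergence_loop(s_i, tau, name):
    total = 0.0
    n = len(s_i) - tau
    for t in range(n):
        si, sit = s_i[t + tau], s_i[t]
        u = si * sit
        total += si * _g(name, si) * _G(name, u) + 2 * u * _g(name, u) * _G(name, si)
    return total / n


def _bootstrap_se(terms, n_boot=200, seed=0):
    """SE of a sample-mean statistic by i.i.d. resampling of its terms."""
    rng = np.random.default_rng(seed)
    n = len(terms)
    means = [np.mean(rng.choice(terms, size=n, replace=True)) for _ in range(n_boot)]
    return float(np.std(means))


def _random_pair(rng, n_channels=3, n_samples=300, tau=5):
    data = rng.standard_normal((n_channels, n_samples))
    return delayed_pair(SignalMatrix(data, 1.0), tau)


def _unit(v):
    return v / np.linalg.norm(v)


# -------------------------------------------------------------- objective

class TestObjective:
    def test_zero_signal_gives_zero(self):
        pair = DelayedPair(np.zeros((2, 50)), np.zeros((2, 50)), tau=3)
        w = np.array([1.0, 0.0])
        assert objective(w, pair, LOGCOSH) == 0.0
        assert objective(w, pair, QUARTIC) == 0.0

    @pytest.mark.parametrize("name", ["logcosh", "quartic"])
    def test_sign_symmetry(self, rng, name):
        nl = make_nonlinearity(name)
        pair = _random_pair(rng)
        w = _unit(rng.standard_normal(3))
        assert objective(w, pair, nl) == pytest.approx(objective(-w, pair, nl), abs=1e-14)

    @pytest.mark.parametrize("name", ["logcosh", "quartic"])
    def test_matches_brute_force_loop(self, rng, name):
        nl = make_nonlinearity(name)
        pair = _random_pair(rng, n_samples=200)
        for _ in range(3):
            w = _unit(rng.standard_normal(3))
            assert objective(w, pair, nl) == pytest.approx(
                objective_loop(w, pair, name), abs=1e-12
            )

    def test_non_unit_w_rejected(self, rng):
        pair = _random_pair(rng)
        with pytest.raises(ParameterError):
            objective(np.array([2.0, 0.0, 0.0]), pair, LOGCOSH)


class TestGradient:
    def test_zero_signal_gives_zero_vector(self):
        pair = DelayedPair(np.zeros((2, 50)), np.zeros((2, 50)), tau=3)
        np.testing.assert_array_equal(
            objective_gradient(np.array([1.0, 0.0]), pair, LOGCOSH), 0.0
        )

    @pytest.mark.parametrize("name", ["logcosh", "quartic"])
    def test_matches_brute_force_loop(self, rng, name):
        nl = make_nonlinearity(name)
        pair = _random_pair(rng, n_samples=150)
        for _ in range(3):
            w = _unit(rng.standard_normal(3))
            np.testing.assert_allclose(
                objective_gradient(w, pair, nl), gradient_loop(w, pair, name),
                atol=1e-12,
            )

    def test_finite_difference_agreement(self, rng):
        """Analytic gradient vs central differences of the brute objective."""
        pair = _random_pair(rng, n_channels=4, n_samples=250, tau=7)
        h = 1e-5
        for _ in range(20):
            w = _unit(rng.standard_normal(4))
            grad = objective_gradient(w, pair, LOGCOSH)
            fd = np.empty(4)
            for k in range(4):
                e = np.zeros(4)
                e[k] = h
                fd[k] = (
                    objective_loop(w + e, pair, "logcosh")
                    - objective_loop(w - e, pair, "logcosh")
                ) / (2 * h)
            assert np.max(np.abs(grad - fd)) / np.linalg.norm(grad) < 1e-5

    def test_odd_in_w(self, rng):
        pair = _random_pair(rng)
        w = _unit(rng.standard_normal(3))
        np.testing.assert_allclose(
            objective_gradient(-w, pair, LOGCOSH),
            -objective_gradient(w, pair, LOGCOSH),
            atol=1e-14,
        )


# -------------------------------------------------------------- extractors

@pytest.fixture(scope="module")
def toy_two_source():
    """Sinusoid + Gaussian noise, mixed, whitened; lag = sinusoid period."""
    rng = np.random.default_rng(11)
    T, period = 3000, 100
    s1 = np.sqrt(2.0) * np.sin(2 * np.pi * np.arange(T) / period)
    s2 = rng.standard_normal(T)
    sources = SignalMatrix(np.vstack([s1, s2]), 500.0)
    A = MixingMatrix(np.array([[0.9, 0.4], [0.3, 0.8]]))
    x = mix(sources, A)
    x_white, transform = whiten(x)
    return sources, A, delayed_pair(x_white, period), transform


class TestGradientAscent:
    def test_recovers_periodic_source(self, toy_two_source):
        sources, _, pair, _ = toy_two_source
        res = gradient_ascent_extract(pair, np.array([0.6, -0.8]), mu=0.1)
        corr = np.corrcoef(res.y, sources.data[0, pair.tau:])[0, 1]
        assert abs(corr) > 0.99

    def test_zero_learning_rate_rejected(self, toy_two_source):
        _, _, pair, _ = toy_two_source
        with pytest.raises(ParameterError):
            gradient_ascent_extract(pair, np.array([1.0, 0.0]), mu=0.0)

    def test_stationary_at_fixed_point(self, toy_two_source):
        _, _, pair, _ = toy_two_source
        fp = fixed_point_extract(pair, np.array([0.6, -0.8]))
        assert fp.converged
        res = gradient_ascent_extract(pair, fp.w, mu=0.1)
        assert res.converged
        assert res.iterations <= 2


class TestFixedPoint:
    def test_unit_norm_iterates(self, mixed_scene, scene_config):
        _, _, _, x_white, _ = mixed_scene
        pair = delayed_pair(x_white, scene_config.target_tau)
        res = fixed_point_extract(pair, REFERENCE_W0_6CH)
        for w in res.w_trace:
            assert abs(np.linalg.norm(w) - 1.0) < 1e-12

    def test_fixed_point_residual(self, mixed_scene, scene_config):
        _, _, _, x_white, _ = mixed_scene
        pair = delayed_pair(x_white, scene_config.target_tau)
        res = fixed_point_extract(pair, REFERENCE_W0_6CH, tol=1e-8)
        assert res.converged
        rhs = objective_gradient(res.w, pair, LOGCOSH)
        resid = rhs - (rhs @ res.w) * res.w
        # the stopping rule 1 - |<w', w>| < tol bounds the angle between w
        # and the next update by sqrt(2 tol), hence the residual fraction too
        assert np.linalg.norm(resid) / np.linalg.norm(rhs) < np.sqrt(2 * 1e-8)

    def test_extracts_fecg_from_benchmark_scene(self, mixed_scene, scene_config):
        sources, A, _, x_white, transform = mixed_scene
        pair = delayed_pair(x_white, scene_config.target_tau)
        res = fixed_point_extract(pair, REFERENCE_W0_6CH)
        idx, corr = match_source(res.y, sources)
        assert sources.labels[idx] == "fecg"
        assert corr > 0.95
        pi = performance_index(global_vector(res.w, transform.V, A))
        assert pi < 0.1

    def test_sign_invariance_of_start(self, mixed_scene, scene_config):
        _, _, _, x_white, _ = mixed_scene
        pair = delayed_pair(x_white, scene_config.target_tau)
        res_pos = fixed_point_extract(pair, REFERENCE_W0_6CH)
        res_neg = fixed_point_extract(pair, -REFERENCE_W0_6CH)
        assert abs(abs(res_pos.w @ res_neg.w) - 1.0) < 1e-6

    def test_stationarity_of_converged_w(self, mixed_scene, scene_config):
        _, _, _, x_white, _ = mixed_scene
        pair = delayed_pair(x_white, scene_config.target_tau)
        res = fixed_point_extract(pair, REFERENCE_W0_6CH)
        grad = objective_gradient(res.w, pair, LOGCOSH)
        projected = grad - (grad @ res.w) * res.w
        assert np.linalg.norm(projected) < 1e-4 * np.linalg.norm(grad)

    def test_zero_start_rejected(self, toy_two_source):
        _, _, pair, _ = toy_two_source
        with pytest.raises(ParameterError):
            fixed_point_extract(pair, np.zeros(2))


# ------------------------------------------------------ theorem conditions

class TestStabilityMargin:
    def test_fecg_vs_noise_is_negative(self, six_sources, scene_config):
        tau = scene_config.target_tau
        fecg = six_sources.data[1]
        noise = six_sources.data[4]
        assert stability_margin(fecg, noise, tau, LOGCOSH) < 0

    def test_white_noise_margin_statistically_zero(self, rng):
        si = rng.standard_normal(8000)
        sj = rng.standard_normal(8000)
        tau = 17
        value = stability_margin(si, sj, tau, LOGCOSH)
        # Monte-Carlo spread from independent regenerations of the same size
        reps = [
            stability_margin(
                rng.standard_normal(8000), rng.standard_normal(8000), tau, LOGCOSH
            )
            for _ in range(30)
        ]
        se = np.std(reps)
        assert abs(value) < 5 * se

    def test_matches_brute_force_loop(self, rng):
        si = rng.standard_normal(100)
        sj = rng.standard_normal(100)
        for name, nl in (("logcosh", LOGCOSH), ("quartic", QUARTIC)):
            assert stability_margin(si, sj, 7, nl) == pytest.approx(
                stability_loop(si, sj, 7, name), abs=1e-12
            )

    def test_length_mismatch(self, rng):
        with pytest.raises(ShapeError):
            stability_margin(rng.standard_normal(50), rng.standard_normal(40), 5, LOGCOSH)


class TestConvergenceCondition:
    def test_zero_series(self):
        assert convergence_condition(np.zeros(100), 5, LOGCOSH) == 0.0

    def test_fecg_significantly_nonzero(self, six_sources, scene_config):
        tau = scene_config.target_tau
        fecg = six_sources.data[1]
        value = convergence_condition(fecg, tau, LOGCOSH)
        si, sit = fecg[tau:], fecg[:-tau]
        u = si * sit
        terms = si * np.tanh(si) * np.log(np.cosh(u)) + 2 * u * np.tanh(u) * np.log(np.cosh(si))
        se = _bootstrap_se(terms)
        assert abs(value) > 5 * se

    def test_matches_brute_force_loop(self, rng):
        si = rng.standard_normal(100)
        for name, nl in (("logcosh", LOGCOSH), ("quartic", QUARTIC)):
            assert convergence_condition(si, 7, nl) == pytest.approx(
                convergence_loop(si, 7, name), abs=1e-12
            )
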