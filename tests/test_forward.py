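"""Forward (generative) model: transfer functions, hemodynamic kernel,
predicted cross-spectra and their closed-form / ODE oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specdcm.forward import (
    BalloonConstants,
    CrossSpectrum,
    FluctuationParams,
    HemodynamicParams,
    NeuralCoupling,
    SpectralModel,
    hemodynamic_kernel,
    model_to_vector,
    n_parameters,
    neural_transfer,
    parameter_names,
    predicted_csd,
    predicted_csd_from_vectors,
    read_crossspectrum,
    stability_check,
    vector_to_model,
    write_crossspectrum,
)


def single_node_model(noise_amp=-np.inf):
    return SpectralModel(
        coupling=NeuralCoupling(offdiag=np.zeros((1, 1)), self_log=np.zeros(1)),
        fluct=FluctuationParams(neural_amp=[0.0], neural_exp=[0.0],
                                noise_amp=noise_amp, noise_exp=0.0),
        hemo=HemodynamicParams(transit=[0.0], decay=[0.0]),
    )


class TestNeuralTransfer:
    def test_scalar_inverse_at_zero_frequency(self):
        c = NeuralCoupling(offdiag=np.zeros((1, 1)), self_log=np.zeros(1))
        T = neural_transfer(c, [0.0])
        assert T[0, 0, 0] == pytest.approx(2.0)  # -(-0.5)^-1

    def test_diagonal_coupling_gives_diagonal_transfer(self):
        c = NeuralCoupling(offdiag=np.zeros((3, 3)), self_log=[0.1, -0.2, 0.0])
        T = neural_transfer(c, [0.01, 0.05, 0.1])
        off = T[:, ~np.eye(3, dtype=bool)]
        assert np.abs(off).max() == 0.0

    def test_matches_dense_inverse_oracle(self):
        A = np.array([[-0.5, 0.2], [0.0, -0.5]])
        c = NeuralCoupling(offdiag=np.array([[0.0, 0.2], [0.0, 0.0]]),
                           self_log=np.zeros(2))
        w = 2 * math.pi * 0.05
        expected = np.linalg.inv(1j * w * np.eye(2) - A)
        T = neural_transfer(c, [0.05])
        np.testing.assert_allclose(T[0], expected, rtol=1e-12)

    def test_vanishes_at_high_frequency(self):
        c = NeuralCoupling(offdiag=np.zeros((2, 2)), self_log=np.zeros(2))
        assert np.abs(neural_transfer(c, [1e4])).max() < 1e-3

    def test_unstable_coupling_rejected(self):
        c = NeuralCoupling(offdiag=np.array([[0.0, 2.0], [2.0, 0.0]]),
                           self_log=np.zeros(2))
        with pytest.raises(ValueError, match="unstable"):
            neural_transfer(c, [0.05])


class TestStability:
    def test_trivial_cases(self):
        assert stability_check(-0.5 * np.eye(3))
        assert not stability_check(0.5 * np.eye(3))

    def test_agrees_with_sde_boundedness(self):
        """Eigenvalue criterion vs long-horizon Euler-Maruyama norms.

        Draws whose spectral abscissa is within 0.05 Hz of zero are
        redrawn: a finite-horizon simulation cannot classify them.
        """
        rng = np.random.default_rng(7)
        mats = []
        while len(mats) < 100:
            A = rng.normal(0, 0.4, (4, 4)) - 0.4 * np.eye(4)
            if abs(np.max(np.linalg.eigvals(A).real)) > 0.05:
                mats.append(A)
        A = np.stack(mats)
        stable = np.array([stability_check(a) for a in A])
        dt, nsteps = 0.05, 8000
        x = rng.normal(0, 0.1, (100, 4))
        exploded = np.zeros(100, dtype=bool)
        for _ in range(nsteps):
            x = x + dt * np.einsum("sij,sj->si", A, x) \
                + math.sqrt(dt) * rng.normal(0, 0.05, (100, 4))
            x = np.where(np.isfinite(x), x, 1e30)
            exploded |= np.linalg.norm(x, axis=1) > 1e6
            x = np.clip(x, -1e30, 1e30)
        assert np.array_equal(stable, ~exploded)


class TestHemodynamicKernel:
    def test_identical_params_identical_kernels(self):
        h = HemodynamicParams(transit=np.zeros(3), decay=np.zeros(3))
        K = hemodynamic_kernel(h, BalloonConstants(), [0.01, 0.05])
        assert np.allclose(K[:, 0], K[:, 1]) and np.allclose(K[:, 0], K[:, 2])

    def test_low_pass(self):
        h = HemodynamicParams(transit=[0.0], decay=[0.0])
        K = hemodynamic_kernel(h, BalloonConstants(), [0.01, 1.0])
        assert abs(K[1, 0]) < 1e-2 * abs(K[0, 0])

    def test_matches_rk4_integration_of_linearized_odes(self):
        """Frequency response vs RK4 time-domain integration, 2% L2."""
        c = BalloonConstants()
        h = HemodynamicParams(transit=[0.1], decay=[-0.1], epsilon=0.05)
        kappa = c.kappa0 * math.exp(h.decay[0])
        tau = c.tau0 * math.exp(h.transit[0])
        eps = c.epsilon0 * math.exp(h.epsilon)
        phi = 1 + (1 - c.e0) * math.log(1 - c.e0) / c.e0
        al = c.grubb
        M = np.array([
            [-kappa, -c.gamma, 0, 0],
            [1, 0, 0, 0],
            [0, 1 / tau, -1 / (al * tau), 0],
            [0, phi / tau, -(1 / al - 1) / tau, -1 / tau]])
        k2e = c.k2 * eps
        k3e = c.k3 + 1 - eps
        C = c.v0 * np.array([0, 0, k2e - k3e, -(c.k1 + k2e)])
        dt, tend = 0.01, 60.0
        nt = int(tend / dt)
        x = np.array([1.0, 0, 0, 0])
        ys = np.empty(nt)
        for i in range(nt):
            ys[i] = C @ x
            k1_ = M @ x
            k2_ = M @ (x + dt / 2 * k1_)
            k3_ = M @ (x + dt / 2 * k2_)
            k4_ = M @ (x + dt * k3_)
            x = x + dt / 6 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        N = 2 ** 16
        fpos = np.fft.rfftfreq(N, d=dt)[1:]
        spec = np.empty(fpos.size + 1, dtype=complex)
        spec[1:] = hemodynamic_kernel(h, c, fpos)[:, 0]
        f0 = 1 / c.gamma
        v0_ = f0 * al
        q0 = phi * f0 - (1 / al - 1) * v0_
        spec[0] = c.v0 * ((k2e - k3e) * v0_ - (c.k1 + k2e) * q0)
        imp = np.fft.irfft(spec, n=N) / dt
        err = np.linalg.norm(imp[:nt] - ys) / np.linalg.norm(ys)
        assert err < 0.02

    def test_nonpositive_rate_rejected(self):
        h = HemodynamicParams(transit=[0.0], decay=[0.0])
        bad = BalloonConstants()
        object.__setattr__(bad, "kappa0", -1.0)
        with pytest.raises(ValueError, match="positive"):
            hemodynamic_kernel(h, bad, [0.05])


class TestPredictedCSD:
    def test_single_node_lorentzian_closed_form(self, freqs):
        """White input, identity kernel: G(w) = 1/(w^2 + 0.25)."""
        m = single_node_model()
        G = predicted_csd(m, freqs, kernels=np.ones((freqs.size, 1))).matrices
        w = 2 * math.pi * freqs
        np.testing.assert_allclose(G[:, 0, 0].real, 1 / (w ** 2 + 0.25),
                                   atol=1e-10)
        assert np.abs(G.imag).max() < 1e-14

    def test_zero_neural_amplitude_leaves_noise_only(self, freqs):
        m = single_node_model(noise_amp=0.3)
        m.fluct.neural_amp = np.array([-np.inf])
        G = predicted_csd(m, freqs).matrices[:, 0, 0].real
        w = 2 * math.pi * freqs
        expected = (1 / 128) * math.exp(0.3) * w ** 0.0
        np.testing.assert_allclose(G, expected, rtol=1e-12)

    def test_diagonal_model_has_zero_cross_spectra(self, freqs):
        m = SpectralModel(
            coupling=NeuralCoupling(offdiag=np.zeros((3, 3)), self_log=np.zeros(3)),
            fluct=FluctuationParams(neural_amp=np.zeros(3), neural_exp=np.full(3, 0.5)),
            hemo=HemodynamicParams(transit=np.zeros(3), decay=np.zeros(3)),
        )
        G = predicted_csd(m, freqs).matrices
        assert np.abs(G[:, ~np.eye(3, dtype=bool)]).max() == 0.0

    def test_three_node_hermitian_psd(self, baseline_model_3, freqs):
        cs = predicted_csd(baseline_model_3, freqs)
        cs.validate()
        eig = np.linalg.eigvalsh(cs.matrices)
        assert eig.min() >= -1e-12 * eig.max()

    def test_scale_covariance_of_signal_term(self, baseline_model_3, freqs):
        """Multiplying exp(neural_amp) by c scales the signal CSD by c."""
        m = baseline_model_3
        G1 = predicted_csd(m, freqs).matrices
        vec = model_to_vector(m)
        names = parameter_names(3)
        vec2 = vec.copy()
        for i in range(3):
            vec2[names.index(f"amp_{i}")] += math.log(3.0)
        G2 = predicted_csd(vector_to_model(vec2, 3), freqs).matrices
        noise = predicted_csd(vector_to_model(
            np.where([nm.startswith("amp") for nm in names], -np.inf, vec), 3),
            freqs).matrices
        np.testing.assert_allclose(G2 - noise, 3.0 * (G1 - noise), rtol=1e-9)

    def test_batched_matches_single(self, baseline_model_3, freqs):
        vec = model_to_vector(baseline_model_3)
        batch = np.stack([vec, vec + 0.01])
        Gb = predicted_csd_from_vectors(batch, 3, freqs)
        G0 = predicted_csd(baseline_model_3, freqs).matrices
        np.testing.assert_allclose(Gb[0], G0, rtol=1e-12)
        G1 = predicted_csd(vector_to_model(vec + 0.01, 3), freqs).matrices
        np.testing.assert_allclose(Gb[1], G1, rtol=1e-12)

    def test_unstable_model_rejected(self, freqs):
        m = single_node_model()
        m.coupling.offdiag = np.zeros((1, 1))
        m.coupling.self_log = np.array([0.0])
        m2 = SpectralModel(
            coupling=NeuralCoupling(offdiag=np.array([[0.0, 1.0], [1.0, 0.0]]),
                                    self_log=np.zeros(2)),
            fluct=FluctuationParams(neural_amp=np.zeros(2), neural_exp=np.zeros(2)),
            hemo=HemodynamicParams(transit=np.zeros(2), decay=np.zeros(2)),
        )
        with pytest.raises(ValueError, match="unstable"):
            predicted_csd(m2, freqs)


class TestVectorization:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=4), st.integers(0, 2 ** 31 - 1))
    def test_roundtrip(self, n, seed):
        vec = np.random.default_rng(seed).normal(0, 0.2, n_parameters(n))
        np.testing.assert_array_equal(model_to_vector(vector_to_model(vec, n)), vec)

    def test_parameter_count(self):
        assert n_parameters(3) == 24
        assert len(parameter_names(3)) == 24


def test_crossspectrum_serialization_roundtrip(tmp_path, baseline_model_3, freqs):
    cs = predicted_csd(baseline_model_3, freqs)
    cs.labels = ["SN", "DAN", "DMN"]
    write_crossspectrum(cs, tmp_path / "sub_csd")
    back = read_crossspectrum(tmp_path / "sub_csd")
    np.testing.assert_allclose(back.matrices, cs.matrices, rtol=1e-10, atol=1e-14)
    np.testing.assert_allclose(back.freqs, cs.freqs)
    assert back.labels == cs.labels


def test_crossspectrum_invariants_enforced(freqs):
    bad = np.zeros((freqs.size, 2, 2), complex)
    bad[:, 0, 1] = 1.0  # not Hermitian
    with pytest.raises(ValueError, match="Hermitian"):
        CrossSpectrum(freqs=freqs, matrices=bad).validate()
    with pytest.raises(ValueError, match="increasing"):
        CrossSpectrum(freqs=freqs[::-1], matrices=bad)
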