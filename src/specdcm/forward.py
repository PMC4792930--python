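"""Generative model of resting-state BOLD cross-spectra (spectral DCM forward model).

A network of ``n`` neural nodes obeys linear stochastic dynamics

    dx/dt = A x + v(t),

where ``A`` (Hz) is the effective-connectivity matrix with inhibitory
self-connections on the diagonal, and ``v`` are endogenous neural
fluctuations with node-wise power-law spectra ``g(w) = exp(alpha) * w**(-beta)``.
Neural activity drives a linearized balloon/windkessel hemodynamic model per
node, and the observed BOLD cross-spectral density (CSD) is

    G_y(w) = K(w) (iwI - A)^-1 G_v(w) (iwI - A)^-H K(w)^H + G_e(w),

with ``K`` the diagonal matrix of hemodynamic frequency responses and
``G_e`` an observation-noise spectrum.

Conventions
-----------
* All public interfaces take frequencies in Hz; internally angular
  frequency ``w = 2*pi*f`` rad/s is used.
* Cross-spectral densities are two-sided densities with respect to
  angular frequency, i.e. the value stored at frequency ``f`` is
  ``G(w = 2*pi*f)``; the per-Hz density is ``2*pi`` times larger.
* Self-connections are parameterized as ``-0.5 * exp(a_ii)`` Hz, a
  log-scaling of a -0.5 Hz reference rate, so that "increased
  self-inhibition" is a positive scalar and ``A`` stays stable under
  unconstrained optimization of ``a_ii``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SELF_RATE",
    "NEURAL_EXPONENT_REF",
    "NeuralCoupling",
    "FluctuationParams",
    "HemodynamicParams",
    "BalloonConstants",
    "SpectralModel",
    "CrossSpectrum",
    "stability_check",
    "neural_transfer",
    "hemodynamic_kernel",
    "predicted_csd",
    "predicted_csd_from_vectors",
    "default_frequency_grid",
    "parameter_names",
    "model_to_vector",
    "vector_to_model",
    "n_parameters",
]

#: Reference magnitude (Hz) of the inhibitory self-connection.
SELF_RATE = 0.5

#: Reference power-law exponent of neural fluctuation and noise spectra.
#: The exponent parameters are stored as absolute values; priors and the
#: synthetic generator are centred here (a mildly 1/f-like spectrum).
NEURAL_EXPONENT_REF = 0.5

#: Reference scale of the neural fluctuation spectrum (density units).
NEURAL_SPEC_SCALE = 1.0

#: Reference scale of the observation-noise spectrum.  Chosen well below
#: the signal scale implied by the balloon constants, so that at the
#: reference parameters (all log-scalings zero) the in-band SNR is high.
NOISE_SPEC_SCALE = 1.0 / 128.0


def _as_vector(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass
class NeuralCoupling:
    """Directed coupling matrix with parameterized self-inhibition.

    Parameters
    ----------
    offdiag : (n, n) array
        Between-node coupling rates in Hz; the diagonal must be zero.
        Entry ``[i, j]`` is the influence of node ``j`` on node ``i``.
    self_log : (n,) array
        Unitless log-scalings ``a_ii``; the effective diagonal of the
        full matrix is ``-SELF_RATE * exp(a_ii)``.
    """

    offdiag: np.ndarray
    self_log: np.ndarray

    def __post_init__(self) -> None:
        self.offdiag = np.asarray(self.offdiag, dtype=float)
        if self.offdiag.ndim != 2 or self.offdiag.shape[0] != self.offdiag.shape[1]:
            raise ValueError("offdiag must be a square matrix")
        n = self.offdiag.shape[0]
        if np.any(np.diag(self.offdiag) != 0.0):
            raise ValueError("offdiag must have a zero diagonal")
        self.self_log = _as_vector(self.self_log, n, "self_log")

    @property
    def n_nodes(self) -> int:
        return self.offdiag.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """Full coupling matrix ``A = offdiag - diag(SELF_RATE * exp(a_ii))``."""
        return self.offdiag + np.diag(-SELF_RATE * np.exp(self.self_log))


@dataclass
class FluctuationParams:
    """Power-law spectra of endogenous fluctuations and observation noise.

    Node-wise neural spectra are ``exp(neural_amp) * w**(-neural_exp)``
    (times a fixed reference scale); the observation-noise spectrum is
    global, ``exp(noise_amp) * w**(-noise_exp)`` on every channel.
    """

    neural_amp: np.ndarray
    neural_exp: np.ndarray
    noise_amp: float = 0.0
    noise_exp: float = NEURAL_EXPONENT_REF

    def __post_init__(self) -> None:
        self.neural_amp = np.asarray(self.neural_amp, dtype=float)
        n = self.neural_amp.shape[0]
        self.neural_exp = _as_vector(self.neural_exp, n, "neural_exp")
        self.noise_amp = float(self.noise_amp)
        self.noise_exp = float(self.noise_exp)

    @property
    def n_nodes(self) -> int:
        return self.neural_amp.shape[0]


@dataclass
class HemodynamicParams:
    """Node-wise hemodynamic parameters as log-scalings of reference rates.

    ``transit`` scales the capillary transit time tau0, ``decay`` scales
    the vasodilatory-signal decay rate kappa0, and ``epsilon`` is a global
    log-scaling of the intravascular/extravascular mixing ratio.
    """

    transit: np.ndarray
    decay: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.transit = np.asarray(self.transit, dtype=float)
        n = self.transit.shape[0]
        self.decay = _as_vector(self.decay, n, "decay")
        self.epsilon = float(self.epsilon)

    @property
    def n_nodes(self) -> int:
        return self.transit.shape[0]


@dataclass
class BalloonConstants:
    """Fixed constants of the balloon/windkessel observation model.

    Defaults are the standard published values (3T BOLD coefficients);
    the mixing ratio epsilon enters the readout as ``k2_eff = k2 * eps``
    and ``k3_eff = k3 + (1 - eps)`` with ``eps = epsilon0 * exp(epsilon)``,
    so at the reference ``eps = 1`` the extravascular term is ``k3``.
    """

    kappa0: float = 0.64  # 1/s, vasodilatory signal decay rate
    gamma: float = 0.32  # 1/s, flow autoregulation rate
    tau0: float = 2.0  # s, capillary transit time
    grubb: float = 0.32  # Grubb's flow-volume exponent
    e0: float = 0.4  # resting oxygen extraction fraction
    v0: float = 0.04  # resting venous volume fraction
    k1: float = 2.77
    k2: float = 0.4
    k3: float = 0.0
    epsilon0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kappa0", "gamma", "tau0", "grubb", "v0", "epsilon0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.e0 < 1:
            raise ValueError("e0 must lie in (0, 1)")
        for name in ("k1", "k2", "k3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SpectralModel:
    """Full per-subject generative parameter set."""

    coupling: NeuralCoupling
    fluct: FluctuationParams
    hemo: HemodynamicParams
    constants: BalloonConstants = field(default_factory=BalloonConstants)

    def __post_init__(self) -> None:
        n = self.coupling.n_nodes
        if self.fluct.n_nodes != n or self.hemo.n_nodes != n:
            raise ValueError("coupling, fluct and hemo must agree on n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.coupling.n_nodes

    def is_stable(self) -> bool:
        return stability_check(self.coupling)


@dataclass
class CrossSpectrum:
    """Complex Hermitian cross-spectral density matrices on a frequency grid."""

    freqs: np.ndarray
    matrices: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=complex)
        if self.freqs.ndim != 1:
            raise ValueError("freqs must be a 1-D array")
        if np.any(self.freqs <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing and positive")
        nf = self.freqs.shape[0]
        if self.matrices.ndim != 3 or self.matrices.shape[0] != nf:
            raise ValueError("matrices must have shape (n_freqs, n, n)")
        if self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be square per frequency")

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    def validate(self, psd_tol: float = 1e-8) -> None:
        """Check Hermitian symmetry and positive semidefiniteness."""
        herm = np.abs(self.matrices - self.matrices.conj().transpose(0, 2, 1)).max()
        scale = max(np.abs(self.matrices).max(), 1e-300)
        if herm > 1e-8 * scale:
            raise ValueError(f"matrices not Hermitian (max asymmetry {herm:.3g})")
        sym = 0.5 * (self.matrices + self.matrices.conj().transpose(0, 2, 1))
        eig = np.linalg.eigvalsh(sym)
        tr = np.trace(sym, axis1=1, axis2=2).real
        if np.any(eig.min(axis=1) < -psd_tol * np.maximum(tr, 1e-300)):
            raise ValueError("matrices not positive semidefinite within tolerance")


def stability_check(coupling: NeuralCoupling | np.ndarray) -> bool:
    """True iff every eigenvalue of the full coupling matrix has negative real part."""
    A = coupling.matrix if isinstance(coupling, NeuralCoupling) else np.asarray(coupling, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("coupling matrix must be square")
    return bool(np.max(np.linalg.eigvals(A).real) < 0.0)


def default_frequency_grid(n_volumes: int, tr: float, n_freqs: int = 32,
                           fmax: float = 0.1) -> np.ndarray:
    """Linearly spaced analysis band from 1/(n_volumes*TR) to ``fmax`` Hz.

    The upper edge matches the conventional resting-state band limit
    (0.008-0.1 Hz bandpass); the lower edge is the fundamental frequency
    of the acquired run.
    """
    f0 = 1.0 / (n_volumes * tr)
    if f0 >= fmax:
        raise ValueError("series too short for the requested band")
    return np.linspace(f0, fmax, n_freqs)


# ---------------------------------------------------------------------------
# transfer functions


def _transfer_from_matrix(A: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """(i w I - A)^-1 for stacked A of shape (..., n, n); returns (..., nf, n, n)."""
    n = A.shape[-1]
    iw = 1j * omega[:, None, None] * np.eye(n)
    return np.linalg.inv(iw - A[..., None, :, :])


def neural_transfer(coupling: NeuralCoupling, freqs) -> np.ndarray:
    """Neural transfer matrices ``(i*2*pi*f I - A)^-1`` per frequency (Hz)."""
    if not stability_check(coupling):
        raise ValueError("coupling matrix is unstable (eigenvalue with Re >= 0)")
    omega = 2.0 * math.pi * np.asarray(freqs, dtype=float)
    return _transfer_from_matrix(coupling.matrix, omega)


def _kernel_from_rates(kappa, tau, epsilon, c: BalloonConstants,
                       omega: np.ndarray) -> np.ndarray:
    """Linearized balloon-model frequency response, neural input -> BOLD.

    ``kappa``/``tau`` have shape (..., n); returns (..., nf, n).  The balloon
    state equations (vasodilatory signal s, flow f, volume v, dHb q) are
    linearized about the resting fixed point, giving the cascade

        f(w) = 1 / ((iw)^2 + kappa iw + gamma)            flow response
        v(w) = f / (tau iw + 1/alpha)                      volume
        q(w) = (phi f - (1/alpha - 1) v) / (tau iw + 1)    deoxyhemoglobin
        y(w) = V0 [ (k2 eps - k3_eff) v - (k1 + k2 eps) q ]

    with ``phi = 1 + (1 - E0) ln(1 - E0) / E0`` the linearized oxygen
    extraction and ``alpha`` the Grubb exponent.
    """
    iw = (1j * omega)[:, None]
    k = np.asarray(kappa, float)[..., None, :]
    t = np.asarray(tau, float)[..., None, :]
    f = 1.0 / (iw ** 2 + k * iw + c.gamma)
    v = f / (t * iw + 1.0 / c.grubb)
    phi = 1.0 + (1.0 - c.e0) * math.log(1.0 - c.e0) / c.e0
    q = (phi * f - (1.0 / c.grubb - 1.0) * v) / (t * iw + 1.0)
    eps = np.asarray(epsilon, float)[..., None, None] if np.ndim(epsilon) else float(epsilon)
    k2e = c.k2 * eps
    k3e = c.k3 + (1.0 - eps)
    return c.v0 * ((k2e - k3e) * v - (c.k1 + k2e) * q)


def hemodynamic_kernel(hemo: HemodynamicParams, constants: BalloonConstants,
                       freqs) -> np.ndarray:
    """Per-node complex frequency response from neural input to BOLD.

    Returns an array of shape (n_freqs, n_nodes).
    """
    kappa = constants.kappa0 * np.exp(hemo.decay)
    tau = constants.tau0 * np.exp(hemo.transit)
    eps = constants.epsilon0 * math.exp(hemo.epsilon)
    if np.any(kappa <= 0) or np.any(tau <= 0) or eps <= 0:
        raise ValueError("mapped hemodynamic rates must be positive")
    omega = 2.0 * math.pi * np.asarray(freqs, dtype=float)
    return _kernel_from_rates(kappa, tau, eps, constants, omega)


def _power_law(amp_log, exponent, omega, scale):
    """scale * exp(amp_log) * omega**(-exponent) with broadcasting (..., nf, n)."""
    a = np.asarray(amp_log, float)[..., None, :]
    b = np.asarray(exponent, float)[..., None, :]
    w = np.asarray(omega, float)[:, None]
    return scale * np.exp(a) * w ** (-b)


def _assemble_csd(T, K, Gv, Ge):
    """G = (K T) diag(Gv) (K T)^H + diag(Ge) with batch/freq leading dims."""
    KT = K[..., :, :, None] * T
    G = np.einsum("...ik,...k,...jk->...ij", KT, Gv, KT.conj())
    n = G.shape[-1]
    idx = np.arange(n)
    G[..., idx, idx] += Ge[..., None]
    return 0.5 * (G + G.conj().swapaxes(-1, -2))


def predicted_csd(model: SpectralModel, freqs, kernels: np.ndarray | None = None
                  ) -> CrossSpectrum:
    """Predicted BOLD cross-spectral density of a stable model.

    Parameters
    ----------
    model : SpectralModel
    freqs : array of frequencies in Hz (strictly positive)
    kernels : optional (n_freqs, n_nodes) complex array overriding the
        hemodynamic frequency response (e.g. an array of ones to inspect
        the neural-level spectrum directly).
    """
    freqs = np.asarray(freqs, dtype=float)
    if not model.is_stable():
        raise ValueError("model is unstable")
    omega = 2.0 * math.pi * freqs
    T = neural_transfer(model.coupling, freqs)
    if kernels is None:
        K = hemodynamic_kernel(model.hemo, model.constants, freqs)
    else:
        K = np.asarray(kernels, dtype=complex)
        if K.shape != (freqs.shape[0], model.n_nodes):
            raise ValueError("kernels must have shape (n_freqs, n_nodes)")
    Gv = _power_law(model.fluct.neural_amp, model.fluct.neural_exp, omega,
                    NEURAL_SPEC_SCALE)
    Ge = NOISE_SPEC_SCALE * np.exp(model.fluct.noise_amp) * omega ** (-model.fluct.noise_exp)
    G = _assemble_csd(T, K, Gv, Ge)
    return CrossSpectrum(freqs=freqs, matrices=G)


def write_crossspectrum(cs: CrossSpectrum, basepath) -> None:
    """Serialize as ``<base>.json`` (frequencies, labels) plus
    ``<base>.txt`` (one row per frequency; interleaved real/imag parts
    of the row-major flattened matrix)."""
    import json
    from pathlib import Path

    base = Path(basepath)
    n = cs.n_nodes
    header = {"freqs": cs.freqs.tolist(), "n_nodes": n,
              "labels": cs.labels or [f"node_{i}" for i in range(n)]}
    base.with_suffix(".json").write_text(json.dumps(header))
    flat = cs.matrices.reshape(cs.freqs.size, -1)
    inter = np.empty((cs.freqs.size, 2 * n * n))
    inter[:, 0::2] = flat.real
    inter[:, 1::2] = flat.imag
    np.savetxt(base.with_suffix(".txt"), inter, fmt="%.12g")


def read_crossspectrum(basepath) -> CrossSpectrum:
    """Inverse of :func:`write_crossspectrum`."""
    import json
    from pathlib import Path

    base = Path(basepath)
    header = json.loads(base.with_suffix(".json").read_text())
    inter = np.loadtxt(base.with_suffix(".txt"), ndmin=2)
    n = int(header["n_nodes"])
    mats = (inter[:, 0::2] + 1j * inter[:, 1::2]).reshape(-1, n, n)
    return CrossSpectrum(freqs=np.asarray(header["freqs"]), matrices=mats,
                         labels=list(header["labels"]))


# ---------------------------------------------------------------------------
# flat parameter vectorization (shared by the cohort generator and inversion)


def parameter_names(n: int) -> list[str]:
    """Canonical parameter order of a full n-node model.

    Off-diagonal couplings row-major (``a_i_j`` = influence of j on i),
    self log-scalings, neural amplitudes, neural exponents, global noise
    amplitude and exponent, transit, decay, epsilon.
    """
    names = [f"a_{i}_{j}" for i in range(n) for j in range(n) if i != j]
    names += [f"self_{i}" for i in range(n)]
    names += [f"amp_{i}" for i in range(n)]
    names += [f"exp_{i}" for i in range(n)]
    names += ["noise_amp", "noise_exp"]
    names += [f"transit_{i}" for i in range(n)]
    names += [f"decay_{i}" for i in range(n)]
    names += ["epsilon"]
    return names


def n_parameters(n: int) -> int:
    return n * n + 4 * n + 3


def model_to_vector(model: SpectralModel) -> np.ndarray:
    """Flatten a SpectralModel into the canonical parameter vector."""
    n = model.n_nodes
    off = model.coupling.offdiag
    mask = ~np.eye(n, dtype=bool)
    return np.concatenate([
        off[mask],
        model.coupling.self_log,
        model.fluct.neural_amp,
        model.fluct.neural_exp,
        [model.fluct.noise_amp, model.fluct.noise_exp],
        model.hemo.transit,
        model.hemo.decay,
        [model.hemo.epsilon],
    ])


def _split_vectors(theta: np.ndarray, n: int):
    """Split (..., p) parameter vectors into named arrays."""
    m = n * n - n
    off_flat = theta[..., :m]
    self_log = theta[..., m:m + n]
    amp = theta[..., m + n:m + 2 * n]
    exp_ = theta[..., m + 2 * n:m + 3 * n]
    noise_amp = theta[..., m + 3 * n]
    noise_exp = theta[..., m + 3 * n + 1]
    transit = theta[..., m + 3 * n + 2:m + 4 * n + 2]
    decay = theta[..., m + 4 * n + 2:m + 5 * n + 2]
    epsilon = theta[..., m + 5 * n + 2]
    mask = ~np.eye(n, dtype=bool)
    off = np.zeros(theta.shape[:-1] + (n, n))
    off[..., mask] = off_flat
    return off, self_log, amp, exp_, noise_amp, noise_exp, transit, decay, epsilon


def vector_to_model(theta: np.ndarray, n: int,
                    constants: BalloonConstants | None = None) -> SpectralModel:
    """Inverse of :func:`model_to_vector`."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_parameters(n),):
        raise ValueError(f"expected vector of length {n_parameters(n)}")
    off, self_log, amp, exp_, namp, nexp, transit, decay, eps = _split_vectors(theta, n)
    return SpectralModel(
        coupling=NeuralCoupling(offdiag=off, self_log=self_log),
        fluct=FluctuationParams(neural_amp=amp, neural_exp=exp_,
                                noise_amp=float(namp), noise_exp=float(nexp)),
        hemo=HemodynamicParams(transit=transit, decay=decay, epsilon=float(eps)),
        constants=constants or BalloonConstants(),
    )


def predicted_csd_from_vectors(theta: np.ndarray, n: int, freqs,
                               constants: BalloonConstants | None = None
                               ) -> np.ndarray:
    """Batched predicted CSD for stacked parameter vectors.

    ``theta`` has shape (..., p); returns complex matrices of shape
    (..., n_freqs, n, n).  No stability check is performed: the transfer
    matrix is well defined for any A without purely imaginary eigenvalues
    on the grid, which is what the optimizer explores.
    """
    c = constants or BalloonConstants()
    theta = np.asarray(theta, dtype=float)
    omega = 2.0 * math.pi * np.asarray(freqs, dtype=float)
    off, self_log, amp, exp_, namp, nexp, transit, decay, eps = _split_vectors(theta, n)
    idx = np.arange(n)
    A = off.copy()
    A[..., idx, idx] = -SELF_RATE * np.exp(self_log)
    T = _transfer_from_matrix(A, omega)
    kappa = c.kappa0 * np.exp(decay)
    tau = c.tau0 * np.exp(transit)
    epsv = c.epsilon0 * np.exp(eps)
    K = _kernel_from_rates(kappa, tau, epsv, c, omega)
    Gv = _power_law(amp, exp_, omega, NEURAL_SPEC_SCALE)
    Ge = NOISE_SPEC_SCALE * np.exp(np.asarray(namp, float)[..., None]) \
        * omega ** (-np.asarray(nexp, float)[..., None])
    return _assemble_csd(T, K, Gv, Ge)
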