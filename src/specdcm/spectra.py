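"""Empirical cross-spectra, representative time courses, and the
functional-connectivity baseline.

The cross-spectral density of an observed multichannel BOLD series is
estimated parametrically: a multivariate autoregressive (MAR) model is
fitted by least squares and its implied spectral matrix is evaluated on
the requested frequency grid.  Channels are linearly detrended and
standardized before fitting (the units are restored afterwards), which
mirrors the confound-corrected data this module expects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _detrend

from .forward import CrossSpectrum

__all__ = [
    "TimeSeries",
    "FCMatrix",
    "svd_timeseries",
    "estimate_csd",
    "fisher_fc",
]

DEFAULT_MAR_ORDER = 8


@dataclass
class TimeSeries:
    """A multichannel BOLD series (volumes x channels) with its TR."""

    data: np.ndarray
    tr: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x channels)")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.labels is None:
            self.labels = [f"ch_{i}" for i in range(self.data.shape[1])]
        elif len(self.labels) != self.data.shape[1]:
            raise ValueError("labels must match the number of channels")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Fisher z-transformed Pearson correlations; diagonal excluded (NaN)."""

    labels: list[str]
    z_values: np.ndarray

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        n = self.z_values.shape[0]
        if self.z_values.shape != (n, n) or len(self.labels) != n:
            raise ValueError("z_values must be square and match labels")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.z_values[off])):
            raise ValueError("off-diagonal z values must be finite")
        if not np.allclose(self.z_values[off],
                           self.z_values.T[off], atol=1e-12):
            raise ValueError("z_values must be symmetric")

    def upper_values(self) -> tuple[list[str], np.ndarray]:
        """Pair labels and z values of the strict upper triangle."""
        n = self.z_values.shape[0]
        idx = np.triu_indices(n, k=1)
        names = [f"{self.labels[i]}~{self.labels[j]}" for i, j in zip(*idx)]
        return names, self.z_values[idx]


def svd_timeseries(voxel_matrix: np.ndarray) -> np.ndarray:
    """Representative series of a voxel block: the first principal
    component of its singular value decomposition.

    Returns the first left singular vector scaled by its singular value,
    with the sign fixed so that its correlation with the voxel-mean
    series is non-negative.
    """
    X = np.asarray(voxel_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("voxel matrix must be (>=3 volumes, >=2 voxels)")
    if not np.any(X):
        raise ValueError("voxel matrix is identically zero")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rep = U[:, 0] * s[0]
    mean = X.mean(axis=1)
    if np.dot(rep - rep.mean(), mean - mean.mean()) < 0:
        rep = -rep
    return rep


def estimate_csd(ts: TimeSeries, order: int = DEFAULT_MAR_ORDER,
                 freqs=None) -> CrossSpectrum:
    """Parametric cross-spectral density via a least-squares MAR fit.

    The spectral matrix of the fitted MAR(p) model,

        S(f) = dt/(2 pi) * H(f) Sigma H(f)^H,
        H(f) = (I - sum_j Phi_j exp(-i 2 pi f dt j))^-1,

    is evaluated on ``freqs`` (Hz) and rescaled to the original channel
    units.  The density convention matches :mod:`specdcm.forward`
    (two-sided, per rad/s).
    """
    from statsmodels.tsa.ar_model import AutoReg
    from statsmodels.tsa.vector_ar.var_model import VAR

    if freqs is None:
        raise ValueError("freqs must be provided")
    freqs = np.asarray(freqs, dtype=float)
    k = ts.n_channels
    T = ts.n_volumes
    if T <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} volumes, got {T}")
    if T < order * k + 1:
        warnings.warn(
            f"{T} volumes is below the order*channels={order * k} guideline; "
            "the MAR fit may be poorly determined", stacklevel=2)

    x = _detrend(ts.data, axis=0)
    std = x.std(axis=0, ddof=1)
    if np.any(std == 0):
        raise ValueError("constant channel after detrending")
    x = x / std

    # condition of the lagged design matrix
    Z = np.hstack([x[order - j - 1:T - j - 1] for j in range(order)])
    cond = np.linalg.cond(Z)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"ill-conditioned MAR regression (condition number {cond:.3g})")

    if k == 1:
        res = AutoReg(x[:, 0], lags=order, trend="n").fit()
        coefs = res.params.reshape(order, 1, 1)
        resid = res.resid
        sigma = np.atleast_2d(resid @ resid / resid.size)
    else:
        res = VAR(x).fit(maxlags=order, trend="n")
        coefs = res.coefs  # (order, k, k)
        sigma = res.sigma_u
    lags = np.arange(1, order + 1)
    ph = np.exp(-2j * math.pi * freqs[:, None] * ts.tr * lags)  # (nf, order)
    Aw = np.eye(k) - np.einsum("fl,lij->fij", ph, coefs)
    H = np.linalg.inv(Aw)
    S = ts.tr / (2.0 * math.pi) * H @ sigma @ H.conj().transpose(0, 2, 1)
    S = S * np.outer(std, std)  # restore original units
    S = 0.5 * (S + S.conj().transpose(0, 2, 1))
    return CrossSpectrum(freqs=freqs, matrices=S, labels=list(ts.labels))


def fisher_fc(ts: TimeSeries) -> FCMatrix:
    """Fisher z-transformed Pearson correlations among the channels."""
    x = ts.data
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant channel: correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    off = ~np.eye(ts.n_channels, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0 - 1e-12):
        raise ValueError("perfectly correlated channels: Fisher z undefined")
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    z = 0.5 * (z + np.where(np.isnan(z.T), z, z.T))  # enforce exact symmetry
    return FCMatrix(labels=list(ts.labels), z_values=z)
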