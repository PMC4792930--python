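"""Bayesian model selection (fixed- and random-effects) and Bayesian
model averaging over a model space.

Fixed-effects selection treats the model as shared across subjects:
posterior model probabilities are the softmax of free energies summed
over subjects.  Random-effects selection treats the model as a random
variable per subject and fits a Dirichlet distribution over model
frequencies by variational Bayes; exceedance probabilities (the
probability a model is more frequent than every other) are computed by
Monte-Carlo sampling from the fitted Dirichlet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, softmax

__all__ = [
    "EvidenceTable",
    "BMSResult",
    "BMAResult",
    "fixed_effects_bms",
    "random_effects_bms",
    "bma",
]


@dataclass
class EvidenceTable:
    """Per-subject, per-model free energies (nats)."""

    free_energies: np.ndarray  # (n_subjects, n_models)
    subject_ids: list[str] | None = None
    model_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.free_energies = np.atleast_2d(np.asarray(self.free_energies, float))
        if not np.all(np.isfinite(self.free_energies)):
            raise ValueError("free energies must be finite")
        ns, nm = self.free_energies.shape
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:04d}" for i in range(ns)]
        if self.model_ids is None:
            self.model_ids = [f"model_{m:03d}" for m in range(nm)]
        if len(self.subject_ids) != ns or len(self.model_ids) != nm:
            raise ValueError("id lists must match the evidence matrix shape")

    @property
    def n_subjects(self) -> int:
        return self.free_energies.shape[0]

    @property
    def n_models(self) -> int:
        return self.free_energies.shape[1]


@dataclass
class BMSResult:
    expected_probs: np.ndarray
    exceedance_probs: np.ndarray
    dirichlet_alpha: np.ndarray | None
    method: str

    def __post_init__(self) -> None:
        for name in ("expected_probs", "exceedance_probs"):
            v = np.asarray(getattr(self, name), float)
            setattr(self, name, v)
            if abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")


@dataclass
class BMAResult:
    """Model-averaged posterior moments per subject."""

    means: np.ndarray      # (n_subjects, p)
    variances: np.ndarray  # (n_subjects, p)
    weights: np.ndarray    # (n_subjects, n_models), rows sum to 1

    def __post_init__(self) -> None:
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("weights must sum to 1 per subject")


def fixed_effects_bms(table: EvidenceTable) -> BMSResult:
    """Softmax of group-summed free energies; exceedance is the argmax
    indicator (under fixed effects one model generates every subject)."""
    if table.n_subjects < 1:
        raise ValueError("need at least one subject")
    total = table.free_energies.sum(axis=0)
    probs = softmax(total - total.max())
    exceed = np.zeros_like(probs)
    exceed[int(np.argmax(total))] = 1.0
    return BMSResult(expected_probs=probs, exceedance_probs=exceed,
                     dirichlet_alpha=None, method="fixed")


def random_effects_bms(table: EvidenceTable, alpha0: float = 1.0,
                       rng: np.random.Generator | int | None = None,
                       n_samples: int = 1_000_000, tol: float = 1e-6,
                       max_iter: int = 10_000) -> BMSResult:
    """Random-effects BMS by variational Bayes over a Dirichlet prior.

    Iterates the standard updates: subject-wise model posteriors
    ``g_nk proportional to exp(F_nk + digamma(alpha_k) - digamma(sum alpha))``
    and Dirichlet counts ``alpha = alpha0 + sum_n g_n``; exceedance
    probabilities are estimated by seeded Monte-Carlo sampling from the
    fitted Dirichlet.
    """
    if table.n_subjects < 2:
        warnings.warn("random-effects BMS with fewer than 2 subjects is "
                      "weakly determined", stacklevel=2)
    F = table.free_energies
    nm = table.n_models
    alpha = np.full(nm, alpha0 + table.n_subjects / nm)
    for _ in range(max_iter):
        logu = F + digamma(alpha) - digamma(alpha.sum())
        g = softmax(logu, axis=1)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(f"random-effects BMS did not converge in {max_iter} iterations")

    rng = np.random.default_rng(rng)
    counts = np.zeros(nm, dtype=np.int64)
    remaining = int(n_samples)
    while remaining > 0:
        chunk = min(remaining, 100_000)
        draws = rng.dirichlet(alpha, size=chunk)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=nm)
        remaining -= chunk
    exceed = counts / counts.sum()
    return BMSResult(expected_probs=alpha / alpha.sum(), exceedance_probs=exceed,
                     dirichlet_alpha=alpha, method="random")


def bma(means: np.ndarray, variances: np.ndarray, probs: np.ndarray,
        occam_window: float | None = None) -> BMAResult:
    """Bayesian model averaging by moment matching.

    Parameters
    ----------
    means, variances : (n_subjects, n_models, p)
        Per-subject, per-model posterior means and marginal variances.
        Parameters absent from a model enter as exact zeros.
    probs : (n_subjects, n_models) or (n_models,)
        Model probabilities; normalized per subject.
    occam_window : float, optional
        If given, models whose log-probability falls more than this many
        nats below the per-subject best are dropped and the weights are
        renormalized.  Default keeps every model.

    The averaged mean is ``sum_m w_m mu_m`` and the averaged variance is
    the mixture variance ``sum_m w_m (sigma_m^2 + mu_m^2) - mean^2``.
    """
    means = np.asarray(means, float)
    variances = np.asarray(variances, float)
    if means.ndim != 3 or means.shape != variances.shape:
        raise ValueError("means and variances must both be (n_subjects, n_models, p)")
    ns, nm, p = means.shape
    w = np.asarray(probs, float)
    if w.ndim == 1:
        w = np.broadcast_to(w, (ns, nm)).copy()
    if w.shape != (ns, nm):
        raise ValueError("probs must be (n_subjects, n_models) or (n_models,)")
    if np.any(w < 0):
        raise ValueError("probs must be non-negative")
    w = w / w.sum(axis=1, keepdims=True)
    if occam_window is not None:
        with np.errstate(divide="ignore"):
            logw = np.log(w)
        keep = logw >= logw.max(axis=1, keepdims=True) - occam_window
        w = np.where(keep, w, 0.0)
        w = w / w.sum(axis=1, keepdims=True)
    avg_mean = np.einsum("sm,smp->sp", w, means)
    second = np.einsum("sm,smp->sp", w, variances + means ** 2)
    avg_var = np.clip(second - avg_mean ** 2, 0.0, None)
    return BMAResult(means=avg_mean, variances=avg_var, weights=w)
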