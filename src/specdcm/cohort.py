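"""Seeded synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
population-based sample approximately uniform in age over 18-88 years,
each subject with a stable spectral generative model whose parameters
drift linearly with age, short resting-state BOLD runs (255 volumes at
TR = 1.97 s by default), demographic covariates, and six cognitive
scores generated from a connectivity profile with an age-moderated
slope.

The simulator synthesizes BOLD directly in the frequency domain (random
Gaussian Fourier coefficients scaled by a matrix square root of the
predicted cross-spectral density), so the population spectrum of the
simulated series equals the forward model's prediction exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import (
    BalloonConstants,
    CrossSpectrum,
    SpectralModel,
    model_to_vector,
    n_parameters,
    parameter_names,
    predicted_csd,
    vector_to_model,
    NEURAL_EXPONENT_REF,
)

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "COGNITIVE_TESTS",
    "baseline_vector",
    "draw_subject_parameters",
    "simulate_bold",
    "generate_cognition",
    "generate_cohort",
    "mean_drift_check",
    "write_cohort",
    "read_timeseries",
]

#: The six cognitive measures emulated by the generator (fluid
#: intelligence, crystallized intelligence, working memory, response
#: consistency, multitasking, face recognition).
COGNITIVE_TESTS = ["cattell", "spot_the_word", "vstm", "response_consistency",
                   "hotel", "benton_faces"]


def _default_age_effects() -> dict[str, float]:
    """Linear slopes (per year of age) on generative parameters.

    Directions follow the empirical aging narrative: self-inhibition
    increases in every node, hemodynamic decay *times* increase (so the
    decay-rate log-scaling decreases), the fluctuation exponent rises in
    the first (midline) node, the fluctuation amplitude falls in one
    lateral node, and a couple of between-node couplings drift.
    Magnitudes are chosen so the spread over a 70-year range stays within
    roughly two prior standard deviations of the inversion's priors.
    """
    return {
        "self_0": 0.0030, "self_1": 0.0030, "self_2": 0.0030,
        "decay_0": -0.0020, "decay_1": -0.0020, "decay_2": -0.0020,
        "exp_0": 0.0040,
        "amp_1": -0.0040,
        "a_0_1": -0.0020,
        "a_2_0": 0.0020,
    }


def _default_param_sd() -> dict[str, float]:
    """Between-subject standard deviations around the age trend."""
    return {"a": 0.03, "self": 0.03, "amp": 0.05, "exp": 0.05,
            "noise": 0.02, "transit": 0.03, "decay": 0.03, "epsilon": 0.02}


def _default_profile_weights() -> dict[str, float]:
    """Linear map from true parameters to the latent connectivity profile."""
    return {"a_0_1": 1.0, "self_0": -1.0}


@dataclass
class CohortConfig:
    """Study-condition configuration of the synthetic cohort."""

    n_subjects: int = 200
    age_range: tuple[float, float] = (18.0, 88.0)
    n_nodes: int = 3
    n_volumes: int = 255
    tr: float = 1.97
    age_effects: dict[str, float] = field(default_factory=_default_age_effects)
    param_sd: dict[str, float] = field(default_factory=_default_param_sd)
    moderation_strength: float = 0.3
    cognition_weights: tuple[float, ...] = (0.5, 0.4, 0.45, 0.35, 0.3, 0.4)
    cognition_age_slopes: tuple[float, ...] = (-0.5, -0.1, -0.45, -0.35, -0.4, -0.3)
    cognition_noise_sd: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8, 0.8, 0.8)
    profile_weights: dict[str, float] = field(default_factory=_default_profile_weights)
    motion_age_slope: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes <= 16:
            raise ValueError("n_volumes must exceed 16")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy low < high")
        for name in ("cognition_weights", "cognition_age_slopes", "cognition_noise_sd"):
            if len(getattr(self, name)) != len(COGNITIVE_TESTS):
                raise ValueError(f"{name} must have {len(COGNITIVE_TESTS)} entries")

    @property
    def age_midpoint(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass
class SubjectRecord:
    """One synthetic participant."""

    id: str
    age: float
    gender: int
    handedness: float
    education: int
    head_motion: float
    cognitive_scores: np.ndarray
    true_params: SpectralModel | None = None

    def __post_init__(self) -> None:
        self.cognitive_scores = np.asarray(self.cognitive_scores, dtype=float)
        if self.cognitive_scores.shape != (len(COGNITIVE_TESTS),):
            raise ValueError("cognitive_scores must have six entries")


@dataclass
class Cohort:
    config: CohortConfig
    table: pd.DataFrame
    subjects: list[SubjectRecord]
    series: list[np.ndarray] | None = None

    @property
    def true_param_matrix(self) -> np.ndarray:
        cols = [f"true_{n}" for n in parameter_names(self.config.n_nodes)]
        return self.table[cols].to_numpy()


def baseline_vector(n: int) -> np.ndarray:
    """Population-baseline parameter vector for an n-node network.

    Off-diagonal couplings are moderate and row-sum bounded below the
    0.5 Hz self-decay rate, so the baseline is comfortably stable; all
    log-scalings are zero (reference values) and the power-law exponents
    sit at the reference exponent.
    """
    names = parameter_names(n)
    vec = np.zeros(n_parameters(n))
    if n == 3:
        off = {"a_0_1": 0.25, "a_0_2": -0.15, "a_1_0": 0.20, "a_1_2": 0.10,
               "a_2_0": -0.10, "a_2_1": 0.15}
        for k, v in off.items():
            vec[names.index(k)] = v
    else:
        for i in range(n):
            j = (i + 1) % n
            if i != j:
                vec[names.index(f"a_{i}_{j}")] = 0.15 if i % 2 == 0 else -0.15
    for i in range(n):
        vec[names.index(f"exp_{i}")] = NEURAL_EXPONENT_REF
    vec[names.index("noise_exp")] = NEURAL_EXPONENT_REF
    return vec


def _sd_for(name: str, param_sd: dict[str, float]) -> float:
    if name in param_sd:
        return param_sd[name]
    key = name.split("_")[0] if not name.startswith("noise") else "noise"
    return param_sd.get(key, 0.0)


def draw_subject_parameters(config: CohortConfig, age: float,
                            rng: np.random.Generator,
                            constants: BalloonConstants | None = None,
                            adjacency: np.ndarray | None = None
                            ) -> SpectralModel:
    """Draw one stable subject-level model at the given age.

    The expected value of each parameter is baseline + slope * (age -
    midpoint of the age range); between-subject variation is Gaussian.
    Unstable draws are rejected and redrawn (at most 100 attempts).
    An optional binary ``adjacency`` zeroes the between-node couplings
    absent from a model specification (mean and spread), so cohorts can
    be generated from any member of a model space.
    """
    lo, hi = config.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside configured range {config.age_range}")
    n = config.n_nodes
    names = parameter_names(n)
    mean = baseline_vector(n)
    for pname, slope in config.age_effects.items():
        if pname not in names:
            raise KeyError(f"unknown parameter in age_effects: {pname!r}")
        mean[names.index(pname)] += slope * (age - config.age_midpoint)
    sds = np.array([_sd_for(nm, config.param_sd) for nm in names])
    if adjacency is not None:
        adj = np.asarray(adjacency, dtype=int)
        for i in range(n):
            for j in range(n):
                if i != j and adj[i, j] == 0:
                    idx = names.index(f"a_{i}_{j}")
                    mean[idx] = 0.0
                    sds[idx] = 0.0
    for _ in range(100):
        vec = mean + rng.normal(0.0, 1.0, size=mean.shape) * sds
        model = vector_to_model(vec, n, constants)
        if model.is_stable():
            return model
    worst = max(config.age_effects.items(), key=lambda kv: abs(kv[1]), default=(None, 0.0))
    raise RuntimeError(
        "no stable parameter draw in 100 attempts; largest configured "
        f"age slope is {worst[0]!r} = {worst[1]}"
    )


def simulate_bold(model: SpectralModel, n_volumes: int, tr: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Synthesize a BOLD run whose population CSD equals ``predicted_csd``.

    Frequency-domain synthesis: for each positive DFT frequency, draw a
    circularly-symmetric complex Gaussian vector, colour it with a matrix
    square root of the predicted cross-spectral density, enforce
    Hermitian symmetry and inverse-transform.  The DC component is zero
    (mean-removed series).  Returns a real (n_volumes, n_nodes) array.
    """
    if not model.is_stable():
        raise ValueError("model is unstable")
    N, n = int(n_volumes), model.n_nodes
    freqs = np.fft.rfftfreq(N, d=tr)[1:]  # positive frequencies incl. Nyquist
    G = predicted_csd(model, freqs).matrices
    # Hermitian matrix square root per frequency
    w, V = np.linalg.eigh(0.5 * (G + G.conj().transpose(0, 2, 1)))
    L = V * np.sqrt(np.clip(w, 0.0, None))[:, None, :]
    # E[X_k X_k^H] = (2 pi N / dt) * G(f_k)  (angular-frequency density)
    scale = math.sqrt(2.0 * math.pi * N / tr)
    z = (rng.standard_normal((freqs.size, n)) +
         1j * rng.standard_normal((freqs.size, n))) / math.sqrt(2.0)
    X = scale * np.einsum("fij,fj->fi", L, z)
    spec = np.zeros((N // 2 + 1, n), dtype=complex)
    spec[1:] = X
    if N % 2 == 0:
        # the Nyquist bin of a real series must itself be real
        spec[-1] = math.sqrt(2.0) * X[-1].real
    return np.fft.irfft(spec, n=N, axis=0)


def generate_cognition(profile: np.ndarray, age: np.ndarray,
                       config: CohortConfig, rng: np.random.Generator
                       ) -> np.ndarray:
    """Cognitive scores with an age-moderated dependence on the profile.

    score_k = w_k * profile * (1 + lambda * z(age)) + beta_k * z(age) + noise,

    where ``z(age)`` is age standardized within the cohort, ``lambda`` is
    the moderation strength and the profile is standardized before use.
    """
    profile = np.asarray(profile, dtype=float)
    age = np.asarray(age, dtype=float)
    if profile.shape != age.shape:
        raise ValueError("profile and age must have the same length")
    z_age = (age - age.mean()) / age.std() if age.std() > 0 else np.zeros_like(age)
    if profile.std() > 0:
        z_prof = (profile - profile.mean()) / profile.std()
    else:
        z_prof = np.zeros_like(profile)
    lam = config.moderation_strength
    w = np.asarray(config.cognition_weights)
    beta = np.asarray(config.cognition_age_slopes)
    sd = np.asarray(config.cognition_noise_sd)
    base = np.outer(z_prof * (1.0 + lam * z_age), w) + np.outer(z_age, beta)
    return base + rng.standard_normal(base.shape) * sd


def _profile_from_params(params: np.ndarray, names: list[str],
                         weights: dict[str, float]) -> np.ndarray:
    prof = np.zeros(params.shape[0])
    for pname, w in weights.items():
        prof += w * params[:, names.index(pname)]
    return prof


def generate_cohort(config: CohortConfig, with_series: bool = False) -> Cohort:
    """Generate the full seeded cohort.

    All randomness flows from ``config.seed`` through named substreams
    (ages/covariates, per-subject parameters, per-subject series,
    cognition), so identical configs produce bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    ss_demo, ss_params, ss_series, ss_cog = root.spawn(4)
    rng_demo = np.random.default_rng(ss_demo)
    n, ns = config.n_nodes, config.n_subjects
    names = parameter_names(n)

    lo, hi = config.age_range
    ages = np.sort(rng_demo.uniform(lo, hi, size=ns))
    gender = rng_demo.integers(0, 2, size=ns)
    handedness = np.clip(rng_demo.normal(70.0, 40.0, size=ns), -100.0, 100.0)
    education = rng_demo.integers(1, 6, size=ns)
    motion = np.clip(
        0.15 + config.motion_age_slope * (ages - config.age_midpoint)
        + rng_demo.normal(0.0, 0.05, size=ns), 0.01, None)

    param_rngs = [np.random.default_rng(s) for s in ss_params.spawn(ns)]
    models = [draw_subject_parameters(config, a, r)
              for a, r in zip(ages, param_rngs)]
    params = np.stack([model_to_vector(m) for m in models])

    series = None
    if with_series:
        series_rngs = [np.random.default_rng(s) for s in ss_series.spawn(ns)]
        series = [simulate_bold(m, config.n_volumes, config.tr, r)
                  for m, r in zip(models, series_rngs)]

    profile = _profile_from_params(params, names, config.profile_weights)
    cognition = generate_cognition(profile, ages, config,
                                   np.random.default_rng(ss_cog))

    subjects = [
        SubjectRecord(id=f"sub-{i:04d}", age=float(ages[i]), gender=int(gender[i]),
                      handedness=float(handedness[i]), education=int(education[i]),
                      head_motion=float(motion[i]),
                      cognitive_scores=cognition[i], true_params=models[i])
        for i in range(ns)
    ]
    table = pd.DataFrame({
        "id": [s.id for s in subjects],
        "age": ages, "gender": gender, "handedness": handedness,
        "education": education, "head_motion": motion, "profile": profile,
    })
    for k, t in enumerate(COGNITIVE_TESTS):
        table[t] = cognition[:, k]
    for j, pname in enumerate(names):
        table[f"true_{pname}"] = params[:, j]
    return Cohort(config=config, table=table, subjects=subjects, series=series)


def mean_drift_check(series: np.ndarray, n_se: float = 5.0) -> bool:
    """Crude stationarity diagnostic: first-half vs second-half mean
    difference below ``n_se`` standard errors on every channel.

    The standard error uses an AR(1) effective-sample-size correction,
    since BOLD-like series are strongly autocorrelated and the naive
    iid standard error would reject stationary runs.
    """
    y = np.asarray(series, dtype=float)
    h = y.shape[0] // 2
    for ch in range(y.shape[1]):
        a, b = y[:h, ch], y[h:2 * h, ch]
        r1 = float(np.corrcoef(y[:-1, ch], y[1:, ch])[0, 1])
        r1 = min(max(r1, -0.99), 0.99)
        neff = max(h * (1.0 - r1) / (1.0 + r1), 2.0)
        se = math.sqrt(a.var(ddof=1) / neff + b.var(ddof=1) / neff)
        if abs(a.mean() - b.mean()) >= n_se * se:
            return False
    return True


# ---------------------------------------------------------------------------
# text serialization


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort as delimited text: one time-series file per subject
    (header carries TR and node labels), a covariate/cognition table, and
    a JSON file of true generative parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    cohort.table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    names = parameter_names(cfg.n_nodes)
    truth = {s.id: dict(zip(names, map(float, model_to_vector(s.true_params))))
             for s in cohort.subjects if s.true_params is not None}
    (outdir / "true_parameters.json").write_text(json.dumps(truth, indent=1))
    if cohort.series is not None:
        ts_dir = outdir / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        labels = [f"node_{i}" for i in range(cfg.n_nodes)]
        for s, y in zip(cohort.subjects, cohort.series):
            path = ts_dir / f"{s.id}_bold.tsv"
            with open(path, "w") as fh:
                fh.write(f"# tr={cfg.tr}\n")
                fh.write("\t".join(labels) + "\n")
                np.savetxt(fh, y, delimiter="\t", fmt="%.10g")


def read_timeseries(path: str | Path):
    """Read a delimited-text BOLD file written by :func:`write_cohort`.

    Returns ``(data, tr, labels)``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "tr=" not in header:
            raise ValueError(f"{path}: missing '# tr=' header")
        tr = float(header.split("tr=")[1].split()[0])
        labels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(f"{path}: column count does not match labels")
    return data, tr, labels
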