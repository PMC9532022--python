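"""Synthetic touchscreen tracing cohorts.

Generates cohorts with the statistical structure that a finger-tracing crowd
experiment exhibits, so the whole pipeline is testable without real data:

* **Systematic subject bias** — each subject deviates from the template in a
  repeatable, smooth, subject-specific way.  Modelled as a low-frequency
  sinusoidal offset field along the curve normal, zero-mean across subjects,
  so self-aggregation cannot cancel it but a crowd can.
* **Trial-to-trial noise** — smooth within-trial wander, modelled as a
  stationary Ornstein-Uhlenbeck process in arc length (correlation length a
  few cm), so successive passes over the same spot deviate independently.
* **Sensor jitter** — small isotropic per-sample noise.
* **Age-dependent skill** — bias and wander scales shrink with age as
  ``(age / 10.5) ** -age_exponent``, reproducing the maturation of motor
  control between 6 and 18 years.
* **Outlier subjects** — a small fraction of subjects get a much larger bias
  amplitude plus a constant one-sided offset along the normal (tracing a
  systematically displaced copy of the shape).  One-sidedness is what makes
  outliers dangerous to mean aggregation; zero-mean deviations, however
  large, average out in a big crowd.
* **Population bias** — a small systematic offset field shared by all
  subjects of a template (people cut corners in similar places).  This is
  what makes the crowd error saturate at a floor as the crowd grows instead
  of shrinking to zero indefinitely.

The finger advances at constant speed, completing ``passes`` laps of the
template in 30 s; sampling is 85 Hz.  Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .io import Cohort, SubjectMeta, TraceRecord
from .templates import TEMPLATE_NAMES, Template, default_templates

__all__ = ["SyntheticConfig", "BiasField", "sample_bias_field", "simulate_trace",
           "generate_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a synthetic tracing cohort.

    Scales are mm at the reference age (10.5 y) unless noted.
    """

    n_subjects: int = 200
    age_range: tuple[float, float] = (6.0, 18.0)
    bias_amplitude: float = 2.5  # subject-bias field scale, mm
    bias_modes: int = 3  # number of sinusoidal components
    population_bias: float = 1.0  # shared (crowd-level) bias scale, mm
    age_exponent: float = 1.0  # skill scaling (age/10.5)**-exponent
    age_reference: float = 10.5  # years
    trial_noise: float = 1.5  # wander (trial-to-trial) scale, mm
    wander_correlation_length: float = 20.0  # mm of arc
    jitter: float = 0.3  # per-sample sensor noise, mm
    speed: float | None = None  # mm/s; None = derive from passes_range
    passes_range: tuple[float, float] = (7.0, 11.0)  # laps per 30 s trace
    sample_rate: float = 85.0  # Hz
    duration: float = 30.0  # s
    outlier_fraction: float = 0.02
    outlier_scale: float = 12.0  # bias amplitude of outlier subjects, mm
    outlier_drift: float = 8.0  # constant one-sided normal offset, mm
    seed: int = 0
    templates: tuple[str, ...] = TEMPLATE_NAMES
    n_dense: int = 2000

    def __post_init__(self):
        for name in ("bias_amplitude", "trial_noise", "jitter",
                     "wander_correlation_length", "outlier_scale",
                     "population_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")

    def skill_factor(self, age: float) -> float:
        """Multiplier applied to bias and wander scales for a given age."""
        return float((age / self.age_reference) ** (-self.age_exponent))


@dataclass
class BiasField:
    """A subject's systematic offset field along one template's normal.

    ``offset(s)`` is periodic in the template arc length L and zero-mean
    across subjects at every arc position (random signs and phases).
    """

    subject_id: str
    template_name: str
    amplitudes: np.ndarray  # (K,) mm
    frequencies: np.ndarray  # (K,) integer cycles per lap
    phases: np.ndarray  # (K,) radians
    length: float  # template arc length L, mm
    drift: float = 0.0  # constant signed normal offset, mm

    def offset(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        phase = 2.0 * np.pi * np.outer(s, self.frequencies) / self.length
        return np.sin(phase + self.phases) @ self.amplitudes + self.drift

    @property
    def variance(self) -> float:
        """Arc-averaged variance of the field about its drift,
        sum(a_k^2) / 2."""
        return float(np.sum(self.amplitudes**2) / 2.0)


def sample_bias_field(
    subject: SubjectMeta,
    template: Template,
    config: SyntheticConfig,
    rng: np.random.Generator,
    amplitude: float | None = None,
    drift: float = 0.0,
    fixed_rms: bool = False,
) -> BiasField:
    """Draw a subject's bias field for one template.

    Mode amplitudes are zero-mean Gaussian with total field variance equal to
    ``amplitude**2`` (default: ``bias_amplitude`` scaled by the subject's
    skill factor); frequencies are 1..bias_modes cycles per lap, phases
    uniform.  With ``fixed_rms`` the realized arc-RMS of the field is pinned
    exactly to ``amplitude`` (random direction and phases only) — used for
    the population field, whose single realization would otherwise make the
    simulated condition a lottery over the configured one.
    """
    if amplitude is None:
        amplitude = config.bias_amplitude
        if subject.age is not None:
            amplitude *= config.skill_factor(subject.age)
    K = config.bias_modes
    # Var(a sin(phase)) = E[a^2]/2 per mode; total field variance amplitude^2.
    amps = rng.normal(0.0, amplitude * np.sqrt(2.0 / K) if K else 0.0, size=K)
    if fixed_rms and K and amplitude > 0:
        norm = np.sqrt(np.sum(amps**2))
        if norm > 0:
            amps *= amplitude * np.sqrt(2.0) / norm
    return BiasField(
        subject_id=subject.subject_id,
        template_name=template.name,
        amplitudes=amps,
        frequencies=np.arange(1, K + 1, dtype=float),
        phases=rng.uniform(0.0, 2.0 * np.pi, size=K),
        length=template.total_length,
        drift=drift,
    )


def _ou_wander(n: int, step: float, corr_length: float, scale: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path sampled every ``step`` mm of arc."""
    if scale == 0.0 or n == 0:
        return np.zeros(n)
    if corr_length <= 0.0:
        return rng.normal(0.0, scale, size=n)
    alpha = np.exp(-step / corr_length)
    innov = rng.standard_normal(n)
    innov[0] *= scale
    innov[1:] *= scale * np.sqrt(1.0 - alpha**2)
    return lfilter([1.0], [1.0, -alpha], innov)


def simulate_trace(
    subject: SubjectMeta,
    template: Template,
    config: SyntheticConfig,
    rng: np.random.Generator,
    bias_field: BiasField | None = None,
    population_field: BiasField | None = None,
) -> TraceRecord:
    """Simulate one 30 s trace of a template by one subject.

    The finger moves along the template at constant speed, displaced along
    the local normal by subject bias (+ optional shared population bias) +
    wander, plus isotropic jitter.
    """
    if bias_field is None:
        bias_field = sample_bias_field(subject, template, config, rng)
    n = int(round(config.sample_rate * config.duration))
    t = np.arange(n) / config.sample_rate
    L = template.total_length
    if config.speed is not None:
        v = config.speed
    else:
        passes = rng.uniform(*config.passes_range)
        v = passes * L / config.duration
    s = rng.uniform(0.0, L) + v * t  # unwrapped arc position

    base = template.point_at(s)
    normal = template.normal_at(s)
    skill = config.skill_factor(subject.age) if subject.age is not None else 1.0
    wander = _ou_wander(
        n, v / config.sample_rate, config.wander_correlation_length,
        config.trial_noise * skill, rng,
    )
    displacement = bias_field.offset(s) + wander
    if population_field is not None:
        displacement = displacement + population_field.offset(s)
    points = base + normal * displacement[:, None]
    if config.jitter > 0:
        points = points + rng.normal(0.0, config.jitter, size=points.shape)
    return TraceRecord(
        subject_id=subject.subject_id,
        template_name=template.name,
        timestamps=t,
        points=points,
    )


def generate_cohort(config: SyntheticConfig,
                    templates: dict[str, Template] | None = None) -> Cohort:
    """Generate a full cohort: every configured template for every subject.

    Deterministic under ``config.seed``; each (subject, template) pair uses
    an independent substream so cohorts are reproducible regardless of
    generation order.
    """
    if templates is None:
        templates = {
            k: v for k, v in default_templates(config.n_dense).items()
            if k in config.templates
        }
    root = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    ages = root.uniform(lo, hi, size=config.n_subjects)
    handed = root.choice(["right", "left"], p=[0.9, 0.1], size=config.n_subjects)
    gender = root.choice(["female", "male"], p=[0.56, 0.44], size=config.n_subjects)
    is_outlier = root.random(config.n_subjects) < config.outlier_fraction

    # One shared offset field per template: the crowd-level systematic error
    # that survives aggregation (the crowd-error floor).
    pop_fields: dict[str, BiasField | None] = {}
    crowd_meta = SubjectMeta(subject_id="__population__")
    for ti, (name, template) in enumerate(templates.items()):
        if config.population_bias > 0:
            pop_rng = np.random.default_rng([config.seed, 2**20, ti])
            pop_fields[name] = sample_bias_field(
                crowd_meta, template, config, pop_rng,
                amplitude=config.population_bias, fixed_rms=True,
            )
        else:
            pop_fields[name] = None

    subjects = [
        SubjectMeta(subject_id=f"S{idx:04d}", age=float(ages[idx]),
                    handedness=str(handed[idx]), gender=str(gender[idx]))
        for idx in range(config.n_subjects)
    ]
    traces = []
    for si, subject in enumerate(subjects):
        for ti, (name, template) in enumerate(templates.items()):
            rng = np.random.default_rng([config.seed, si, ti])
            amplitude = config.outlier_scale if is_outlier[si] else None
            drift = config.outlier_drift if is_outlier[si] else 0.0
            fld = sample_bias_field(subject, template, config, rng,
                                    amplitude=amplitude, drift=drift)
            traces.append(
                simulate_trace(subject, template, config, rng, fld,
                               population_field=pop_fields[name])
            )
    return Cohort(subjects=subjects, traces=traces, templates=dict(templates))


def zero_bias_config(**overrides) -> SyntheticConfig:
    """Convenience: independent-noise-only cohort (no subject or population
    bias, no outliers, age-independent skill)."""
    base = SyntheticConfig(bias_amplitude=0.0, population_bias=0.0,
                           outlier_fraction=0.0, age_exponent=0.0)
    return replace(base, **overrides)
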