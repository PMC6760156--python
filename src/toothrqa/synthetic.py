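"""Synthetic twin cohorts with quasi-periodic elemental tooth profiles.

Laser-ablation tooth sampling yields, for each subject and element, a
metal:Ca ratio sampled along growth increments datable relative to birth
(about 152 locations on average, spanning roughly -120 to +200 days).
This module emulates that output format so the downstream recurrence,
mixed-model and dimensionality-reduction stages can be exercised and
validated without access to any cohort data.

The generative signal model is deliberately minimal: a sinusoid whose
phase undergoes Brownian diffusion, plus AR(1) observation noise, with a
single ``regularity`` knob in [0, 1] controlling both the phase-diffusion
step and the noise level.  ``regularity`` maps monotonically onto the
recurrence features analysed downstream (determinism, mean diagonal
length, entropy), so diagnosis-specific deficits are injected on the
generative knob rather than on the features themselves — parameter
recovery tests are therefore non-circular.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError

__all__ = [
    "Zygosity",
    "Diagnosis",
    "SubjectRecord",
    "ElementalTimeSeries",
    "SignalParams",
    "CohortConfig",
    "generate_element_series",
    "generate_cohort",
    "scaled_group_sizes",
    "DEFAULT_ELEMENTS",
    "DEFAULT_GROUP_SIZES",
    "ELEMENT_BASE_LEVELS",
]


class Zygosity(str, enum.Enum):
    MZ = "MZ"
    DZ = "DZ"
    SINGLETON = "SINGLETON"


class Diagnosis(str, enum.Enum):
    TD = "TD"
    ADHD = "ADHD"
    ASD = "ASD"
    COMORBID = "COMORBID"


#: Default single elements plus calcium (needed for the Zn-Ca pairing).
DEFAULT_ELEMENTS = ("Zn", "Cu", "Pb", "Co", "V", "Li", "Sn", "Mn", "Ca")

#: Observed diagnosis counts in the motivating twin cohort (74 subjects).
DEFAULT_GROUP_SIZES = {
    Diagnosis.TD: 41,
    Diagnosis.ADHD: 13,
    Diagnosis.ASD: 8,
    Diagnosis.COMORBID: 12,
}

#: Plausible metal:Ca ratio scales per element.  Dentine trace metals sit
#: orders of magnitude below calcium; downstream RQA calibrates its radius
#: per matrix, so only the relative within-series dynamics matter.
ELEMENT_BASE_LEVELS = {
    "Zn": 5e-4,
    "Cu": 1e-5,
    "Pb": 2e-6,
    "Co": 5e-7,
    "V": 1e-6,
    "Li": 2e-6,
    "Sn": 1e-6,
    "Mn": 5e-6,
    "Ca": 1.0,
}

#: Full-scale IQ means/SDs per diagnosis group (cohort Table values).
IQ_DISTRIBUTIONS = {
    Diagnosis.ADHD: (101.15, 4.16),
    Diagnosis.ASD: (86.12, 20.97),
    Diagnosis.COMORBID: (90.75, 19.75),
    Diagnosis.TD: (99.85, 15.18),
}


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: twin-cluster membership, covariates, diagnosis."""

    subject_id: str
    pair_id: str
    zygosity: Zygosity
    sex: str  # "M" or "F"
    gestational_days: float
    birth_weight: float  # kg
    diagnosis: Diagnosis
    iq: float | None = None

    def __post_init__(self):
        if self.gestational_days <= 0:
            raise ValidationError("gestational_days must be > 0", "gestational_days")
        if self.birth_weight <= 0:
            raise ValidationError("birth_weight must be > 0", "birth_weight")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}", "sex")
        object.__setattr__(self, "zygosity", Zygosity(self.zygosity))
        object.__setattr__(self, "diagnosis", Diagnosis(self.diagnosis))


@dataclass
class ElementalTimeSeries:
    """One element's metal:Ca ratio trace for one subject.

    ``times`` are days relative to birth (negative = prenatal), strictly
    increasing; ``values`` are nonnegative ratios of the same length.
    """

    subject_id: str
    element: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("times and values must be 1-D", "times")
        if len(self.times) != len(self.values):
            raise ValidationError("times and values must have equal length", "values")
        if len(self.times) < 2:
            raise ValidationError("a series needs at least 2 samples", "times")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing", "times")
        if np.any(self.values < 0):
            raise ValidationError("ratio values must be nonnegative", "values")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SignalParams:
    """Generative parameters for one quasi-periodic ratio trace.

    regularity : float in [0, 1]
        1 = perfectly periodic.  Scales the phase-diffusion step as
        ``phase_jitter_sd * (1 - regularity)`` (radians per sqrt(day)) and
        the AR(1) innovation sd as ``noise_sd * (2 - regularity)``.
    marginal : {"additive", "lognormal"}
        Additive places the cycle and noise around ``base_level`` and
        clips at zero; lognormal exponentiates them onto a positive scale.
    """

    base_level: float = 1.0
    amplitude: float = 0.35
    period_days: float = 30.0
    regularity: float = 0.8
    phase_jitter_sd: float = 1.0
    noise_sd: float = 0.05
    ar_coeff: float = 0.3
    n_points_mean: int = 152
    day_min: float = -120.0
    day_max: float = 200.0
    marginal: str = "additive"

    def __post_init__(self):
        if not 0.0 <= self.regularity <= 1.0:
            raise ValidationError("regularity must lie in [0, 1]", "regularity")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0", "noise_sd")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValidationError("ar_coeff must lie in [0, 1)", "ar_coeff")
        if not self.day_min < 0 < self.day_max:
            raise ValidationError("need day_min < 0 < day_max", "day_min")
        if self.period_days <= 0:
            raise ValidationError("period_days must be > 0", "period_days")
        if self.n_points_mean < 2:
            raise ValidationError("n_points_mean must be >= 2", "n_points_mean")
        if self.phase_jitter_sd < 0:
            raise ValidationError("phase_jitter_sd must be >= 0", "phase_jitter_sd")
        if self.base_level < 0:
            raise ValidationError("base_level must be >= 0", "base_level")
        if self.marginal not in ("additive", "lognormal"):
            raise ValidationError("marginal must be 'additive' or 'lognormal'", "marginal")


def generate_element_series(
    params: SignalParams,
    subject_factor: float = 1.0,
    rng_seed: int = 0,
    subject_id: str = "",
    element: str = "",
) -> ElementalTimeSeries:
    """Simulate one elemental trace: sinusoid + phase diffusion + AR(1) noise.

    The number of samples is Poisson around ``n_points_mean`` (floored at
    20); days are uniformly spaced over ``[day_min, day_max]``.  The phase
    walk is Brownian with per-step sd
    ``phase_jitter_sd * (1 - regularity) * sqrt(dt)``.  Deterministic
    given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    n = max(20, int(rng.poisson(params.n_points_mean)))
    days = np.linspace(params.day_min, params.day_max, n)
    dt = (params.day_max - params.day_min) / (n - 1)

    phase0 = rng.uniform(0.0, 2.0 * math.pi)
    step_sd = params.phase_jitter_sd * (1.0 - params.regularity) * math.sqrt(dt)
    steps = rng.normal(0.0, 1.0, n - 1) * step_sd
    phase = phase0 + np.concatenate([[0.0], np.cumsum(steps)])

    innov_sd = params.noise_sd * (2.0 - params.regularity)
    innov = rng.normal(0.0, 1.0, n) * innov_sd
    a = params.ar_coeff
    noise = np.empty(n)
    # stationary AR(1) start so early samples are not systematically quieter
    noise[0] = innov[0] / math.sqrt(1.0 - a * a) if innov_sd > 0 else 0.0
    for i in range(1, n):
        noise[i] = a * noise[i - 1] + innov[i]

    cycle = params.amplitude * np.sin(2.0 * math.pi * days / params.period_days + phase)
    if params.marginal == "additive":
        values = np.clip(params.base_level * subject_factor + cycle + noise, 0.0, None)
    else:
        rel = params.base_level if params.base_level > 0 else 1.0
        values = params.base_level * subject_factor * np.exp((cycle + noise) / rel)
    return ElementalTimeSeries(subject_id, element, days, values)


@dataclass
class CohortConfig:
    """Structure and effect injection for a simulated twin cohort.

    ``pathway_effects`` maps ``(diagnosis, key)`` to a regularity shift,
    where ``key`` is an element symbol (shifts that element's regularity)
    or a zinc pair like ``"Zn-Cu"`` (shifts the *partner* element's
    regularity for subjects with that diagnosis, degrading the pair's
    cross-recurrence).  ``twin_correlation`` is the weight with which MZ
    co-twins share latent signal parameters; DZ twins share at half that
    weight.
    """

    n_pairs: int = 30
    triplet_count: int = 1
    singleton_count: int = 11
    group_sizes: Mapping[Diagnosis, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    pathway_effects: Mapping[tuple[Diagnosis, str], float] = field(default_factory=dict)
    twin_correlation: float = 0.5
    seed: int = 0
    signal: SignalParams = field(default_factory=SignalParams)

    def __post_init__(self):
        self.group_sizes = {Diagnosis(k): int(v) for k, v in self.group_sizes.items()}
        if self.n_pairs < 0 or self.triplet_count < 0 or self.singleton_count < 0:
            raise ValidationError("cohort counts must be nonnegative", "n_pairs")
        total = self.total_subjects
        if sum(self.group_sizes.values()) != total:
            raise ValidationError(
                f"group sizes sum to {sum(self.group_sizes.values())}, "
                f"but the cohort has {total} subjects",
                "group_sizes",
            )
        if not 0.0 <= self.twin_correlation <= 1.0:
            raise ValidationError("twin_correlation must lie in [0, 1]", "twin_correlation")
        norm_effects = {}
        for (dx, key), shift in self.pathway_effects.items():
            dx = Diagnosis(dx)
            target = key.split("-", 1)[1] if "-" in key else key
            if target not in self.elements or (
                "-" in key and key.split("-", 1)[0] not in self.elements
            ):
                raise ValidationError(
                    f"pathway_effects key {key!r} references an element "
                    "absent from the configured element list",
                    "pathway_effects",
                )
            norm_effects[(dx, key)] = float(shift)
        self.pathway_effects = norm_effects

    @property
    def total_subjects(self) -> int:
        return 2 * self.n_pairs + 3 * self.triplet_count + self.singleton_count


def scaled_group_sizes(total: int) -> dict[Diagnosis, int]:
    """Diagnosis counts proportional to the default 74-subject cohort,
    allocated by largest remainder so they sum exactly to ``total``."""
    base_total = sum(DEFAULT_GROUP_SIZES.values())
    quotas = {dx: total * n / base_total for dx, n in DEFAULT_GROUP_SIZES.items()}
    sizes = {dx: int(q) for dx, q in quotas.items()}
    short = total - sum(sizes.values())
    for dx in sorted(quotas, key=lambda d: quotas[d] - sizes[d], reverse=True)[:short]:
        sizes[dx] += 1
    return sizes


def _trunc_normal(rng, mean, sd, lo=-np.inf, hi=np.inf):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return min(max(mean, lo), hi)


def _regularity_shift(config: CohortConfig, dx: Diagnosis, element: str) -> float:
    shift = config.pathway_effects.get((dx, element), 0.0)
    # zinc-pair effects land on the partner element's regularity
    shift += config.pathway_effects.get((dx, f"Zn-{element}"), 0.0)
    return shift


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], list[ElementalTimeSeries]]:
    """Simulate a full twin cohort and its per-element traces.

    Co-twins share a latent subject factor and latent regularity deviation
    with weight ``twin_correlation`` (MZ; half for DZ); gestational length
    is shared within a birth group, and MZ groups are same-sex.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    groups: list[tuple[str, int, Zygosity]] = []
    for i in range(config.n_pairs):
        zyg = Zygosity.MZ if i % 2 == 0 else Zygosity.DZ
        groups.append((f"P{i + 1:04d}", 2, zyg))
    for i in range(config.triplet_count):
        groups.append((f"T{i + 1:04d}", 3, Zygosity.MZ))
    for i in range(config.singleton_count):
        groups.append((f"S{i + 1:04d}", 1, Zygosity.SINGLETON))

    labels: list[Diagnosis] = []
    for dx, count in config.group_sizes.items():
        labels.extend([dx] * count)
    labels = [labels[i] for i in rng.permutation(len(labels))]

    subjects: list[SubjectRecord] = []
    all_series: list[ElementalTimeSeries] = []
    subj_idx = 0
    for pair_id, size, zyg in groups:
        gest = _trunc_normal(rng, 246.0, 24.0, 180.0, 300.0)
        shared_sex = rng.choice(["M", "F"])
        shared_factor = _trunc_normal(rng, 1.0, 0.3, lo=0.2)
        shared_reg_dev = rng.normal(0.0, 0.08)
        if zyg is Zygosity.MZ:
            w = config.twin_correlation
        elif zyg is Zygosity.DZ:
            w = config.twin_correlation / 2.0
        else:
            w = 0.0

        for _ in range(size):
            dx = labels[subj_idx]
            sid = f"{pair_id}-{subj_idx + 1:03d}"
            sex = shared_sex if zyg is Zygosity.MZ else rng.choice(["M", "F"])
            own_factor = _trunc_normal(rng, 1.0, 0.3, lo=0.2)
            factor = w * shared_factor + (1.0 - w) * own_factor
            own_reg_dev = rng.normal(0.0, 0.08)
            reg_dev = w * shared_reg_dev + (1.0 - w) * own_reg_dev
            bw = _trunc_normal(rng, 2.4, 0.7, lo=0.3)
            iq_mean, iq_sd = IQ_DISTRIBUTIONS[dx]
            iq = rng.normal(iq_mean, iq_sd)
            subjects.append(
                SubjectRecord(sid, pair_id, zyg, str(sex), gest, bw, dx, iq)
            )
            for element in config.elements:
                level = ELEMENT_BASE_LEVELS.get(element, 1e-6)
                reg = float(
                    np.clip(
                        config.signal.regularity
                        + reg_dev
                        + _regularity_shift(config, dx, element),
                        0.0,
                        1.0,
                    )
                )
                params = replace(
                    config.signal,
                    base_level=level,
                    amplitude=config.signal.amplitude * level,
                    noise_sd=config.signal.noise_sd * level,
                    regularity=reg,
                )
                series_seed = int(rng.integers(2**31))
                all_series.append(
                    generate_element_series(params, factor, series_seed, sid, element)
                )
            subj_idx += 1
    return subjects, all_series
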