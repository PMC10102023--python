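"""Seeded synthetic autopsy cohorts with circadian clock-gene structure.

The generator emulates a forensic autopsy series in which heart-tissue
expression of two antiphase core clock genes, *BMAL1* and *NR1D1*, was
measured in each case with a known time of death.  Each gene follows a
multiplicative (log-scale) cosinor::

    E(t) = exp(mesor + amplitude * cos(2*pi*(t - acrophase)/24) + noise)

with log-normal case-to-case noise.  NR1D1 peaks in the morning (06:00 by
default) and BMAL1 in the evening (18:00), so the NR1D1/BMAL1 ratio
oscillates with doubled log-amplitude and peaks at 06:00.

Beyond the rhythm itself the generator models the covariate composition of
a real cohort (sex, age, postmortem interval, cause-of-death categories),
an "arrhythmic" subpopulation whose personal clock phase is uniformly
shifted (shift workers, irregular lifestyles -- the source of low-ratio
outliers at peak times), and loss of oscillation in protracted deaths from
chronic brain injury, modelled as amplitude attenuation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneOscillator",
    "CohortConfig",
    "CauseCategory",
    "CAUSE_CATEGORIES",
    "cosinor_expression",
    "generate_cohort",
    "ct_from_expression",
    "ct_to_expression",
]

HOURS_PER_DAY = 24.0


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class GeneOscillator:
    """Log-scale cosinor parameters for one gene.

    Parameters
    ----------
    mesor:
        Baseline of log-expression (natural log, arbitrary units).
    amplitude:
        Log-scale amplitude, >= 0.  The noiseless peak/trough expression
        ratio of a single gene is ``exp(2 * amplitude)``.
    acrophase:
        Clock time of peak expression, hours in [0, 24).
    noise_sd:
        Standard deviation of additive Gaussian noise on the log scale
        (i.e. log-normal multiplicative noise), >= 0.
    """

    mesor: float
    amplitude: float
    acrophase: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0 <= self.acrophase < HOURS_PER_DAY:
            raise ConfigurationError(
                f"acrophase must lie in [0, 24), got {self.acrophase}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class CauseCategory:
    name: str
    cause_class: str          # "intrinsic" or "extrinsic"
    probability: float        # cohort proportion
    head_injury: bool = False


# Cause-of-death composition of the reference autopsy series (318 cases:
# 245 extrinsic, 73 intrinsic).  Head-injury deaths split further into
# immediate deaths from acute brain injury and protracted deaths from
# chronic brain injury (cerebral edema / hernia / hypoxia).
CAUSE_CATEGORIES: tuple[CauseCategory, ...] = (
    CauseCategory("intoxication", "extrinsic", 14 / 318),
    CauseCategory("drowning", "extrinsic", 48 / 318),
    CauseCategory("hemorrhagic_traumatic_shock", "extrinsic", 46 / 318),
    CauseCategory("asphyxia_hanging", "extrinsic", 29 / 318),
    CauseCategory("burn", "extrinsic", 33 / 318),
    CauseCategory("head_injury", "extrinsic", 50 / 318, head_injury=True),
    CauseCategory("other_extrinsic", "extrinsic", 25 / 318),
    CauseCategory("ischemic_heart_failure", "intrinsic", 34 / 318),
    CauseCategory("circulation_failure", "intrinsic", 18 / 318),
    CauseCategory("other_intrinsic", "intrinsic", 21 / 318),
)

CAUSE_CLASS: dict[str, str] = {c.name: c.cause_class for c in CAUSE_CATEGORIES}

# Age mixture calibrated to the reference cohort: three age strata with
# observed proportions 13/318 (<=19 y), 200/318 (20-69 y), 105/318 (>=70 y).
# Within-stratum laws chosen so the mixture mean is exactly 58.7 years:
# uniform(2 months, 19), triangular(20, mode 57.61775, 69), uniform(70, 97).
_AGE_GROUP_PROBS = (13 / 318, 200 / 318, 105 / 318)
_AGE_YOUNG = (2 / 12, 19.0)
_AGE_MID = (20.0, 57.61775, 69.0)     # (left, mode, right)
_AGE_OLD = (70.0, 97.0)

# PMI law: lognormal(mu, sigma) truncated at 96 h, parameters solved so the
# truncated mean is exactly 22.3 h and P(PMI > 30 h) = 68/318.
_PMI_MEANLOG = 2.9505778769695095
_PMI_SDLOG = 0.5728268779610275


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generative model."""

    n_cases: int = 318
    oscillator_nr1d1: GeneOscillator = field(
        default_factory=lambda: GeneOscillator(
            mesor=0.0, amplitude=2.0, acrophase=6.0, noise_sd=0.5
        )
    )
    oscillator_bmal1: GeneOscillator = field(
        default_factory=lambda: GeneOscillator(
            mesor=0.0, amplitude=2.0, acrophase=18.0, noise_sd=0.5
        )
    )
    #: probability that a case's personal acrophase is drawn uniformly on
    #: [0, 24) -- the shift-worker / irregular-lifestyle outlier mechanism.
    #: The same personal offset is applied to both genes, preserving the
    #: 12-h antiphase relation.
    arrhythmic_fraction: float = 0.15
    #: multiplier in [0, 1] applied to both amplitudes for chronic-brain-
    #: injury cases; 0 means complete loss of oscillation.
    chronic_brain_injury_attenuation: float = 0.0
    p_male: float = 224 / 318
    cause_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {c.name: c.probability for c in CAUSE_CATEGORIES}
    )
    #: among head-injury deaths, probability of protracted death from
    #: chronic brain injury (vs immediate death from acute injury): 15/50.
    p_chronic_given_head_injury: float = 15 / 50
    pmi_meanlog: float = _PMI_MEANLOG
    pmi_sdlog: float = _PMI_SDLOG
    pmi_max: float = 96.0
    #: optional per-hour log-scale decay applied identically to both genes
    #: (common postmortem RNA degradation); cancels in the ratio.
    pmi_degradation_rate: float = 0.0
    age_group_probabilities: tuple[float, float, float] = _AGE_GROUP_PROBS
    #: amplification efficiency used to derive Ct columns; None omits them.
    ct_efficiency: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ConfigurationError(f"n_cases must be >= 0, got {self.n_cases}")
        for name, p in (
            ("arrhythmic_fraction", self.arrhythmic_fraction),
            ("chronic_brain_injury_attenuation", self.chronic_brain_injury_attenuation),
            ("p_male", self.p_male),
            ("p_chronic_given_head_injury", self.p_chronic_given_head_injury),
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        probs = list(self.cause_probabilities.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("cause probabilities must lie in [0, 1]")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"cause probabilities must sum to 1, got {sum(probs)}"
            )
        unknown = set(self.cause_probabilities) - set(CAUSE_CLASS)
        if unknown:
            raise ConfigurationError(f"unknown cause categories: {sorted(unknown)}")
        if not math.isclose(sum(self.age_group_probabilities), 1.0, abs_tol=1e-9):
            raise ConfigurationError("age group probabilities must sum to 1")
        if self.pmi_max <= 0:
            raise ConfigurationError("pmi_max must be positive")
        if self.ct_efficiency is not None and not 0 < self.ct_efficiency <= 1:
            raise ConfigurationError("ct_efficiency must lie in (0, 1]")

    # -- JSON (de)serialization -------------------------------------------

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cause_probabilities"] = dict(self.cause_probabilities)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"invalid JSON: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigurationError("config JSON must be an object")
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for osc_key in ("oscillator_nr1d1", "oscillator_bmal1"):
            if osc_key in d:
                if not isinstance(d[osc_key], dict):
                    raise ConfigurationError(f"{osc_key} must be an object")
                d[osc_key] = GeneOscillator(**d[osc_key])
        if "age_group_probabilities" in d:
            d["age_group_probabilities"] = tuple(d["age_group_probabilities"])
        return cls(**d)


def cosinor_expression(
    t: np.ndarray | float,
    osc: GeneOscillator,
    noise_draw: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """Relative expression of one gene at clock time ``t`` (hours).

    ``exp(mesor + amplitude * cos(2*pi*(t - acrophase)/24) + noise_sd * z)``
    where ``z`` is the supplied standard-normal deviate.  Strictly positive
    for all inputs.
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t >= HOURS_PER_DAY)):
        raise ValueError("clock time must lie in [0, 24)")
    log_e = (
        osc.mesor
        + osc.amplitude * np.cos(2 * np.pi * (t - osc.acrophase) / HOURS_PER_DAY)
        + osc.noise_sd * np.asarray(noise_draw, dtype=float)
    )
    out = np.exp(log_e)
    return out if out.ndim else float(out)


def ct_from_expression(
    expr: np.ndarray | float, efficiency: float = 1.0
) -> np.ndarray | float:
    """qPCR cycle threshold implied by a relative expression value.

    Ct = -log(expr) / log(1 + efficiency); expression 1 maps to Ct 0 and
    each doubling (at efficiency 1) subtracts one cycle.
    """
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must lie in (0, 1], got {efficiency}")
    expr = np.asarray(expr, dtype=float)
    if np.any(expr <= 0):
        raise ValueError("expression must be strictly positive")
    out = -np.log(expr) / np.log1p(efficiency)
    return out if out.ndim else float(out)


def ct_to_expression(
    ct: np.ndarray | float, efficiency: float = 1.0
) -> np.ndarray | float:
    """Inverse of :func:`ct_from_expression`."""
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must lie in (0, 1], got {efficiency}")
    ct = np.asarray(ct, dtype=float)
    out = np.exp(-ct * np.log1p(efficiency))
    return out if out.ndim else float(out)


# Named child-stream order is part of the determinism contract: each random
# component draws from its own SeedSequence child, so adding draws to one
# component never perturbs another.
_STREAMS = (
    "time_of_death",
    "sex",
    "age_group",
    "age_value",
    "pmi",
    "cause",
    "brain_injury",
    "arrhythmic",
    "phase_offset",
    "noise_bmal1",
    "noise_nr1d1",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _draw_ages(config: CohortConfig, group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(group)
    age = np.empty(n)
    young = group == 0
    mid = group == 1
    old = group == 2
    age[young] = rng.uniform(*_AGE_YOUNG, size=young.sum())
    left, mode, right = _AGE_MID
    age[mid] = rng.triangular(left, mode, right, size=mid.sum())
    age[old] = rng.uniform(*_AGE_OLD, size=old.sum())
    return age


def _draw_pmi(config: CohortConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    # exact truncation at pmi_max via inverse-CDF on [0, F(pmi_max)]
    law = stats.lognorm(s=config.pmi_sdlog, scale=np.exp(config.pmi_meanlog))
    u = rng.uniform(0.0, law.cdf(config.pmi_max), size=n)
    return law.ppf(u)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a synthetic autopsy cohort as a case table.

    Returns a DataFrame with one row per case and the documented column
    order: case_id, time_of_death, sex, age, pmi, cause_class,
    cause_subcategory, brain_injury, expr_bmal1, expr_nr1d1, ct_bmal1,
    ct_nr1d1.  Identical config (including seed) yields an identical table.
    """
    n = config.n_cases
    rngs = _rngs(config.seed)

    tod = rngs["time_of_death"].uniform(0.0, HOURS_PER_DAY, size=n)
    sex = np.where(rngs["sex"].uniform(size=n) < config.p_male, "male", "female")
    age_group = rngs["age_group"].choice(
        3, size=n, p=np.asarray(config.age_group_probabilities)
    )
    age = _draw_ages(config, age_group, rngs["age_value"])
    pmi = _draw_pmi(config, n, rngs["pmi"])

    names = list(config.cause_probabilities)
    probs = np.array([config.cause_probabilities[k] for k in names])
    cause_idx = rngs["cause"].choice(len(names), size=n, p=probs)
    cause = np.array(names, dtype=object)[cause_idx]
    cause_class = np.array([CAUSE_CLASS[c] for c in cause], dtype=object)

    head = cause == "head_injury"
    chronic_draw = rngs["brain_injury"].uniform(size=n)
    brain_injury = np.full(n, "none", dtype=object)
    brain_injury[head & (chronic_draw < config.p_chronic_given_head_injury)] = "chronic"
    brain_injury[head & (chronic_draw >= config.p_chronic_given_head_injury)] = "acute"

    arrhythmic = rngs["arrhythmic"].uniform(size=n) < config.arrhythmic_fraction
    offset = np.where(
        arrhythmic, rngs["phase_offset"].uniform(0.0, HOURS_PER_DAY, size=n), 0.0
    )
    chronic = brain_injury == "chronic"
    atten = np.where(chronic, config.chronic_brain_injury_attenuation, 1.0)

    z_b = rngs["noise_bmal1"].standard_normal(n)
    z_n = rngs["noise_nr1d1"].standard_normal(n)

    def _expr(osc: GeneOscillator, z: np.ndarray) -> np.ndarray:
        # personal phase offset shifts the effective death time relative to
        # the oscillator; amplitude attenuation applies to chronic cases
        phase = 2 * np.pi * (tod - offset - osc.acrophase) / HOURS_PER_DAY
        log_e = osc.mesor + atten * osc.amplitude * np.cos(phase) + osc.noise_sd * z
        if config.pmi_degradation_rate:
            log_e = log_e - config.pmi_degradation_rate * pmi
        return np.exp(log_e)

    expr_b = _expr(config.oscillator_bmal1, z_b)
    expr_n = _expr(config.oscillator_nr1d1, z_n)

    if config.ct_efficiency is not None and n > 0:
        ct_b = ct_from_expression(expr_b, config.ct_efficiency)
        ct_n = ct_from_expression(expr_n, config.ct_efficiency)
    else:
        ct_b = np.full(n, np.nan)
        ct_n = np.full(n, np.nan)

    return pd.DataFrame(
        {
            "case_id": [f"case_{i:05d}" for i in range(n)],
            "time_of_death": tod,
            "sex": sex,
            "age": age,
            "pmi": pmi,
            "cause_class": cause_class,
            "cause_subcategory": cause,
            "brain_injury": brain_injury,
            "expr_bmal1": expr_b,
            "expr_nr1d1": expr_n,
            "ct_bmal1": ct_b,
            "ct_nr1d1": ct_n,
        }
    )
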