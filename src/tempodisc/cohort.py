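"""Simulated participants and patient groups for end-to-end testing.

Participants are value-based choice agents whose true log discount rates
are normally distributed within sex x education strata.  Each simulated
participant completes the full adjusting-amount staircase session and is
scored by the indices module, so every downstream stage (norm building,
classification, group contrasts, ROC) can be exercised without any real
data.

Defaults encode the normative study conditions: stratum frequencies from
the published demographics of the 357-participant Italian sample, stratum
ln-k means at the published stratified medians with sd 2.27, and clinical
case-control moments ln k ~ N(-2.33, 1.59) (mOFC) vs N(-3.79, 2.27)
(normative).  Choice noise (softmax temperature, lapse) is a calibration
choice documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .indices import DiscountIndices, score_participant
from .normative import Stratum
from .staircase import ChoicePolicy, ChoiceTrial, DiscountProfile, TaskConfig, run_session

#: sex x education frequencies of the normative sample (187 M / 170 F;
#: education 102/128/127), treated as independent margins.
_SEX_P = {"F": 170 / 357, "M": 187 / 357}
_EDU_P = {1: 102 / 357, 2: 128 / 357, 3: 127 / 357}
DEFAULT_STRATUM_WEIGHTS: dict[Stratum, float] = {
    Stratum(s, e): _SEX_P[s] * _EDU_P[e] for s in ("F", "M") for e in (1, 2, 3)
}

#: stratified medians of the published log-k norms — the default stratum means.
DEFAULT_LOG_K_MEANS: dict[Stratum, float] = {
    Stratum("F", 1): -2.70,
    Stratum("F", 2): -3.73,
    Stratum("F", 3): -4.35,
    Stratum("M", 1): -3.94,
    Stratum("M", 2): -4.10,
    Stratum("M", 3): -4.13,
}

DEFAULT_LOG_K_SD = 2.27
DEFAULT_TEMPERATURE = 4.0  # EUR; softmax choice noise (calibration, see methods)
DEFAULT_LAPSE = 0.05

#: age bands (inclusive) and frequencies of the normative sample.
AGE_BANDS = ((21, 39), (40, 59), (60, 92))
AGE_BAND_P = (91 / 357, 140 / 357, 126 / 357)

GROUPS = ("normative", "mOFC", "nonFC")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one simulated cohort; fully reproducible from ``seed``."""

    n: int
    seed: int
    stratum_weights: Mapping[Stratum, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_WEIGHTS)
    )
    log_k_mean_by_stratum: Mapping[Stratum, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_K_MEANS)
    )
    log_k_sd: float = DEFAULT_LOG_K_SD
    temperature: float = DEFAULT_TEMPERATURE
    lapse: float = DEFAULT_LAPSE
    model: str = "hyperbolic"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        total = sum(self.stratum_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"stratum weights must sum to 1, got {total}")
        if self.log_k_sd <= 0:
            raise ValueError("log_k_sd must be > 0")
        missing = set(self.stratum_weights) - set(self.log_k_mean_by_stratum)
        if missing:
            raise ValueError(f"no ln-k mean for strata {sorted(missing)}")


@dataclass(frozen=True)
class SimulatedParticipant:
    """One simulated participant with ground truth and derived indices."""

    id: str
    stratum: Stratum
    age: int
    group: str
    k_true: float
    seed: int
    profile: DiscountProfile
    indices: DiscountIndices
    trial_log: tuple[ChoiceTrial, ...] = ()


def _participant_seed(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def sample_cohort(
    spec: CohortSpec,
    *,
    group: str = "normative",
    config: TaskConfig = TaskConfig(),
    id_prefix: str | None = None,
    keep_trials: bool = False,
) -> list[SimulatedParticipant]:
    """Draw a cohort and run every participant through the staircase.

    Strata are multinomial draws from ``spec.stratum_weights``; ages are
    uniform within the demographic age bands with the published band
    frequencies; ln k ~ Normal(stratum mean, sd).  Each participant's
    session uses an independent seed derived from ``spec.seed``.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root)
    children = root.spawn(spec.n)
    strata = sorted(spec.stratum_weights)
    weights = np.array([spec.stratum_weights[s] for s in strata])
    weights = weights / weights.sum()
    stratum_idx = rng.choice(len(strata), size=spec.n, p=weights)
    band_idx = rng.choice(len(AGE_BANDS), size=spec.n, p=AGE_BAND_P)
    prefix = id_prefix if id_prefix is not None else group
    out: list[SimulatedParticipant] = []
    for i in range(spec.n):
        stratum = strata[stratum_idx[i]]
        lo, hi = AGE_BANDS[band_idx[i]]
        age = int(rng.integers(lo, hi + 1))
        ln_k = rng.normal(spec.log_k_mean_by_stratum[stratum], spec.log_k_sd)
        pid = f"{prefix}-{i:05d}"
        pseed = _participant_seed(children[i])
        policy = ChoicePolicy(
            model=spec.model,
            k_true=float(np.exp(ln_k)),
            temperature=spec.temperature,
            lapse=spec.lapse,
            seed=pseed,
        )
        trial_log, profile = run_session(policy, config, participant_id=pid)
        out.append(
            SimulatedParticipant(
                id=pid,
                stratum=stratum,
                age=age,
                group=group,
                k_true=policy.k_true,
                seed=pseed,
                profile=profile,
                indices=score_participant(profile),
                trial_log=tuple(trial_log) if keep_trials else (),
            )
        )
    return out


def sample_case_control(
    n_pos: int,
    n_neg: int,
    *,
    pos_mean: float = -2.33,
    pos_sd: float = 1.59,
    neg_mean: float = -3.79,
    neg_sd: float = 2.27,
    temperature: float = DEFAULT_TEMPERATURE,
    lapse: float = DEFAULT_LAPSE,
    seed: int | None = None,
) -> tuple[list[SimulatedParticipant], list[SimulatedParticipant]]:
    """Simulate a clinical positive group and a normative control group.

    Default ln-k moments are the published group statistics: mOFC patients
    N(-2.33, 1.59) versus the normative sample N(-3.79, 2.27).  Group
    membership shifts every stratum mean to the group mean, so group is
    the only systematic effect.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both groups need at least 1 participant")
    root = np.random.SeedSequence(seed)
    seed_pos, seed_neg = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in root.spawn(2))

    def spec(n, mean, sd, s):
        return CohortSpec(
            n=n,
            seed=s,
            log_k_mean_by_stratum={st: mean for st in DEFAULT_STRATUM_WEIGHTS},
            log_k_sd=sd,
            temperature=temperature,
            lapse=lapse,
        )

    positives = sample_cohort(spec(n_pos, pos_mean, pos_sd, seed_pos), group="mOFC")
    negatives = sample_cohort(spec(n_neg, neg_mean, neg_sd, seed_neg), group="normative")
    return positives, negatives
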