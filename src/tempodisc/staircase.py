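"""Adjusting-amount staircase task for monetary delay discounting.

The task presents repeated binary choices between a fixed delayed amount
(EUR 40 by default) and an immediate amount that is titrated by a halving
staircase: the immediate offer starts at half the delayed amount, moves up
after a "delayed" choice and down after an "immediate" choice, and the step
halves on every trial.  After five choices per delay the offer that *would*
be shown on the sixth trial is taken as the indifference point — the
immediate amount subjectively equal to the delayed reward at that delay.

Six delays are probed (2, 14, 30, 90, 180 and 360 days) in a randomized
block order.  The module can drive a simulated choice policy or replay a
logged human session from CSV.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .models import MODELS, subjective_value

DEFAULT_DELAYS = (2, 14, 30, 90, 180, 360)

SESSION_LOG_COLUMNS = (
    "participant_id",
    "block_index",
    "trial_index",
    "delay_days",
    "immediate_amount",
    "delayed_amount",
    "choice",
)


class Choice(str, Enum):
    """One binary intertemporal choice."""

    IMMEDIATE = "immediate"
    DELAYED = "delayed"


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the staircase task.

    Defaults reproduce the unified monetary task: EUR 40 delayed, first
    immediate offer EUR 20, six delays in days, five choices per delay.
    """

    delayed_amount: float = 40.0
    first_immediate: float = 20.0
    delays: tuple[float, ...] = DEFAULT_DELAYS
    choices_per_delay: int = 5
    block_order_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.first_immediate < self.delayed_amount:
            raise ValueError(
                "first immediate offer must satisfy 0 < first_immediate "
                f"< delayed_amount, got {self.first_immediate} vs {self.delayed_amount}"
            )
        delays = tuple(float(d) for d in self.delays)
        if len(delays) == 0 or any(d <= 0 for d in delays):
            raise ValueError("delays must be positive")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValueError("delays must be strictly increasing")
        if self.choices_per_delay < 1:
            raise ValueError("choices_per_delay must be >= 1")
        object.__setattr__(self, "delays", delays)

    @property
    def first_step(self) -> float:
        """Initial staircase adjustment: half the first offer gap."""
        return (self.delayed_amount - self.first_immediate) / 2.0


@dataclass(frozen=True)
class ChoiceTrial:
    """One staircase step: the offer pair shown and the choice made."""

    block_index: int
    trial_index: int
    delay_days: float
    immediate_amount: float
    delayed_amount: float
    choice: Choice
    adjustment_applied: float  # step that produced this trial's offer (0 for trial 1)


@dataclass(frozen=True)
class DelayBlock:
    """Five titrated choices at one delay and the resulting indifference point."""

    delay_days: float
    trials: tuple[ChoiceTrial, ...]
    indifference_point: float


@dataclass(frozen=True)
class DiscountProfile:
    """A participant's indifference points, one per delay, sorted by delay.

    ``sv_raw`` holds the indifference points in currency units;
    ``sv_fraction`` expresses them as a fraction of the delayed amount.
    """

    participant_id: str
    delays: np.ndarray
    sv_raw: np.ndarray
    delayed_amount: float

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        sv_raw = np.asarray(self.sv_raw, dtype=float)
        if delays.shape != sv_raw.shape or delays.ndim != 1:
            raise ValueError("delays and sv_raw must be 1-d arrays of equal length")
        if np.any(np.diff(delays) <= 0):
            raise ValueError("profile delays must be strictly increasing")
        if np.any(sv_raw < 0) or np.any(sv_raw > self.delayed_amount):
            raise ValueError("subjective values must lie in [0, delayed_amount]")
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "sv_raw", sv_raw)

    @property
    def sv_fraction(self) -> np.ndarray:
        return self.sv_raw / self.delayed_amount

    @property
    def points(self) -> list[tuple[float, float, float]]:
        """(delay_days, sv_raw, sv_fraction) triples sorted by delay."""
        return [
            (float(d), float(r), float(f))
            for d, r, f in zip(self.delays, self.sv_raw, self.sv_fraction)
        ]


@dataclass(frozen=True)
class ChoicePolicy:
    """Simulated chooser: noisy value maximizer with a lapse rate.

    The probability of taking the delayed option is a logistic function of
    the value difference ``delayed_amount * SV(k, D) - immediate`` scaled by
    ``temperature`` (currency units), mixed with a ``lapse`` probability of
    choosing at random.  ``temperature = 0`` degenerates to the
    deterministic maximizer; exact value ties go to the immediate option.
    """

    model: str = "hyperbolic"
    k_true: float = 0.02
    temperature: float = 0.0
    lapse: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown discount model {self.model!r}")
        if self.k_true <= 0:
            raise ValueError("k_true must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not 0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")

    def p_delayed(self, immediate: float, delayed: float, delay_days: float) -> float:
        """Probability of choosing the delayed reward for this offer pair."""
        value = delayed * subjective_value(self.model, self.k_true, delay_days)
        if self.temperature == 0.0:
            base = 1.0 if value > immediate else 0.0  # tie -> immediate
        else:
            base = 1.0 / (1.0 + math.exp(-(value - immediate) / self.temperature))
        return self.lapse * 0.5 + (1.0 - self.lapse) * base

    def choose(self, immediate: float, delayed: float, delay_days: float,
               rng: np.random.Generator) -> Choice:
        p = self.p_delayed(immediate, delayed, delay_days)
        return Choice.DELAYED if rng.random() < p else Choice.IMMEDIATE


def adjust_offer(prev_offer: float, step: float, choice: Choice) -> tuple[float, float]:
    """Apply one staircase adjustment.

    A delayed choice raises the next immediate offer by ``step``, an
    immediate choice lowers it; the step halves.  Amounts are kept at full
    floating precision (the sequence 10, 5, 2.5, 1.25, 0.625 at defaults).
    """
    if step <= 0:
        raise ValueError(f"staircase step must be > 0, got {step}")
    if prev_offer <= 0:
        raise ValueError(f"offer must be > 0, got {prev_offer}")
    choice = Choice(choice)
    if choice is Choice.DELAYED:
        next_offer = prev_offer + step
    else:
        next_offer = prev_offer - step
    return next_offer, step / 2.0


def run_block(
    delay_days: float,
    policy: ChoicePolicy,
    config: TaskConfig = TaskConfig(),
    *,
    block_index: int = 0,
    rng: np.random.Generator | None = None,
) -> DelayBlock:
    """Run one five-choice staircase block at a single delay."""
    if delay_days not in config.delays:
        raise ValueError(f"delay {delay_days} not in configured delays {config.delays}")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    offer = config.first_immediate
    step = config.first_step
    applied = 0.0
    trials: list[ChoiceTrial] = []
    for t in range(1, config.choices_per_delay + 1):
        choice = policy.choose(offer, config.delayed_amount, delay_days, rng)
        trials.append(
            ChoiceTrial(
                block_index=block_index,
                trial_index=t,
                delay_days=float(delay_days),
                immediate_amount=offer,
                delayed_amount=config.delayed_amount,
                choice=choice,
                adjustment_applied=applied,
            )
        )
        applied = step
        offer, step = adjust_offer(offer, step, choice)
    # `offer` is now the amount the (hypothetical) next trial would show:
    # the staircase estimate of the subjective value at this delay.
    return DelayBlock(delay_days=float(delay_days), trials=tuple(trials),
                      indifference_point=offer)


def block_order(config: TaskConfig, rng: np.random.Generator) -> tuple[float, ...]:
    """Seeded uniform permutation of the configured delays."""
    return tuple(rng.permutation(np.asarray(config.delays, dtype=float)).tolist())


def run_session(
    policy: ChoicePolicy,
    config: TaskConfig = TaskConfig(),
    *,
    participant_id: str = "sim",
) -> tuple[list[ChoiceTrial], DiscountProfile]:
    """Run a full session: one randomized block per delay.

    A single integer seed (``policy.seed``) drives both the block-order
    permutation and the policy's choice noise; ``config.block_order_seed``,
    when set, overrides the permutation stream.
    """
    rng = np.random.default_rng(policy.seed)
    if config.block_order_seed is not None:
        order_rng = np.random.default_rng(config.block_order_seed)
    else:
        order_rng = rng
    order = block_order(config, order_rng)
    trial_log: list[ChoiceTrial] = []
    by_delay: dict[float, float] = {}
    for b, delay in enumerate(order):
        block = run_block(delay, policy, config, block_index=b, rng=rng)
        trial_log.extend(block.trials)
        by_delay[delay] = block.indifference_point
    delays = sorted(by_delay)
    profile = DiscountProfile(
        participant_id=participant_id,
        delays=np.asarray(delays),
        sv_raw=np.asarray([by_delay[d] for d in delays]),
        delayed_amount=config.delayed_amount,
    )
    return trial_log, profile


class SessionLogError(ValueError):
    """Raised when a session log is malformed or inconsistent with the staircase."""


def write_session_log(
    trial_log: Sequence[ChoiceTrial],
    path: str | Path,
    *,
    participant_id: str = "sim",
    metadata: dict | None = None,
) -> None:
    """Write a session to CSV (one row per trial, '#' metadata header)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        writer = csv.writer(fh)
        writer.writerow(SESSION_LOG_COLUMNS)
        for tr in trial_log:
            writer.writerow(
                [
                    participant_id,
                    tr.block_index,
                    tr.trial_index,
                    repr(float(tr.delay_days)),
                    repr(float(tr.immediate_amount)),
                    repr(float(tr.delayed_amount)),
                    tr.choice.value,
                ]
            )


def read_session_log(path: str | Path) -> tuple[list[ChoiceTrial], DiscountProfile]:
    """Read and validate a session log, replaying the staircase.

    Every logged offer is checked against the offer the staircase rules
    would have produced from the preceding choices; a mismatch raises
    :class:`SessionLogError` naming the offending row.
    """
    path = Path(path)
    rows: list[tuple[int, dict]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None:
        raise SessionLogError(f"{path}: no trials (empty file)")
    missing = set(SESSION_LOG_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise SessionLogError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(reader, start=2):  # header is line 1
        rows.append((i, row))
    if not rows:
        raise SessionLogError(f"{path}: no trials")

    # Group rows into blocks, preserving presentation order.
    blocks: dict[int, list[tuple[int, dict]]] = {}
    participant_id = rows[0][1]["participant_id"]
    for lineno, row in rows:
        try:
            b = int(row["block_index"])
        except (TypeError, ValueError) as exc:
            raise SessionLogError(f"{path}:{lineno}: bad block_index {row['block_index']!r}") from exc
        blocks.setdefault(b, []).append((lineno, row))

    trial_log: list[ChoiceTrial] = []
    delays: list[float] = []
    ips: list[float] = []
    for b in sorted(blocks):
        block_rows = sorted(blocks[b], key=lambda lr: int(lr[1]["trial_index"]))
        first_lineno, first = block_rows[0]
        try:
            delayed_amount = float(first["delayed_amount"])
            first_offer = float(first["immediate_amount"])
            delay = float(first["delay_days"])
        except (TypeError, ValueError) as exc:
            raise SessionLogError(f"{path}:{first_lineno}: malformed numeric field") from exc
        offer = first_offer
        step = (delayed_amount - first_offer) / 2.0
        applied = 0.0
        for t, (lineno, row) in enumerate(block_rows, start=1):
            if int(row["trial_index"]) != t:
                raise SessionLogError(
                    f"{path}:{lineno}: trial_index {row['trial_index']} out of sequence "
                    f"(expected {t}) in block {b}"
                )
            try:
                imm = float(row["immediate_amount"])
                damt = float(row["delayed_amount"])
                ddays = float(row["delay_days"])
            except (TypeError, ValueError) as exc:
                raise SessionLogError(f"{path}:{lineno}: malformed numeric field") from exc
            if row["choice"] not in (Choice.IMMEDIATE.value, Choice.DELAYED.value):
                raise SessionLogError(f"{path}:{lineno}: bad choice {row['choice']!r}")
            if damt != delayed_amount or ddays != delay:
                raise SessionLogError(
                    f"{path}:{lineno}: delay/delayed_amount change within block {b}"
                )
            if not math.isclose(imm, offer, rel_tol=0, abs_tol=1e-9):
                raise SessionLogError(
                    f"{path}:{lineno}: offer {imm} inconsistent with staircase replay "
                    f"(expected {offer}) in block {b}"
                )
            choice = Choice(row["choice"])
            trial_log.append(
                ChoiceTrial(
                    block_index=b,
                    trial_index=t,
                    delay_days=delay,
                    immediate_amount=imm,
                    delayed_amount=damt,
                    choice=choice,
                    adjustment_applied=applied,
                )
            )
            applied = step
            offer, step = adjust_offer(offer, step, choice)
        delays.append(delay)
        ips.append(offer)

    order = np.argsort(delays)
    profile = DiscountProfile(
        participant_id=participant_id,
        delays=np.asarray(delays, dtype=float)[order],
        sv_raw=np.asarray(ips, dtype=float)[order],
        delayed_amount=float(rows[0][1]["delayed_amount"]),
    )
    return trial_log, profile
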