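"""Discount-rate indices from a participant's indifference points.

Given a :class:`~tempodisc.staircase.DiscountProfile` this module estimates

* the hyperbolic discount rate ``k`` (SV = 1/(1 + kD)),
* the exponential discount rate ``k`` (SV = exp(-kD)),
* the area under the empirical discounting curve (AUC), and
* the count of inconsistent preferences (subjective-value rebounds of at
  least 20% of the delayed reward between adjacent delays).

``k`` is fitted by nonlinear least squares over ``ln k``: a coarse global
grid on ln k in [-12, 2] followed by bounded local refinement.  The grid
start makes the single-parameter problem immune to local minima; the floor
``k >= e^-12`` keeps ``ln k`` finite for non-discounting profiles.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .models import MODELS
from .staircase import DiscountProfile

LNK_LO = -12.0
LNK_HI = 2.0
_LNK_GRID = np.linspace(LNK_LO, LNK_HI, 141)  # 0.1 spacing
K_FLOOR = math.exp(LNK_LO)

INDICES_COLUMNS = (
    "participant_id",
    "k_hyp",
    "log_k_hyp",
    "r2_hyp",
    "k_exp",
    "log_k_exp",
    "r2_exp",
    "auc",
    "n_inconsistent",
)


@dataclass(frozen=True)
class FitResult:
    """One discount-function fit: rate, natural-log rate, fit quality."""

    model: str
    k: float
    log_k: float
    r2: float
    sse: float
    converged: bool


@dataclass(frozen=True)
class DiscountIndices:
    """All indices for one participant."""

    hyperbolic: FitResult
    exponential: FitResult
    auc: float
    n_inconsistent: int


def _predict(model: str, lnk, delays):
    """SV predictions for ln-k value(s) x delays; broadcasts over a grid."""
    k = np.exp(np.atleast_1d(np.asarray(lnk, dtype=float)))[:, None]
    d = np.asarray(delays, dtype=float)[None, :]
    if model == "hyperbolic":
        return 1.0 / (1.0 + k * d)
    return np.exp(-k * d)


def _sse(model: str, lnk, delays, sv) -> np.ndarray:
    resid = _predict(model, lnk, delays) - np.asarray(sv, dtype=float)[None, :]
    return (resid ** 2).sum(axis=1)


def _r2(sse: float, sv: np.ndarray) -> float:
    sstot = float(((sv - sv.mean()) ** 2).sum())
    if sstot < 1e-12:
        return 1.0 if sse < 1e-12 else 0.0
    return max(0.0, 1.0 - sse / sstot)


def fit_k(profile: DiscountProfile, model: str) -> FitResult:
    """Least-squares discount-rate fit for one profile.

    Minimizes the sum of squared residuals between observed sv-fractions
    and the model curve over ``ln k``.  Requires at least two points with
    distinct delays.  An exactly flat profile at SV = 1 (no measurable
    discounting) is reported at the rate floor with zero residuals, the
    ``k -> 0`` limit.
    """
    if model not in MODELS:
        raise ValueError(f"unknown discount model {model!r}")
    delays = np.asarray(profile.delays, dtype=float)
    sv = np.asarray(profile.sv_fraction, dtype=float)
    if np.unique(delays).size < 2:
        raise ValueError("need at least 2 points with distinct delays to fit k")
    if np.all(sv >= 1.0 - 1e-12):
        return FitResult(model=model, k=K_FLOOR, log_k=LNK_LO, r2=1.0, sse=0.0,
                         converged=True)
    grid_sse = _sse(model, _LNK_GRID, delays, sv)
    i = int(np.argmin(grid_sse))
    lo = _LNK_GRID[max(i - 1, 0)]
    hi = _LNK_GRID[min(i + 1, _LNK_GRID.size - 1)]
    res = minimize_scalar(
        lambda x: float(_sse(model, x, delays, sv)[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    lnk = float(np.clip(res.x, LNK_LO, LNK_HI))
    sse = float(_sse(model, lnk, delays, sv)[0])
    # the bracket endpoints can beat the interior optimum at the bounds
    if grid_sse[i] < sse:
        lnk, sse = float(_LNK_GRID[i]), float(grid_sse[i])
    return FitResult(
        model=model,
        k=math.exp(lnk),
        log_k=lnk,
        r2=_r2(sse, sv),
        sse=sse,
        converged=bool(res.success),
    )


def compute_auc(
    profile: DiscountProfile,
    *,
    anchor_at_zero: bool = True,
    max_delay: float | None = None,
) -> float:
    """Area under the empirical discounting curve, in [0, 1].

    Delays are normalized by the maximum delay (360 days at defaults) and
    subjective values by the delayed amount; the area is the trapezoid sum
    (x2 - x1)(y1 + y2)/2 over successive points.  By default the curve is
    anchored at (0, 1) — full value at zero delay — so a non-discounter
    scores exactly 1.
    """
    delays = np.asarray(profile.delays, dtype=float)
    if np.any(np.diff(delays) <= 0):
        raise ValueError("profile delays must be strictly increasing without duplicates")
    norm = float(max_delay if max_delay is not None else delays[-1])
    if norm <= 0:
        raise ValueError("max delay must be > 0")
    x = delays / norm
    y = np.asarray(profile.sv_fraction, dtype=float)
    if anchor_at_zero:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[1.0], y])
    return float(np.trapezoid(y, x))


def count_inconsistencies(profile: DiscountProfile, *, fraction: float = 0.2) -> int:
    """Count inconsistent preferences between adjacent delays.

    A pair of adjacent delays is inconsistent when the subjective value at
    the longer delay exceeds the shorter delay's value by at least
    ``fraction`` of the delayed reward (R2 >= R1 + R/5 at the default 20%,
    i.e. +8 currency units for a EUR 40 reward).  Comparisons use raw
    currency values.
    """
    jumps = np.diff(np.asarray(profile.sv_raw, dtype=float))
    return int(np.sum(jumps >= fraction * profile.delayed_amount))


def score_participant(profile: DiscountProfile) -> DiscountIndices:
    """All discounting indices for one profile."""
    return DiscountIndices(
        hyperbolic=fit_k(profile, "hyperbolic"),
        exponential=fit_k(profile, "exponential"),
        auc=compute_auc(profile),
        n_inconsistent=count_inconsistencies(profile),
    )


def indices_row(participant_id: str, ind: DiscountIndices) -> dict:
    """Flatten indices into the CSV dialect row."""
    return {
        "participant_id": participant_id,
        "k_hyp": ind.hyperbolic.k,
        "log_k_hyp": ind.hyperbolic.log_k,
        "r2_hyp": ind.hyperbolic.r2,
        "k_exp": ind.exponential.k,
        "log_k_exp": ind.exponential.log_k,
        "r2_exp": ind.exponential.r2,
        "auc": ind.auc,
        "n_inconsistent": ind.n_inconsistent,
    }


def write_indices_csv(
    rows: Iterable[dict],
    path: str | Path,
    *,
    metadata: dict | None = None,
    extra_columns: Sequence[str] = (),
) -> None:
    """Write scored indices to CSV with a '#' metadata header."""
    path = Path(path)
    columns = list(INDICES_COLUMNS) + [c for c in extra_columns if c not in INDICES_COLUMNS]
    with path.open("w", newline="", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
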