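"""Stratified normative percentile tables and distribution checks.

Normative thresholds are type-8 (median-unbiased) sample quantiles of the
natural-log hyperbolic discount rate and of the discounting AUC, stratified
by sex (F/M) and three education levels (3-8, 9-13 and 14-23 years of
schooling).  The package ships the tables published for an Italian adult
normative sample of 357 participants under the registry name
``"italian_2022"``; tables can also be rebuilt from any scored cohort.

Classification flags extreme performances: by default, log-k below the
stratum's 10th percentile (or AUC above the 90th) marks extremely *low*
discounting, log-k above the 90th (or AUC below the 10th) extremely *high*
discounting; comparisons are strict, so a score exactly at a threshold is
typical.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

INDEX_TYPES = ("log_k_hyperbolic", "auc")
PERCENTILE_LEVELS = (5, 10, 25, 50, 75, 85, 90, 95)
EDUCATION_LEVELS = (1, 2, 3)  # 3-8, 9-13, 14-23 years
SEXES = ("F", "M")

#: sha256 of the packaged norm CSVs, checked at load time.
_PACKAGED_NORMS = {
    "italian_2022": {
        "log_k_hyperbolic": (
            "italian_2022_log_k.csv",
            "sha256:21541c62299144e0577df26134a5f56e2e11d4fe53979a6fe443753de9303632",
        ),
        "auc": (
            "italian_2022_auc.csv",
            "sha256:1cf4317ab6b139da6a1e51721fc49d1a5b46f9c6c4a0f8f46053faa5a40471ae",
        ),
    }
}

CLASS_LOW = "extremely_low_discounting"
CLASS_TYPICAL = "typical"
CLASS_HIGH = "extremely_high_discounting"


class Stratum(NamedTuple):
    """One normative cell: sex x education level."""

    sex: str
    education_level: int


def all_strata() -> tuple[Stratum, ...]:
    return tuple(Stratum(s, e) for s in SEXES for e in EDUCATION_LEVELS)


def education_level_from_years(years: float) -> int:
    """Map years of schooling to the three normative education levels.

    3-8 years -> 1 (primary), 9-13 -> 2 (secondary), 14-23 -> 3 (degree and
    above).  Norms are undefined outside 3-23 years.
    """
    if not 3 <= years <= 23:
        raise ValueError("norms undefined for education outside 3-23 years")
    if years <= 8:
        return 1
    if years <= 13:
        return 2
    return 3


@dataclass(frozen=True)
class NormativeTable:
    """Percentile thresholds per stratum for one index."""

    index_type: str
    entries: Mapping[Stratum, Mapping[int, float]]
    provenance: str = "rebuilt"  # or "packaged_published_tables"

    def __post_init__(self) -> None:
        if self.index_type not in INDEX_TYPES:
            raise ValueError(f"unknown index type {self.index_type!r}")
        for stratum, levels in self.entries.items():
            ordered = sorted(levels)
            vals = [levels[p] for p in ordered]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"thresholds not monotone in percentile level for stratum {stratum}"
                )


def quantile_type8(values: Sequence[float], p: float) -> float:
    """Type-8 (median-unbiased) sample quantile.

    Linear interpolation between order statistics at plotting positions
    p_k = (k - 1/3)/(n + 1/3); approximately median-unbiased for any
    continuous distribution.  Probabilities below the first plotting
    position return the sample minimum, above the last the maximum.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("quantile of empty sample")
    if not 0 <= p <= 1:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    n = x.size
    h = (n + 1.0 / 3.0) * p + 1.0 / 3.0
    if h <= 1:
        return float(x[0])
    if h >= n:
        return float(x[-1])
    j = int(math.floor(h))
    g = h - j
    return float((1.0 - g) * x[j - 1] + g * x[j])


def build_normative_table(
    scored: Iterable[tuple[float, Stratum]],
    index_type: str,
    *,
    levels: Sequence[int] = PERCENTILE_LEVELS,
) -> NormativeTable:
    """Build a stratified percentile table from (score, stratum) pairs.

    Every sex x education stratum must contribute at least two
    observations; missing or underpopulated strata raise an error listing
    them.
    """
    if index_type not in INDEX_TYPES:
        raise ValueError(f"unknown index type {index_type!r}")
    by_stratum: dict[Stratum, list[float]] = {s: [] for s in all_strata()}
    for score, stratum in scored:
        stratum = Stratum(*stratum)
        if stratum not in by_stratum:
            raise ValueError(f"unknown stratum {stratum}")
        by_stratum[stratum].append(float(score))
    short = [s for s, v in by_stratum.items() if len(v) < 2]
    if short:
        raise ValueError(
            "strata with fewer than 2 observations: "
            + ", ".join(f"{s.sex}/level{s.education_level}" for s in short)
        )
    entries = {
        s: {int(p): quantile_type8(v, p / 100.0) for p in levels}
        for s, v in by_stratum.items()
    }
    return NormativeTable(index_type=index_type, entries=entries, provenance="rebuilt")


def lookup(table: NormativeTable, stratum: Stratum, percentile_level: int) -> float:
    """Exact stored threshold for a stratum and percentile level."""
    stratum = Stratum(*stratum)
    try:
        levels = table.entries[stratum]
    except KeyError:
        raise KeyError(f"stratum {stratum} not in table") from None
    try:
        return float(levels[int(percentile_level)])
    except KeyError:
        raise KeyError(
            f"percentile level {percentile_level} not in table (has {sorted(levels)})"
        ) from None


def classify_against_norms(
    score: float,
    stratum: Stratum,
    index_type: str,
    table: NormativeTable,
    *,
    low_level: int = 10,
    high_level: int = 90,
) -> str:
    """Flag a score as extremely low/high discounting or typical.

    log-k scores below the ``low_level`` threshold indicate extremely low
    discounting, above ``high_level`` extremely high; the mapping reverses
    for AUC (smaller AUC = steeper discounting).  Inequalities are strict:
    boundary scores are typical.
    """
    if index_type != table.index_type:
        raise ValueError(f"table holds {table.index_type}, asked for {index_type}")
    if index_type == "auc" and not 0 <= score <= 1:
        raise ValueError(f"AUC score must lie in [0, 1], got {score}")
    lo = lookup(table, stratum, low_level)
    hi = lookup(table, stratum, high_level)
    if index_type == "log_k_hyperbolic":
        if score < lo:
            return CLASS_LOW
        if score > hi:
            return CLASS_HIGH
    else:
        if score < lo:
            return CLASS_HIGH
        if score > hi:
            return CLASS_LOW
    return CLASS_TYPICAL


class IcFit(NamedTuple):
    """Information criteria for one maximum-likelihood distribution fit."""

    bic: float
    aic: float
    loglik: float
    params: tuple


def distribution_ic(values: Sequence[float]) -> dict[str, IcFit]:
    """Gaussian vs Cauchy maximum-likelihood fit comparison.

    Fits both two-parameter families by maximum likelihood (Gaussian in
    closed form, Cauchy by numerical MLE) and reports
    AIC = 2*2 - 2 ln L and BIC = 2 ln n - 2 ln L; the lower value marks the
    better-fitting family.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(v) == 0:
        raise ValueError("constant data: Cauchy scale is degenerate")
    n = v.size
    out: dict[str, IcFit] = {}

    mu, sigma = float(v.mean()), float(v.std(ddof=0))
    ll_gauss = float(stats.norm.logpdf(v, mu, sigma).sum())
    out["gaussian"] = IcFit(
        bic=2.0 * math.log(n) - 2.0 * ll_gauss,
        aic=4.0 - 2.0 * ll_gauss,
        loglik=ll_gauss,
        params=(mu, sigma),
    )

    loc, scale = stats.cauchy.fit(v)
    ll_cauchy = float(stats.cauchy.logpdf(v, loc, scale).sum())
    out["cauchy"] = IcFit(
        bic=2.0 * math.log(n) - 2.0 * ll_cauchy,
        aic=4.0 - 2.0 * ll_cauchy,
        loglik=ll_cauchy,
        params=(float(loc), float(scale)),
    )
    return out


# ---------------------------------------------------------------------------
# Packaged norms


def _data_path(filename: str) -> Path:
    return Path(resources.files("tempodisc") / "data" / filename)


def _read_norm_csv(path: Path, index_type: str) -> NormativeTable:
    entries: dict[Stratum, dict[int, float]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(ln for ln in fh if not ln.startswith("#")):
            if row["index_type"] != index_type:
                raise ValueError(f"{path}: unexpected index_type {row['index_type']!r}")
            s = Stratum(row["sex"], int(row["education_level"]))
            entries.setdefault(s, {})[int(row["percentile_level"])] = float(row["threshold"])
    return NormativeTable(index_type=index_type, entries=entries,
                          provenance="packaged_published_tables")


def load_norms(name: str = "italian_2022") -> dict[str, NormativeTable]:
    """Load a packaged norms registry entry, verifying file checksums.

    Returns a mapping ``{"log_k_hyperbolic": table, "auc": table}``.  The
    log-k table is on the natural-log scale of the hyperbolic rate.
    """
    try:
        spec = _PACKAGED_NORMS[name]
    except KeyError:
        raise KeyError(
            f"unknown norms {name!r}; available: {sorted(_PACKAGED_NORMS)}"
        ) from None
    tables: dict[str, NormativeTable] = {}
    for index_type, (filename, checksum) in spec.items():
        path = _data_path(filename)
        digest = "sha256:" + hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != checksum:
            raise RuntimeError(f"norms file {filename} corrupted (checksum mismatch)")
        tables[index_type] = _read_norm_csv(path, index_type)
    return tables
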