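"""Criterion-validity statistics: ROC/Youden, rank-sum, ANCOVA, Bartlett.

These implement, from first principles, the statistics used to establish
that a discounting index separates a clinical group (e.g. patients with a
medial-orbitofrontal lesion, the positive class) from a normative sample:

* empirical ROC curves with trapezoid AUC and the Youden-index optimal
  cutoff;
* the Wilcoxon rank-sum (Mann-Whitney) test with midranks, tie-corrected
  normal approximation and continuity correction;
* Gaussian linear models with drop-one (partial) F tests and partial
  eta-squared for a group factor adjusted for covariates;
* Bartlett's test of variance homogeneity.

The ROC AUC equals the Mann-Whitney probability U/(n1*n2) with ties
counted one-half, a property the test suite checks by brute-force pair
counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats

DIRECTIONS = ("higher_is_positive", "lower_is_positive")


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve over all distinct observed cutoffs.

    ``cutoffs`` are on the original score scale; a score counts as positive
    when it is >= the cutoff (direction ``higher_is_positive``) or <= the
    cutoff (``lower_is_positive``) — ties fall on the positive side.  The
    leading sentinel cutoff classifies nothing as positive.
    """

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc_roc: float
    youden_j: float
    optimal_cutoff: float
    direction: str


@dataclass(frozen=True)
class ContrastResult:
    """One test statistic with p-value and (where defined) effect size."""

    statistic: float
    df: tuple | float | None
    p_value: float
    effect_size: float | None = None


def roc_curve(
    positives: Sequence[float],
    negatives: Sequence[float],
    direction: str = "higher_is_positive",
) -> RocCurve:
    """Empirical ROC curve of a score against binary group membership."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    sign = 1.0 if direction == "higher_is_positive" else -1.0
    p = sign * pos
    q = sign * neg
    # oriented thresholds, descending; +inf sentinel = classify nothing positive
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([p, q]))[::-1]])
    tpr = (p[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (q[None, :] >= thresholds[:, None]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    cutoffs = sign * thresholds
    j = tpr - fpr
    # tie-break: larger J, then smaller FPR, then smaller original cutoff
    best = min(range(thresholds.size), key=lambda i: (-j[i], fpr[i], cutoffs[i]))
    return RocCurve(
        cutoffs=cutoffs,
        tpr=tpr,
        fpr=fpr,
        auc_roc=auc,
        youden_j=float(j[best]),
        optimal_cutoff=float(cutoffs[best]),
        direction=direction,
    )


def youden_optimal(roc: RocCurve) -> tuple[float, float]:
    """Youden index J = max(TPR - FPR) and its cutoff.

    Ties are broken toward the smaller false-positive rate, then the
    smaller cutoff.
    """
    j = roc.tpr - roc.fpr
    best = min(range(roc.cutoffs.size), key=lambda i: (-j[i], roc.fpr[i], roc.cutoffs[i]))
    return float(j[best]), float(roc.cutoffs[best])


def wilcoxon_ranksum(
    x: Sequence[float],
    y: Sequence[float],
    *,
    continuity: bool = True,
) -> ContrastResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks for ties; p-value from the normal approximation with the
    tie-corrected variance and a +/-0.5 continuity correction.  The
    reported statistic is the Mann-Whitney count W = U for the first
    sample (number of (x, y) pairs with x > y, ties counting one-half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        raise ValueError("degenerate variance: all pooled values are tied")
    z = u - mu
    if continuity:
        z -= math.copysign(0.5, z) if z != 0 else 0.0
    z /= math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return ContrastResult(statistic=u, df=None, p_value=float(p))


def _encode_terms(
    group: Sequence,
    covariates: Mapping[str, Sequence] | None,
    n: int,
) -> dict[str, tuple[np.ndarray, list[str]]]:
    """Term name -> (column block, column labels); factors as treatment dummies."""
    terms: dict[str, tuple[np.ndarray, list[str]]] = {}

    def dummies(values, name):
        values = np.asarray(values)
        levels = sorted(set(values.tolist()))
        if len(levels) < 2:
            raise ValueError(f"term {name!r} has a single level")
        cols = np.column_stack([(values == lv).astype(float) for lv in levels[1:]])
        return cols, [f"{name}[{lv}]" for lv in levels[1:]]

    terms["group"] = dummies(group, "group")
    for name, values in (covariates or {}).items():
        arr = np.asarray(values)
        if arr.shape[0] != n:
            raise ValueError(f"covariate {name!r} has length {arr.shape[0]}, expected {n}")
        if arr.dtype.kind in "OUSb":
            terms[name] = dummies(arr, name)
        else:
            terms[name] = (arr.astype(float).reshape(-1, 1), [name])
    return terms


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def partial_f_ancova(
    response: Sequence[float],
    group: Sequence,
    covariates: Mapping[str, Sequence] | None = None,
) -> dict[str, ContrastResult]:
    """Gaussian linear model with drop-one F tests per term.

    Fits ``response ~ group + covariates`` by least squares (QR) and, for
    each term, compares the full model against the model with that term
    removed.  Reports F, (df1, df2), p and partial eta-squared
    SS_term / (SS_term + SS_residual).  Categorical covariates (including
    the group factor) enter as treatment-coded dummies; with no
    interactions the drop-one sums of squares coincide with Type-III.
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    terms = _encode_terms(group, covariates, n)
    blocks = [block for block, _ in terms.values()]
    labels = ["intercept"] + [lab for _, labs in terms.values() for lab in labs]
    X = np.column_stack([np.ones(n)] + blocks)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more parameters than observations")
    # rank check with column pivoting so aliased columns can be named
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if np.any(diag < tol):
        aliased = [labels[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    sse_full = _sse(X, y)
    df_resid = n - X.shape[1]
    out: dict[str, ContrastResult] = {}
    for name, (block, _) in terms.items():
        X_red = np.column_stack(
            [np.ones(n)] + [b for t, (b, _) in terms.items() if t != name]
        )
        ss_term = _sse(X_red, y) - sse_full
        df1 = block.shape[1]
        f = (ss_term / df1) / (sse_full / df_resid)
        p = float(stats.f.sf(f, df1, df_resid))
        eta = ss_term / (ss_term + sse_full)
        out[name] = ContrastResult(
            statistic=float(f), df=(df1, df_resid), p_value=p, effect_size=float(eta)
        )
    return out


def bartlett_test(groups: Sequence[Sequence[float]]) -> ContrastResult:
    """Bartlett's test of equal variances across groups.

    K^2 with the standard correction factor, referred to a chi-square with
    g - 1 degrees of freedom.  Requires >= 2 groups of >= 2 observations
    each with positive variance.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    g = len(arrs)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    ni = np.array([a.size for a in arrs], dtype=float)
    vi = np.array([a.var(ddof=1) for a in arrs])
    if np.any(vi == 0):
        raise ValueError("a group has zero variance")
    n = ni.sum()
    sp2 = float(((ni - 1) * vi).sum() / (n - g))
    k2 = float((n - g) * math.log(sp2) - ((ni - 1) * np.log(vi)).sum())
    c = 1.0 + (float((1.0 / (ni - 1)).sum()) - 1.0 / (n - g)) / (3.0 * (g - 1))
    k2 /= c
    p = float(stats.chi2.sf(k2, g - 1))
    return ContrastResult(statistic=k2, df=g - 1, p_value=p)
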