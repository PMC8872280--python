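"""Discount functions mapping delay to subjective value.

Two single-parameter families are supported:

* hyperbolic:   SV(D) = 1 / (1 + k D)      (Mazur)
* exponential:  SV(D) = exp(-k D)          (Samuelson)

``SV`` is the subjective value of a delayed reward expressed as a fraction
of its face amount, ``D`` the delay in days and ``k`` the per-day discount
rate.  Both families equal 1 at zero delay and decrease monotonically in
both ``k`` and ``D``.
"""

from __future__ import annotations

import numpy as np

MODELS = ("hyperbolic", "exponential")


def subjective_value(model: str, k: float, delay_days):
    """Subjective value (fraction of the delayed amount) at delay ``D``.

    Parameters
    ----------
    model : {"hyperbolic", "exponential"}
    k : float
        Per-day discount rate, ``k >= 0``.
    delay_days : float or array-like
        Delay in days, ``D >= 0``.

    Returns
    -------
    float or ndarray in (0, 1].
    """
    if model not in MODELS:
        raise ValueError(f"unknown discount model {model!r}; expected one of {MODELS}")
    if k < 0:
        raise ValueError(f"discount rate k must be >= 0, got {k}")
    d = np.asarray(delay_days, dtype=float)
    if np.any(d < 0):
        raise ValueError("delay must be >= 0 days")
    if model == "hyperbolic":
        sv = 1.0 / (1.0 + k * d)
    else:
        sv = np.exp(-k * d)
    if np.ndim(delay_days) == 0:
        return float(sv)
    return sv
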