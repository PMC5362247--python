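"""Decay kinetics: relative quantification and semi-log half-life fits.

Shutoff time courses (transcription inhibitor for mRNA, translation
inhibitor for protein) are fit by ordinary least squares of log abundance on
time; first-order decay gives ``t1/2 = ln(2) / k`` with ``k = -slope``.

qPCR input is converted to relative abundance with the comparative-Ct
method against a reference RNA measured on the same time grid:
``abundance(t) = 2 ** -((Ct_t(t) - Ct_ref(t)) - (Ct_t(0) - Ct_ref(0)))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import AlignmentError, DomainError, InsufficientDataError

LN2 = math.log(2.0)

#: Slopes with decay rate below this (per minute) are reported as non-decaying.
MIN_DECAY_RATE = 1e-6


@dataclass
class DecayTimeCourse:
    label: str
    times: np.ndarray       # minutes, strictly increasing, >= 0
    abundances: np.ndarray  # relative units, > 0

    def __init__(self, label: str, times: Sequence[float], abundances: Sequence[float]):
        self.label = label
        self.times = np.asarray(times, dtype=float)
        self.abundances = np.asarray(abundances, dtype=float)
        if self.times.size != self.abundances.size:
            raise AlignmentError("times and abundances differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise DomainError("times must be >= 0")
        if np.any(~np.isfinite(self.abundances)) or np.any(self.abundances <= 0):
            raise DomainError("abundances must be finite and > 0")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class DecayFit:
    label: str
    k: float                  # decay rate, 1/min (0 when non-decaying)
    half_life: float | None   # minutes; None when non-decaying
    intercept: float          # log-abundance at t=0
    r_squared: float          # clamped to [0, 1]
    non_decaying: bool = False
    r_squared_clamped: bool = False


def relative_quantity(
    times: Sequence[float],
    ct_target: Sequence[float],
    ct_reference: Sequence[float],
    label: str = "",
) -> DecayTimeCourse:
    """Comparative-Ct relative abundance series, anchored to the first point.

    The first time point (nominally t=0) defines the baseline delta-Ct, so
    its abundance is exactly 1.
    """
    t = np.asarray(times, dtype=float)
    tgt = np.asarray(ct_target, dtype=float)
    ref = np.asarray(ct_reference, dtype=float)
    if not (t.size == tgt.size == ref.size):
        raise AlignmentError("time, target-Ct, and reference-Ct series differ in length")
    if np.any(~np.isfinite(tgt)) or np.any(~np.isfinite(ref)):
        raise DomainError("Ct values must be finite")
    delta = tgt - ref
    ddct = delta - delta[0]
    return DecayTimeCourse(label=label, times=t, abundances=np.power(2.0, -ddct))


def fit_decay(tc: DecayTimeCourse, nonlinear: bool = False) -> DecayFit:
    """Fit first-order decay to a time course.

    Default: OLS of ln(abundance) on time (the semi-log method). With
    ``nonlinear=True`` a nonlinear least-squares exponential fit is used
    instead (r_squared is then computed in log space for comparability).
    Slopes at or above ``-MIN_DECAY_RATE`` are flagged non-decaying.
    """
    if len(tc) < 3:
        raise InsufficientDataError(f"decay fit needs >= 3 points, got {len(tc)}")
    log_a = np.log(tc.abundances)
    res = stats.linregress(tc.times, log_a)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2

    if nonlinear:
        def model(t, a0, k):
            return a0 * np.exp(-k * t)

        (a0, k_nl), _ = optimize.curve_fit(
            model,
            tc.times,
            tc.abundances,
            p0=[math.exp(intercept), max(-slope, MIN_DECAY_RATE)],
            maxfev=10000,
        )
        slope, intercept = -float(k_nl), math.log(abs(a0))
        pred = np.log(model(tc.times, a0, k_nl))
        ss_res = float(np.sum((log_a - pred) ** 2))
        ss_tot = float(np.sum((log_a - log_a.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    clamped = not (0.0 <= r2 <= 1.0)
    r2 = min(max(r2, 0.0), 1.0)
    k = -slope
    if k <= MIN_DECAY_RATE:
        return DecayFit(
            label=tc.label,
            k=0.0,
            half_life=None,
            intercept=intercept,
            r_squared=r2,
            non_decaying=True,
            r_squared_clamped=clamped,
        )
    return DecayFit(
        label=tc.label,
        k=k,
        half_life=LN2 / k,
        intercept=intercept,
        r_squared=r2,
        r_squared_clamped=clamped,
    )
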