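"""Weighted inter-patient correlation analysis with t-based significance.

Patients contribute one observation each (mean CTV motion amplitude,
mean breathing period, mean single-fraction interplay d5/d95, CTV
volume); the number of repeated motion measurements per patient acts as
a frequency weight.  Significance of a weighted Pearson coefficient
rho_w uses the test statistic

    t = rho_w * sqrt((N - 2) / (1 - rho_w^2)),

compared one-sided against the Student-t critical value at a 95%
confidence level.  Both degrees-of-freedom conventions (N - 2 = 7 and
df = 9 for N = 9) are supported for the critical value; the default
``df=9`` matches the tabulated t_crit = 1.833 commonly used with N = 9
observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_TCRIT_DF = 9


@dataclass(frozen=True)
class PatientObservation:
    """One patient's summary row for the correlation analysis."""

    patient_id: str
    amplitude_mm: float  # mean CTV motion amplitude over measurements
    period_s: float  # mean breathing period
    d5d95: float  # mean single-fraction interplay d5/d95
    ctv_volume_cc: float
    weight: int  # number of repeated motion measurements

    def __post_init__(self) -> None:
        if self.weight < 1 or int(self.weight) != self.weight:
            raise ValueError("weight must be a positive integer")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be non-negative")
        if self.d5d95 < 1.0 - 1e-9:
            raise ValueError("d5/d95 must be >= 1")


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation with frequency-weight semantics.

    Equals the unweighted coefficient on the sample with each point
    replicated ``w`` times (for integer w); reduces to ordinary Pearson
    for equal weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def t_statistic(rho: float, n: int) -> float:
    """t = rho * sqrt((N - 2) / (1 - rho^2)) for a correlation coefficient.

    Signed; use ``abs`` for a magnitude comparison against a one-sided
    critical value.  |rho| = 1 yields a signed infinity (degenerate,
    trivially significant).
    """
    if n < 3:
        raise ValueError("need N >= 3")
    if abs(rho) >= 1.0:
        return float(np.sign(rho) * np.inf)
    return float(rho * np.sqrt((n - 2) / (1.0 - rho * rho)))


def critical_t(confidence: float = 0.95, df: int = DEFAULT_TCRIT_DF) -> float:
    """One-sided Student-t critical value (1.833 at 95%, df = 9)."""
    return float(sps.t.ppf(confidence, df))


def significance(t: float, t_crit: Optional[float] = None) -> bool:
    """Significant iff t > t_crit (strict inequality)."""
    if t_crit is None:
        t_crit = critical_t()
    return bool(t > t_crit)


def correlation_suite(
    observations: Sequence[PatientObservation],
    t_crit: Optional[float] = None,
) -> pd.DataFrame:
    """The four inter-patient correlation rows.

    Weighted: amplitude vs d5/d95, period vs amplitude, period vs
    d5/d95.  Unweighted: CTV volume vs d5/d95 (volumes are constant
    over fractions, so measurement counts carry no information there).
    Each row reports rho, t, |t| and the significance decision.
    """
    if t_crit is None:
        t_crit = critical_t()
    obs = list(observations)
    n = len(obs)
    amp = [o.amplitude_mm for o in obs]
    per = [o.period_s for o in obs]
    dd = [o.d5d95 for o in obs]
    vol = [o.ctv_volume_cc for o in obs]
    w = [o.weight for o in obs]
    ones = [1] * n
    pairs = [
        ("amplitude_vs_d5d95", amp, dd, w),
        ("period_vs_amplitude", per, amp, w),
        ("period_vs_d5d95", per, dd, w),
        ("volume_vs_d5d95", vol, dd, ones),
    ]
    rows = []
    for name, x, y, weights in pairs:
        rho = weighted_pearson(x, y, weights)
        t = t_statistic(rho, n)
        rows.append(
            {
                "pair": name,
                "weighted": weights is w,
                "rho": rho,
                "t": t,
                "abs_t": abs(t),
                "t_crit": t_crit,
                "significant": significance(t, t_crit),
            }
        )
    return pd.DataFrame(rows)
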