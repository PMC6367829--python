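"""DVH curves, scalar dose metrics, and scenario comparisons.

Doses are handled in % of the prescription.  Percentile metrics (d2,
d5, d95) use the linear-interpolation quantile of the sorted voxel-dose
list, so d5/d95 is bit-reproducible given a dose grid; volume metrics
(v95, v107, v30) are exact voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

CTV_METRICS = ("dmean", "d2", "d5", "d95", "d5d95", "v95", "v107")


@dataclass
class DvhCurve:
    """Cumulative DVH: fraction of volume receiving at least each dose.

    ``dose`` is a dense non-negative grid (% of prescription) and
    ``volume`` the corresponding volume fraction, monotone
    non-increasing from 1.  The sorted voxel doses are retained so
    percentile queries are exact rather than bin-limited.
    """

    structure: str
    dose: np.ndarray
    volume: np.ndarray
    voxel_doses_sorted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"structure": self.structure, "dose_pct": self.dose,
             "volume_fraction": self.volume}
        )


def compute_dvh(
    dose: np.ndarray, mask: np.ndarray, structure: str = "", bin_width: float = 0.1
) -> DvhCurve:
    """Exact voxel-counting cumulative DVH of a structure.

    ``bin_width`` (in % of prescription) controls only the exported
    dense curve; queries interpolate on the raw voxel doses.
    """
    if not mask.any():
        raise ValueError("structure mask is empty")
    vals = np.sort(np.asarray(dose)[mask].ravel())
    top = max(float(vals[-1]) * 1.02, 1.0)
    grid = np.arange(0.0, top + bin_width, bin_width)
    # fraction of voxels with dose >= d
    frac = 1.0 - np.searchsorted(vals, grid, side="left") / vals.size
    return DvhCurve(structure, grid, frac, vals)


def d_at_volume(dvh: DvhCurve, p: float) -> float:
    """Dose (% of prescription) received by at least p% of the volume.

    Linear-interpolation quantile on the sorted voxel doses: d_p is the
    (1 - p/100) quantile, e.g. d95 is the near-minimum dose covering
    95% of the structure.
    """
    if not 0 < p <= 100:
        raise ValueError("p must be in (0, 100]")
    return float(np.quantile(dvh.voxel_doses_sorted, 1.0 - p / 100.0))


def v_at_dose(dvh: DvhCurve, level: float) -> float:
    """Percentage of the structure volume receiving at least ``level``%."""
    if level < 0:
        raise ValueError("dose level must be non-negative")
    n = dvh.voxel_doses_sorted.size
    return 100.0 * (n - np.searchsorted(dvh.voxel_doses_sorted, level, side="left")) / n


def metrics_from_values(voxel_doses: np.ndarray) -> Dict[str, float]:
    """Scalar metric set from a structure's voxel-dose vector."""
    vals = np.sort(np.asarray(voxel_doses, dtype=float).ravel())
    if vals.size == 0:
        raise ValueError("no voxels")
    n = vals.size

    def d_at(p: float) -> float:
        return float(np.quantile(vals, 1.0 - p / 100.0))

    def v_at(level: float) -> float:
        return 100.0 * (n - np.searchsorted(vals, level, side="left")) / n

    d5 = d_at(5)
    d95 = d_at(95)
    return {
        "dmean": float(vals.mean()),
        "d2": d_at(2),
        "d5": d5,
        "d95": d95,
        "d5d95": d5 / d95 if d95 > 0 else np.inf,
        "v95": v_at(95.0),
        "v107": v_at(107.0),
        "v30": v_at(30.0),
    }


def structure_metrics(dose: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    """Scalar metric set for one structure: dmean, d2/d5/d95, v95/v107/v30."""
    if not mask.any():
        raise ValueError("structure mask is empty")
    return metrics_from_values(np.asarray(dose)[mask])


def dose_report(
    dose: np.ndarray, structures, names: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Metric table over a set of structures (one row per structure)."""
    if names is None:
        names = structures.names()
    rows = []
    for name in names:
        row = {"structure": name}
        row.update(structure_metrics(dose, structures[name]))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_scenarios(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "greater",
    alpha: float = 0.05,
) -> Tuple[float, bool, bool]:
    """One-sided Wilcoxon rank-sum test between two metric samples.

    Exact null distribution for combined n <= 20 without ties, normal
    approximation with tie correction otherwise.  Returns (p-value,
    reject-at-alpha, all-tied flag); fully tied samples return the
    p = 0.5 convention, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.5, False, True
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    p = float(res.pvalue)
    return p, p < alpha, False
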