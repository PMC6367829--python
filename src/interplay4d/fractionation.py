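"""Stochastic fractionated-treatment simulation and interplay mitigation.

Every fraction of a simulated treatment draws, independently and
uniformly, a motion input m and a starting-phase pair (i, k) for the
two fields; the cumulative dose after n fractions is the mean of the
first n fraction doses (doses are in % of the per-fraction
prescription, so the running mean keeps metrics comparable across n).
Randomness comes from the counter-based Philox generator, one named
seed per realization, so realizations are reproducible and
order-independent to simulate in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .four_d import InterplayEngine, StartingPhasePair, N_PHASES
from .metrics import metrics_from_values

METRIC_COLS = ("dmean", "d2", "d5", "d95", "d5d95", "v95", "v107")


@dataclass
class TreatmentRealization:
    """One simulated fractionated treatment.

    ``provenance`` lists (motion_id, i, k) per fraction; ``per_n`` has
    one row per fraction count n with the CTV metrics of the cumulative
    (running-mean) dose.
    """

    seed: int
    provenance: List[Tuple[str, int, int]]
    per_n: pd.DataFrame
    final_ctv_dose: np.ndarray

    @property
    def n_fractions(self) -> int:
        return len(self.provenance)

    def metric_at(self, name: str, n: int) -> float:
        return float(self.per_n.loc[self.per_n["n"] == n, name].iloc[0])


def simulate_treatment(
    engine: InterplayEngine,
    n_fractions: int = 28,
    seed: int = 0,
    m_ids: Optional[Sequence[str]] = None,
) -> TreatmentRealization:
    """Simulate one fractionated treatment with random (m, i, k) draws.

    Deterministic given the seed.  The cumulative CTV dose after n
    fractions is the mean of the first n fraction doses; metrics are
    recorded for every n in 1..n_fractions.
    """
    if m_ids is None:
        m_ids = list(engine.motions)
    if len(m_ids) == 0:
        raise ValueError("need at least one motion input")
    rng = np.random.Generator(np.random.Philox(seed))
    provenance: List[Tuple[str, int, int]] = []
    cum = None
    rows = []
    for n in range(1, n_fractions + 1):
        m = m_ids[rng.integers(len(m_ids))]
        i = int(rng.integers(N_PHASES))
        k = int(rng.integers(N_PHASES))
        provenance.append((m, i, k))
        vec = engine.field_dose_4d(m, 0, i) + engine.field_dose_4d(m, 1, k)
        cum = vec.copy() if cum is None else cum + vec
        row = {"n": n}
        row.update(metrics_from_values(cum / n))
        rows.append(row)
    return TreatmentRealization(
        seed=seed,
        provenance=provenance,
        per_n=pd.DataFrame(rows),
        final_ctv_dose=cum / n_fractions,
    )


def simulate_ensemble(
    engine: InterplayEngine,
    n_sim: int,
    n_fractions: int = 28,
    seed: int = 0,
    m_ids: Optional[Sequence[str]] = None,
) -> List[TreatmentRealization]:
    """``n_sim`` independent treatments with seeds spawned from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(n_sim) % (2**31)
    return [
        simulate_treatment(engine, n_fractions, int(s), m_ids) for s in seeds
    ]


def fractionation_curve(realizations: Sequence[TreatmentRealization]) -> pd.DataFrame:
    """Per-n distribution summaries of the cumulative-dose CTV metrics.

    For each metric: median and quartiles over realizations; plus, per
    realization, the first fraction count at which v95 = 100% and
    v107 = 0% (NaN if never reached).
    """
    if len(realizations) == 0:
        raise ValueError("need at least one realization")
    frames = []
    for r in realizations:
        df = r.per_n.copy()
        df["seed"] = r.seed
        frames.append(df)
    allruns = pd.concat(frames, ignore_index=True)
    records = []
    for n, group in allruns.groupby("n"):
        rec = {"n": int(n)}
        for m in METRIC_COLS:
            rec[f"{m}_median"] = float(group[m].median())
            rec[f"{m}_q25"] = float(group[m].quantile(0.25))
            rec[f"{m}_q75"] = float(group[m].quantile(0.75))
        records.append(rec)
    return pd.DataFrame(records)


def first_n_to_coverage(realization: TreatmentRealization) -> Dict[str, float]:
    """First n with full coverage (v95 = 100%) and no hot spots (v107 = 0%)."""
    df = realization.per_n

    def first(cond: pd.Series) -> float:
        hits = df.loc[cond, "n"]
        return float(hits.iloc[0]) if len(hits) else float("nan")

    return {
        "first_n_v95_100": first(df["v95"] >= 100.0),
        "first_n_v107_0": first(df["v107"] <= 0.0),
    }


def longitudinal_comparison(
    engine: InterplayEngine,
    single_m: str,
    all_m: Optional[Sequence[str]] = None,
    n_sim: int = 30,
    n_fractions: int = 28,
    seed: int = 0,
) -> pd.DataFrame:
    """Single- vs multi-measurement estimate of the interplay evolution.

    Simulates ``n_sim`` treatments using only ``single_m`` (a single
    pre-treatment acquisition) and ``n_sim`` treatments sampling the
    motion input per fraction from ``all_m``; returns per-n ensemble
    means of d5/d95 for both arms and their absolute difference.
    """
    if all_m is None:
        all_m = list(engine.motions)
    if len(all_m) < 2:
        raise ValueError("need at least two motion inputs for the comparison")
    arm_single = simulate_ensemble(
        engine, n_sim, n_fractions, seed=seed, m_ids=[single_m]
    )
    arm_all = simulate_ensemble(
        engine, n_sim, n_fractions, seed=seed + 1, m_ids=list(all_m)
    )

    def mean_curve(realizations: Sequence[TreatmentRealization]) -> pd.Series:
        stacked = pd.concat([r.per_n for r in realizations])
        return stacked.groupby("n")["d5d95"].mean()

    single = mean_curve(arm_single)
    multi = mean_curve(arm_all)
    return pd.DataFrame(
        {
            "n": single.index,
            "d5d95_single": single.values,
            "d5d95_multi": multi.values,
            "abs_diff": np.abs(single.values - multi.values),
        }
    )
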