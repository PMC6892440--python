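"""Severity labelling of affected sib pairs and Δ-score cohort construction.

Each pair of affected sibs is labelled by ADI-R total cumulative social score
(SOCT_CS, higher = more severe): the sib with the higher score is the *severe*
sib, the other the *mild* sib, and Δ = |severe − mild|.  Pairs are then
stratified into a large-difference cohort (Δ ≥ 10), a small-difference cohort
(Δ ≤ 4), and an excluded middle (4 < Δ < 10).  Thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SibPair",
    "CohortPartition",
    "PairRejection",
    "assign_severity",
    "label_pairs",
    "partition_pairs",
    "cohort_summary",
]

PHENOTYPE_COLUMNS = ("sample_id", "family_id", "sex", "age_years", "soct_cs")


class PairRejection(ValueError):
    """Raised when a sib pair cannot be severity-labelled (e.g. missing score)."""


@dataclass(frozen=True)
class SibPair:
    """A pair of affected sibs; labelled fields are filled by :func:`assign_severity`."""

    family_id: str
    sib_a: str
    sib_b: str
    severe_id: Optional[str] = None
    mild_id: Optional[str] = None
    delta: Optional[int] = None
    tie: bool = False

    def __post_init__(self) -> None:
        if self.sib_a == self.sib_b:
            raise ValueError(f"pair {self.family_id}: sib_a and sib_b are identical")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be non-negative")

    @property
    def labeled(self) -> bool:
        return self.severe_id is not None


def assign_severity(pair: SibPair, scores: Mapping[str, float]) -> SibPair:
    """Label the severe/mild sibs of a pair from a sample → SOCT_CS mapping.

    The severe sib is the one with the higher score.  Equal scores produce a
    deterministic lexicographic tie-break on sample id with ``tie=True`` set;
    a missing or non-finite score raises :class:`PairRejection`.
    """
    vals = {}
    for sib in (pair.sib_a, pair.sib_b):
        score = scores.get(sib)
        if score is None or (isinstance(score, float) and not np.isfinite(score)):
            raise PairRejection(f"pair {pair.family_id}: missing SOCT_CS for sample {sib!r}")
        vals[sib] = float(score)
    a, b = pair.sib_a, pair.sib_b
    if vals[a] == vals[b]:
        severe, mild = sorted((a, b))
        tie = True
    else:
        severe, mild = (a, b) if vals[a] > vals[b] else (b, a)
        tie = False
    return SibPair(
        family_id=pair.family_id,
        sib_a=pair.sib_a,
        sib_b=pair.sib_b,
        severe_id=severe,
        mild_id=mild,
        delta=abs(vals[a] - vals[b]),
        tie=tie,
    )


def label_pairs(pairs: pd.DataFrame, phenotypes: pd.DataFrame):
    """Severity-label every pair in a pairs table.

    Returns ``(labelled_pairs, rejections)`` where rejections is a DataFrame
    (family_id, reason) for pairs lacking usable scores.
    """
    scores = dict(zip(phenotypes["sample_id"], phenotypes["soct_cs"]))
    labelled: List[SibPair] = []
    rejected = []
    for row in pairs.itertuples(index=False):
        pair = SibPair(family_id=str(row.family_id), sib_a=str(row.sib_a), sib_b=str(row.sib_b))
        try:
            labelled.append(assign_severity(pair, scores))
        except PairRejection as exc:
            rejected.append({"family_id": pair.family_id, "reason": str(exc)})
    return labelled, pd.DataFrame(rejected, columns=["family_id", "reason"])


@dataclass
class CohortPartition:
    """Δ-stratified pair cohorts: ``large`` (Δ ≥ large_min), ``small`` (Δ ≤ small_max)."""

    large: List[SibPair] = field(default_factory=list)
    small: List[SibPair] = field(default_factory=list)
    excluded: List[SibPair] = field(default_factory=list)
    large_min: float = 10
    small_max: float = 4

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cohort, pairs in (("large", self.large), ("small", self.small), ("excluded", self.excluded)):
            for p in pairs:
                rows.append(
                    {
                        "family_id": p.family_id,
                        "delta": p.delta,
                        "cohort": cohort,
                        "severe_id": p.severe_id,
                        "mild_id": p.mild_id,
                        "tie": p.tie,
                    }
                )
        return pd.DataFrame(rows, columns=["family_id", "delta", "cohort", "severe_id", "mild_id", "tie"])


def partition_pairs(
    pairs: Sequence[SibPair], large_min: float = 10, small_max: float = 4
) -> CohortPartition:
    """Partition labelled pairs into large-Δ / small-Δ / excluded cohorts.

    Thresholds are inclusive (Δ = 10 is large, Δ = 4 is small); pairs strictly
    between the thresholds are excluded.  ``large_min`` must exceed
    ``small_max`` so the cohorts are disjoint.
    """
    if large_min <= small_max:
        raise ValueError(f"large_min ({large_min}) must exceed small_max ({small_max})")
    part = CohortPartition(large_min=large_min, small_max=small_max)
    for pair in pairs:
        if not pair.labeled:
            raise ValueError(f"pair {pair.family_id} is not severity-labelled")
        if pair.delta >= large_min:
            part.large.append(pair)
        elif pair.delta <= small_max:
            part.small.append(pair)
        else:
            part.excluded.append(pair)
    return part


def _welch(x: np.ndarray, y: np.ndarray):
    if len(x) < 2 or len(y) < 2:
        return np.nan, np.nan
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate: no within-group variability
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def cohort_summary(partition: CohortPartition, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort severe/mild score means ± SEM and a two-sided Welch t-test.

    Cohorts with fewer than two pairs get NaN statistics (flagged via the
    ``n`` column rather than an error).
    """
    scores = dict(zip(phenotypes["sample_id"], phenotypes["soct_cs"]))
    rows = []
    for cohort, pairs in (("large", partition.large), ("small", partition.small)):
        sev = np.array([scores[p.severe_id] for p in pairs], dtype=float)
        mild = np.array([scores[p.mild_id] for p in pairs], dtype=float)
        n = len(pairs)
        t, p = _welch(sev, mild)
        rows.append(
            {
                "cohort": cohort,
                "n_pairs": n,
                "severe_mean": sev.mean() if n else np.nan,
                "severe_sem": stats.sem(sev) if n > 1 else np.nan,
                "mild_mean": mild.mean() if n else np.nan,
                "mild_sem": stats.sem(mild) if n > 1 else np.nan,
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
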