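"""Inter-rater agreement and tuning protocol for paired manual measurements.

Two independent raters measure the same set of structures; agreement is
quantified per descriptor by a symmetric mismatch percentage

    mismatch(v1, v2) = |v1 - v2| / mean(v1, v2) * 100,

pairs are *matched* when their mismatch is within a tolerance (the study
convention is +/-3 %), and disagreeing pairs are iterated through an
auditable revise-and-remeasure tuning loop.  A linear calibration of rater 2
on rater 1 summarizes the systematic component of the disagreement, with the
percentage error E = 100 * b / x-bar (intercept over the pooled mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaterPairTable",
    "TuningRound",
    "TuningReport",
    "RaterRegression",
    "mismatch_percent",
    "match_rate",
    "tuning_loop",
    "rater_regression",
]


@dataclass(frozen=True)
class RaterPairTable:
    """Aligned rater-1/rater-2 measurement pairs for one descriptor."""

    table: pd.DataFrame  # columns: patient_id, side, rater1, rater2
    descriptor: str = "volume_cm3"
    units: str = "cm3"

    def __post_init__(self) -> None:
        required = {"patient_id", "side", "rater1", "rater2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pair table missing columns {sorted(missing)}")
        if self.table[["rater1", "rater2"]].isna().any().any():
            raise ValueError("pair table has orphan (unpaired) measurements")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def values(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.table["rater1"].to_numpy(float),
                self.table["rater2"].to_numpy(float))

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, descriptor: str = "volume_cm3",
                    units: str = "") -> "RaterPairTable":
        """Pivot a tidy cohort table (one row per patient/hemisphere/rater)
        into aligned rater pairs for one descriptor."""
        wide = cohort.pivot_table(index=["patient_id", "hemisphere"],
                                  columns="rater", values=descriptor)
        if wide.isna().any().any():
            raise ValueError("cohort table has unpaired measurements")
        out = wide.reset_index().rename(
            columns={"hemisphere": "side", 1: "rater1", 2: "rater2"})
        out.columns.name = None
        return cls(table=out[["patient_id", "side", "rater1", "rater2"]],
                   descriptor=descriptor, units=units)


def mismatch_percent(m1: float, m2: float) -> float:
    """Symmetric percentage mismatch between two positive measurements.

    ``|m1 - m2| / ((m1 + m2)/2) * 100`` — symmetric, zero iff equal, and
    scale invariant.
    """
    m1, m2 = float(m1), float(m2)
    if m1 <= 0 or m2 <= 0:
        raise ValueError("mismatch is defined for positive measurements only")
    return abs(m1 - m2) / ((m1 + m2) / 2.0) * 100.0


def match_rate(pairs: RaterPairTable, tolerance: float = 3.0
               ) -> tuple[int, int, int]:
    """Count pairs whose mismatch is within ``tolerance`` percent.

    Returns ``(matched, total, percent)`` with the percentage rounded to the
    nearest integer for reporting.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    v1, v2 = pairs.values
    mm = np.abs(v1 - v2) / ((v1 + v2) / 2.0) * 100.0
    matched = int((mm <= tolerance).sum())
    total = len(pairs)
    return matched, total, int(round(100.0 * matched / total))


@dataclass(frozen=True)
class TuningRound:
    round_index: int
    mismatch_percent: pd.Series       # per pair, keyed like the pair table
    flagged: tuple[tuple, ...]        # (patient_id, side) keys above threshold
    mean_mismatch: float


@dataclass(frozen=True)
class TuningReport:
    rounds: tuple[TuningRound, ...]
    converged: bool
    final_match_rate: int             # percent, integer
    threshold: float

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


RevisionCallback = Callable[[RaterPairTable, list[tuple]], RaterPairTable]


def tuning_loop(pairs: RaterPairTable, threshold: float = 3.0,
                revise: RevisionCallback | None = None,
                max_rounds: int = 10) -> TuningReport:
    """Iterate the flag -> revise -> re-measure protocol until agreement.

    Each round computes per-pair mismatches, flags pairs above ``threshold``
    percent, and (when flagged pairs remain) hands them to ``revise``, which
    returns an updated pair table — standing in for the human re-tracing
    step.  The loop stops when the summary (mean) mismatch drops to the
    threshold, when nothing changes, or at ``max_rounds``.  The full audit
    trail is retained.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    rounds: list[TuningRound] = []
    current = pairs
    converged = False
    for rnd in range(max_rounds):
        v1, v2 = current.values
        mm = pd.Series(np.abs(v1 - v2) / ((v1 + v2) / 2.0) * 100.0,
                       index=pd.MultiIndex.from_frame(
                           current.table[["patient_id", "side"]]))
        flagged = tuple(mm.index[mm > threshold])
        rounds.append(TuningRound(round_index=rnd, mismatch_percent=mm,
                                  flagged=flagged,
                                  mean_mismatch=float(mm.mean())))
        if rounds[-1].mean_mismatch <= threshold:
            converged = True
            break
        if revise is None:
            break
        current = revise(current, list(flagged))
    matched, total, pct = match_rate(current, tolerance=threshold)
    return TuningReport(rounds=tuple(rounds), converged=converged,
                        final_match_rate=pct, threshold=threshold)


@dataclass(frozen=True)
class RaterRegression:
    """OLS calibration of rater 2 on rater 1 for one descriptor."""

    slope: float
    intercept: float
    r_squared: float
    percent_error: float  # E = 100 * intercept / pooled mean
    pooled_mean: float

    def __post_init__(self) -> None:
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("R^2 must be in [0, 1]")
        expected = 100.0 * self.intercept / self.pooled_mean
        if abs(self.percent_error - expected) > 1e-9:
            raise ValueError("percent_error inconsistent with intercept/mean")


def rater_regression(pairs: RaterPairTable) -> RaterRegression:
    """Fit rater-2 values on rater-1 values by ordinary least squares.

    The percentage error is ``E = 100 * b / x-bar`` with ``b`` the intercept
    and ``x-bar`` the mean of the pooled values from both raters.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs to regress")
    v1, v2 = pairs.values
    if np.ptp(v1) == 0:
        raise ValueError("zero variance in the rater-1 predictor")
    fit = stats.linregress(v1, v2)
    pooled_mean = float(np.mean(np.concatenate([v1, v2])))
    return RaterRegression(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        percent_error=100.0 * float(fit.intercept) / pooled_mean,
        pooled_mean=pooled_mean)
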