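"""Study-level statistics for hippocampal volumetry cohorts.

Covers the statistical workflow of a cross-sectional manual-volumetry study:
finite-population sample-size calculation, Kolmogorov-Smirnov normality
screening, two-tailed t-tests (from raw data or from published summary
statistics), least-squares and weighted least-squares quadratic fits of
volume against age, grouped summaries by sex/hemisphere/rater, per-rater
descriptor-table averaging, and a probe relating low-volume structures to
the other morphological descriptors.

A cohort table is a tidy :class:`pandas.DataFrame` with one row per
patient x hemisphere x rater and the columns produced by
:func:`hippomorph.phantoms.simulate_cohort`.

No multiple-testing correction is applied anywhere in this module; reports
carry that caveat explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSizeParams",
    "StudySummary",
    "FitResult",
    "sample_size",
    "validate_cohort",
    "ks_normality",
    "t_test",
    "t_from_summary",
    "fit_volume_age",
    "group_summary",
    "table2_average",
    "low_volume_probe",
]

DESCRIPTOR_COLUMNS = ["volume_cm3", "aspect_ratio", "diameter_cm",
                      "roundness", "sphericity", "vs_ratio"]


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeParams:
    """Finite-population sample-size inputs.

    ``n = N Z^2 p q / (e^2 (N - 1) + Z^2 p q)`` with population size ``N``,
    confidence statistic ``Z``, success/failure probabilities ``p``/``q``
    (``p + q = 1``) and maximum estimation error ``e``.
    """

    population: int
    z: float
    p: float
    q: float
    e: float

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population size must be >= 1")
        if not (0 < self.p < 1 and 0 < self.q < 1):
            raise ValueError("p and q must be in (0, 1)")
        if abs(self.p + self.q - 1.0) > 1e-9:
            raise ValueError("p + q must equal 1")
        if self.e <= 0:
            raise ValueError("estimation error must be positive")
        if self.z <= 0:
            raise ValueError("Z must be positive")


def sample_size(params: SampleSizeParams) -> tuple[float, int]:
    """Finite-population sample size; returns ``(exact, rounded)``."""
    zpq = params.z ** 2 * params.p * params.q
    n = params.population * zpq / (params.e ** 2 * (params.population - 1) + zpq)
    return float(n), int(round(n))


# ---------------------------------------------------------------------------
# Normality and t-tests
# ---------------------------------------------------------------------------


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sanity-check a tidy cohort table (ages, duplicate records)."""
    required = {"patient_id", "age", "sex", "hemisphere", "rater", "volume_cm3"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if ((cohort["age"] < 0) | (cohort["age"] > 120)).any():
        raise ValueError("ages must lie within [0, 120] years")
    dup = cohort.duplicated(subset=["patient_id", "hemisphere", "rater"])
    if dup.any():
        raise ValueError("duplicate (patient, hemisphere, rater) records")
    return cohort


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    Compares the empirical CDF with a normal whose mean and SD are estimated
    from the sample, using the standard asymptotic p-value.  Estimating the
    parameters from the same data makes this test conservative (the
    Lilliefors caveat); that is logged, not corrected.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 values")
    sd = v.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(v.mean()))):
        raise ValueError("zero variance: KS normality test undefined")
    logger.debug("KS test with estimated mean/sd is conservative (Lilliefors)")
    d, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(d), float(p)


def t_test(values_a: np.ndarray, values_b: np.ndarray,
           variant: str = "welch") -> tuple[float, float, float]:
    """Two-sample two-tailed t-test; returns ``(t, df, p)``.

    ``variant``: ``"welch"`` (default, unequal variances) or ``"student"``
    (pooled variance).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    equal_var = _variant_equal_var(variant)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and np.mean(a) == np.mean(b):
        # degenerate identical groups: t = 0, p = 1 by convention
        df = len(a) + len(b) - 2.0
        return 0.0, df, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def t_from_summary(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int,
                   variant: str = "welch") -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns ``(t, df, p)``.

    Suitable for comparing published cohort summaries (mean, SD, n) against
    one's own, e.g. country-comparison tables.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("summary SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("summary group sizes must be >= 2")
    equal_var = _variant_equal_var(variant)
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2.0
    else:
        a, b = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
    return float(t), float(df), float(p)


def _variant_equal_var(variant: str) -> bool:
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    return variant == "student"


@dataclass(frozen=True)
class StudySummary:
    """Published cohort summary used in cross-study comparisons."""

    label: str
    n: int
    mean_volume_cm3: float
    sd_cm3: float | None = None
    age_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mean_volume_cm3 <= 0:
            raise ValueError("mean volume must be positive")
        if self.sd_cm3 is not None and self.sd_cm3 < 0:
            raise ValueError("sd must be >= 0")


# ---------------------------------------------------------------------------
# Volume-age fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Quadratic volume-age fit result.

    ``coefficients`` are highest power first (numpy polynomial order).  The
    vertex (peak age/volume) is undefined when the quadratic coefficient is
    ~0; then ``vertex_defined`` is False.
    """

    coefficients: tuple[float, float, float]
    r_squared: float
    peak_age: float | None
    peak_volume: float | None
    scheme: str
    vertex_defined: bool

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-9:
            raise ValueError("R^2 cannot exceed 1")


def fit_volume_age(cohort: pd.DataFrame, scheme: str = "ols",
                   eps: float = 1e-6) -> FitResult:
    """Degree-2 polynomial fit of volume on age.

    Schemes
    -------
    ``ols``
        Ordinary least squares.
    ``wls_residual``
        Two-stage: OLS first, then WLS with weights ``1 / (|residual| +
        eps)``.  (Down-weights poorly fit points; the literal
        weights-equal-residuals reading would up-weight outliers.)
    ``wls_literal``
        WLS with weights ``|residual| + eps`` from the first-stage OLS, kept
        for fidelity experiments with the residual-weighting description.
    ``wls_binned``
        WLS with each record weighted by the mean volume of its 5-year age
        bin.

    R^2 is computed on the weighted fit.
    """
    if len(cohort) < 6:
        raise ValueError("need at least 6 records")
    age = cohort["age"].to_numpy(float)
    vol = cohort["volume_cm3"].to_numpy(float)
    if np.ptp(age) < 1e-9:
        raise ValueError("insufficient spread in age")
    design = np.column_stack([age ** 2, age, np.ones_like(age)])
    if scheme == "ols":
        weights = np.ones_like(vol)
    elif scheme in ("wls_residual", "wls_literal"):
        ols_fit = sm.OLS(vol, design).fit()
        absres = np.abs(ols_fit.resid)
        weights = (1.0 / (absres + eps) if scheme == "wls_residual"
                   else absres + eps)
    elif scheme == "wls_binned":
        bins = np.floor((age - age.min()) / 5.0)
        bin_means = pd.Series(vol).groupby(bins).transform("mean").to_numpy()
        weights = bin_means
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    fit = sm.WLS(vol, design, weights=weights).fit()
    a2, a1, a0 = (float(c) for c in fit.params)
    vertex_defined = abs(a2) > 1e-12
    peak_age = -a1 / (2 * a2) if vertex_defined else None
    peak_vol = a0 - a1 ** 2 / (4 * a2) if vertex_defined else None
    return FitResult(coefficients=(a2, a1, a0),
                     r_squared=float(fit.rsquared),
                     peak_age=peak_age, peak_volume=peak_vol,
                     scheme=scheme, vertex_defined=vertex_defined)


# ---------------------------------------------------------------------------
# Group summaries and table averaging
# ---------------------------------------------------------------------------

_GROUP_LEVELS = {"sex": ("M", "F"), "hemisphere": ("R", "L"), "rater": (2, 1)}


def group_summary(cohort: pd.DataFrame, by: str,
                  value: str = "volume_cm3",
                  variant: str = "welch") -> dict:
    """Per-group mean/sd/n plus the pairwise difference and its t-test.

    ``by`` is one of ``sex``, ``hemisphere`` or ``rater``; the difference is
    reported with the conventional sign (male - female, right - left,
    rater2 - rater1).
    """
    if by not in _GROUP_LEVELS:
        raise ValueError("by must be 'sex', 'hemisphere' or 'rater'")
    hi, lo = _GROUP_LEVELS[by]
    g_hi = cohort.loc[cohort[by] == hi, value].to_numpy(float)
    g_lo = cohort.loc[cohort[by] == lo, value].to_numpy(float)
    if len(g_hi) == 0 or len(g_lo) == 0:
        raise ValueError(f"both {by} groups must be non-empty")
    if len(g_hi) >= 2 and len(g_lo) >= 2:
        t, df, p = t_test(g_hi, g_lo, variant=variant)
    else:  # single-measurement group: summary only, test undefined
        t = df = p = None
    summary = {
        str(hi): {"n": int(len(g_hi)), "mean": float(g_hi.mean()),
                  "sd": float(g_hi.std(ddof=1)) if len(g_hi) > 1 else 0.0},
        str(lo): {"n": int(len(g_lo)), "mean": float(g_lo.mean()),
                  "sd": float(g_lo.std(ddof=1)) if len(g_lo) > 1 else 0.0},
        "difference": float(g_hi.mean() - g_lo.mean()),
        "difference_convention": f"{hi} - {lo}",
        "t": t, "df": df, "p": p,
        "multiple_testing_correction": "none",
    }
    return summary


def table2_average(rater_means: dict[str, tuple[float, float]],
                   decimals: int = 2) -> dict[str, float]:
    """Average the two per-rater descriptor means, rounded for reporting."""
    out = {}
    for name, (m1, m2) in rater_means.items():
        if m1 is None or m2 is None:
            raise ValueError(f"both rater means required for {name}")
        out[name] = round((float(m1) + float(m2)) / 2.0, decimals)
    return out


# ---------------------------------------------------------------------------
# Low-volume descriptor probe
# ---------------------------------------------------------------------------


def low_volume_probe(cohort: pd.DataFrame,
                     thresholds: dict[int, float]) -> dict:
    """Relate low-volume structures to the other descriptors.

    Flags records whose volume is at or below the per-rater threshold
    (e.g. ``{1: 2.3, 2: 2.4}`` cm^3) and reports, for each other descriptor,
    the flagged subgroup's mean percentile position within the full
    distribution.  Percentiles below 50 mean the flagged (small) structures
    sit left of the median — the direction expected when a descriptor
    shrinks with volume.

    Returns ``{"n_flagged": ..., "descriptors": {name: {"mean_percentile":
    ..., "n": ...}}}``; an empty report (no flagged records) is not an
    error.
    """
    for rater, thr in thresholds.items():
        if thr <= 0:
            raise ValueError(f"threshold for rater {rater} must be positive")
    flagged_mask = pd.Series(False, index=cohort.index)
    for rater, thr in thresholds.items():
        flagged_mask |= (cohort["rater"] == rater) & (cohort["volume_cm3"] <= thr)
    flagged = cohort[flagged_mask]
    report: dict = {"n_flagged": int(len(flagged)), "descriptors": {}}
    if len(flagged) == 0:
        return report
    for name in DESCRIPTOR_COLUMNS:
        if name == "volume_cm3" or name not in cohort.columns:
            continue
        full = cohort[name].to_numpy(float)
        sub = flagged[name].to_numpy(float)
        pct = [stats.percentileofscore(full, v, kind="mean") for v in sub]
        report["descriptors"][name] = {
            "mean_percentile": float(np.mean(pct)),
            "n": int(len(sub)),
        }
    return report
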