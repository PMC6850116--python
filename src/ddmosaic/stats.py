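"""Statistical core for low-fraction mosaicism calling.

A droplet digital PCR assay (or a deep amplicon run) reduces to a binomial
observation: ``k`` mutant events among ``n`` informative events.  The mutant
allele fraction (MAF) is estimated as ``k/n`` with a two-sided exact
Clopper-Pearson 95% confidence interval, and a sample is called *mosaic*
when the CI lower bound exceeds a detection floor (default 0.01%) and the
upper bound stays below the constitutional-heterozygote value (50%).  The
detection floor itself is calibrated by pooling negative-control assays into
a single false-mutant-call rate and asking at which droplet number the
zero-expectation CI upper bound drops under the floor.

Exact (rather than normal-approximation) intervals are used because the
regime of interest is k of order 0-10 at n of order 1e4-1e6, where Wald
intervals misbehave and a zero count must yield a well-defined bound.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import EstimationError, ParameterError
from .records import AlleleCounts, DropletCounts, check_fraction

__all__ = [
    "MAFEstimate",
    "SampleCall",
    "ErrorRateEstimate",
    "ConcordanceStats",
    "DetectionLimitCurve",
    "binomial_ci",
    "estimate_maf",
    "classify_sample",
    "pool_error_rate",
    "detection_limit_curve",
    "concordance",
    "LOWER_CUT",
    "UPPER_CUT",
]

#: positive-detection rule cutoffs, as fractions: CI lower bound must exceed
#: 0.01% and CI upper bound must stay below 50.00% (both strict).
LOWER_CUT = 1e-4
UPPER_CUT = 0.50

# comparisons against the cutoffs happen after rounding to this many decimal
# places so that a bound entered as a printed two-decimal percent compares
# exactly as printed, immune to float division artefacts
_CMP_DECIMALS = 12


@dataclass(frozen=True)
class MAFEstimate:
    """Point MAF with a two-sided exact CI, all as fractions in [0, 1].

    ``k`` and ``n`` are absent for estimates transcribed from printed tables,
    where only the rounded point value and bounds are known.
    """

    maf: float
    ci_low: float
    ci_high: float
    k: Optional[int] = None
    n: Optional[int] = None
    alpha: float = 0.05
    platform: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ParameterError(
                f"CI bounds must satisfy 0 <= ci_low <= ci_high <= 1, got "
                f"({self.ci_low!r}, {self.ci_high!r})"
            )
        check_fraction("maf", self.maf)

    @classmethod
    def from_percent(
        cls,
        maf_pct: float,
        ci_low_pct: float,
        ci_high_pct: float,
        platform: Optional[str] = None,
    ) -> "MAFEstimate":
        return cls(
            maf=maf_pct / 100.0,
            ci_low=ci_low_pct / 100.0,
            ci_high=ci_high_pct / 100.0,
            platform=platform,
        )


@dataclass(frozen=True)
class SampleCall:
    """Outcome of the positive-detection rule for one sample."""

    call: str  # negative / mosaic / het_consistent
    rule_inputs: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Pooled false-mutant-call rate from negative-control assays."""

    pooled_rate: float
    total_mu: int
    total_informative: int
    ci: Tuple[float, float]


@dataclass(frozen=True)
class ConcordanceStats:
    """OLS concordance of one platform's MAFs on another's."""

    r_squared: float
    slope: float
    intercept: float
    n_pairs: int


@dataclass(frozen=True)
class DetectionLimitCurve:
    """CI-upper-bound curve over droplet numbers, with the cutoff crossing."""

    table: pd.DataFrame  # columns: n, expected_k, upper_bound, below_cutoff
    cutoff: float
    min_n_below_cutoff: Optional[int]


def binomial_ci(k: int, n: int, alpha: float = 0.05):
    """Two-sided exact (Clopper-Pearson) binomial CI for k successes in n.

    Returns ``(lower, upper)`` as fractions.  ``lower`` is exactly 0 when
    k = 0 and ``upper`` exactly 1 when k = n.  Accepts array-like ``k`` for
    vectorised use (``n`` and ``alpha`` scalar).
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha!r}")
    n = int(n)
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n!r}")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > n):
        raise ParameterError(f"k must satisfy 0 <= k <= n={n}, got {k!r}")
    kf = k_arr.astype(float)
    with np.errstate(invalid="ignore"):
        lower = np.where(kf == 0, 0.0, _sps.beta.ppf(alpha / 2.0, kf, n - kf + 1.0))
        upper = np.where(kf == n, 1.0, _sps.beta.ppf(1.0 - alpha / 2.0, kf + 1.0, n - kf))
    if k_arr.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def estimate_maf(counts, alpha: float = 0.05, platform: Optional[str] = None) -> MAFEstimate:
    """MAF point estimate k/n with exact CI from a count record.

    Non-informative droplets are excluded from the denominator.  A zero
    denominator raises :class:`EstimationError`: "no data" is distinct from
    "MAF = 0".
    """
    if isinstance(counts, DropletCounts):
        k, n = counts.mu, counts.informative
        platform = platform or "mDDPCR"
    elif isinstance(counts, AlleleCounts):
        k, n = counts.alt_reads, counts.depth
        platform = platform or counts.platform_tag
    else:
        raise ParameterError(f"counts must be DropletCounts or AlleleCounts, got {type(counts).__name__}")
    if n < 1:
        raise EstimationError("zero informative events: MAF is undefined, not zero")
    lo, hi = binomial_ci(k, n, alpha)
    return MAFEstimate(maf=k / n, ci_low=lo, ci_high=hi, k=k, n=n, alpha=alpha, platform=platform)


def classify_sample(
    est: MAFEstimate,
    lower_cut: float = LOWER_CUT,
    upper_cut: float = UPPER_CUT,
) -> SampleCall:
    """Apply the positive-detection rule to one MAF estimate.

    mosaic          iff ci_low > lower_cut and ci_high < upper_cut (strict);
    het_consistent  iff ci_high >= upper_cut (interval reaches the
                    constitutional-heterozygote fraction);
    negative        otherwise.

    Bounds transcribed from printed two-decimal percents compare exactly as
    printed (comparisons use a fixed decimal precision).
    """
    lo = round(est.ci_low, _CMP_DECIMALS)
    hi = round(est.ci_high, _CMP_DECIMALS)
    lc = round(lower_cut, _CMP_DECIMALS)
    uc = round(upper_cut, _CMP_DECIMALS)
    if lo > lc and hi < uc:
        call = "mosaic"
    elif hi >= uc:
        call = "het_consistent"
    else:
        call = "negative"
    return SampleCall(
        call=call,
        rule_inputs={"ci_low": est.ci_low, "ci_high": est.ci_high,
                     "lower_cut": lower_cut, "upper_cut": upper_cut},
    )


def pool_error_rate(controls: Iterable[DropletCounts], alpha: float = 0.05) -> ErrorRateEstimate:
    """Pool negative-control assays into one false-mutant-call rate.

    All control droplets are treated as draws from a single error process:
    rate = sum(mu) / sum(informative), with an exact CI on the pooled counts.
    """
    controls = list(controls)
    if not controls:
        raise ParameterError("controls must be a non-empty list of DropletCounts")
    total_mu = sum(c.mu for c in controls)
    total_inf = sum(c.informative for c in controls)
    if total_inf < 1:
        raise ParameterError("controls contain zero informative droplets in total")
    ci = binomial_ci(total_mu, total_inf, alpha)
    return ErrorRateEstimate(
        pooled_rate=total_mu / total_inf,
        total_mu=total_mu,
        total_informative=total_inf,
        ci=ci,
    )


def detection_limit_curve(
    error_rate: float,
    n_grid: Sequence[int],
    alpha: float = 0.05,
    cutoff: float = LOWER_CUT,
) -> DetectionLimitCurve:
    """CI-upper-bound curve over informative-droplet numbers.

    For each n the expected mutant count under the pure-error model is
    ``round(error_rate * n)``; the row records the exact CI upper bound at
    that count and whether it falls below the MAF cutoff.  The smallest grid
    n with the bound under the cutoff is the assay's usable droplet number
    for that detection floor.
    """
    check_fraction("error_rate", error_rate, upper_open=True)
    check_fraction("cutoff", cutoff)
    ns = [int(n) for n in n_grid]
    if not ns:
        raise ParameterError("n_grid must be non-empty")
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ParameterError("n_grid must be strictly increasing")
    if ns[0] < 1:
        raise ParameterError("n_grid entries must be >= 1")
    rows = []
    for n in ns:
        ek = int(round(error_rate * n))
        _, upper = binomial_ci(ek, n, alpha)
        rows.append({"n": n, "expected_k": ek, "upper_bound": upper,
                     "below_cutoff": bool(upper < cutoff)})
    table = pd.DataFrame(rows)
    below = table.loc[table["below_cutoff"], "n"]
    min_n = int(below.iloc[0]) if len(below) else None
    return DetectionLimitCurve(table=table, cutoff=cutoff, min_n_below_cutoff=min_n)


def concordance(pairs: Sequence[Tuple[float, float]]) -> ConcordanceStats:
    """Ordinary least squares of platform-2 MAFs on platform-1 MAFs.

    ``pairs`` is a sequence of (maf_platform1, maf_platform2); returns the
    fit's R^2, slope, intercept and pair count.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ParameterError("pairs must contain at least 2 (x, y) pairs")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("pairs contain missing or non-finite values")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ParameterError("zero variance in predictor MAFs")
    fit = _sps.linregress(x, y)
    return ConcordanceStats(
        r_squared=float(fit.rvalue ** 2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=int(arr.shape[0]),
    )
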