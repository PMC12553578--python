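"""Benford's-Law conformity testing for per-species observation counts.

Benford's Law gives the expected distribution of leading significant digits
in numbers that span several orders of magnitude, ``P(d) = log10(1 + 1/d)``.
Per-species occurrence counts in a well-mixed, effort-neutral dataset are
expected to approximate this distribution; systematic over- or
under-recording of particular species distorts it. The module tests first-
and first-two-digit conformity with a chi-square goodness-of-fit statistic,
the mean absolute deviation (MAD) of digit proportions, and the distortion
factor (percent displacement of the digit-collapsed mean from its Benford
expectation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BenfordResult",
    "leading_digits",
    "benford_expected",
    "benford_test",
    "distortion_factor",
    "classify_mad",
    "MAD_BANDS",
]

# Nigrini's MAD conformity bands: upper bounds for (close, acceptable,
# marginal); anything above the last bound is nonconforming.
MAD_BANDS = {
    1: (0.006, 0.012, 0.015),
    2: (0.0012, 0.0018, 0.0022),
}

CONFORMITY_LABELS = ("close", "acceptable", "marginal", "nonconforming")

# Expected mean of values collapsed onto [10, 100) under the Benford
# density 1/(x ln 10): integral of x * 1/(x ln10) dx from 10 to 100.
EXPECTED_COLLAPSED_MEAN = 90.0 / math.log(10.0)


@dataclass
class BenfordResult:
    """Digit-frequency comparison between data and the Benford expectation."""

    k: int
    bins: np.ndarray
    observed_prop: np.ndarray
    expected_prop: np.ndarray
    chi2: float
    df: int
    p_value: float
    mad: float
    distortion: float
    n: int
    conformity: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "mad": self.mad,
            "distortion": self.distortion,
            "conformity": self.conformity,
            "bins": self.bins.tolist(),
            "observed_prop": self.observed_prop.tolist(),
            "expected_prop": self.expected_prop.tolist(),
            "warnings": list(self.warnings),
        }


def _check_k(k: int) -> None:
    if k not in (1, 2):
        raise ValueError(f"k must be 1 or 2, got {k!r}")


def digit_bins(k: int) -> np.ndarray:
    """Bin values for the first-``k``-digits test: 1–9 or 10–99."""
    _check_k(k)
    lo = 10 ** (k - 1)
    return np.arange(lo, 10 * lo)


def leading_digits(x, k: int = 2):
    """First ``k`` significant decimal digits of positive ``x`` as an integer.

    ``leading_digits(456, 2) == 45``; ``leading_digits(0.00456, 1) == 4``;
    ``leading_digits(1, 2) == 10`` (1 reads as "1.0", digits "10").
    Accepts scalars or arrays.
    """
    _check_k(k)
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        bad = np.asarray(arr <= 0).nonzero()
        raise ValueError(f"leading_digits requires positive finite values; offending indices {bad[0][:10].tolist()}")
    # Collapse to [10^(k-1), 10^k), round away binary-float fuzz at 12
    # significant decimal digits (so 1.9 reads as 19, not 18.999...),
    # then truncate. Guard the decade boundaries on both sides.
    exponent = np.floor(np.log10(arr))
    mantissa = arr / 10.0 ** (exponent - (k - 1))
    lo = 10 ** (k - 1)
    mantissa = np.where(mantissa < lo, mantissa * 10.0, mantissa)
    mantissa = np.where(mantissa >= 10 * lo, mantissa / 10.0, mantissa)
    out = np.floor(np.round(mantissa, 12)).astype(np.int64)
    out = np.where(out >= 10 * lo, lo, out)
    return out if out.ndim else int(out)


def benford_expected(k: int = 2) -> np.ndarray:
    """Benford probabilities ``log10(1 + 1/d)`` over the k-digit bin range."""
    d = digit_bins(k).astype(float)
    return np.log10(1.0 + 1.0 / d)


def distortion_factor(counts) -> float:
    """Percent displacement of the collapsed mean from the Benford mean.

    Each value is collapsed to ``c = 10 * x / 10**floor(log10 x)`` in
    [10, 100); the distortion factor is ``100 * (mean(c) - EM) / EM`` with
    ``EM = 90 / ln 10``. Negative values indicate an excess of small
    leading digits relative to Benford.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("distortion_factor requires a non-empty sample")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("distortion_factor requires positive finite values")
    collapsed = 10.0 * arr / 10.0 ** np.floor(np.log10(arr))
    # exact powers of ten collapse to 10, not 100
    collapsed = np.where(collapsed >= 100.0, collapsed / 10.0, collapsed)
    am = collapsed.mean()
    return 100.0 * (am - EXPECTED_COLLAPSED_MEAN) / EXPECTED_COLLAPSED_MEAN


def classify_mad(mad: float, k: int = 2) -> str:
    """Conformity class for a MAD value under Nigrini's convention."""
    _check_k(k)
    if mad < 0:
        raise ValueError("mad must be non-negative")
    for bound, label in zip(MAD_BANDS[k], CONFORMITY_LABELS):
        if mad <= bound:
            return label
    return "nonconforming"


def benford_test(counts, k: int = 2) -> BenfordResult:
    """Test a vector of positive counts against Benford's Law.

    Parameters
    ----------
    counts
        Positive values (per-species observation counts).
    k
        Number of leading digits: 1 (bins 1–9, df 8) or 2 (bins 10–99,
        df 89; the default, matching the finer-grained convention for
        large samples).

    Returns
    -------
    BenfordResult
        chi2 = n * sum((phat_d - p_d)^2 / p_d), MAD of bin proportions,
        distortion factor, chi-square tail p-value, and the MAD
        conformity class.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("benford_test requires a non-empty sample")
    bad = np.nonzero(~np.isfinite(arr) | (arr <= 0))[0]
    if bad.size:
        raise ValueError(
            f"benford_test requires positive counts; offending indices {bad[:10].tolist()}"
        )
    bins = digit_bins(k)
    expected = benford_expected(k)
    n = arr.size

    warns: list[str] = []
    if n < bins.size:
        warns.append(f"sample size {n} below number of bins {bins.size}; test underpowered")
        warnings.warn(warns[-1], stacklevel=2)
    min_exp = n * expected.min()
    if min_exp < 5:
        warns.append(f"minimum expected bin count {min_exp:.2f} < 5; chi-square approximation weak")

    digits = np.atleast_1d(leading_digits(arr, k))
    observed_counts = np.bincount(digits, minlength=10 * bins[0])[bins[0]:]
    observed = observed_counts / n

    chi2 = float(n * np.sum((observed - expected) ** 2 / expected))
    df = bins.size - 1
    p_value = float(stats.chi2.sf(chi2, df))
    mad = float(np.mean(np.abs(observed - expected)))

    return BenfordResult(
        k=k,
        bins=bins,
        observed_prop=observed,
        expected_prop=expected,
        chi2=chi2,
        df=df,
        p_value=p_value,
        mad=mad,
        distortion=distortion_factor(arr),
        n=n,
        conformity=classify_mad(mad, k),
        warnings=warns,
    )
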