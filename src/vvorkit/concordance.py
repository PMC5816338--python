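"""Agreement between the two gain methods: ICC and Bland–Altman statistics.

The intra-class correlation coefficient used here is the two-way
random-effects, absolute-agreement, single-measure form — ICC(2,1) in the
Shrout–Fleiss taxonomy, ICC(A,1) in McGraw–Wong notation.  The two gain
methods play the role of raters crossed with subjects, and absolute
agreement (rather than consistency) is what clinical interchangeability of
the methods requires.  An ICC of at least 0.90 is conventionally read as
excellent concordance.

Bland–Altman analysis reports the mean difference (bias) and the 95% limits
of agreement, ``bias +/- 1.96 * SD`` of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .errors import InsufficientDataError, UndefinedStatisticError

ICC_FORM = "ICC(2,1) two-way random, absolute agreement, single measure"

#: Conventional threshold for excellent concordance.
ICC_EXCELLENT = 0.90


@dataclass
class AgreementResult:
    """Agreement statistics between two measurement methods.

    Fields are filled by :func:`icc_agreement` (icc*) and
    :func:`bland_altman` (bias, loa*); :func:`agreement` fills both.
    """

    n_pairs: int
    icc: float | None = None
    icc_ci_low: float | None = None
    icc_ci_high: float | None = None
    icc_form: str = ICC_FORM
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None


def _as_pairs(a, b, min_len: int, op: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise InsufficientDataError(f"{op}: inputs must be 1-D of equal length")
    if len(a) < min_len:
        raise InsufficientDataError(f"{op}: need >= {min_len} pairs, got {len(a)}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InsufficientDataError(f"{op}: inputs must be finite")
    return a, b


def _icc_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the subjects x methods two-way decomposition."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(a, b, confidence: float = 0.95) -> AgreementResult:
    """ICC(2,1) between two paired measurement vectors, with a 95% CI.

    The CI uses the McGraw–Wong F-distribution bounds with Satterthwaite
    degrees of freedom.

    Raises
    ------
    InsufficientDataError
        for fewer than 3 pairs.
    UndefinedStatisticError
        when total variance is zero (all measurements identical).
    """
    a, b = _as_pairs(a, b, 3, "icc_agreement")
    x = np.column_stack([a, b])
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    n, k = x.shape
    msr, msc, mse = _icc_mean_squares(x)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0.0 and msc == 0.0:
        # perfect agreement: no within-subject variability at all
        low = high = icc
    else:
        a_ = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if not np.isfinite(a_):
            low = high = icc
        else:
            b_ = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
            num = (a_ * msc + b_ * mse) ** 2
            den = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else n - 1
            f_low = f_dist.ppf(1 - alpha / 2, n - 1, v)
            f_high = f_dist.ppf(1 - alpha / 2, v, n - 1)
            low = n * (msr - f_low * mse) / (
                f_low * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            high = n * (f_high * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_high * msr
            )
    low = min(max(float(low), -1.0), float(icc))
    high = max(min(float(high), 1.0), float(icc))
    return AgreementResult(
        n_pairs=n, icc=float(icc), icc_ci_low=low, icc_ci_high=high
    )


def bland_altman(a, b) -> AgreementResult:
    """Bias and 95% limits of agreement of the differences ``a - b``."""
    a, b = _as_pairs(a, b, 2, "bland_altman")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        n_pairs=len(d),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def agreement(a, b) -> AgreementResult:
    """Full agreement block: ICC(2,1) plus Bland–Altman bias and limits."""
    icc_res = icc_agreement(a, b)
    ba_res = bland_altman(a, b)
    icc_res.bias = ba_res.bias
    icc_res.loa_low = ba_res.loa_low
    icc_res.loa_high = ba_res.loa_high
    return icc_res
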