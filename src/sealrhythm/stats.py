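"""Descriptive statistics and the two-sample Kolmogorov-Smirnov test.

The interval series are compared by simple descriptive statistics (mean,
sample SD, coefficient of variation CV = SD/mean — low CV within bouts
indicates temporal regularity) and by the two-sample KS test, implemented
here from first principles:

* ``D`` is the supremum distance between the two right-continuous
  empirical CDFs, attained at one of the pooled sample points.
* The p-value is asymptotic: ``Q(lambda) = 2 * sum_{k>=1} (-1)^{k-1}
  exp(-2 k^2 lambda^2)`` with ``lambda = D * sqrt(n1*n2/(n1+n2))``,
  clamped to [0, 1]. No exact small-sample computation and no continuity
  correction are applied.

Ties are handled correctly because ECDF differences are evaluated at the
pooled unique points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import IntervalSeries

__all__ = [
    "SummaryStats",
    "KSResult",
    "summarize",
    "ecdf_value",
    "ks_two_sample",
    "kolmogorov_sf",
]


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD, CV, min and max of one interval series (ms).

    ``sd`` and ``cv`` are ``None`` when n < 2 (undefined, not zero).
    """

    n: int
    mean: float
    sd: float | None
    cv: float | None
    min: float
    max: float

    def rounded(self) -> dict:
        """Report-precision view: 0.1 ms for moments, 2 decimals for CV."""
        return {
            "n": self.n,
            "mean_ms": round(self.mean, 1),
            "sd_ms": None if self.sd is None else round(self.sd, 1),
            "cv": None if self.cv is None else round(self.cv, 2),
            "min_ms": round(self.min, 1),
            "max_ms": round(self.max, 1),
        }


def summarize(s: IntervalSeries | np.ndarray) -> SummaryStats:
    """Descriptive statistics with the n-1 (sample) SD denominator."""
    values = s.values if isinstance(s, IntervalSeries) else np.asarray(s, float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot summarize an empty series")
    mean = float(values.mean())
    if n >= 2:
        sd = float(values.std(ddof=1))
        cv = sd / mean
    else:
        sd = cv = None
    return SummaryStats(
        n=n, mean=mean, sd=sd, cv=cv, min=float(values.min()), max=float(values.max())
    )


def ecdf_value(s: IntervalSeries | np.ndarray, x: float) -> float:
    """Right-continuous ECDF: fraction of values <= x."""
    values = s.values if isinstance(s, IntervalSeries) else np.asarray(s, float)
    if len(values) == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    return float(np.count_nonzero(values <= x)) / len(values)


def kolmogorov_sf(lam: float, max_terms: int = 1000) -> float:
    """Asymptotic Kolmogorov survival function Q(lambda), clamped to [0, 1].

    For small lambda the alternating series converges too slowly, so the
    equivalent Jacobi-theta form of the CDF is used there instead.
    """
    if lam <= 0:
        return 1.0
    if lam < 1.0:
        # CDF(lam) = sqrt(2*pi)/lam * sum_k exp(-(2k-1)^2 pi^2 / (8 lam^2))
        cdf = 0.0
        for k in range(1, max_terms + 1):
            term = np.exp(-((2 * k - 1) ** 2) * np.pi**2 / (8.0 * lam * lam))
            cdf += term
            if term < 1e-18:
                break
        cdf *= np.sqrt(2.0 * np.pi) / lam
        return float(min(1.0, max(0.0, 1.0 - cdf)))
    total = 0.0
    for k in range(1, max_terms + 1):
        term = np.exp(-2.0 * k * k * lam * lam)
        if term < 1e-18:
            break
        total += term if k % 2 else -term
    return float(min(1.0, max(0.0, 2.0 * total)))


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS statistic D, asymptotic p-value and sample sizes."""

    d: float
    p: float
    n1: int
    n2: int

    def rounded(self) -> dict:
        return {"D": round(self.d, 2), "p": round(self.p, 2),
                "n1": self.n1, "n2": self.n2}


def ks_two_sample(
    a: IntervalSeries | np.ndarray, b: IntervalSeries | np.ndarray
) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum over the pooled sample points of
    ``|ECDF_a(x) - ECDF_b(x)|``; the p-value uses the asymptotic
    Kolmogorov distribution with effective size ``n1*n2/(n1+n2)``.
    """
    xa = np.sort(a.values if isinstance(a, IntervalSeries) else np.asarray(a, float))
    xb = np.sort(b.values if isinstance(b, IntervalSeries) else np.asarray(b, float))
    n1, n2 = len(xa), len(xb)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.union1d(xa, xb)
    fa = np.searchsorted(xa, pooled, side="right") / n1
    fb = np.searchsorted(xb, pooled, side="right") / n2
    d = float(np.abs(fa - fb).max())
    lam = d * np.sqrt(n1 * n2 / (n1 + n2))
    return KSResult(d=d, p=kolmogorov_sf(lam), n1=n1, n2=n2)
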