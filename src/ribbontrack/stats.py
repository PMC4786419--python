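"""Nonparametric tests and displacement-vector summaries.

The displacement analysis uses only distribution-free tests: an exact sign
test on the fraction of toward-membrane (positive ddx) displacements, and
the two-sample Wilcoxon rank-sum (Mann-Whitney) test for comparing
displacement distributions between conditions.  Population means are
reported ± sem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .dynamics import DisplacementVector

__all__ = ["TestResult", "VectorSummary", "sign_test", "rank_sum_test",
           "summarize_displacements"]

#: exact rank-sum enumeration is used up to these sample sizes (no ties)
EXACT_MIN_N = 7
EXACT_TOTAL_N = 14


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int = 0
    sidedness: str = "two_sided"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def sign_test(n_positive: int, n: int, sidedness: str = "two_sided") -> TestResult:
    """Exact binomial sign test against equal probability of + and -.

    Two-sided p is twice the smaller tail, capped at 1.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= n_positive <= n:
        raise ValueError("n_positive must lie in [0, n]")
    if sidedness not in ("two_sided", "one_sided"):
        raise ValueError(f"sidedness={sidedness!r}")
    dist = sps.binom(n, 0.5)
    upper = float(dist.sf(n_positive - 1))   # P(X >= n_positive)
    lower = float(dist.cdf(n_positive))      # P(X <= n_positive)
    if sidedness == "one_sided":
        p = min(upper, lower)
    else:
        p = min(1.0, 2.0 * min(upper, lower))
    return TestResult(statistic=float(n_positive), p_value=p,
                      method="sign_exact", n1=n, sidedness=sidedness)


def rank_sum_test(sample_a, sample_b, sidedness: str = "two_sided") -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact permutation distribution for small tie-free samples
    (min(n1, n2) <= 7 and n1 + n2 <= 14), otherwise the normal approximation
    with tie correction.  The statistic reported is the rank sum of
    ``sample_a``.  Identical samples yield p = 1 with a degeneracy flag.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if sidedness not in ("two_sided", "one_sided"):
        raise ValueError(f"sidedness={sidedness!r}")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    rank_sum_a = float(sps.rankdata(pooled)[:n1].sum())
    if np.ptp(pooled) == 0:
        return TestResult(statistic=rank_sum_a, p_value=1.0,
                          method="rank_sum_normal", n1=n1, n2=n2,
                          sidedness=sidedness, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = (min(n1, n2) <= EXACT_MIN_N and n1 + n2 <= EXACT_TOTAL_N
                and not has_ties)
    alternative = "two-sided" if sidedness == "two_sided" else "less"
    if sidedness == "one_sided":
        # one-sided: smaller tail of the two directions
        p_less = sps.mannwhitneyu(a, b, alternative="less",
                                  method="exact" if exact_ok else "asymptotic").pvalue
        p_greater = sps.mannwhitneyu(a, b, alternative="greater",
                                     method="exact" if exact_ok else "asymptotic").pvalue
        p = float(min(p_less, p_greater))
    else:
        p = float(sps.mannwhitneyu(
            a, b, alternative=alternative,
            method="exact" if exact_ok else "asymptotic").pvalue)
    return TestResult(statistic=rank_sum_a, p_value=min(p, 1.0),
                      method="rank_sum_exact" if exact_ok else "rank_sum_normal",
                      n1=n1, n2=n2, sidedness=sidedness)


@dataclass(frozen=True)
class VectorSummary:
    """Summary of a set of displacement vectors (nm).

    ``frac_below`` uses a strict inequality (amplitude < threshold);
    ``mean_amp_pos``/``mean_amp_neg`` are the mean amplitudes of the
    toward-membrane (ddx > 0) and away (ddx < 0) subsets, each ± sem.
    """

    n: int
    mean_ddx: float
    mean_ddy: float
    sem_ddx: float
    frac_below: float
    frac_positive_ddx: float
    mean_amp_pos: float
    sem_amp_pos: float
    mean_amp_neg: float
    sem_amp_neg: float
    threshold: float


def _sem(x: np.ndarray) -> float:
    if x.size == 0:
        return float("nan")
    if x.size == 1:
        return 0.0
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def summarize_displacements(vectors: list[DisplacementVector],
                            threshold: float = 50.0) -> VectorSummary:
    """Component-wise mean vector, amplitude fractions and subset amplitudes."""
    if len(vectors) == 0:
        raise ValueError("vectors must be non-empty")
    ddx = np.asarray([v.ddx for v in vectors], dtype=float)
    ddy = np.asarray([v.ddy for v in vectors], dtype=float)
    amp = np.hypot(ddx, ddy)
    pos, neg = amp[ddx > 0], amp[ddx < 0]
    return VectorSummary(
        n=len(vectors),
        mean_ddx=float(ddx.mean()),
        mean_ddy=float(ddy.mean()),
        sem_ddx=_sem(ddx),
        frac_below=float((amp < threshold).mean()),
        frac_positive_ddx=float((ddx > 0).mean()),
        mean_amp_pos=float(pos.mean()) if pos.size else float("nan"),
        sem_amp_pos=_sem(pos),
        mean_amp_neg=float(neg.mean()) if neg.size else float("nan"),
        sem_amp_neg=_sem(neg),
        threshold=float(threshold),
    )
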