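"""Statistical decision rule and exact small-sample tests.

The study design compares per-animal rates either within animals (observed
vs. chance overlap in the same mouse) or between treatment groups, with a
Shapiro-Wilk normality gate deciding between parametric and rank-based
tests.  At the sample sizes typical of such cohorts (5-7 animals per group)
asymptotic rank-test p-values are unreliable, so the Wilcoxon signed-rank
and Mann-Whitney null distributions are enumerated exactly here via dynamic
programming over rank subsets.

Conventions
-----------
* Wilcoxon signed-rank statistic ``W`` is the *sum of signed ranks*
  (positive minus negative rank sum), ranging over
  ``[-n(n+1)/2, +n(n+1)/2]``; the positive-rank-sum S relates by
  ``W = 2*S - n(n+1)/2``.
* Mann-Whitney ``U`` is reported in the min convention,
  ``U = min(U1, m*n - U1)``.
* All p-values are two-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

Design = Literal["independent", "paired", "correlation"]
Method = Literal[
    "unpaired_t", "paired_t", "wilcoxon_signed_rank", "mann_whitney", "pearson"
]

#: largest pair count for which the signed-rank null is enumerated exactly
MAX_EXACT_SIGNED_RANK = 25
#: largest combined sample size for which the U null is enumerated exactly
MAX_EXACT_MANN_WHITNEY = 40


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``statistic`` is t, W (sum of signed ranks), U (min convention) or
    Pearson's r depending on ``method``.  ``n`` holds the sample size(s)
    actually used (after zero-difference removal for the signed-rank test).
    ``exact`` marks p-values computed from a fully enumerated null.
    """

    method: Method
    statistic: float
    p_two_tailed: float
    n: tuple[int, ...]
    df: float | None = None
    exact: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError(f"p_two_tailed outside [0, 1]: {self.p_two_tailed}")


# ---------------------------------------------------------------------------
# exact null distributions
# ---------------------------------------------------------------------------

def signed_rank_null(ranks: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null of the positive-rank-sum S over uniform sign flips.

    Parameters
    ----------
    ranks : sequence of float
        The (mid-)ranks of the absolute differences.  Half-integer midranks
        are handled by doubling internally.

    Returns
    -------
    support, counts : ndarray
        ``support[i]`` is a possible value of S (on the original rank
        scale), ``counts[i]`` the number of the ``2**n`` sign assignments
        producing it.
    """
    r2 = np.asarray(ranks, dtype=float) * 2.0
    r2i = np.rint(r2).astype(np.int64)
    if not np.allclose(r2, r2i):
        raise ValueError("ranks must be integers or half-integers")
    total = int(r2i.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in r2i:
        r = int(r)
        counts[r:] += counts[: total + 1 - r]
    support = np.nonzero(counts)[0]
    return support / 2.0, counts[support]


def mann_whitney_null(m: int, n: int) -> np.ndarray:
    """Exact tie-free null of U: ``counts[u]`` of all C(m+n, m) labelings.

    Computed by the standard partition recurrence
    ``f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u)`` (equivalently the
    Gaussian-binomial generating function), so the whole distribution costs
    O(m * n * m*n).
    """
    if m < 1 or n < 1:
        raise ValueError("both group sizes must be >= 1")
    mn = m * n
    # f[j, u] for the current number of x's i
    f = np.zeros((n + 1, mn + 1), dtype=np.int64)
    f[:, 0] = 1  # i = 0
    for _ in range(m):
        g = np.zeros_like(f)
        g[0, 0] = 1
        for j in range(1, n + 1):
            g[j] = g[j - 1]
            g[j, j:] += f[j, : mn + 1 - j]
        f = g
    return f[n]


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def wilcoxon_exact(
    differences: Sequence[float] | None = None,
    *,
    n: int | None = None,
    w: float | None = None,
) -> TestResult:
    """Two-tailed Wilcoxon matched-pairs signed-rank test with exact null.

    Either raw paired ``differences`` or a precomputed ``(n, w)`` pair may
    be given, where ``w`` is the sum of signed ranks of ``n`` untied,
    nonzero differences.  Zero differences are removed before ranking; ties
    are midranked and the exact enumeration then runs over the midrank
    values, flagged in ``note``.

    The two-tailed p-value is ``P(|W'| >= |W|)`` under the uniform
    sign-flip null, by full enumeration for up to 25 pairs.
    """
    if (differences is None) == (n is None and w is None):
        raise ValueError("give either differences or both n and w")
    tied = False
    if differences is not None:
        d = np.asarray(differences, dtype=float)
        if d.ndim != 1:
            raise ValueError("differences must be a 1-D vector")
        n_zero = int(np.sum(d == 0))
        if n_zero:
            logger.info("wilcoxon: removed %d zero difference(s)", n_zero)
            d = d[d != 0]
        n_eff = d.size
        if n_eff == 0:
            raise ValueError("no nonzero differences left to rank")
        ranks = stats.rankdata(np.abs(d))
        tied = np.unique(np.abs(d)).size < n_eff
        w_stat = float(np.sum(np.sign(d) * ranks))
    else:
        if n is None or w is None:
            raise ValueError("both n and w are required")
        n_eff = int(n)
        if n_eff < 1:
            raise ValueError("n must be >= 1")
        m_tot = n_eff * (n_eff + 1) // 2
        if abs(w) > m_tot or (int(w) - m_tot) % 2 != 0:
            raise ValueError(
                f"W={w} is not attainable with n={n_eff} untied ranks"
            )
        ranks = np.arange(1, n_eff + 1, dtype=float)
        w_stat = float(w)

    m_tot = float(ranks.sum())
    if n_eff <= MAX_EXACT_SIGNED_RANK:
        support, counts = signed_rank_null(ranks)
        w_support = 2.0 * support - m_tot  # signed-rank scale
        tail = counts[np.abs(w_support) >= abs(w_stat) - 1e-9].sum()
        p = min(1.0, float(tail) / float(2 ** n_eff))
        exact = True
    else:  # pragma: no cover - cohorts this large do not occur in the design
        sigma = np.sqrt(np.sum(ranks**2))
        z = w_stat / sigma
        p = float(2.0 * stats.norm.sf(abs(z)))
        exact = False
    note = "midranks (ties); enumeration over tied midranks" if tied else ""
    return TestResult(
        method="wilcoxon_signed_rank",
        statistic=w_stat,
        p_two_tailed=p,
        n=(n_eff,),
        # enumeration over midranks is approximate in the sense that the
        # tied null is conditional on the observed tie pattern
        exact=exact and not tied,
        note=note,
    )


def mannwhitney_exact(
    xs: Sequence[float] | None = None,
    ys: Sequence[float] | None = None,
    *,
    m: int | None = None,
    n: int | None = None,
    u: float | None = None,
) -> TestResult:
    """Two-tailed Mann-Whitney test with exact tie-free null.

    Either two samples or a precomputed ``(m, n, u)`` triple may be given.
    With ``u* = min(U, m*n - U)`` the two-tailed p-value is
    ``P(U' <= u*) + P(U' >= m*n - u*)`` under the exact rank-sum null.
    Tied samples fall back to the tie-corrected normal approximation and
    are flagged via ``exact=False``.
    """
    from_data = xs is not None or ys is not None
    if from_data == (m is not None or n is not None or u is not None):
        raise ValueError("give either (xs, ys) or (m, n, u)")
    tied = False
    if from_data:
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        if x.size == 0 or y.size == 0:
            raise ValueError("both groups must be non-empty")
        m_eff, n_eff = x.size, y.size
        combined = np.concatenate([x, y])
        ranks = stats.rankdata(combined)
        tied = np.unique(combined).size < combined.size
        u1 = float(ranks[: m_eff].sum() - m_eff * (m_eff + 1) / 2.0)
        u_stat = min(u1, m_eff * n_eff - u1)
    else:
        if m is None or n is None or u is None:
            raise ValueError("m, n and u are all required")
        m_eff, n_eff = int(m), int(n)
        if m_eff < 1 or n_eff < 1:
            raise ValueError("both group sizes must be >= 1")
        if not (0 <= u <= m_eff * n_eff):
            raise ValueError(f"U={u} outside [0, {m_eff * n_eff}]")
        u_stat = float(min(u, m_eff * n_eff - u))

    mn = m_eff * n_eff
    if not tied and m_eff + n_eff <= MAX_EXACT_MANN_WHITNEY:
        counts = mann_whitney_null(m_eff, n_eff)
        total = counts.sum()
        us = np.arange(mn + 1)
        u_star = u_stat
        tail = counts[(us <= u_star + 1e-9) | (us >= mn - u_star - 1e-9)].sum()
        p = min(1.0, float(tail) / float(total))
        exact = True
        note = ""
    else:
        # tie-corrected normal approximation with continuity correction
        mu = mn / 2.0
        if from_data:
            _, t_counts = np.unique(combined, return_counts=True)
            tie_term = np.sum(t_counts**3 - t_counts)
        else:  # pragma: no cover
            tie_term = 0.0
        ntot = m_eff + n_eff
        var = mn / 12.0 * ((ntot + 1) - tie_term / (ntot * (ntot - 1)))
        if var <= 0:
            raise ValueError("all observations identical; U test undefined")
        z = (abs(u_stat - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        exact = False
        note = "ties: midranks with tie-corrected normal approximation"
    return TestResult(
        method="mann_whitney",
        statistic=u_stat,
        p_two_tailed=p,
        n=(m_eff, n_eff),
        exact=exact,
        note=note,
    )


def t_tests(
    xs: Sequence[float],
    ys: Sequence[float],
    paired: bool,
    welch: bool = False,
) -> TestResult:
    """Student's t-test, paired or unpaired (pooled variance by default)."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        if x.size < 2:
            raise ValueError("need at least 2 pairs")
        d = x - y
        if np.allclose(d.std(ddof=1), 0) and np.allclose(d, d[0]) and d[0] == 0:
            return TestResult("paired_t", 0.0, 1.0, (x.size,), df=x.size - 1)
        res = stats.ttest_rel(x, y)
        return TestResult(
            method="paired_t",
            statistic=float(res.statistic),
            p_two_tailed=float(res.pvalue),
            n=(x.size,),
            df=float(x.size - 1),
        )
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.isclose(x.mean(), y.mean()):
            return TestResult(
                "unpaired_t", 0.0, 1.0, (x.size, y.size), df=x.size + y.size - 2
            )
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(x.size + y.size - 2)
    return TestResult(
        method="unpaired_t",
        statistic=float(res.statistic),
        p_two_tailed=float(res.pvalue),
        n=(x.size, y.size),
        df=df,
        note="welch" if welch else "",
    )


def pearson_test(xs: Sequence[float], ys: Sequence[float]) -> TestResult:
    """Pearson correlation with the t-based two-tailed p-value."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation test")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one channel; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        method="pearson",
        statistic=float(r),
        p_two_tailed=float(p),
        n=(x.size,),
        df=float(x.size - 2),
    )


# ---------------------------------------------------------------------------
# decision rule
# ---------------------------------------------------------------------------

def normality_gate(*samples: Sequence[float], alpha: float = 0.05) -> bool:
    """Shapiro-Wilk gate: True iff every sample looks normal at ``alpha``.

    Constant vectors (on which the test statistic is undefined) are treated
    as non-normal and logged rather than raised.
    """
    if not samples:
        raise ValueError("at least one sample required")
    for s in samples:
        v = np.asarray(s, dtype=float)
        if v.size < 3:
            raise ValueError("Shapiro-Wilk requires n >= 3")
        if np.allclose(v, v[0]):
            logger.warning("normality_gate: constant sample treated as non-normal")
            return False
        if stats.shapiro(v).pvalue <= alpha:
            return False
    return True


def choose_test(design: Design, normal: bool) -> Method:
    """Map (design, normality) to the test the decision rule prescribes."""
    table: dict[tuple[Design, bool], Method] = {
        ("independent", True): "unpaired_t",
        ("independent", False): "mann_whitney",
        ("paired", True): "paired_t",
        ("paired", False): "wilcoxon_signed_rank",
        ("correlation", True): "pearson",
        ("correlation", False): "pearson",
    }
    key = (design, bool(normal))
    if key not in table:
        raise ValueError(f"unknown design {design!r}")
    return table[key]


def compare(
    xs: Sequence[float],
    ys: Sequence[float],
    design: Design,
    alpha: float = 0.05,
) -> TestResult:
    """Run the full decision rule: normality gate, test choice, test.

    For the paired design normality is assessed on the differences, which
    is the quantity the paired tests act on.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if design == "correlation":
        return pearson_test(x, y)
    if design == "paired":
        normal = normality_gate(x - y, alpha=alpha)
    else:
        normal = normality_gate(x, y, alpha=alpha)
    method = choose_test(design, normal)
    if method == "unpaired_t":
        return t_tests(x, y, paired=False)
    if method == "paired_t":
        return t_tests(x, y, paired=True)
    if method == "wilcoxon_signed_rank":
        return wilcoxon_exact(x - y)
    return mannwhitney_exact(x, y)
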