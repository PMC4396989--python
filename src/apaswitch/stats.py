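"""Statistical tests for APA site switching between two samples.

A gene's evidence is a 2xN contingency table: rows are the two samples,
columns the gene's N tandem poly(A) sites ordered proximal to distal, and
cells the supporting-read counts n_ij. Two complementary tests are run:

* an **independence test** (Pearson chi-squared, or the Freeman-Halton
  generalization of Fisher's exact test for small tables), sensitive to any
  departure of the two samples' site-usage profiles — site order and
  inter-site distances play no role;
* a **linear-by-linear trend test**, which scores the columns by their
  3'-UTR lengths L_j and the rows by 1 and 2, computes the count-weighted
  Pearson correlation r between the two scores, and refers
  M^2 = (n - 1) r^2 to a chi-squared distribution with one degree of
  freedom. The trend test detects shifts of the average 3'-UTR length and
  is blind to switching patterns that preserve it.

Genes whose grand total is below a small-sample threshold (default 30) are
dispatched to the exact test and reported without a trend result, since the
chi-squared approximation underlying the trend statistic is unreliable
there.

Multiple testing is handled by Benjamini-Hochberg step-up FDR, applied
separately to each test's p-values across the tested cohort. Genes are then
partitioned into the significance groups CL (both tests), CO (independence
only), LO (trend only) and NS (neither).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

from .io import TandemGene

logger = logging.getLogger("apaswitch")

ROW_SCORES = (1.0, 2.0)

#: significance groups
GROUPS = ("CL", "CO", "LO", "NS")


class UntestableError(ValueError):
    """The table carries no testable switching signal (e.g. a single
    informative column, or an empty sample)."""


class FisherWorkloadError(RuntimeError):
    """Exact-test enumeration would exceed the workload cap; use the
    chi-squared test instead."""


@dataclass(frozen=True)
class ContingencyTable:
    """The 2xN read-count table with column scores (3'-UTR lengths).

    Row scores are fixed at (1, 2); column scores must be strictly
    increasing, mirroring the proximal-to-distal ordering of the sites.
    """

    counts: tuple[tuple[int, ...], tuple[int, ...]]
    col_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != 2:
            raise ValueError("exactly two rows (samples) are supported")
        r1, r2 = (tuple(int(c) for c in row) for row in self.counts)
        object.__setattr__(self, "counts", (r1, r2))
        object.__setattr__(self, "col_scores", tuple(float(s) for s in self.col_scores))
        n_cols = len(r1)
        if len(r2) != n_cols or len(self.col_scores) != n_cols:
            raise ValueError("rows and col_scores must have equal length")
        if n_cols < 2:
            raise UntestableError("a switching test needs at least two poly(A) sites")
        if any(c < 0 for c in r1 + r2):
            raise ValueError("counts must be non-negative")
        if any(b <= a for a, b in zip(self.col_scores, self.col_scores[1:])):
            raise ValueError("col_scores must be strictly increasing")
        if self.grand_total <= 0:
            raise UntestableError("table has no reads")

    @property
    def n_cols(self) -> int:
        return len(self.col_scores)

    @property
    def grand_total(self) -> int:
        return sum(self.counts[0]) + sum(self.counts[1])

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @classmethod
    def from_gene(cls, gene: TandemGene) -> "ContingencyTable":
        if not gene.is_testable:
            raise UntestableError(
                f"{gene.gene_id}: needs >= 2 sites and > 0 reads "
                f"(has {gene.n_sites} sites, {gene.grand_total} reads)"
            )
        return cls((gene.counts_sample1, gene.counts_sample2), gene.utr_lengths)


# ---------------------------------------------------------------------------
# independence tests
# ---------------------------------------------------------------------------

def _nonzero_columns(table: ContingencyTable) -> np.ndarray:
    obs = table.to_array()
    return obs[:, obs.sum(axis=0) > 0]


def pearson_chi2_stat(table: ContingencyTable) -> tuple[float, int]:
    """Pearson X^2 and its degrees of freedom, after dropping all-zero
    columns. No continuity correction is applied."""
    obs = _nonzero_columns(table)
    if obs.shape[1] < 2:
        raise UntestableError("fewer than two non-zero columns")
    if obs.shape[1] < table.n_cols:
        logger.debug("dropped %d all-zero column(s)", table.n_cols - obs.shape[1])
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if (row_tot == 0).any():
        raise UntestableError("one sample has no reads; independence is vacuous")
    expected = row_tot @ col_tot / n
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    return x2, df

def chi_squared_test(table: ContingencyTable) -> float:
    """Upper-tail p-value of Pearson's chi-squared test of independence.

    The tail probability is taken from the chi-squared survival function,
    which stays accurate for extreme statistics (p-values down to the
    smallest positive floats are representable, never rounded to 0 by a
    1 - CDF subtraction).
    """
    x2, df = pearson_chi2_stat(table)
    return float(chi2.sf(x2, df))


def fisher_exact_test(
    table: ContingencyTable,
    tie_rel_tol: float = 1e-7,
    max_tables: int = 2_000_000,
) -> float:
    """Exact test of independence for a 2xN table (Freeman-Halton).

    Sums the multivariate-hypergeometric probabilities, conditional on the
    observed margins, of every table whose probability does not exceed the
    observed table's (with a relative tie tolerance for floating-point
    equality). Enumeration is over the first row's column allocations; a
    workload cap guards against tables too large for exact enumeration.
    """
    obs = _nonzero_columns(table).astype(int)
    if obs.shape[1] < 2:
        raise UntestableError("fewer than two non-zero columns")
    col_tot = obs.sum(axis=0)
    r1 = int(obs[0].sum())
    n = int(obs.sum())
    workload = 1
    for c in col_tot:
        workload *= min(int(c), r1) + 1
        if workload > max_tables:
            raise FisherWorkloadError(
                f"exact enumeration would visit > {max_tables} tables "
                f"(grand total {n}); use the chi-squared test"
            )

    log_denominator = _lchoose(n, r1)

    def log_p(first_row: Sequence[int]) -> float:
        return sum(_lchoose(int(c), int(a)) for c, a in zip(col_tot, first_row)) - log_denominator

    log_p_obs = log_p(obs[0])
    threshold = log_p_obs + math.log1p(tie_rel_tol)
    suffix_sums = np.concatenate([np.cumsum(col_tot[::-1])[::-1], [0]])

    total = 0.0
    k = len(col_tot)

    def recurse(j: int, remaining: int, log_acc: float) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col_tot[j]:
                lp = log_acc + _lchoose(int(col_tot[j]), remaining) - log_denominator
                if lp <= threshold:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(suffix_sums[j + 1]))
        hi = min(int(col_tot[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, log_acc + _lchoose(int(col_tot[j]), a))

    recurse(0, r1, 0.0)
    return min(total, 1.0)


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


# ---------------------------------------------------------------------------
# linear trend test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    r: float
    m2: float
    p: float


def linear_trend_test(table: ContingencyTable) -> TrendResult:
    """Linear-by-linear association test on the scored 2xN table.

    r is the Pearson correlation between row scores (1, 2) and column
    scores (the 3'-UTR lengths), computed over the n reads with the cell
    counts as weights; M^2 = (n - 1) r^2 is referred to chi-squared with
    one degree of freedom. If either weighted score variance vanishes
    (e.g. one sample empty, or effectively one site), r is defined as 0 and
    p as 1.
    """
    w = table.to_array()
    n = w.sum()
    if n < 2:
        raise UntestableError("trend test needs a grand total of at least 2")
    x = np.asarray(ROW_SCORES)[:, None]
    y = np.asarray(table.col_scores)[None, :]
    mx = (w * x).sum() / n
    my = (w * y).sum() / n
    cov = (w * (x - mx) * (y - my)).sum() / n
    var_x = (w * (x - mx) ** 2).sum() / n
    var_y = (w * (y - my) ** 2).sum() / n
    if var_x <= 0 or var_y <= 0:
        return TrendResult(r=0.0, m2=0.0, p=1.0)
    r = float(cov / math.sqrt(var_x * var_y))
    r = max(-1.0, min(1.0, r))
    m2 = float((n - 1) * r * r)
    return TrendResult(r=r, m2=m2, p=float(chi2.sf(m2, 1)))


# ---------------------------------------------------------------------------
# dispatch, FDR, grouping
# ---------------------------------------------------------------------------

CHI_SQUARED = "chi_squared"
FISHER_EXACT = "fisher_exact"


@dataclass
class SwitchTestResult:
    """Per-gene switching-test outcome.

    Trend fields are None for small-sample genes dispatched to the exact
    test (the trend statistic's chi-squared approximation is unreliable
    there). q-values are filled in by :func:`run_gene_tests` /
    :func:`attach_fdr`.
    """

    gene_id: str
    n_sites: int
    grand_total: int
    independence_method: str
    p_independence: float
    r: float | None = None
    m2: float | None = None
    p_trend: float | None = None
    q_independence: float | None = None
    q_trend: float | None = None


def select_and_run(
    table: ContingencyTable,
    gene_id: str = "",
    small_threshold: int = 30,
) -> SwitchTestResult:
    """Run the appropriate pair of tests for one gene's table.

    Tables with grand total >= ``small_threshold`` get the chi-squared
    independence test plus the linear trend test; smaller tables get
    Fisher's exact test only.
    """
    n = table.grand_total
    if n >= small_threshold:
        p_ind = chi_squared_test(table)
        trend = linear_trend_test(table)
        return SwitchTestResult(
            gene_id=gene_id,
            n_sites=table.n_cols,
            grand_total=n,
            independence_method=CHI_SQUARED,
            p_independence=p_ind,
            r=trend.r,
            m2=trend.m2,
            p_trend=trend.p,
        )
    p_ind = fisher_exact_test(table)
    return SwitchTestResult(
        gene_id=gene_id,
        n_sites=table.n_cols,
        grand_total=n,
        independence_method=FISHER_EXACT,
        p_independence=p_ind,
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at
    1 and mapped back to the input order. Monotone non-decreasing along the
    sorted p-values, and q >= p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def attach_fdr(results: Iterable[SwitchTestResult]) -> list[SwitchTestResult]:
    """Fill q_independence / q_trend across a cohort of results.

    Each test's p-values are adjusted separately: the independence FDR runs
    over every tested gene, the trend FDR only over genes with a trend
    result.
    """
    results = list(results)
    if results:
        q_ind = bh_fdr([res.p_independence for res in results])
        for res, q in zip(results, q_ind):
            res.q_independence = float(q)
    with_trend = [res for res in results if res.p_trend is not None]
    if with_trend:
        q_tr = bh_fdr([res.p_trend for res in with_trend])
        for res, q in zip(with_trend, q_tr):
            res.q_trend = float(q)
    return results


def run_gene_tests(
    genes: Iterable[TandemGene],
    small_threshold: int = 30,
) -> tuple[list[SwitchTestResult], list[tuple[str, str]]]:
    """Test every testable gene and attach BH q-values.

    Returns (results, skipped) where ``skipped`` lists (gene_id, reason)
    for genes that could not be tested.
    """
    results: list[SwitchTestResult] = []
    skipped: list[tuple[str, str]] = []
    for gene in genes:
        try:
            table = ContingencyTable.from_gene(gene)
            results.append(select_and_run(table, gene.gene_id, small_threshold))
        except (UntestableError, FisherWorkloadError) as exc:
            logger.info("skipping %s: %s", gene.gene_id, exc)
            skipped.append((gene.gene_id, str(exc)))
    return attach_fdr(results), skipped


def group_genes(
    results: Iterable[SwitchTestResult],
    fdr_cutoff: float = 0.01,
) -> dict[str, list[str]]:
    """Partition genes into CL / CO / LO / NS at an FDR cutoff.

    CL: significant in both the independence and the trend test;
    CO: independence only; LO: trend only; NS: neither. Genes without a
    trend result (small-sample dispatch) can only fall in CO or NS. The
    partition is exhaustive and disjoint.
    """
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    for res in results:
        if res.q_independence is None:
            raise ValueError(f"{res.gene_id}: q-values not populated; run attach_fdr first")
        sig_ind = res.q_independence < fdr_cutoff
        sig_trend = res.q_trend is not None and res.q_trend < fdr_cutoff
        if sig_ind and sig_trend:
            groups["CL"].append(res.gene_id)
        elif sig_ind:
            groups["CO"].append(res.gene_id)
        elif sig_trend:
            groups["LO"].append(res.gene_id)
        else:
            groups["NS"].append(res.gene_id)
    return groups
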