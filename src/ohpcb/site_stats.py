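"""Site-level descriptive summaries and exact nonparametric tests.

Concentration data here are lognormal-like and the group sizes tiny (2-5
samples per site), so the central summaries are the geometric mean/geometric
standard deviation and the hypothesis tests are exact: the
Wilcoxon-Mann-Whitney test by full enumeration of all C(n_x+n_y, n_x) rank
assignments, and the Spearman test by full enumeration of all n! rank
permutations.  Both switch to the usual normal/t approximations above a size
threshold, with the method recorded in the result.  Two-sided exact p-values
are tail-doubled (capped at 1), e.g. complete separation of two groups of
five gives p = 2/252 = 0.0079 and perfect rank agreement of five pairs gives
p = 2/120 = 0.017.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StatSummary",
    "RegressionFit",
    "TestResult",
    "CorrelationResult",
    "summarize",
    "gm_gsd",
    "ratio_ohpcb_pcb",
    "mann_whitney_exact",
    "spearman_exact",
    "pearson_log",
    "loglog_fit",
    "ALPHA",
    "EXACT_MW_LIMIT",
    "EXACT_SPEARMAN_LIMIT",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05  # significance level used pipeline-wide
EXACT_MW_LIMIT = 12  # enumerate when n_x + n_y <= this
EXACT_SPEARMAN_LIMIT = 8  # enumerate when n <= this


@dataclass(frozen=True)
class StatSummary:
    """median, mean +- sd, GM and GSD of one group of values."""

    median: float
    mean: float
    sd: float
    gm: float | None
    gsd: float | None
    n: int
    n_zero_excluded: int = 0


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: float
    method: str  # "exact" | "normal-approx"
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    estimate: float
    p_value: float
    method: str
    n: int


@dataclass(frozen=True)
class RegressionFit:
    """OLS of ln(y) on ln(x); slope is the log-log elasticity."""

    beta0: float
    beta1: float
    p_value: float
    n: int
    scale: str = "log-log"

    def fold_change(self, factor: float) -> float:
        """Expected multiplicative change in y when x changes by ``factor``."""
        if factor <= 0:
            raise ValueError("factor must be > 0")
        return float(factor**self.beta1)


def gm_gsd(values: Iterable[float]) -> dict:
    """Geometric mean and geometric standard deviation of positive values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    if np.any(vals <= 0):
        raise ValueError("gm_gsd requires all-positive values")
    logs = np.log(vals)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if vals.size > 1 else None
    return {"gm": gm, "gsd": gsd}


def summarize(values: Iterable[float]) -> StatSummary:
    """Descriptive summary; zeros (censored) are excluded from GM/GSD only."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    positive = vals[vals > 0]
    n_zero = int(vals.size - positive.size)
    if n_zero:
        logger.info("summarize: %d zero value(s) excluded from GM/GSD", n_zero)
    if positive.size:
        g = gm_gsd(positive)
        gm, gsd = g["gm"], g["gsd"]
    else:
        gm, gsd = None, None
    return StatSummary(
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        gm=gm,
        gsd=gsd,
        n=int(vals.size),
        n_zero_excluded=n_zero,
    )


def ratio_ohpcb_pcb(total_oh: float, total_pcb: float) -> float:
    """[OH-PCBs]/[PCBs] as a percentage."""
    if total_pcb <= 0:
        raise ValueError("total PCB concentration must be > 0")
    if total_oh < 0:
        raise ValueError("negative OH-PCB total")
    return 100.0 * total_oh / total_pcb


def _two_sided_from_tails(p_low: float, p_high: float) -> float:
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_MW_LIMIT
) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test, exact for small groups.

    For n_x + n_y <= ``exact_limit`` the null distribution of the rank sum of
    x is enumerated over all C(n_x+n_y, n_x) assignments of the (midrank-tied)
    pooled ranks; p is the doubled smaller tail, capped at 1.  Larger groups
    use the tie-corrected normal approximation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("NaN in input")
    n = x.size + y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    t_obs = float(ranks[: x.size].sum())
    if n <= exact_limit:
        total = math.comb(n, x.size)
        n_le = n_ge = 0
        for combo in combinations(range(n), x.size):
            t = ranks[list(combo)].sum()
            if t <= t_obs + 1e-9:
                n_le += 1
            if t >= t_obs - 1e-9:
                n_ge += 1
        p = _two_sided_from_tails(n_le / total, n_ge / total)
        return TestResult(p, t_obs, "exact", n)
    logger.info(
        "mann_whitney_exact: n=%d above exact limit %d; normal approximation",
        n,
        exact_limit,
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.pvalue), float(res.statistic), "normal-approx", n)


def _rho_against(rx_centered: np.ndarray, ry_rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of rx against each row of ry_rows (rank vectors)."""
    ry_c = ry_rows - ry_rows.mean(axis=1, keepdims=True)
    num = ry_c @ rx_centered
    den = np.linalg.norm(ry_c, axis=1) * np.linalg.norm(rx_centered)
    return num / den


def spearman_exact(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_SPEARMAN_LIMIT
) -> CorrelationResult:
    """Spearman rank correlation with an exact two-sided permutation p.

    For n <= ``exact_limit`` the p-value is the proportion of all n! rank
    permutations of y whose |rho| is at least the observed |rho|; above the
    limit the usual t approximation is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    rho = float(_rho_against(rx_c, ry[None, :])[0])
    if n <= exact_limit:
        perm_idx = np.array(list(permutations(range(n))))
        rhos = _rho_against(rx_c, ry[perm_idx])
        count = int(np.count_nonzero(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, count / perm_idx.shape[0], "exact", n)
    logger.info(
        "spearman_exact: n=%d above exact limit %d; t approximation", n, exact_limit
    )
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho, float(res.pvalue), "t-approx", n)


def pearson_log(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of ln-transformed pairs with a two-sided t p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log transform requires positive values")
    res = stats.pearsonr(np.log(x), np.log(y))
    return CorrelationResult(float(res.statistic), float(res.pvalue), "t-approx", x.size)


def loglog_fit(pcb: Sequence[float], oh: Sequence[float]) -> RegressionFit:
    """OLS of ln(OH-PCB total) on ln(PCB total).

    The slope beta1 is the log-log elasticity: a PCB level ``f`` times higher
    predicts an OH-PCB level ``f**beta1`` times higher
    (:meth:`RegressionFit.fold_change`).
    """
    pcb = np.asarray(list(pcb), dtype=float)
    oh = np.asarray(list(oh), dtype=float)
    if pcb.size != oh.size:
        raise ValueError("paired inputs required")
    if pcb.size < 3:
        raise ValueError("need n >= 3")
    if np.any(pcb <= 0) or np.any(oh <= 0):
        raise ValueError("log-log fit requires positive pairs")
    lx, ly = np.log(pcb), np.log(oh)
    if np.unique(lx).size == 1:
        raise ValueError("degenerate x: all PCB totals equal")
    res = stats.linregress(lx, ly)
    return RegressionFit(
        beta0=float(res.intercept),
        beta1=float(res.slope),
        p_value=float(res.pvalue),
        n=int(pcb.size),
    )
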