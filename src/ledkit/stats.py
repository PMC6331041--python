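"""Inferential machinery for the divergence analysis.

Two-sample permutation tests (difference of medians), correlation tests with
t-based p-values, Poisson regression of interaction counts on divergence, and
the primary-tissue enrichment battery (overall chi-square goodness of fit plus
per-tissue exact binomial tests with Bonferroni correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "PermutationTestResult",
    "CorrelationTestResult",
    "PoissonFitResult",
    "permutation_test_median_diff",
    "correlation_test",
    "fit_poisson_regression",
    "tissue_enrichment",
]

#: largest number of distinct label assignments for which the permutation
#: test automatically switches to exhaustive enumeration
EXACT_ENUMERATION_LIMIT = 5000


@dataclass(frozen=True)
class PermutationTestResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False


@dataclass(frozen=True)
class CorrelationTestResult:
    method: str
    r: float
    t_stat: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PoissonFitResult:
    beta0: float
    beta1: float
    se0: float
    se1: float
    wald_p: float
    residual_deviance: float
    gof_p: float
    n_iterations: int
    converged: bool
    n: int


def permutation_test_median_diff(
    a,
    b,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool | None = None,
) -> PermutationTestResult:
    """Two-sample permutation test with |median(a) − median(b)| as statistic.

    Monte-Carlo mode shuffles the pooled sample ``n_perm`` times and uses the
    add-one estimator p = (1 + #{permuted ≥ observed}) / (1 + n_perm), so p is
    never zero and never below 1/(n_perm + 1).  When the number of distinct
    label assignments C(n, n_a) is small (``exact=None`` auto-switches below
    ``EXACT_ENUMERATION_LIMIT``, or pass ``exact=True``), all assignments are
    enumerated and p is the exact tail fraction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = abs(float(np.median(a)) - float(np.median(b)))
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size

    n_assignments = math.comb(n, na)
    if exact is None:
        exact = n_assignments <= EXACT_ENUMERATION_LIMIT
    if exact:
        tol = 1e-12
        hits = 0
        idx = np.arange(n)
        for chosen in combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            stat = abs(
                float(np.median(pooled[mask])) - float(np.median(pooled[~mask]))
            )
            if stat >= observed - tol:
                hits += 1
        return PermutationTestResult(
            observed_stat=observed,
            p_value=hits / n_assignments,
            n_permutations=n_assignments,
            seed=seed,
            exact=True,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, 200_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        perm = np.tile(pooled, (size, 1))
        perm = rng.permuted(perm, axis=1)
        stats = np.abs(
            np.median(perm[:, :na], axis=1) - np.median(perm[:, na:], axis=1)
        )
        hits += int((stats >= observed - 1e-12).sum())
        done += size
    p = (1 + hits) / (1 + n_perm)
    return PermutationTestResult(
        observed_stat=observed,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        exact=False,
    )


def correlation_test(x, y, method: str = "pearson") -> CorrelationTestResult:
    """Pearson's r or Spearman's rho with a t-based two-sided p-value.

    Incomplete cases (NaN in either vector) are dropped first.  Spearman is
    computed as Pearson on mid-ranks.  The p-value comes from
    t = r·√((n−2)/(1−r²)) against the t distribution with n − 2 df; a perfect
    correlation gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete cases, got {n}")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationTestResult(method=method, r=r, t_stat=t, p_value=p, n=n)


def fit_poisson_regression(y, x) -> PoissonFitResult:
    """Poisson regression of counts on one predictor, log link.

    Fit by iteratively reweighted least squares (tolerance 1e-8 on the
    deviance, at most 100 iterations).  Reports Wald p for the slope, the
    residual deviance D = 2Σ[y·ln(y/μ̂) − (y − μ̂)] (y = 0 terms contribute
    2μ̂) and its upper-tail χ² probability at n − 2 df as a goodness-of-fit
    p-value.  Non-convergence is flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-d vectors of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if not np.isfinite(x).all():
        raise ValueError("predictor contains non-finite values")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("y must contain non-negative integer counts")

    design = sm.add_constant(x)
    model = sm.GLM(y, design, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    n = y.size
    deviance = float(res.deviance)
    gof_p = float(sps.chi2.sf(deviance, n - 2))
    n_iter = len(res.fit_history.get("deviance", [])) - 1
    return PoissonFitResult(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        se0=float(res.bse[0]),
        se1=float(res.bse[1]),
        wald_p=float(res.pvalues[1]),
        residual_deviance=deviance,
        gof_p=gof_p,
        n_iterations=max(n_iter, 0),
        converged=bool(res.converged),
        n=n,
    )


def tissue_enrichment(
    top_tissues,
    genome_tissues,
    tissue_order: list[str] | None = None,
) -> tuple[float, float, int, pd.DataFrame]:
    """Primary-tissue enrichment of a top-divergence gene set.

    Expected counts derive from the genome-wide primary-tissue frequencies;
    the overall test is a χ² goodness of fit with T − 1 df, and each tissue
    additionally gets a two-sided exact binomial test (number of successes =
    observed count, trials = top-set size, success probability = genome
    frequency), Bonferroni-adjusted by the number of tissues.

    Returns ``(chi2_stat, chi2_p, df, rows)`` where ``rows`` has one line per
    tissue: observed, expected, chi_component = (O − E)/√E, binom_p_raw,
    binom_p_adj.
    """
    top = pd.Series(list(top_tissues), dtype=str)
    genome = pd.Series(list(genome_tissues), dtype=str)
    if top.empty or genome.empty:
        raise ValueError("both label collections must be non-empty")
    vocab = (
        list(tissue_order)
        if tissue_order is not None
        else list(dict.fromkeys(genome))
    )
    unknown = set(top) - set(vocab)
    if unknown:
        raise ValueError(
            f"top-set tissue(s) {sorted(unknown)} absent from genome vocabulary"
        )
    n_top = len(top)
    genome_counts = genome.value_counts().reindex(vocab).fillna(0).astype(int)
    obs = top.value_counts().reindex(vocab).fillna(0).astype(int)
    freq = genome_counts / genome_counts.sum()
    expected = n_top * freq

    with np.errstate(divide="ignore", invalid="ignore"):
        comp = (obs - expected) / np.sqrt(expected)
    comp = comp.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    nonzero = expected > 0
    chi2_stat = float((comp[nonzero] ** 2).sum())
    df = len(vocab) - 1
    chi2_p = float(sps.chi2.sf(chi2_stat, df))

    raw_p = []
    for t in vocab:
        p_t = float(freq[t])
        if p_t == 0.0:
            raw_p.append(1.0 if obs[t] == 0 else 0.0)
        else:
            raw_p.append(
                float(sps.binomtest(int(obs[t]), n_top, p_t).pvalue)
            )
    n_tests = len(vocab)
    rows = pd.DataFrame(
        {
            "tissue": vocab,
            "observed": obs.to_numpy(),
            "expected": expected.to_numpy(),
            "chi_component": comp.to_numpy(),
            "binom_p_raw": raw_p,
            "binom_p_adj": [min(1.0, n_tests * p) for p in raw_p],
        }
    )
    return chi2_stat, chi2_p, df, rows
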