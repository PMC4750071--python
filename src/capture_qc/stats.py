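"""Paired nonparametric comparison of per-sample metrics across methods.

One-sided Wilcoxon signed-rank tests, exact for the sample sizes that
matter here. With n paired samples per method (after dropping zero
differences), the exact null distribution of W+ — the sum of the ranks
of positive differences — is computed by a generating-function pass
over the (average, possibly tied) ranks: ranks are doubled so ties at
.5 stay integral, and the polynomial ``prod_i (1 + z^{2 r_i}) / 2^n``
gives the exact probability of every achievable W+. Exact enumeration
is used up to ``n = 25`` (covering a 24-sample cohort); beyond that
the normal approximation with tie correction and continuity correction
takes over. Zero differences are dropped (Wilcoxon's original rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairedComparison", "wilcoxon_signed_rank", "metric_comparison_table"]

EXACT_LIMIT = 25

_null_cache: dict[tuple[int, ...], np.ndarray] = {}


@dataclass
class PairedComparison:
    metric: str
    method_a: str
    method_b: str
    alternative: str  # "greater": H1 is a > b; "less": a < b
    n: int
    n_effective: int
    w_plus: float
    p_value: float


def _exact_null_pmf(double_ranks: tuple[int, ...]) -> np.ndarray:
    """PMF of 2*W+ over 0..sum(double_ranks) under the exchangeable null."""
    pmf = _null_cache.get(double_ranks)
    if pmf is not None:
        return pmf
    total = sum(double_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    pmf = counts / 2 ** len(double_ranks)
    _null_cache[double_ranks] = pmf
    return pmf


def wilcoxon_signed_rank(
    x,
    y,
    alternative: str = "greater",
    metric: str = "",
    method_a: str = "A",
    method_b: str = "B",
) -> PairedComparison:
    """One-sided Wilcoxon signed-rank test on paired values.

    ``alternative="greater"`` tests whether ``x`` tends to exceed
    ``y`` (P(W+ >= w) under the null); ``"less"`` the reverse.
    Raises if every difference is zero (the test is undefined).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 2")
    d = x - y
    d = d[d != 0]
    n_eff = d.size
    if n_eff == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n_eff <= EXACT_LIMIT:
        dr = tuple(int(round(2 * r)) for r in sorted(ranks))
        pmf = _exact_null_pmf(dr)
        w2 = int(round(2 * w_plus))
        if alternative == "greater":
            p = float(pmf[w2:].sum())
        else:
            p = float(pmf[: w2 + 1].sum())
    else:
        mean = n_eff * (n_eff + 1) / 4
        # tie correction on the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24 - tie_term
        if alternative == "greater":
            z = (w_plus - mean - 0.5) / np.sqrt(var)
            p = float(sps.norm.sf(z))
        else:
            z = (w_plus - mean + 0.5) / np.sqrt(var)
            p = float(sps.norm.cdf(z))
    return PairedComparison(
        metric=metric,
        method_a=method_a,
        method_b=method_b,
        alternative=alternative,
        n=x.size,
        n_effective=n_eff,
        w_plus=w_plus,
        p_value=min(p, 1.0),
    )


def metric_comparison_table(
    per_sample_metrics: dict[str, dict[str, float]],
    alpha: float = 0.025,
    metric: str = "",
) -> pd.DataFrame:
    """Test every method pair in both directions on shared samples.

    ``per_sample_metrics`` maps method -> {sample -> value}; all methods
    must cover the same sample set (an error lists what is missing).
    No multiple-testing correction is applied to the significance flag;
    a Bonferroni-adjusted column is emitted for transparency.
    """
    methods = sorted(per_sample_metrics)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    sample_sets = {m: set(per_sample_metrics[m]) for m in methods}
    union = set.union(*sample_sets.values())
    problems = {m: sorted(union - s) for m, s in sample_sets.items() if union - s}
    if problems:
        raise ValueError(f"sample sets differ between methods; missing: {problems}")
    samples = sorted(union)

    rows = []
    n_tests = len(methods) * (len(methods) - 1)
    for a in methods:
        for b in methods:
            if a == b:
                continue
            va = [per_sample_metrics[a][s] for s in samples]
            vb = [per_sample_metrics[b][s] for s in samples]
            try:
                cmp_ = wilcoxon_signed_rank(
                    va, vb, alternative="greater", metric=metric, method_a=a, method_b=b
                )
                p, w, ne = cmp_.p_value, cmp_.w_plus, cmp_.n_effective
            except ValueError:
                p, w, ne = None, None, 0
            rows.append(
                {
                    "metric": metric,
                    "greater": a,
                    "lesser": b,
                    "n": len(samples),
                    "n_effective": ne,
                    "w_plus": w,
                    "p_value": p,
                    "significant": (p is not None and p <= alpha),
                    "p_bonferroni": min(p * n_tests, 1.0) if p is not None else None,
                }
            )
    return pd.DataFrame(rows)
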