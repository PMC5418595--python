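"""Incorporation-bias and producer-enrichment statistics.

Per-gene χ² goodness-of-fit of observed promoter-category counts against the
chance expectation (with an exact multinomial fallback when expected counts
are small), and a two-sided Fisher's exact test for category enrichment among
producer strains.  Fisher's test is computed by exact integer hypergeometric
enumeration; Benjamini–Hochberg adjustment is provided for multi-gene use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .read_classifier import PromoterCountTable


@dataclass
class BiasTestResult:
    gene: str
    stage: str
    statistic: float
    dof: int
    p_value: float
    expected_counts: dict[str, float]
    observed_counts: dict[str, int]
    method: str  # "chi2" or "exact_multinomial"
    note: str = ""


@dataclass
class EnrichmentTestResult:
    gene: str
    category: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float


def chi2_gof(
    observed: Mapping[str, int],
    null: Mapping[str, float],
    *,
    exact_threshold: float = 5.0,
    max_enumeration: int = 200_000,
    n_sim: int = 100_000,
    seed: int = 0,
) -> tuple[float, int, float, dict[str, float], str, str]:
    """Core goodness-of-fit machinery shared by :func:`chi2_bias_test`.

    Returns (statistic, dof, p, expected, method, note).  Categories with zero
    null mass are excluded from the support; observed counts there are an
    error.  When any expected count is below ``exact_threshold`` the p-value
    is computed by exact multinomial tail enumeration (Monte-Carlo above
    ``max_enumeration`` outcomes) and that method is authoritative.
    """
    support = [c for c, p in null.items() if p > 0]
    off_support = [c for c, n in observed.items() if n and null.get(c, 0.0) <= 0]
    if off_support:
        raise ValueError(f"observed counts in zero-probability categories: {off_support}")
    probs = np.array([null[c] for c in support], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("null probabilities must sum to 1")
    obs = np.array([int(observed.get(c, 0)) for c in support], dtype=np.int64)
    total = int(obs.sum())
    if total == 0:
        raise ValueError("all-zero observed table")

    expected = total * probs
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = len(support) - 1
    p_chi2 = float(stats.chi2.sf(stat, dof))

    method, note = "chi2", ""
    p_value = p_chi2
    if expected.min() < exact_threshold:
        method = "exact_multinomial"
        n_outcomes = math.comb(total + len(support) - 1, len(support) - 1)
        if n_outcomes <= max_enumeration:
            p_value = _exact_multinomial_tail(stat, total, probs)
        else:
            rng = np.random.default_rng(seed)
            draws = rng.multinomial(total, probs, size=n_sim)
            stats_sim = ((draws - expected) ** 2 / expected).sum(axis=1)
            hits = int((stats_sim >= stat - 1e-9).sum())
            p_value = (hits + 1) / (n_sim + 1)
            note = f"monte_carlo:{n_sim}"
    exp_map = {c: float(e) for c, e in zip(support, expected)}
    return stat, dof, p_value, exp_map, method, note


def _exact_multinomial_tail(stat_obs: float, n: int, probs: np.ndarray) -> float:
    """P(χ² statistic ≥ observed) under the multinomial null, by enumeration."""
    k = probs.size
    expected = n * probs
    logp = np.log(probs)
    lg = math.lgamma
    total = 0.0
    counts = np.zeros(k, dtype=np.int64)

    def rec(i: int, remaining: int, log_coef: float, partial: float) -> None:
        nonlocal total
        if i == k - 1:
            c = remaining
            stat = partial + (c - expected[i]) ** 2 / expected[i]
            if stat >= stat_obs - 1e-9:
                total += math.exp(log_coef - lg(c + 1) + c * logp[i])
            return
        for c in range(remaining + 1):
            rec(i + 1, remaining - c,
                log_coef - lg(c + 1) + c * logp[i],
                partial + (c - expected[i]) ** 2 / expected[i])

    rec(0, n, lg(n + 1), 0.0)
    return min(1.0, total)


def chi2_bias_test(
    observed: PromoterCountTable,
    null: Mapping[str, float],
    gene: str,
    **kwargs,
) -> BiasTestResult:
    """Test a slot's observed category counts against the chance distribution."""
    obs = {
        cat: n for (g, cat), n in observed.category_counts.items() if g == gene
    }
    if not obs:
        raise ValueError(f"no category counts for gene {gene!r}")
    stat, dof, p, expected, method, note = chi2_gof(obs, null, **kwargs)
    support = set(expected)
    return BiasTestResult(
        gene=gene, stage=observed.stage, statistic=stat, dof=dof, p_value=p,
        expected_counts=expected,
        observed_counts={c: int(obs.get(c, 0)) for c in support},
        method=method, note=note,
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test by integer hypergeometric enumeration.

    Returns (odds_ratio, p).  The odds ratio is the sample (a·d)/(b·c), with
    ∞ when b·c = 0 and a·d > 0, and NaN for the degenerate 0/0 case.  The
    two-sided p sums hypergeometric weights w(k) ≤ w(a)·(1 + 1e-7) — the
    standard tie rule — over all tables with the observed margins; weights are
    exact integers so the comparison is exact up to the deliberate slack.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts in contingency table")
    if a * d == 0 and b * c == 0:
        odds = math.nan
    elif b * c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)

    n = a + b + c + d
    if n == 0:
        return odds, 1.0
    row1 = a + b
    col1 = a + c
    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    weights = [math.comb(row1, k) * math.comb(n - row1, col1 - k)
               for k in range(k_min, k_max + 1)]
    w_obs = weights[a - k_min]
    # integer-exact version of w <= w_obs * (1 + 1e-7)
    numer = sum(w for w in weights if w * 10**7 <= w_obs * (10**7 + 1))
    denom = sum(weights)
    return odds, numer / denom


def fisher_enrichment_test(
    producer_counts: PromoterCountTable,
    reference_counts: PromoterCountTable,
    category: str,
    gene: str,
) -> EnrichmentTestResult:
    """Is *category* over-represented at *gene* among producers vs reference?

    Builds the 2×2 table [[producers with category, producers without],
    [reference with, reference without]] from slot observations at *gene*.
    """
    a = producer_counts.category_counts.get((gene, category), 0)
    b = producer_counts.total(gene) - a
    c = reference_counts.category_counts.get((gene, category), 0)
    d = reference_counts.total(gene) - c
    odds, p = fisher_exact_2x2(((a, b), (c, d)))
    return EnrichmentTestResult(
        gene=gene, category=category, table=((a, b), (c, d)),
        p_value=p, odds_ratio=odds,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    order = np.argsort(p)
    m = p.size
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bias_report(
    tables: Sequence[PromoterCountTable],
    null_by_gene: Mapping[str, Mapping[str, float]],
    **kwargs,
) -> list[BiasTestResult]:
    """Run the per-gene χ² bias test for every (stage table, gene) pair."""
    results = []
    for table in tables:
        genes = sorted({g for (g, _) in table.counts})
        for gene in genes:
            if table.total(gene) == 0:
                continue
            results.append(chi2_bias_test(table, null_by_gene[gene], gene, **kwargs))
    return results
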