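"""Transmission disequilibrium testing of patrilineal lineages.

Each patrilineal lineage is a proxy for one Y chromosome; under Mendelian
transmission the children of its fathers are male or female with equal
probability.  The TDT here is the one-degree-of-freedom chi-squared test
of that 50:50 expectation over a lineage's informative transmissions,
scanned across lineages with Benjamini-Hochberg FDR control, plus the
exact binomial confidence envelope for the male proportion and a Monte
Carlo test that randomizes the sexes of a single family's transmissions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pedigree import Lineage, Pedigree, patrilineal_lineages

DEFAULT_MIN_OFFSPRING = 75  # lineages must have MORE than this many


@dataclass
class TDTResult:
    lineage_id: str
    n_transmissions: int
    n_male: int
    n_female: int
    chi2: float
    p_value: float
    passed_size_filter: bool
    p_fdr: Optional[float] = None
    ci_low: int = 0
    ci_high: int = 0
    df: int = 1

    @property
    def male_proportion(self) -> float:
        return self.n_male / self.n_transmissions


@dataclass
class MonteCarloResult:
    n_transmissions: int
    n_favored_observed: int
    n_reps: int
    n_at_least_as_extreme: int
    p_value: float
    seed: int
    sidedness: str = "two-sided"


def tdt_chi2(n_male: int, n_female: int) -> tuple[float, float]:
    """Chi-squared test (1 df, no continuity correction) of a 50:50 sex
    ratio among ``n_male + n_female`` transmissions."""
    n = n_male + n_female
    if n < 1:
        raise ValueError("at least one sexed transmission is required")
    expected = n / 2.0
    chi2 = (n_male - expected) ** 2 / expected + (n_female - expected) ** 2 / expected
    return chi2, float(stats.chi2.sf(chi2, df=1))


def apply_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def binomial_ci(
    n: int, prob: float = 0.5, q_low: float = 0.005, q_high: float = 0.995
) -> tuple[int, int]:
    """Binomial count quantiles bounding the null sex-ratio envelope.

    Returns the smallest counts whose cumulative mass reaches ``q_low``
    and ``q_high`` (the 99% envelope by default) for ``n`` transmissions
    at per-child male probability ``prob``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < q_low < q_high < 1.0):
        raise ValueError("quantiles must satisfy 0 < q_low < q_high < 1")
    lo = int(stats.binom.ppf(q_low, n, prob))
    hi = int(stats.binom.ppf(q_high, n, prob))
    return lo, hi


def scan_lineages(
    ped: Pedigree,
    min_offspring: int = DEFAULT_MIN_OFFSPRING,
    lineages: Optional[Sequence[Lineage]] = None,
) -> list[TDTResult]:
    """TDT over every patrilineal lineage with at least one transmission.

    ``passed_size_filter`` marks lineages with strictly more than
    ``min_offspring`` transmissions; BH-FDR adjustment is applied across
    those lineages only (small families are reported with a raw p-value
    but no ``p_fdr``).  Lineages whose sexed transmissions are all unknown
    are skipped.
    """
    if min_offspring < 0:
        raise ValueError("min_offspring must be >= 0")
    if lineages is None:
        lineages = patrilineal_lineages(ped)
    results = []
    for lin in lineages:
        if lin.n_transmissions < 1 or lin.n_male + lin.n_female < 1:
            continue
        chi2, p = tdt_chi2(lin.n_male, lin.n_female)
        lo, hi = binomial_ci(lin.n_transmissions)
        results.append(
            TDTResult(
                lineage_id=lin.founder_id,
                n_transmissions=lin.n_transmissions,
                n_male=lin.n_male,
                n_female=lin.n_female,
                chi2=chi2,
                p_value=p,
                passed_size_filter=lin.n_transmissions > min_offspring,
                ci_low=lo,
                ci_high=hi,
            )
        )
    passing = [r for r in results if r.passed_size_filter]
    if passing:
        adjusted = apply_fdr([r.p_value for r in passing])
        for r, q in zip(passing, adjusted):
            r.p_fdr = q
    return results


def monte_carlo_family(
    n: int, n_favored: int, n_reps: int = 10_000, seed: int = 0,
    sidedness: str = "two-sided",
) -> MonteCarloResult:
    """Monte Carlo approximation of the TDT for a single family.

    Each replicate assigns the sexes of ``n`` transmissions independently
    with a fair coin; a replicate counts as at least as extreme when its
    male count deviates from n/2 by at least as much as the observed
    ``n_favored`` (two-sided, matching the chi-squared test; one-sided
    counts replicates with at least ``n_favored`` males).
    """
    if not (0 <= n_favored <= n):
        raise ValueError("need 0 <= n_favored <= n")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if sidedness not in ("two-sided", "one-sided"):
        raise ValueError("sidedness must be 'two-sided' or 'one-sided'")
    rng = np.random.default_rng(seed)
    males = rng.binomial(n, 0.5, size=n_reps)
    if sidedness == "two-sided":
        extreme = int(
            np.count_nonzero(np.abs(males - n / 2.0) >= abs(n_favored - n / 2.0))
        )
    else:
        extreme = int(np.count_nonzero(males >= n_favored))
    return MonteCarloResult(
        n_transmissions=n,
        n_favored_observed=n_favored,
        n_reps=n_reps,
        n_at_least_as_extreme=extreme,
        p_value=extreme / n_reps,
        seed=seed,
        sidedness=sidedness,
    )


def exact_binomial_two_sided(n: int, n_favored: int) -> float:
    """Exact two-sided tail: P(|X - n/2| >= |n_favored - n/2|), X ~ Bin(n, ½).

    Computed by summing binomial point masses; the limit of the Monte
    Carlo p-value as the number of replicates grows.
    """
    dev = abs(n_favored - n / 2.0)
    k = np.arange(n + 1)
    mask = np.abs(k - n / 2.0) >= dev
    return float(stats.binom.pmf(k[mask], n, 0.5).sum())


def tdt_report(results: Sequence[TDTResult]) -> pd.DataFrame:
    """Scatter-ready table: one row per lineage with male proportion and
    the 99% binomial envelope expressed as proportions."""
    return pd.DataFrame(
        {
            "lineage_id": [r.lineage_id for r in results],
            "n_transmissions": [r.n_transmissions for r in results],
            "n_male": [r.n_male for r in results],
            "n_female": [r.n_female for r in results],
            "male_proportion": [r.male_proportion for r in results],
            "chi2": [r.chi2 for r in results],
            "p_value": [r.p_value for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "passed_size_filter": [r.passed_size_filter for r in results],
            "ci_low_prop": [r.ci_low / r.n_transmissions for r in results],
            "ci_high_prop": [r.ci_high / r.n_transmissions for r in results],
        }
    )
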