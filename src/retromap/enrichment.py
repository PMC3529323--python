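"""Overlap and category over-representation statistics.

The chance expectation for the overlap of two sets drawn independently
from a universe of N genes is |A||B|/N; the observed/expected ratio is the
enrichment effect size, and significance comes from the hypergeometric
tail (one-sided Fisher test), optionally cross-checked by a Monte-Carlo
permutation null. ``category_scan`` applies the same arithmetic across a
map of functional categories with the p < 0.05 and twofold-ratio
retention rule.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected overlap of a foreground set with a category."""

    foreground_size: int
    category_size: int
    universe_size: int
    observed: int
    expected: float  # unrounded
    ratio: float  # observed / unrounded expected
    p_over: float
    p_under: float

    def as_dict(self) -> dict:
        return asdict(self)


def expected_overlap(n_a: int, n_b: int, n_universe: int) -> float:
    """Expected overlap |A||B|/N of independent random sets, unrounded."""
    if n_universe <= 0:
        raise ValueError("universe size must be positive")
    if n_a > n_universe or n_b > n_universe:
        raise ValueError("set sizes cannot exceed the universe size")
    return n_a * n_b / n_universe


def hypergeom_pvalue(
    observed: int, n_a: int, n_b: int, n_universe: int, tail: str = "over"
) -> float:
    """Hypergeometric tail probability of an overlap.

    ``over``: P(X >= observed); ``under``: P(X <= observed) for
    X ~ Hypergeometric(N=n_universe, K=n_a, n=n_b).
    """
    if observed > min(n_a, n_b) or observed < 0:
        raise ValueError(
            f"observed={observed} impossible for sets of {n_a} and {n_b}"
        )
    rv = stats.hypergeom(n_universe, n_a, n_b)
    if tail == "over":
        return float(rv.sf(observed - 1))
    if tail == "under":
        return float(rv.cdf(observed))
    raise ValueError("tail must be 'over' or 'under'")


def enrichment_test(
    foreground: set, category: set, universe: set
) -> EnrichmentResult:
    """Overlap statistics of a foreground gene set against a category."""
    universe = set(universe)
    if not set(foreground) <= universe:
        raise ValueError("foreground is not contained in the universe")
    if not set(category) <= universe:
        raise ValueError("category is not contained in the universe")
    n_f, n_c, n_u = len(foreground), len(category), len(universe)
    observed = len(set(foreground) & set(category))
    expected = expected_overlap(n_f, n_c, n_u)
    return EnrichmentResult(
        foreground_size=n_f,
        category_size=n_c,
        universe_size=n_u,
        observed=observed,
        expected=expected,
        ratio=observed / expected if expected > 0 else np.nan,
        p_over=hypergeom_pvalue(observed, n_f, n_c, n_u, "over"),
        p_under=hypergeom_pvalue(observed, n_f, n_c, n_u, "under"),
    )


def permutation_null(
    foreground_size: int,
    category: set,
    universe: set,
    observed: int,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Monte-Carlo cross-check of the hypergeometric null.

    Draws ``n_perm`` random foregrounds of the given size from the
    universe and returns the add-one-smoothed empirical
    P(overlap >= observed) plus summary statistics of the null overlaps.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    uni = np.array(sorted(universe))
    in_cat = np.isin(uni, np.array(sorted(category)))
    overlaps = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        idx = rng.choice(uni.size, size=foreground_size, replace=False)
        overlaps[i] = int(in_cat[idx].sum())
    p_emp = (1 + int((overlaps >= observed).sum())) / (n_perm + 1)
    return {
        "p_over": p_emp,
        "null_mean": float(overlaps.mean()),
        "null_sd": float(overlaps.std(ddof=1)),
        "n_perm": n_perm,
    }


def category_scan(
    foreground: set,
    categories: dict[str, set],
    universe: set,
    p_threshold: float = 0.05,
    min_ratio: float = 2.0,
) -> pd.DataFrame:
    """Over/under-representation across a map of functional categories.

    Returns one row per category with the full :class:`EnrichmentResult`
    columns plus ``retained``: True when the better tail p-value is below
    ``p_threshold`` and the ratio is at least ``min_ratio``-fold in either
    direction (ratio >= min_ratio or <= 1/min_ratio).
    """
    if not categories:
        raise ValueError("empty category map")
    rows = []
    for name, members in categories.items():
        res = enrichment_test(foreground, set(members) & set(universe), universe)
        rec = res.as_dict()
        rec["category"] = name
        rec["retained"] = (
            min(res.p_over, res.p_under) < p_threshold
            and np.isfinite(res.ratio)
            and (res.ratio >= min_ratio or res.ratio <= 1.0 / min_ratio)
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("category")
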