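"""Discriminative statistics: set frequencies, ratio-maximizing threshold
selection under boundary constraints, binomial enrichment against a random
genomic background, and holdout evaluation.

For a feature E and a promoter set S, ``E^S`` denotes the fraction of
sequences in S containing at least one occurrence of E.  The optimal
detection threshold maximizes ``E^TSP / E^NP`` subject to the boundary
conditions ``E^TSP >= min_tsp`` (default 0.75, i.e. at least 10 of 13
positives) and ``E^NP <= max_np`` (default 0.50); both bounds inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .features import FeatureDefinition, FeatureHit, feature_score
from .seqio import PromoterSet

DEFAULT_MIN_TSP = 0.75
DEFAULT_MAX_NP = 0.50


@dataclass
class DiscriminationResult:
    """Per-feature discrimination summary at one threshold."""

    feature_id: str
    threshold: float
    freq_tsp: float
    freq_np: float
    ratio: float
    feasible: bool
    freq_lowtsp: float | None = None
    freq_rp: float | None = None
    p_value: float | None = None
    counts: dict = field(default_factory=dict)


def element_frequency(pset: PromoterSet, hits: list[FeatureHit]) -> float:
    """Fraction of sequences in the set with at least one hit."""
    if len(pset) == 0:
        raise ValueError("empty promoter set")
    ids = set(pset.ids)
    hit_ids = {h.seq_id for h in hits}
    unknown = hit_ids - ids
    if unknown:
        raise ValueError(f"hits reference ids not in set: {sorted(unknown)[:3]}")
    return len(hit_ids) / len(pset)


def scores_by_sequence(feature: FeatureDefinition, pset: PromoterSet) -> list[float]:
    """Best per-sequence feature score for every record in the set."""
    return [feature_score(rec, feature) for rec in pset]


def frequency_at_threshold(scores: list[float], threshold: float) -> tuple[int, float]:
    k = sum(1 for s in scores if s >= threshold)
    return k, k / len(scores)


def _ratio(freq_tsp: float, freq_np: float, n_np: int) -> float:
    # Features entirely absent from NP are the best cases; rank them with a
    # half-count pseudofrequency instead of an undefined/infinite ratio.
    if freq_np == 0.0:
        return freq_tsp / (0.5 / n_np)
    return freq_tsp / freq_np

def default_grid(feature: FeatureDefinition, *sets: PromoterSet) -> list[float]:
    """The sorted set of observed per-sequence maximal scores.

    Frequencies only change at observed scores, so this grid makes the
    threshold sweep exact rather than step-size dependent.
    """
    observed = set()
    for pset in sets:
        observed.update(s for s in scores_by_sequence(feature, pset)
                        if s != float("-inf"))
    return sorted(observed)


def sweep_thresholds(
    feature: FeatureDefinition,
    tsp: PromoterSet,
    np_set: PromoterSet,
    grid: list[float],
    min_tsp: float = DEFAULT_MIN_TSP,
    max_np: float = DEFAULT_MAX_NP,
) -> list[DiscriminationResult]:
    """One DiscriminationResult per threshold in an ascending grid."""
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if any(grid[i] > grid[i + 1] for i in range(len(grid) - 1)):
        raise ValueError("threshold grid must be sorted ascending")
    tsp_scores = scores_by_sequence(feature, tsp)
    np_scores = scores_by_sequence(feature, np_set)
    results = []
    for t in grid:
        k_tsp, f_tsp = frequency_at_threshold(tsp_scores, t)
        k_np, f_np = frequency_at_threshold(np_scores, t)
        results.append(
            DiscriminationResult(
                feature_id=feature.feature_id,
                threshold=t,
                freq_tsp=f_tsp,
                freq_np=f_np,
                ratio=_ratio(f_tsp, f_np, len(np_set)),
                feasible=(f_tsp >= min_tsp and f_np <= max_np),
                counts={"k_tsp": k_tsp, "n_tsp": len(tsp),
                        "k_np": k_np, "n_np": len(np_set)},
            )
        )
    return results


def select_optimal(
    results: list[DiscriminationResult],
    min_tsp: float = DEFAULT_MIN_TSP,
    max_np: float = DEFAULT_MAX_NP,
) -> DiscriminationResult | None:
    """The feasible result maximizing the TSP/NP frequency ratio.

    Feasibility is recomputed from the stated bounds (both inclusive).
    Ties are broken by higher positive-set frequency, then by higher
    threshold.  Returns ``None`` when no threshold is feasible.
    """
    if not results:
        raise ValueError("no results to select from")
    feasible = [
        replace(r, feasible=True)
        for r in results
        if r.freq_tsp >= min_tsp and r.freq_np <= max_np
    ]
    if not feasible:
        return None
    return max(feasible, key=lambda r: (r.ratio, r.freq_tsp, r.threshold))


def select_most_sensitive(
    results: list[DiscriminationResult],
    max_np: float = DEFAULT_MAX_NP,
) -> DiscriminationResult | None:
    """The threshold maximizing positive-set sensitivity subject to the
    negative-set bound; ties broken by higher ratio, then higher threshold.

    Used for the module-search stage: there each member detector should be
    maximally sensitive and the combination, not the single element,
    carries the specificity.
    """
    if not results:
        raise ValueError("no results to select from")
    admissible = [r for r in results if r.freq_np <= max_np]
    if not admissible:
        return None
    return max(admissible, key=lambda r: (r.freq_tsp, r.ratio, r.threshold))


def binomial_pvalue(k: int, n: int, q: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, q).

    Computed by direct term summation over the smaller tail for accuracy.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 <= q <= 1.0):
        raise ValueError("require 0 <= q <= 1")
    if k == 0:
        return 1.0
    upper = sum(
        math.comb(n, j) * q**j * (1.0 - q) ** (n - j) for j in range(k, n + 1)
    )
    return min(1.0, upper)


def evaluate_holdout(
    feature: FeatureDefinition,
    threshold: float,
    lowtsp: PromoterSet,
) -> float:
    """Element frequency in the holdout set at a threshold frozen beforehand.

    The gap between this and the positive-set frequency estimates
    overfitting of the threshold selection.
    """
    scores = scores_by_sequence(feature, lowtsp)
    _, freq = frequency_at_threshold(scores, threshold)
    return freq


def discriminate(
    feature: FeatureDefinition,
    tsp: PromoterSet,
    np_set: PromoterSet,
    lowtsp: PromoterSet | None = None,
    rp: PromoterSet | None = None,
    min_tsp: float = DEFAULT_MIN_TSP,
    max_np: float = DEFAULT_MAX_NP,
    grid: list[float] | None = None,
) -> DiscriminationResult | None:
    """Full single-feature analysis: sweep, select, holdout, enrichment.

    The binomial enrichment p-value compares the positive-set hit count
    with the background (RP) frequency at the same selected threshold.
    Returns ``None`` if no feasible threshold exists.
    """
    if grid is None:
        grid = default_grid(feature, tsp, np_set)
    if not grid:
        return None
    results = sweep_thresholds(feature, tsp, np_set, grid, min_tsp, max_np)
    best = select_optimal(results, min_tsp, max_np)
    if best is None:
        return None
    if lowtsp is not None:
        best.freq_lowtsp = evaluate_holdout(feature, best.threshold, lowtsp)
    if rp is not None:
        rp_scores = scores_by_sequence(feature, rp)
        k_rp, best.freq_rp = frequency_at_threshold(rp_scores, best.threshold)
        best.counts.update({"k_rp": k_rp, "n_rp": len(rp)})
        best.p_value = binomial_pvalue(
            best.counts["k_tsp"], best.counts["n_tsp"], best.freq_rp
        )
    return best
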