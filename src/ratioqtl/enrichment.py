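"""Overlap of protein pairs with an interaction reference.

Fold enrichment is estimated against resampled random pairs from the same
protein universe; annotated pair classes are tested with Fisher's exact
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "InteractionReference",
    "fisher_exact_2x2",
    "fold_enrichment",
    "n_possible_pairs",
]


def n_possible_pairs(n_proteins: int) -> int:
    """Number of distinct unordered pairs among ``n_proteins`` proteins."""
    if n_proteins < 0:
        raise ValueError(f"n_proteins must be >= 0, got {n_proteins}")
    return n_proteins * (n_proteins - 1) // 2


def _norm_pair(pair) -> frozenset:
    a, b = pair
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return frozenset((a, b))


@dataclass
class InteractionReference:
    """Unordered protein pairs with interaction confidence scores in [0, 1].

    ``high_confidence`` is the set of pairs with score strictly above the
    threshold.
    """

    scores: dict[frozenset, float]
    score_min: float = 0.7

    def __post_init__(self) -> None:
        for pair, s in self.scores.items():
            if len(pair) != 2:
                raise ValueError(f"not an unordered pair: {set(pair)}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score out of [0, 1]: {s} for {set(pair)}")

    @classmethod
    def from_pairs(cls, pairs_scores, score_min: float = 0.7):
        scores: dict[frozenset, float] = {}
        for a, b, s in pairs_scores:
            scores[_norm_pair((a, b))] = float(s)
        return cls(scores=scores, score_min=score_min)

    @property
    def high_confidence(self) -> set[frozenset]:
        return {p for p, s in self.scores.items() if s > self.score_min}


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    resampled_mean: float
    resampled_sd: float
    fold: float
    n_resamples: int
    seed: int


def fold_enrichment(
    pairs,
    reference: InteractionReference,
    universe=None,
    n_resamples: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed reference links among query pairs vs. random pairs.

    Each resample draws ``len(pairs)`` distinct unordered pairs uniformly
    from the universe (default: the proteins appearing in the query pairs)
    and counts high-confidence reference links; fold = observed / mean.
    """
    query = {_norm_pair(p) for p in pairs}
    if not query:
        raise ValueError("query pair set is empty")
    if universe is None:
        universe = sorted({p for pair in query for p in pair})
    else:
        universe = sorted(set(universe))
    total = n_possible_pairs(len(universe))
    if total < len(query):
        raise ValueError(
            f"universe of {len(universe)} proteins yields only {total} pairs; "
            f"cannot draw {len(query)} distinct pairs"
        )
    links = reference.high_confidence
    observed = len(query & links)

    iu, ju = np.triu_indices(len(universe), k=1)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = rng.choice(total, size=len(query), replace=False)
        sample = {
            frozenset((universe[iu[k]], universe[ju[k]])) for k in idx
        }
        counts[r] = len(sample & links)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_resamples > 1 else math.nan
    fold = observed / mean if mean > 0 else math.nan
    return EnrichmentResult(
        observed=observed,
        resampled_mean=mean,
        resampled_sd=sd,
        fold=fold,
        n_resamples=n_resamples,
        seed=seed,
    )


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int
) -> tuple[float, float, float]:
    """Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    Returns (sample odds ratio, one-sided upper-tail p, two-sided p); the
    two-sided p sums all tables with fixed margins whose probability does
    not exceed the observed table's.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError(f"negative count in {table.tolist()}")
    if table.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        raise ValueError("both margins must be positive")
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    p_greater = float(stats.fisher_exact(table, alternative="greater")[1])
    p_two = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return odds, p_greater, p_two
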