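"""Fisher-exact gene-set enrichment with network-analysis score conventions.

For a focus set of n proteins drawn from a universe of N, and a gene set of
size K overlapping the focus set in k proteins, the right-tail Fisher exact
(hypergeometric) p-value is

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

computed stably in log space.  The enrichment score is -log10(p); two
significance conventions are applied: pathways at p <= 0.05 and networks at
score strictly > 2 (the stricter of the two thresholds in circulation; the
comparator is configurable).  One-sided enrichment only; no multiple-testing
correction by default.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GeneSetCollection:
    """Named accession sets over a declared background universe."""

    sets: dict[str, set[str]]
    universe: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    @classmethod
    def from_gmt(
        cls, sets: Mapping[str, set[str]], universe: set[str] | None = None
    ) -> "GeneSetCollection":
        return cls(sets={k: set(v) for k, v in sets.items()}, universe=set(universe or ()))

    @property
    def n_universe(self) -> int:
        return len(self.universe)


def fisher_right_tail(k: int, n: int, K: int, N: int) -> float:
    """Right-tail Fisher exact p-value for an overlap of k.

    ``k`` overlap, ``n`` focus-set size, ``K`` gene-set size, ``N`` universe
    size.  Stable log-space evaluation via the hypergeometric survival
    function; ``k = 0`` returns exactly 1.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # P(X >= k) with X ~ Hypergeom(N, K, n)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def score_gene_sets(
    focus: set[str],
    collection: GeneSetCollection,
    pathway_alpha: float = 0.05,
    network_score_threshold: float = 2.0,
    strict_network_threshold: bool = True,
) -> pd.DataFrame:
    """Score every gene set against a focus set; rank by ascending p.

    Focus proteins outside the universe are warned about and intersected
    away.  Ties in p break by descending overlap, then set name.  The
    network flag uses ``score > threshold`` when strict (default), else
    ``>=``.
    """
    if not focus:
        raise ValueError("empty focus set")
    stray = focus - collection.universe
    if stray:
        logger.warning(
            "%d focus proteins outside the universe were dropped: %s",
            len(stray),
            ", ".join(sorted(stray)[:5]) + ("..." if len(stray) > 5 else ""),
        )
    focus_in = focus & collection.universe
    if not focus_in:
        raise ValueError("no focus proteins remain inside the universe")
    N = collection.n_universe
    n = len(focus_in)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(focus_in & members)
        p = fisher_right_tail(k, n, K, N)
        score = float(-np.log10(p)) if p > 0 else float("inf")
        network_sig = (
            score > network_score_threshold
            if strict_network_threshold
            else score >= network_score_threshold
        )
        rows.append(
            {
                "set": name,
                "n_focus": n,
                "set_size": K,
                "overlap": k,
                "pvalue": p,
                "score": score,
                "pathway_significant": p <= pathway_alpha,
                "network_significant": network_sig,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["pvalue", "overlap", "set"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return out
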