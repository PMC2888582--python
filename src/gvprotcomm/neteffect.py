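"""Net-effect modeling of biological processes.

Two balances per process: (a) among differentially expressed proteins mapped
to a slim category, the number expressed higher minus the number expressed
lower in the second cell type; (b) among curated regulators, the number of
agonists minus the number of antagonists.  Proteins belonging to several
categories count in each (no fractional attribution); the process list is
data, not code.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from gvprotcomm.quantify import QuantMatrix

logger = logging.getLogger(__name__)


def expression_net_effect(
    matrix: QuantMatrix,
    slim_map: Mapping[str, set[str]],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per slim category: differential proteins up, down, and net = up - down.

    Requires :func:`gvprotcomm.quantify.anova_differential` to have populated
    ``matrix.stats``.  "Up"/"down" follow the direction convention of the
    differential calls (expression in the second cell type relative to the
    first).
    """
    if matrix.stats is None:
        raise ValueError("matrix has no differential calls; run anova_differential first")
    stats = matrix.stats
    diff = stats[stats["differential"]]
    if categories is None:
        categories = sorted({c for cats in slim_map.values() for c in cats})
    rows = []
    for cat in categories:
        members = [acc for acc in diff.index if cat in slim_map.get(acc, ())]
        n_up = int((diff.loc[members, "direction"] == "higher").sum())
        n_down = int((diff.loc[members, "direction"] == "lower").sum())
        rows.append(
            {"process": cat, "n_up": n_up, "n_down": n_down, "net": n_up - n_down}
        )
    return pd.DataFrame(rows)


def regulation_net_effect(
    assertions: pd.DataFrame,
    universe: set[str],
) -> pd.DataFrame:
    """Per process: agonists minus antagonists among the protein universe.

    ``assertions`` uses the regulation-table dialect (accession,
    process_term, direction); assertions about proteins outside the universe
    are excluded with a log message.  Contradictory duplicates raise.
    """
    required = {"accession", "process_term", "direction"}
    missing = required - set(assertions.columns)
    if missing:
        raise ValueError(f"regulation table missing columns {sorted(missing)}")
    dirs = assertions.groupby(["accession", "process_term"])["direction"].nunique()
    conflicts = dirs[dirs > 1]
    if not conflicts.empty:
        acc, proc = conflicts.index[0]
        raise ValueError(f"contradictory directions asserted for ({acc!r}, {proc!r})")
    in_universe = assertions["accession"].isin(universe)
    dropped = assertions.loc[~in_universe, "accession"].unique()
    if len(dropped):
        logger.warning(
            "excluding %d regulation assertions outside the protein universe: %s",
            int((~in_universe).sum()),
            ", ".join(sorted(dropped)[:5]) + ("..." if len(dropped) > 5 else ""),
        )
    scoped = assertions[in_universe].drop_duplicates(subset=["accession", "process_term"])
    counts = (
        scoped.groupby(["process_term", "direction"])["accession"]
        .nunique()
        .unstack("direction", fill_value=0)
        .reindex(columns=["agonist", "antagonist"], fill_value=0)
    )
    out = counts.reset_index().rename(
        columns={"process_term": "process", "agonist": "n_agonist", "antagonist": "n_antagonist"}
    )
    out["net"] = out["n_agonist"] - out["n_antagonist"]
    return out.sort_values("process").reset_index(drop=True)
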