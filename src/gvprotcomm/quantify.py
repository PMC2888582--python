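"""ProtQuant-style label-free quantification and differential expression.

The abundance proxy is the XCorr-weighted spectral count: for each retained
protein and each (cell type, replicate), the sum of Xcorr over that protein's
passing PSMs (zero when unobserved — absence of sampled spectra is evidence
of low abundance, so cells are 0, not missing).  Differential expression
between the two cell types is assessed per protein by one-way ANOVA on the
per-replicate sums at alpha <= 0.05, with the direction taken from the group
means.  No cross-replicate normalisation and no multiple-testing correction
are applied by default; total-sum scaling and Benjamini-Hochberg are opt-in
switches.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gvprotcomm.io import PsmRecord, records_to_frame


@dataclasses.dataclass
class QuantMatrix:
    """Protein x (cell type, replicate) sum-Xcorr table with per-row statistics.

    ``values`` is indexed by accession with a (sample, replicate) column
    MultiIndex; ``stats`` is populated by :func:`anova_differential`.
    """

    values: pd.DataFrame
    samples: tuple[str, ...]
    stats: pd.DataFrame | None = None
    n_untestable: int = 0

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    def group_values(self, sample: str) -> pd.DataFrame:
        return self.values[sample]


def build_quant_matrix(
    psms: pd.DataFrame | Sequence[PsmRecord],
    retained_accessions: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
    normalize: bool = False,
) -> QuantMatrix:
    """Aggregate passing target PSMs into the sum-Xcorr matrix.

    Shared-peptide PSMs contribute their Xcorr to every parent accession.
    Every retained protein gets a cell for every (sample, replicate), zero
    where unobserved.  ``normalize`` rescales each replicate column to the
    mean total sum-Xcorr (off by default).
    """
    frame = psms if isinstance(psms, pd.DataFrame) else records_to_frame(psms)
    if frame["is_decoy"].any():
        raise ValueError("quantification expects target PSMs only")
    exploded = frame.assign(accession=frame["accession"].str.split(";")).explode(
        "accession"
    )
    if retained_accessions is not None:
        exploded = exploded[exploded["accession"].isin(set(retained_accessions))]
    if samples is None:
        samples = tuple(sorted(frame["sample"].unique()))
    replicates_per_sample = {
        s: tuple(sorted(exploded.loc[exploded["sample"] == s, "replicate"].unique()))
        for s in samples
    }
    rep_sets = {reps for reps in replicates_per_sample.values() if reps}
    if len(rep_sets) > 1:
        raise ValueError(
            f"replicate labels inconsistent between cell types: {replicates_per_sample}"
        )
    replicates = sorted(rep_sets.pop()) if rep_sets else []
    sums = (
        exploded.groupby(["accession", "sample", "replicate"])["xcorr"]
        .sum()
        .unstack(["sample", "replicate"], fill_value=0.0)
    )
    columns = pd.MultiIndex.from_product(
        [list(samples), replicates], names=["sample", "replicate"]
    )
    index = (
        pd.Index(sorted(set(retained_accessions)), name="accession")
        if retained_accessions is not None
        else sums.index.sort_values()
    )
    values = sums.reindex(index=index, columns=columns, fill_value=0.0).astype(float)
    if normalize:
        totals = values.sum(axis=0)
        target = totals[totals > 0].mean()
        scale = target / totals.replace(0.0, np.nan)
        values = values.mul(scale.fillna(1.0), axis=1)
    return QuantMatrix(values=values, samples=tuple(samples))


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Explicit sums-of-squares one-way ANOVA with defined degenerate limits.

    Zero between- and within-variance (all observations identical) is defined
    as F = 0, p = 1; zero within-variance with distinct means is F = inf,
    p = 0.
    """
    n_total = sum(len(g) for g in groups)
    grand = sum(g.sum() for g in groups) / n_total
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ssw <= 0.0:
        if ssb <= 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_between) / (ssw / df_within)
    return float(f), float(stats.f.sf(f, df_between, df_within))


def anova_differential(
    matrix: QuantMatrix, alpha: float = 0.05, bh_correct: bool = False
) -> QuantMatrix:
    """Per-protein one-way ANOVA between the two cell types.

    A protein is called differential when p <= alpha (after optional BH
    correction) and the row is testable.  All-zero rows are untestable and
    tallied in ``n_untestable``.  Direction is relative to the second sample
    ("higher"/"lower" expression there), defined only for differential rows.
    """
    if len(matrix.samples) != 2:
        raise ValueError("differential testing requires exactly two cell types")
    for s in matrix.samples:
        if matrix.group_values(s).shape[1] < 2:
            raise ValueError(f"cell type {s!r} has fewer than 2 replicates")
    a_name, b_name = matrix.samples
    a = matrix.group_values(a_name).to_numpy(float)
    b = matrix.group_values(b_name).to_numpy(float)

    n = len(matrix.values)
    fstat = np.zeros(n)
    pval = np.ones(n)
    testable = ~((a == 0).all(axis=1) & (b == 0).all(axis=1))
    for i in range(n):
        if not testable[i]:
            fstat[i], pval[i] = np.nan, np.nan
            continue
        fstat[i], pval[i] = _one_way_anova([a[i], b[i]])

    p_adj = pval.copy()
    if bh_correct:
        mask = testable
        order = np.argsort(pval[mask])
        m = mask.sum()
        ranked = pval[mask][order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        p_adj[mask] = adj

    differential = testable & (p_adj <= alpha)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    direction = np.where(
        differential, np.where(mean_b > mean_a, "higher", "lower"), None
    )
    stats_frame = pd.DataFrame(
        {
            f"mean_{a_name}": mean_a,
            f"mean_{b_name}": mean_b,
            "F": fstat,
            "pvalue": pval,
            "pvalue_adj": p_adj,
            "testable": testable,
            "differential": differential,
            "direction": direction,
        },
        index=matrix.values.index,
    )
    return QuantMatrix(
        values=matrix.values,
        samples=matrix.samples,
        stats=stats_frame,
        n_untestable=int((~testable).sum()),
    )


def classify_membership(matrix: QuantMatrix) -> pd.Series:
    """Partition proteins into <sample>-only classes and "common".

    A protein belongs to a cell type iff it has at least one passing PSM
    there, i.e. a positive sum-Xcorr cell.
    """
    if len(matrix.samples) != 2:
        raise ValueError("membership partition requires exactly two cell types")
    a_name, b_name = matrix.samples
    in_a = (matrix.group_values(a_name) > 0).any(axis=1)
    in_b = (matrix.group_values(b_name) > 0).any(axis=1)
    labels = np.select(
        [in_a & in_b, in_a & ~in_b, ~in_a & in_b],
        ["common", f"{a_name}-only", f"{b_name}-only"],
        default="absent",
    )
    return pd.Series(labels, index=matrix.values.index, name="membership")


def membership_counts(membership: pd.Series, samples: tuple[str, str]) -> dict[str, int]:
    """Class counts plus per-cell-type totals; classes sum to the protein total."""
    a_name, b_name = samples
    counts = membership.value_counts().to_dict()
    only_a = counts.get(f"{a_name}-only", 0)
    only_b = counts.get(f"{b_name}-only", 0)
    common = counts.get("common", 0)
    observed = only_a + only_b + common
    return {
        f"{a_name}-only": only_a,
        f"{b_name}-only": only_b,
        "common": common,
        f"total_{a_name}": only_a + common,
        f"total_{b_name}": only_b + common,
        "total": observed,
    }
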