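"""Target-decoy confidence estimation.

Matches against the reversed database model the random-match Xcorr
distribution.  Because match quality depends on precursor charge, an empirical
null is fitted per charge state, and a target PSM's p-value is the add-one
smoothed probability that a decoy match at the same charge reaches its Xcorr:

    p = (#{decoy Xcorr_z >= x} + 1) / (N_z + 1)

Peptide evidence is collapsed to the best Xcorr per (peptide, charge) so
repeated spectra of one peptide do not multiply confidence (they still count
in quantification).  A protein is retained when at least one distinct peptide
reaches p < alpha; Fisher's method over its distinct-peptide p-values is
reported as an auxiliary ranking statistic.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gvprotcomm.io import PsmRecord, records_to_frame


@dataclasses.dataclass
class DecoyNull:
    """Per-charge empirical null: sorted decoy Xcorr values."""

    values: dict[int, np.ndarray]

    def count(self, charge: int) -> int:
        return len(self.values.get(charge, ()))

    def usable(self, charge: int) -> bool:
        return self.count(charge) > 0


@dataclasses.dataclass(frozen=True)
class PeptideEvidence:
    peptide: str
    charge: int
    best_xcorr: float
    pvalue: float
    accessions: tuple[str, ...]

    @property
    def shared(self) -> bool:
        return len(self.accessions) > 1


@dataclasses.dataclass(frozen=True)
class ProteinCall:
    accession: str
    n_significant_peptides: int
    n_peptides: int
    fisher_chi2: float
    fisher_pvalue: float
    retained: bool
    has_shared_peptides: bool


def fit_decoy_null(decoys: pd.DataFrame | Sequence[PsmRecord]) -> DecoyNull:
    """Build one sorted empirical Xcorr null per charge from decoy PSMs."""
    frame = decoys if isinstance(decoys, pd.DataFrame) else records_to_frame(decoys)
    if not frame["is_decoy"].all():
        raise ValueError("fit_decoy_null received target (non-decoy) records")
    values = {
        int(z): np.sort(group["xcorr"].to_numpy(dtype=float))
        for z, group in frame.groupby("charge")
    }
    return DecoyNull(values=values)


def empirical_pvalue(x: float, charge: int, null: DecoyNull) -> float:
    """Add-one smoothed exceedance probability under the decoy null.

    Ties count as exceedances; with no decoy above ``x`` the floor is
    1/(N+1), and a score below every decoy yields exactly 1.
    """
    if not null.usable(charge):
        raise ValueError(f"no decoy null available for charge +{charge}")
    arr = null.values[charge]
    n_ge = len(arr) - int(np.searchsorted(arr, x, side="left"))
    return (n_ge + 1) / (len(arr) + 1)


def empirical_pvalues(xs: np.ndarray, charge: int, null: DecoyNull) -> np.ndarray:
    """Vectorised :func:`empirical_pvalue` for one charge state."""
    if not null.usable(charge):
        raise ValueError(f"no decoy null available for charge +{charge}")
    arr = null.values[charge]
    n_ge = len(arr) - np.searchsorted(arr, np.asarray(xs, dtype=float), side="left")
    return (n_ge + 1) / (len(arr) + 1)


def collect_peptide_evidence(
    targets: pd.DataFrame | Sequence[PsmRecord], null: DecoyNull
) -> list[PeptideEvidence]:
    """Best-Xcorr evidence per (peptide, charge) with its empirical p-value."""
    frame = targets if isinstance(targets, pd.DataFrame) else records_to_frame(targets)
    if frame["is_decoy"].any():
        raise ValueError("collect_peptide_evidence received decoy records")
    if frame.empty:
        return []
    best = (
        frame.groupby(["peptide", "charge"])
        .agg(best_xcorr=("xcorr", "max"), accession=("accession", _union_accessions))
        .reset_index()
    )
    evidence = []
    for charge, group in best.groupby("charge"):
        pvals = empirical_pvalues(group["best_xcorr"].to_numpy(), int(charge), null)
        for (_, row), p in zip(group.iterrows(), pvals):
            evidence.append(
                PeptideEvidence(
                    peptide=row["peptide"],
                    charge=int(charge),
                    best_xcorr=float(row["best_xcorr"]),
                    pvalue=float(p),
                    accessions=tuple(sorted(row["accession"])),
                )
            )
    evidence.sort(key=lambda e: (e.peptide, e.charge))
    return evidence


def _union_accessions(column: pd.Series) -> set[str]:
    out: set[str] = set()
    for cell in column:
        out.update(str(cell).split(";"))
    return out


def call_proteins(
    peptides: Sequence[PeptideEvidence], alpha: float = 0.05
) -> list[ProteinCall]:
    """Protein retention: >=1 distinct peptide with p < alpha.

    A shared peptide confers evidence on every parent accession.  The Fisher
    combination chi^2 = -2 sum(ln p) on 2k df is computed over each protein's
    distinct-peptide p-values and reported for ranking only; retention uses
    the literal per-peptide threshold.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    per_protein: dict[str, list[PeptideEvidence]] = {}
    for ev in peptides:
        for acc in ev.accessions:
            per_protein.setdefault(acc, []).append(ev)
    calls = []
    for acc in sorted(per_protein):
        evs = per_protein[acc]
        # distinct peptides: best (smallest) p per peptide sequence
        best_p: dict[str, float] = {}
        shared = False
        for ev in evs:
            best_p[ev.peptide] = min(best_p.get(ev.peptide, 1.0), ev.pvalue)
            shared = shared or ev.shared
        pvals = np.array(sorted(best_p.values()))
        chi2 = float(-2.0 * np.log(pvals).sum())
        fisher_p = float(stats.chi2.sf(chi2, df=2 * len(pvals)))
        n_sig = int((pvals < alpha).sum())
        calls.append(
            ProteinCall(
                accession=acc,
                n_significant_peptides=n_sig,
                n_peptides=len(pvals),
                fisher_chi2=chi2,
                fisher_pvalue=fisher_p,
                retained=n_sig >= 1,
                has_shared_peptides=shared,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[ProteinCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])
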