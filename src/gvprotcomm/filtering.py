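"""Primary SEQUEST-output filter applied before any statistics.

A PSM passes when all four gates hold, in this order:

1. peptide length >= 6 residues,
2. deltaCn >= 0.1,
3. Xcorr >= its charge-state threshold (1.9 / 2.2 / 3.7 for +1 / +2 / +3),
4. Rsp < 5.

Length, deltaCn and Xcorr comparisons are inclusive; the Rsp bound is strict.
Rejections are tallied by the first failing gate; charges without a threshold
get their own bucket.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gvprotcomm.io import PsmRecord, records_to_frame, frame_to_records

DEFAULT_XCORR_THRESHOLDS = {1: 1.9, 2: 2.2, 3: 3.7}

#: rejection buckets, in gate order
REJECTION_REASONS = ("length", "deltacn", "charge", "xcorr", "rsp")


@dataclasses.dataclass(frozen=True)
class FilterPolicy:
    min_peptide_length: int = 6
    min_deltacn: float = 0.1
    xcorr_thresholds: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_XCORR_THRESHOLDS)
    )
    max_rsp: int = 5  # exclusive bound: pass requires rsp < max_rsp

    def __post_init__(self) -> None:
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be positive")
        missing = [z for z in (1, 2, 3) if z not in self.xcorr_thresholds]
        if missing:
            raise ValueError(f"xcorr_thresholds missing charges {missing}")
        if any(t <= 0 for t in self.xcorr_thresholds.values()):
            raise ValueError("xcorr thresholds must be positive")


def apply_primary_filter(
    psms: pd.DataFrame | Sequence[PsmRecord],
    policy: FilterPolicy | None = None,
):
    """Apply the primary filter; return (passing PSMs, rejection tally).

    Accepts either the PSM DataFrame dialect or a sequence of
    :class:`PsmRecord`; the passing set is returned in the same form.  The
    tally is a :class:`collections.Counter` over ``REJECTION_REASONS`` keyed
    by the first failing gate, so ``len(passing) + sum(tally.values())``
    always equals the input count.
    """
    policy = policy or FilterPolicy()
    as_records = not isinstance(psms, pd.DataFrame)
    frame = records_to_frame(psms) if as_records else psms

    length_ok = frame["peptide"].str.len() >= policy.min_peptide_length
    deltacn_ok = frame["deltacn"] >= policy.min_deltacn
    known_charge = frame["charge"].isin(list(policy.xcorr_thresholds))
    thresholds = frame["charge"].map(policy.xcorr_thresholds)
    xcorr_ok = known_charge & (frame["xcorr"] >= thresholds.fillna(np.inf))
    rsp_ok = frame["rsp"] < policy.max_rsp

    passing_mask = length_ok & deltacn_ok & xcorr_ok & rsp_ok
    reason = np.select(
        [
            ~length_ok,
            ~deltacn_ok,
            ~known_charge,
            ~xcorr_ok,
            ~rsp_ok,
        ],
        ["length", "deltacn", "charge", "xcorr", "rsp"],
        default="pass",
    )
    tally = Counter(
        {r: int((reason == r).sum()) for r in REJECTION_REASONS if (reason == r).any()}
    )
    passing = frame[passing_mask].reset_index(drop=True)
    return (frame_to_records(passing) if as_records else passing), tally
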