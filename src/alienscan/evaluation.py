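"""Scoring called events against a planted truth set.

Used by the run-all pipeline on synthetic data: every planted event must be
recovered with the right type and chromosome (recall), every call must
correspond to a planted event (precision), and recovered breakpoints are
scored by their mean absolute error in Mb against the planted coordinates
(chromosome ends, which are not real breakpoints, are excluded).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .events import (ARM_ADDITION, EventCall, INTERSTITIAL_DELETION, TELOSOME,
                     TERMINAL_DELETION, TRANSLOCATION_CANDIDATE,
                     WHOLE_CHROMOSOME_ABSENCE, WHOLE_CHROMOSOME_ADDITION)
from .formats_io import GenomeLayout

__all__ = ["match_events", "event_category"]

# planted truth type -> acceptable called types (an exactly planted arm is a
# telosome by construction, so the two arm-level labels form one category)
_TRUTH_TO_CALLED = {
    "whole_chromosome_addition": {WHOLE_CHROMOSOME_ADDITION},
    "arm_addition": {ARM_ADDITION, TELOSOME},
    "terminal_deletion": {TERMINAL_DELETION},
    "interstitial_deletion": {INTERSTITIAL_DELETION},
    "translocation": {TRANSLOCATION_CANDIDATE},
    "whole_chromosome_absence": {WHOLE_CHROMOSOME_ABSENCE},
}


def event_category(called_type: str) -> str:
    """Collapse called types onto the truth categories."""
    for truth_type, called in _TRUTH_TO_CALLED.items():
        if called_type in called:
            return truth_type
    raise ValueError(f"unknown event type {called_type!r}")


def _called_chromosome(ev: EventCall) -> str:
    if ev.donor_segment is not None:
        return ev.donor_segment.chromosome
    return ev.recipient_segment.chromosome


def match_events(called: Sequence[EventCall], truth: pd.DataFrame,
                 layout: GenomeLayout) -> dict:
    """Greedy one-to-one matching of calls to planted events.

    A call matches a planted event when sample, chromosome (donor chromosome
    for donor-side events) and category agree.  Returns recall, precision,
    breakpoint MAE in Mb (over matched events' non-terminal boundaries) and
    the raw counts.
    """
    unmatched = truth.reset_index(drop=True).copy()
    unmatched["taken"] = False
    abs_errors: list[float] = []
    n_matched = 0
    for ev in called:
        cat = event_category(ev.type)
        chrom = _called_chromosome(ev)
        cand = unmatched[(~unmatched["taken"])
                         & (unmatched["sample_id"] == ev.sample_id)
                         & (unmatched["event_type"] == cat)
                         & (unmatched["chromosome"] == chrom)]
        if cand.empty:
            continue
        row = cand.iloc[0]
        unmatched.loc[row.name, "taken"] = True
        n_matched += 1
        abs_errors.extend(_boundary_errors(ev, row, layout))
    n_truth = len(truth)
    n_called = len(called)
    return {
        "n_truth": int(n_truth),
        "n_called": int(n_called),
        "n_matched": int(n_matched),
        "recall": n_matched / n_truth if n_truth else 1.0,
        "precision": n_matched / n_called if n_called else 1.0,
        "breakpoint_mae_mb": float(np.mean(abs_errors)) if abs_errors else 0.0,
        "n_breakpoints": len(abs_errors),
    }


def _boundary_errors(ev: EventCall, row: pd.Series, layout: GenomeLayout
                     ) -> list[float]:
    """Absolute errors (Mb) of the call's defining segment boundaries against
    the planted interval, skipping chromosome ends."""
    errors: list[float] = []

    def _compare(seg, chrom: str, t_start: float, t_end: float) -> None:
        if seg is None or pd.isna(t_start):
            return
        L = layout.length_of(chrom)
        if t_start > 0:
            errors.append(abs(seg.start - t_start) / 1e6)
        if t_end < L:
            errors.append(abs(seg.end - t_end) / 1e6)

    cat = row["event_type"]
    if cat == "translocation":
        # donor gain interval is in chromosome/start/end; recipient loss apart
        _compare(ev.donor_segment, row["chromosome"], row["start"], row["end"])
        _compare(ev.recipient_segment, row["recipient_chromosome"],
                 row["recipient_start"], row["recipient_end"])
        return errors

    if row["side"] == "donor":
        seg = ev.donor_segment
    else:
        seg = ev.recipient_segment
    if seg is None:
        return errors
    if cat in ("terminal_deletion", "interstitial_deletion"):
        # truth interval is the deleted (absent) region
        _compare(seg, row["chromosome"], row["start"], row["end"])
    elif cat in ("arm_addition",):
        _compare(seg, row["chromosome"], row["start"], row["end"])
    # whole-chromosome events have only terminal boundaries: nothing to score
    return errors
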