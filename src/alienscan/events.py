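"""Segment calling and typed chromosome-event classification.

Ratio profiles are segmented into present/absent runs with an exact dynamic
program (minimal misclassified informative windows subject to a minimum run
length), breakpoints are refined to the midpoint between the outermost
flanking markers, and segments are combined into typed events: whole
chromosome additions, arm additions/telosomes, terminal and interstitial
deletions, translocation candidates (donor gain paired with a recipient loss
in the same homoeologous group), and whole-chromosome absences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import PRESENT, GenotypeMatrix, GenomeLayout, SampleSheet
from .coverage import RatioProfile, WindowGrid

__all__ = ["SegmentCall", "EventCall", "CallerParams", "segment_ratio",
           "refine_breakpoints", "classify_events", "population_summary",
           "truncate_pct"]

PRESENT_STATE = "present"
ABSENT_STATE = "absent"

# EventCall.type values
WHOLE_CHROMOSOME_ADDITION = "whole_chromosome_addition"
ARM_ADDITION = "arm_addition"
TELOSOME = "telosome"
TERMINAL_DELETION = "terminal_deletion"
INTERSTITIAL_DELETION = "interstitial_deletion"
TRANSLOCATION_CANDIDATE = "translocation_candidate"
WHOLE_CHROMOSOME_ABSENCE = "whole_chromosome_absence"


@dataclass
class SegmentCall:
    """A maximal constant-state run on one chromosome of one sample."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    state: str
    n_windows: int = 0
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end}: start must be < end")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass
class EventCall:
    """A typed chromosome rearrangement with optional donor/recipient evidence."""

    sample_id: str
    type: str
    homoeologous_group: int
    description: str
    donor_segment: Optional[SegmentCall] = None
    recipient_segment: Optional[SegmentCall] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.type == TRANSLOCATION_CANDIDATE:
            if self.donor_segment is None or self.recipient_segment is None:
                raise ValueError("translocation_candidate needs donor and recipient segments")
            if self.donor_segment.state != PRESENT_STATE:
                raise ValueError("translocation donor segment must be state=present")
            if self.recipient_segment.state != ABSENT_STATE:
                raise ValueError("translocation recipient segment must be state=absent")


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds of the segment and event caller."""

    present_threshold: float = 0.5
    min_run: int = 3
    whole_chrom_fraction: float = 0.95
    arm_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.present_threshold < 1):
            raise ValueError("present_threshold must be in (0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _optimal_labels(states: np.ndarray, min_run: int) -> np.ndarray:
    """Binary labeling minimizing (mistakes, runs) under a min-run constraint.

    ``states`` is the thresholded per-informative-window observation (True =
    present).  Every maximal constant run of the returned labeling has at
    least ``min_run`` elements; among labelings with minimal misclassified
    windows the one with fewest runs is chosen, and remaining ties are broken
    deterministically (present preferred).  Sequences shorter than
    ``min_run`` collapse to a single majority run (ties -> present).
    """
    n = len(states)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if n < min_run:
        n_present = int(states.sum())
        return np.full(n, n_present >= n - n_present)

    INF = (math.inf, math.inf)
    # state: (label, run_len capped at min_run) -> (mistakes, runs); label 1=present
    # label preference at ties: present (1) before absent (0)
    cost = {}
    back: list[dict] = [dict() for _ in range(n)]
    for label in (1, 0):
        c = (float(label != states[0]), 1.0)
        cost[(label, 1)] = c
        back[0][(label, 1)] = None
    for i in range(1, n):
        new_cost = {}
        for (label, run), c in cost.items():
            mis = float(label != states[i])
            # continue the current run
            key = (label, min(run + 1, min_run))
            cand = (c[0] + mis, c[1])
            if cand < new_cost.get(key, INF):
                new_cost[key] = cand
                back[i][key] = (label, run)
            # switch label, allowed only once the current run is long enough
            if run >= min_run:
                other = 1 - label
                mis2 = float(other != states[i])
                key2 = (other, 1)
                cand2 = (c[0] + mis2, c[1] + 1.0)
                if cand2 < new_cost.get(key2, INF):
                    new_cost[key2] = cand2
                    back[i][key2] = (label, run)
        cost = new_cost
    # final run must be complete
    finals = [(c, -k[0], k) for k, c in cost.items() if k[1] >= min_run]
    finals.sort()
    key = finals[0][2]
    labels = np.zeros(n, dtype=bool)
    for i in range(n - 1, -1, -1):
        labels[i] = bool(key[0])
        key = back[i][key]
    return labels


def _runs(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs as (first_index, last_index, label)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i - 1, bool(labels[start])))
            start = i
    return runs


def segment_ratio(r: RatioProfile, p: CallerParams = CallerParams(),
                  positions: Optional[dict[str, np.ndarray]] = None
                  ) -> list[SegmentCall]:
    """Two-state segmentation of a ratio profile.

    Informative windows are thresholded (present iff ratio >=
    ``present_threshold``) and labeled by the exact minimal-misclassification
    dynamic program with run length >= ``min_run``.  Masked windows inherit
    the surrounding segment; a masked gap between two different-state
    segments is split at its midpoint (the extra window going to the earlier
    segment).  Segment boundaries snap to window boundaries and clip to
    chromosome ends.  ``positions`` (chromosome -> sorted placed-marker
    positions of the profile's marker set) fills ``n_markers`` when given.
    """
    w = r.grid.window_size
    segments: list[SegmentCall] = []
    for chrom in r.grid.chromosomes():
        mask = r.mask[chrom]
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        states = r.ratio[chrom][idx] >= p.present_threshold
        labels = _optimal_labels(states, p.min_run)
        runs = _runs(labels)
        L = r.grid.layout.length_of(chrom)
        nw = r.grid.n_windows(chrom)
        # genomic boundaries between consecutive runs
        bounds = [0]
        for k in range(len(runs) - 1):
            i = idx[runs[k][1]]       # last informative window of run k
            j = idx[runs[k + 1][0]]   # first informative window of run k+1
            gap = j - i - 1
            bwin = i + 1 + -(-gap // 2)  # earlier segment takes ceil(gap/2)
            bounds.append(bwin * w)
        bounds.append(L)
        for k, (a, b, lab) in enumerate(runs):
            start, end = bounds[k], bounds[k + 1]
            nwin = min(-(-end // w), nw) - start // w
            nmark = 0
            if positions is not None and chrom in positions:
                pos = positions[chrom]
                nmark = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            segments.append(SegmentCall(r.bc_sample_id, chrom, int(start), int(end),
                                        PRESENT_STATE if lab else ABSENT_STATE,
                                        n_windows=int(nwin), n_markers=nmark))
    return segments


# ---------------------------------------------------------------------------
# breakpoint refinement
# ---------------------------------------------------------------------------

def _marker_arrays(placements: pd.DataFrame, G: GenotypeMatrix, sample_id: str
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """chromosome -> (sorted positions, is-present-in-sample flags)."""
    calls = G.calls[sample_id]
    out = {}
    for chrom, sub in placements.groupby("chromosome"):
        sub = sub.sort_values("position", kind="mergesort")
        pos = sub["position"].to_numpy(dtype=np.int64)
        pres = sub["marker_id"].map(calls).to_numpy() == PRESENT
        out[chrom] = (pos, pres)
    return out


def refine_breakpoints(segs: Sequence[SegmentCall], placements: pd.DataFrame,
                       G: GenotypeMatrix, sample_id: str, grid: WindowGrid
                       ) -> list[SegmentCall]:
    """Move each present/absent boundary to the midpoint between the outermost
    present-call marker on the present side and the nearest marker beyond it
    that supports absence (a non-present call, or any placed marker already
    inside the absent segment).

    The search is confined to the boundary window on each side; if either
    side has no qualifying marker, the window edge stands.  Marker counts
    and sizes are updated afterwards.
    """
    w = grid.window_size
    arrays = _marker_arrays(placements, G, sample_id)
    refined = [SegmentCall(s.sample_id, s.chromosome, s.start, s.end, s.state,
                           s.n_windows, s.n_markers) for s in segs]
    by_chrom: dict[str, list[SegmentCall]] = {}
    for s in refined:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom, chrom_segs in by_chrom.items():
        chrom_segs.sort(key=lambda s: s.start)
        if chrom not in arrays:
            continue
        pos, pres = arrays[chrom]
        for left, right in zip(chrom_segs, chrom_segs[1:]):
            if left.state == right.state:
                continue
            b = left.end
            if left.state == PRESENT_STATE:
                # outermost present-call marker in the boundary window
                in_p = (pos >= max(b - w, left.start)) & (pos < b) & pres
                if not in_p.any():
                    continue
                p_pos = int(pos[in_p].max())
                # nearest marker beyond it supporting absence: either not
                # present-called, or located inside the absent segment
                in_a = (pos > p_pos) & (pos < min(b + w, right.end)) \
                    & (~pres | (pos >= b))
                if not in_a.any():
                    continue
                a_pos = int(pos[in_a].min())
            else:
                in_p = (pos >= b) & (pos < min(b + w, right.end)) & pres
                if not in_p.any():
                    continue
                p_pos = int(pos[in_p].min())
                in_a = (pos < p_pos) & (pos >= max(b - w, left.start)) \
                    & (~pres | (pos < b))
                if not in_a.any():
                    continue
                a_pos = int(pos[in_a].max())
            new_b = (p_pos + a_pos) // 2
            new_b = max(left.start + 1, min(new_b, right.end - 1))
            left.end = new_b
            right.start = new_b
        for s in chrom_segs:
            s.n_markers = int(np.searchsorted(pos, s.end) - np.searchsorted(pos, s.start))
    return refined


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _span(segs: list[SegmentCall], state: str) -> Optional[SegmentCall]:
    sel = [s for s in segs if s.state == state]
    if not sel:
        return None
    first, last = min(sel, key=lambda s: s.start), max(sel, key=lambda s: s.end)
    return SegmentCall(sel[0].sample_id, sel[0].chromosome, first.start, last.end,
                       state, sum(s.n_windows for s in sel),
                       sum(s.n_markers for s in sel))


def _arm_letter(layout: GenomeLayout, chrom: str, start: int, end: int) -> str:
    """S or L by which arm holds the majority of the interval."""
    cen = layout.centromere_of(chrom)
    on_s = _overlap(start, end, 0, cen)
    on_l = _overlap(start, end, cen, layout.length_of(chrom))
    return "S" if on_s >= on_l else "L"


@dataclass
class _ChromShape:
    """Donor-side shape of one chromosome: derived quantities for typing."""

    chrom: str
    segs: list[SegmentCall]
    present_frac: float
    arm_frac: tuple[float, float]  # (short, long) present fraction
    present_span: Optional[SegmentCall]


def _shape(layout: GenomeLayout, chrom: str, segs: list[SegmentCall]) -> _ChromShape:
    L = layout.length_of(chrom)
    cen = layout.centromere_of(chrom)
    present = [s for s in segs if s.state == PRESENT_STATE]
    plen = sum(s.end - s.start for s in present)
    s_len = sum(_overlap(s.start, s.end, 0, cen) for s in present)
    l_len = sum(_overlap(s.start, s.end, cen, L) for s in present)
    return _ChromShape(chrom, sorted(segs, key=lambda s: s.start), plen / L,
                       (s_len / cen, l_len / (L - cen)), _span(segs, PRESENT_STATE))


def _translocation_description(layout: GenomeLayout, donor: SegmentCall,
                               recipient: SegmentCall, window_size: int) -> str:
    """Nomenclature like ``T5DS·5DL-5ML``: retained recipient arms (intact
    arm first, broken arm second), then the donor fragment's chromosome+arm."""
    rchrom = recipient.chromosome
    cen = layout.centromere_of(rchrom)
    L = layout.length_of(rchrom)
    broken = _arm_letter(layout, rchrom, recipient.start, recipient.end)
    intact = "L" if broken == "S" else "S"
    arm_lo, arm_hi = (0, cen) if broken == "S" else (cen, L)
    lost = _overlap(recipient.start, recipient.end, arm_lo, arm_hi)
    whole_arm_lost = (arm_hi - arm_lo) - lost <= window_size
    donor_arm = _arm_letter(layout, donor.chromosome, donor.start, donor.end)
    donor_id = f"{donor.chromosome}{donor_arm}"
    if whole_arm_lost:
        return f"T{rchrom}{intact}-{donor_id}"
    return f"T{rchrom}{intact}·{rchrom}{broken}-{donor_id}"


def classify_events(donor_segs: Sequence[SegmentCall],
                    recipient_segs: Sequence[SegmentCall],
                    layout: GenomeLayout,
                    p: CallerParams = CallerParams(),
                    window_size: int = 1_000_000) -> list[EventCall]:
    """Combine donor (alien-set) and recipient (wheat-set) segments into events.

    Donor chromosomes: a present fraction >= ``whole_chrom_fraction`` is a
    whole-chromosome addition; presence confined to one arm covering >=
    ``arm_fraction`` of it is an arm addition (telosome when the proximal
    segment edge sits within one window of the centromere); a chromosome
    present on both arms with internal/terminal absent segments yields
    interstitial/terminal deletions; a sub-arm terminal present fragment is a
    translocation candidate when the same sample lost recipient chromatin in
    the same homoeologous group (M donors pair only with D-sub-genome losses;
    U donors pair with any wheat genome but are flagged low-confidence).
    Unpaired recipient losses become terminal/interstitial deletions or, when
    (nearly) the whole chromosome is absent, a whole-chromosome absence.
    """
    by_sample: dict[str, tuple[list[SegmentCall], list[SegmentCall]]] = {}
    for s in donor_segs:
        by_sample.setdefault(s.sample_id, ([], []))[0].append(s)
    for s in recipient_segs:
        by_sample.setdefault(s.sample_id, ([], []))[1].append(s)

    events: list[EventCall] = []
    for sample in sorted(by_sample):
        d_segs, r_segs = by_sample[sample]
        events.extend(_classify_sample(sample, d_segs, r_segs, layout, p, window_size))
    return events


def _classify_sample(sample: str, donor_segs: list[SegmentCall],
                     recipient_segs: list[SegmentCall], layout: GenomeLayout,
                     p: CallerParams, w: int) -> list[EventCall]:
    events: list[EventCall] = []

    # recipient-side loss candidates, available for translocation pairing
    losses: list[SegmentCall] = []
    whole_absent: list[str] = []
    r_by_chrom: dict[str, list[SegmentCall]] = {}
    for s in recipient_segs:
        r_by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom, segs in r_by_chrom.items():
        L = layout.length_of(chrom)
        absent = [s for s in segs if s.state == ABSENT_STATE]
        alen = sum(s.end - s.start for s in absent)
        if alen / L >= p.whole_chrom_fraction:
            whole_absent.append(chrom)
        else:
            losses.extend(absent)
    consumed: set[int] = set()

    def _pair_loss(donor_chrom: str) -> Optional[SegmentCall]:
        group = layout.group_of(donor_chrom)
        genome = layout.genome_of(donor_chrom)
        cands = [(k, s) for k, s in enumerate(losses) if k not in consumed
                 and layout.group_of(s.chromosome) == group
                 and (genome != "M" or layout.genome_of(s.chromosome) == "D")]
        if not cands:
            return None
        k, best = max(cands, key=lambda ks: (ks[1].end - ks[1].start, ks[1].chromosome))
        consumed.add(k)
        return best

    d_by_chrom: dict[str, list[SegmentCall]] = {}
    for s in donor_segs:
        d_by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom in sorted(d_by_chrom):
        segs = d_by_chrom[chrom]
        shape = _shape(layout, chrom, segs)
        if shape.present_span is None:
            continue
        group = layout.group_of(chrom)
        genome = layout.genome_of(chrom)
        low_conf = genome == "U"
        L = layout.length_of(chrom)
        cen = layout.centromere_of(chrom)
        span = shape.present_span
        absent_segs = [s for s in shape.segs if s.state == ABSENT_STATE]
        # a segmented absent run is already >= min_run informative windows of
        # evidence, so it blocks the whole-addition call even when small
        if shape.present_frac >= p.whole_chrom_fraction and not absent_segs:
            events.append(EventCall(sample, WHOLE_CHROMOSOME_ADDITION, group,
                                    chrom, donor_segment=span))
            continue
        s_frac, l_frac = shape.arm_frac
        one_arm = ((s_frac >= p.arm_fraction and l_frac < 1 - p.arm_fraction)
                   or (l_frac >= p.arm_fraction and s_frac < 1 - p.arm_fraction))
        confined = (s_frac < 1 - p.arm_fraction) or (l_frac < 1 - p.arm_fraction)
        terminal_fragment = (span.start <= w) != (span.end >= L - w)
        if one_arm or (confined and terminal_fragment):
            loss = _pair_loss(chrom)
            arm = _arm_letter(layout, chrom, span.start, span.end)
            if loss is not None:
                desc = _translocation_description(layout, span, loss, w)
                events.append(EventCall(sample, TRANSLOCATION_CANDIDATE, group,
                                        desc, donor_segment=span,
                                        recipient_segment=loss,
                                        low_confidence=low_conf))
            elif one_arm:
                proximal = span.start if arm == "L" else span.end
                typ = TELOSOME if abs(proximal - cen) <= w else ARM_ADDITION
                events.append(EventCall(sample, typ, group, f"{chrom}{arm}",
                                        donor_segment=span))
            else:
                events.append(EventCall(sample, ARM_ADDITION, group,
                                        f"{chrom}{arm} fragment", donor_segment=span,
                                        low_confidence=True))
            continue
        # chromosome substantially present on both arms: score its absences
        for s in shape.segs:
            if s.state != ABSENT_STATE:
                continue
            touches_telomere = s.start == 0 or s.end == L
            typ = TERMINAL_DELETION if touches_telomere else INTERSTITIAL_DELETION
            arm = _arm_letter(layout, chrom, s.start, s.end)
            events.append(EventCall(sample, typ, group,
                                    f"{chrom}{arm} {typ.replace('_', ' ')} "
                                    f"{s.size_mb:.1f} Mb",
                                    donor_segment=s))

    # recipient-side leftovers
    for chrom in whole_absent:
        events.append(EventCall(sample, WHOLE_CHROMOSOME_ABSENCE,
                                layout.group_of(chrom), f"-{chrom}",
                                recipient_segment=_span(r_by_chrom[chrom], ABSENT_STATE)))
    for k, s in enumerate(losses):
        if k in consumed:
            continue
        L = layout.length_of(s.chromosome)
        touches = s.start == 0 or s.end == L
        typ = TERMINAL_DELETION if touches else INTERSTITIAL_DELETION
        arm = _arm_letter(layout, s.chromosome, s.start, s.end)
        events.append(EventCall(sample, typ, layout.group_of(s.chromosome),
                                f"{s.chromosome}{arm} {typ.replace('_', ' ')} "
                                f"{s.size_mb:.1f} Mb",
                                recipient_segment=s))
    return events


# ---------------------------------------------------------------------------
# population summary
# ---------------------------------------------------------------------------

def truncate_pct(numerator: int, denominator: int) -> float:
    """Percentage truncated (not rounded) to one decimal."""
    if denominator == 0:
        return 0.0
    return math.floor(1000.0 * numerator / denominator) / 10.0


def population_summary(events: Sequence[EventCall], S: SampleSheet,
                       layout: GenomeLayout) -> pd.DataFrame:
    """Per-population carrier counts for every donor chromosome.

    A BC line carries chromatin from donor chromosome ``c`` iff any of its
    events has a donor segment on ``c`` (additions, arm fragments,
    translocations, and deletion calls on an otherwise-present donor
    chromosome all count).  Rows ``U-any``/``M-any`` aggregate lines carrying
    any chromatin of that sub-genome.  Percentages are truncated to one
    decimal.
    """
    pops: dict[str, list[str]] = {}
    for sid in S.bc_lines:
        pop = S.population_of(sid) or "all"
        pops.setdefault(pop, []).append(sid)
    carriers: dict[str, dict[str, set]] = {}
    for ev in events:
        if ev.donor_segment is None:
            continue
        chrom = ev.donor_segment.chromosome
        carriers.setdefault(chrom, {}).setdefault("lines", set()).add(ev.sample_id)

    donor_chroms = layout.chromosomes(genomes=("U", "M"))
    rows = []
    for pop, lines in sorted(pops.items()):
        line_set = set(lines)
        for chrom in donor_chroms:
            carrier = carriers.get(chrom, {}).get("lines", set()) & line_set
            rows.append({"population": pop, "chromosome": chrom,
                         "n_lines": len(lines), "n_carriers": len(carrier),
                         "pct": truncate_pct(len(carrier), len(lines))})
        for genome in ("U", "M"):
            any_carrier = set()
            for chrom in layout.chromosomes(genomes=(genome,)):
                any_carrier |= carriers.get(chrom, {}).get("lines", set())
            any_carrier &= line_set
            rows.append({"population": pop, "chromosome": f"{genome}-any",
                         "n_lines": len(lines), "n_carriers": len(any_carrier),
                         "pct": truncate_pct(len(any_carrier), len(lines))})
    return pd.DataFrame(rows, columns=["population", "chromosome", "n_lines",
                                       "n_carriers", "pct"])
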