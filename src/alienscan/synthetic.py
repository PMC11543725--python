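"""Truth-annotated synthetic datasets for the whole pipeline.

The generator emulates the study design the pipeline targets: a hexaploid
wheat recipient (A, B, D sub-genomes), an allotetraploid wild donor carrying
U and M sub-genomes, diploid U/M progenitors, wheat/alien chromosome addition
controls, and two backcross populations whose lines carry planted
whole-chromosome additions, arm additions/telosomes, terminal and
interstitial deletions, reciprocal-loss translocations and whole-chromosome
absences.  Marker density rises toward telomeres; per-chromosome marker
counts default to the scale and ratios typical of Silico-DArT panels on
these genomes.  Everything is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .formats_io import (ABSENT, MISSING, PRESENT, GenotypeMatrix,
                         GenomeLayout, Role, SampleSheet,
                         write_chrom_sizes, write_dart_matrix, write_sample_sheet)

__all__ = ["SimConfig", "NoiseConfig", "Panel", "TruthSet", "SimulatedDataset",
           "DEFAULT_MARKER_COUNTS", "simulate_panel", "plant_population",
           "emit_alignment_hits", "simulate_dataset", "write_dataset"]

# Default marker counts per chromosome (homoeologous group -> count), on the
# scale and with the ratios typical of a wheat/Aegilops Silico-DArT panel:
# U-genome chromosomes yield the most markers, wheat sub-genomes the fewest
# (wheat-specific markers are the minority after partitioning).
DEFAULT_MARKER_COUNTS: dict[str, dict[int, int]] = {
    "U": {1: 714, 2: 1261, 3: 851, 4: 1074, 5: 1291, 6: 1175, 7: 1320},
    "M": {1: 576, 2: 766, 3: 628, 4: 556, 5: 699, 6: 436, 7: 605},
    "A": {1: 397, 2: 223, 3: 497, 4: 401, 5: 533, 6: 310, 7: 486},
    "B": {1: 300, 2: 387, 3: 467, 4: 388, 5: 398, 6: 413, 7: 447},
    "D": {1: 431, 2: 463, 3: 423, 4: 374, 5: 630, 6: 423, 7: 607},
}

MB = 1_000_000


@dataclass(frozen=True)
class NoiseConfig:
    """Independent per-call error rates.

    ``false_absent``/``false_present`` flip BC-line calls; ``missing_rate``
    turns calls of every sample into '-' (which is what drives the
    low-quality-parent exclusions of the partition stage).
    """

    false_absent: float = 0.02
    false_present: float = 0.005
    missing_rate: float = 0.01

    def __post_init__(self) -> None:
        for r in (self.false_absent, self.false_present, self.missing_rate):
            if not (0 <= r <= 1):
                raise ValueError("noise rates must lie in [0, 1]")

    @classmethod
    def clean(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study; a fixed seed fixes the bytes."""

    seed: int = 0
    scale: float = 0.1                  # fraction of wheat-like chromosome lengths
    groups: int = 7
    length_range_mb: tuple[float, float] = (300.0, 800.0)   # full-scale
    centromere_range: tuple[float, float] = (0.35, 0.5)     # fraction of length
    marker_counts: dict[str, dict[int, int]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_MARKER_COUNTS.items()})
    marker_scale: float = 1.0
    telomere_bias: float = 3.0          # distal/proximal density multiplier
    distal_fraction: float = 0.25       # of each arm, measured from the telomere
    marker_length: int = 69
    ambiguous_fraction: float = 0.05    # alien markers present in both progenitors
    both_donor_fraction: float = 0.7    # alien markers shared by both donor accessions
    n_bc: int = 40
    populations: tuple[str, str] = ("POP_A", "POP_B")
    pop_split: tuple[int, int] = (35, 44)   # relative sizes of the two populations
    n_recipient_controls: int = 4
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    # event roster sampling
    m_carrier_rate: float = 0.85
    u_carrier_rate: float = 0.15
    recipient_event_rate: float = 0.2
    donor_event_weights: dict[str, float] = field(default_factory=lambda: {
        "whole_chromosome_addition": 0.30, "arm_addition": 0.15,
        "terminal_deletion": 0.15, "interstitial_deletion": 0.15,
        "translocation": 0.25})
    recipient_event_weights: dict[str, float] = field(default_factory=lambda: {
        "terminal_deletion": 0.5, "interstitial_deletion": 0.3,
        "whole_chromosome_absence": 0.2})
    # alignment-hit emission
    decoy_rate: float = 0.2
    weak_hit_fraction: float = 0.02

    def with_noise(self, noise: NoiseConfig) -> "SimConfig":
        return replace(self, noise=noise)


@dataclass
class Panel:
    """A marker panel: genome layout plus truth class/position per marker."""

    layout: GenomeLayout
    markers: pd.DataFrame  # marker_id (index), chromosome, position, true_class,
                           # ambiguous, in_donor_a, in_donor_b
    cfg: SimConfig


@dataclass
class TruthSet:
    """Planted truth: events per BC line and the pre-noise call matrix."""

    events: pd.DataFrame   # sample_id, event_type, side, chromosome, start, end,
                           # recipient_chromosome, recipient_start, recipient_end
    clean_calls: GenotypeMatrix


@dataclass
class SimulatedDataset:
    panel: Panel
    genotypes: GenotypeMatrix
    sheet: SampleSheet
    truth: TruthSet


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def simulate_panel(cfg: SimConfig) -> Panel:
    """Genome layout and marker panel with telomere-biased marker density."""
    rng = _rng(cfg, 0)
    genomes = ("A", "B", "D", "U", "M")
    rows = []
    for genome in genomes:
        for group in range(1, cfg.groups + 1):
            lo, hi = cfg.length_range_mb
            length = int(rng.uniform(lo, hi) * MB * cfg.scale)
            cen = int(length * rng.uniform(*cfg.centromere_range))
            rows.append({"name": f"{group}{genome}", "genome": genome,
                         "length": length, "centromere": cen, "group": group})
    layout = GenomeLayout(pd.DataFrame(rows))

    mrng = _rng(cfg, 1)
    records = []
    for genome in genomes:
        true_class = {"A": "wheat_specific", "B": "wheat_specific",
                      "D": "wheat_specific", "U": "aegilops_U",
                      "M": "aegilops_M"}[genome]
        for group in range(1, cfg.groups + 1):
            chrom = f"{group}{genome}"
            n = max(1, int(round(cfg.marker_counts[genome][group] * cfg.marker_scale)))
            pos = _telomere_biased_positions(
                mrng, n, layout.length_of(chrom), layout.centromere_of(chrom),
                cfg.telomere_bias, cfg.distal_fraction, cfg.marker_length)
            for p in pos:
                records.append((chrom, int(p), true_class))
    markers = pd.DataFrame(records, columns=["chromosome", "position", "true_class"])
    markers.index = pd.Index([f"M{i:06d}" for i in range(len(markers))],
                             name="marker_id")

    alien = markers["true_class"].isin(["aegilops_U", "aegilops_M"]).to_numpy()
    amb = np.zeros(len(markers), dtype=bool)
    amb[alien] = mrng.random(alien.sum()) < cfg.ambiguous_fraction
    markers["ambiguous"] = amb
    both = mrng.random(len(markers)) < cfg.both_donor_fraction
    pick_a = mrng.random(len(markers)) < 0.5
    markers["in_donor_a"] = alien & (both | pick_a)
    markers["in_donor_b"] = alien & (both | ~pick_a)
    return Panel(layout, markers, cfg)


def _telomere_biased_positions(rng: np.random.Generator, n: int, length: int,
                               centromere: int, bias: float,
                               distal_fraction: float, marker_length: int
                               ) -> np.ndarray:
    """Positions from a piecewise-constant density, ``bias``-fold higher in
    the distal ``distal_fraction`` of each arm (telomeres at 0 and length)."""
    d_s = centromere * distal_fraction            # distal part of the short arm
    d_l = (length - centromere) * distal_fraction
    regions = np.array([
        (0, d_s, bias),
        (d_s, centromere, 1.0),
        (centromere, length - d_l, 1.0),
        (length - d_l, length, bias),
    ])
    widths = regions[:, 1] - regions[:, 0]
    weights = widths * regions[:, 2]
    weights = weights / weights.sum()
    counts = rng.multinomial(n, weights)
    pos = np.concatenate([
        rng.uniform(regions[i, 0], regions[i, 1], size=counts[i])
        for i in range(len(regions))
    ])
    pos = np.clip(pos.astype(np.int64), 0, max(0, length - marker_length))
    return np.sort(pos)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

_DONOR_EVENTS = ("whole_chromosome_addition", "arm_addition",
                 "terminal_deletion", "interstitial_deletion", "translocation")
_RECIPIENT_EVENTS = ("terminal_deletion", "interstitial_deletion",
                     "whole_chromosome_absence")
_MIN_EDGE = 4 * MB  # at default window size: >= 4 windows per planted feature


def plant_population(cfg: SimConfig, panel: Panel) -> SimulatedDataset:
    """Plant event rosters into BC lines and emit noisy genotype calls."""
    layout = panel.layout
    markers = panel.markers

    pop_a, pop_b = cfg.populations
    n_a = int(round(cfg.n_bc * cfg.pop_split[0] / sum(cfg.pop_split)))
    bc_ids = ([f"{pop_a}_{i + 1:03d}" for i in range(n_a)]
              + [f"{pop_b}_{i + 1:03d}" for i in range(cfg.n_bc - n_a)])
    bc_pops = [pop_a] * n_a + [pop_b] * (cfg.n_bc - n_a)

    sheet_rows = [("WHEAT_P", Role.RECIPIENT_PARENT.value, "", "")]
    sheet_rows += [(f"WCTRL{i + 1}", Role.RECIPIENT_CONTROL.value, "", "")
                   for i in range(cfg.n_recipient_controls)]
    sheet_rows += [("DONOR_A", Role.DONOR_PARENT.value, "", pop_a),
                   ("DONOR_B", Role.DONOR_PARENT.value, "", pop_b),
                   ("PROG_U", Role.U_PROGENITOR.value, "", ""),
                   ("PROG_M", Role.M_PROGENITOR.value, "", "")]
    for genome in ("U", "M"):
        for group in range(1, cfg.groups + 1):
            chrom = f"{group}{genome}"
            sheet_rows.append((f"ADD_{chrom}", Role.ADDITION_CONTROL.value, chrom, ""))
    sheet_rows += [(sid, Role.BC_LINE.value, "", pop)
                   for sid, pop in zip(bc_ids, bc_pops)]
    sheet = SampleSheet(pd.DataFrame(
        sheet_rows, columns=["sample_id", "role", "carried_chromosome", "population"]))

    sample_ids = [r[0] for r in sheet_rows]
    n_m, n_s = len(markers), len(sample_ids)
    col = {sid: j for j, sid in enumerate(sample_ids)}
    calls = np.full((n_m, n_s), ABSENT, dtype=np.int8)

    chrom_arr = markers["chromosome"].to_numpy()
    pos_arr = markers["position"].to_numpy()
    cls_arr = markers["true_class"].to_numpy()
    amb_arr = markers["ambiguous"].to_numpy()
    is_wheat = cls_arr == "wheat_specific"
    is_u = cls_arr == "aegilops_U"
    is_m = cls_arr == "aegilops_M"
    in_donor = {"DONOR_A": markers["in_donor_a"].to_numpy(),
                "DONOR_B": markers["in_donor_b"].to_numpy()}
    donor_of_pop = {pop_a: "DONOR_A", pop_b: "DONOR_B"}

    # parents, controls, progenitors, addition lines
    wheat_background = (["WHEAT_P"]
                        + [f"WCTRL{i + 1}" for i in range(cfg.n_recipient_controls)]
                        + [r[0] for r in sheet_rows if r[1] == Role.ADDITION_CONTROL.value])
    for sid in wheat_background:
        calls[is_wheat, col[sid]] = PRESENT
    for sid in ("DONOR_A", "DONOR_B"):
        calls[in_donor[sid], col[sid]] = PRESENT
    calls[is_u | (is_m & amb_arr), col["PROG_U"]] = PRESENT
    calls[is_m | (is_u & amb_arr), col["PROG_M"]] = PRESENT
    for genome, m_genome in (("U", is_u), ("M", is_m)):
        for group in range(1, cfg.groups + 1):
            chrom = f"{group}{genome}"
            on_chrom = m_genome & (chrom_arr == chrom)
            calls[on_chrom, col[f"ADD_{chrom}"]] = PRESENT

    # BC lines: plant events, then write calls
    erng = _rng(cfg, 2)
    truth_rows = []
    for sid, pop in zip(bc_ids, bc_pops):
        donor_sid = donor_of_pop[pop]
        roster = _sample_roster(erng, cfg, layout)
        j = col[sid]
        calls[is_wheat, j] = PRESENT  # wheat background, pre-loss
        donor_flag = in_donor[donor_sid]
        for ev in roster:
            truth_rows.append({"sample_id": sid, **ev})
            if ev["side"] == "donor":
                for s, e in ev["present_intervals"]:
                    on = (chrom_arr == ev["chromosome"]) & (pos_arr >= s) & (pos_arr < e)
                    sel = on & donor_flag & (is_u | is_m)
                    calls[sel, j] = PRESENT
                if ev["event_type"] == "translocation":
                    s, e = ev["recipient_start"], ev["recipient_end"]
                    lost = ((chrom_arr == ev["recipient_chromosome"])
                            & (pos_arr >= s) & (pos_arr < e) & is_wheat)
                    calls[lost, j] = ABSENT
            else:
                s, e = ev["start"], ev["end"]
                lost = ((chrom_arr == ev["chromosome"])
                        & (pos_arr >= s) & (pos_arr < e) & is_wheat)
                calls[lost, j] = ABSENT

    clean = pd.DataFrame(calls.copy(), index=markers.index, columns=sample_ids)
    truth_cols = ["sample_id", "event_type", "side", "chromosome", "start", "end",
                  "recipient_chromosome", "recipient_start", "recipient_end"]
    truth_events = pd.DataFrame(truth_rows).reindex(columns=truth_cols) \
        if truth_rows else pd.DataFrame(columns=truth_cols)

    # noise: flips on BC lines only, missing calls on every sample
    noisy = calls
    noise = cfg.noise
    seq = np.random.SeedSequence([int(cfg.seed), 3])
    streams = seq.spawn(n_s)
    for sid in sample_ids:
        j = col[sid]
        nrng = np.random.default_rng(streams[j])
        if sid in bc_ids and (noise.false_absent > 0 or noise.false_present > 0):
            u = nrng.random(n_m)
            pres = noisy[:, j] == PRESENT
            noisy[pres & (u < noise.false_absent), j] = ABSENT
            noisy[~pres & (u < noise.false_present), j] = PRESENT
        if noise.missing_rate > 0:
            miss = nrng.random(n_m) < noise.missing_rate
            noisy[miss, j] = MISSING

    genotypes = GenotypeMatrix(pd.DataFrame(noisy, index=markers.index,
                                            columns=sample_ids))
    return SimulatedDataset(panel, genotypes, sheet,
                            TruthSet(truth_events, GenotypeMatrix(clean)))


def _sample_roster(rng: np.random.Generator, cfg: SimConfig,
                   layout: GenomeLayout) -> list[dict]:
    """Event roster for one BC line; every event occupies its own
    homoeologous group so calls cannot cross-pair."""
    roster: list[dict] = []
    used_groups: set[int] = set()

    def free_group() -> Optional[int]:
        free = [g for g in range(1, cfg.groups + 1) if g not in used_groups]
        if not free:
            return None
        return int(rng.choice(free))

    for genome, rate in (("M", cfg.m_carrier_rate), ("U", cfg.u_carrier_rate)):
        if rng.random() >= rate:
            continue
        g = free_group()
        if g is None:
            continue
        used_groups.add(g)
        etype = _weighted_choice(rng, cfg.donor_event_weights)
        ev = _plant_donor_event(rng, layout, f"{g}{genome}", etype)
        if ev is not None:
            roster.append(ev)
    if rng.random() < cfg.recipient_event_rate:
        g = free_group()
        if g is not None:
            used_groups.add(g)
            etype = _weighted_choice(rng, cfg.recipient_event_weights)
            wheat_genome = str(rng.choice(["A", "B", "D"]))
            ev = _plant_recipient_event(rng, layout, f"{g}{wheat_genome}", etype)
            if ev is not None:
                roster.append(ev)
    return roster


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    return str(rng.choice(names, p=w / w.sum()))


def _arm_bounds(layout: GenomeLayout, chrom: str, arm: str) -> tuple[int, int]:
    cen = layout.centromere_of(chrom)
    return (0, cen) if arm == "S" else (cen, layout.length_of(chrom))


def _plant_donor_event(rng: np.random.Generator, layout: GenomeLayout,
                       chrom: str, etype: str) -> Optional[dict]:
    L = layout.length_of(chrom)
    cen = layout.centromere_of(chrom)
    base = {"side": "donor", "chromosome": chrom,
            "recipient_chromosome": "", "recipient_start": np.nan,
            "recipient_end": np.nan}
    if etype == "whole_chromosome_addition":
        return {**base, "event_type": etype, "start": 0, "end": L,
                "present_intervals": [(0, L)]}
    arm = str(rng.choice(["S", "L"]))
    a0, a1 = _arm_bounds(layout, chrom, arm)
    arm_len = a1 - a0
    if arm_len < 4 * _MIN_EDGE:
        arm = "L" if arm == "S" else "S"
        a0, a1 = _arm_bounds(layout, chrom, arm)
        arm_len = a1 - a0
        if arm_len < 4 * _MIN_EDGE:
            return {**base, "event_type": "whole_chromosome_addition",
                    "start": 0, "end": L, "present_intervals": [(0, L)]}
    if etype == "arm_addition":
        return {**base, "event_type": etype, "start": a0, "end": a1,
                "present_intervals": [(a0, a1)]}
    if etype == "terminal_deletion":
        size = int(np.clip(rng.uniform(0.15, 0.6) * arm_len,
                           _MIN_EDGE, arm_len - _MIN_EDGE))
        if arm == "S":
            dstart, dend = 0, size
            present = [(size, L)]
        else:
            dstart, dend = L - size, L
            present = [(0, L - size)]
        return {**base, "event_type": etype, "start": dstart, "end": dend,
                "present_intervals": present}
    if etype == "interstitial_deletion":
        max_size = min(12 * MB, arm_len - 2 * _MIN_EDGE)
        if max_size < 3 * MB:
            return {**base, "event_type": "whole_chromosome_addition",
                    "start": 0, "end": L, "present_intervals": [(0, L)]}
        size = int(rng.uniform(3 * MB, max_size))
        lo = max(a0, _MIN_EDGE)
        hi = min(a1 - size, L - _MIN_EDGE - size)
        if hi <= lo:
            return {**base, "event_type": "whole_chromosome_addition",
                    "start": 0, "end": L, "present_intervals": [(0, L)]}
        dstart = int(rng.uniform(lo, hi))
        return {**base, "event_type": etype, "start": dstart, "end": dstart + size,
                "present_intervals": [(0, dstart), (dstart + size, L)]}
    if etype == "translocation":
        frag = int(np.clip(rng.uniform(0.2, 0.7) * arm_len,
                           _MIN_EDGE, arm_len - _MIN_EDGE))
        dstart, dend = (0, frag) if arm == "S" else (L - frag, L)
        genome = layout.genome_of(chrom)
        rec_genome = "D" if genome == "M" else str(rng.choice(["A", "B", "D"]))
        rchrom = f"{layout.group_of(chrom)}{rec_genome}"
        rarm = str(rng.choice(["S", "L"]))
        r0, r1 = _arm_bounds(layout, rchrom, rarm)
        rlen = r1 - r0
        rsize = int(np.clip(rng.uniform(0.2, 0.7) * rlen, _MIN_EDGE, rlen - _MIN_EDGE))
        rstart, rend = (0, rsize) if rarm == "S" else \
            (layout.length_of(rchrom) - rsize, layout.length_of(rchrom))
        return {**base, "event_type": etype, "start": dstart, "end": dend,
                "present_intervals": [(dstart, dend)],
                "recipient_chromosome": rchrom,
                "recipient_start": rstart, "recipient_end": rend}
    raise ValueError(f"unknown donor event type {etype!r}")


def _plant_recipient_event(rng: np.random.Generator, layout: GenomeLayout,
                           chrom: str, etype: str) -> Optional[dict]:
    L = layout.length_of(chrom)
    base = {"side": "recipient", "chromosome": chrom,
            "recipient_chromosome": "", "recipient_start": np.nan,
            "recipient_end": np.nan}
    if etype == "whole_chromosome_absence":
        return {**base, "event_type": etype, "start": 0, "end": L}
    arm = str(rng.choice(["S", "L"]))
    a0, a1 = _arm_bounds(layout, chrom, arm)
    arm_len = a1 - a0
    if arm_len < 4 * _MIN_EDGE:
        return {**base, "event_type": "whole_chromosome_absence",
                "start": 0, "end": L}
    if etype == "terminal_deletion":
        size = int(np.clip(rng.uniform(0.15, 0.6) * arm_len,
                           _MIN_EDGE, arm_len - _MIN_EDGE))
        dstart, dend = (0, size) if arm == "S" else (L - size, L)
        return {**base, "event_type": etype, "start": dstart, "end": dend}
    # interstitial
    max_size = min(12 * MB, arm_len - 2 * _MIN_EDGE)
    if max_size < 3 * MB:
        return {**base, "event_type": "whole_chromosome_absence",
                "start": 0, "end": L}
    size = int(rng.uniform(3 * MB, max_size))
    lo = max(a0, _MIN_EDGE)
    hi = min(a1 - size, L - _MIN_EDGE - size)
    if hi <= lo:
        return None
    dstart = int(rng.uniform(lo, hi))
    return {**base, "event_type": "interstitial_deletion",
            "start": dstart, "end": dstart + size}


# ---------------------------------------------------------------------------
# alignment hits
# ---------------------------------------------------------------------------

def emit_alignment_hits(panel: Panel, cfg: SimConfig, path: str | Path,
                        lengths_path: str | Path) -> None:
    """Write a 12-column tabular alignment file plus a marker-length table.

    Each marker gets one true hit at its true position (top bitscore, half of
    them written in minus orientation), decoy hits on other chromosomes at a
    cfg-controlled rate with strictly lower bitscores, and a small fraction
    of markers get only a sub-threshold (40%-length) hit so the placement
    filter is exercised.
    """
    rng = _rng(cfg, 4)
    mlen = cfg.marker_length
    markers = panel.markers
    chroms = panel.layout.chromosomes()
    lines = []
    weak = rng.random(len(markers)) < cfg.weak_hit_fraction
    minus = rng.random(len(markers)) < 0.5
    decoy = rng.random(len(markers)) < cfg.decoy_rate
    for k, (mid, row) in enumerate(markers.iterrows()):
        chrom, pos = row["chromosome"], int(row["position"])
        if weak[k]:
            alen = int(0.4 * mlen)
            lines.append((mid, chrom, 95.0, alen, 2, 0, 1, alen,
                          pos + 1, pos + alen, 1e-4, 45.0))
            continue
        sstart, send = pos + 1, pos + mlen
        if minus[k]:
            sstart, send = send, sstart
        lines.append((mid, chrom, 100.0, mlen, 0, 0, 1, mlen,
                      sstart, send, 1e-30, 130.0))
        if decoy[k]:
            other = chroms[int(rng.integers(len(chroms)))]
            if other == chrom:
                other = chroms[(chroms.index(other) + 1) % len(chroms)]
            dpos = int(rng.integers(0, max(1, panel.layout.length_of(other) - mlen)))
            lines.append((mid, other, 90.0, mlen, 6, 1, 1, mlen,
                          dpos + 1, dpos + mlen, 1e-10,
                          float(rng.uniform(60.0, 120.0))))
    with open(path, "w") as fh:
        for line in lines:
            fh.write("\t".join(str(x) for x in line) + "\n")
    with open(lengths_path, "w") as fh:
        fh.write("marker_id\tlength\n")
        for mid in markers.index:
            fh.write(f"{mid}\t{mlen}\n")


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Panel + population in one call."""
    return plant_population(cfg, simulate_panel(cfg))


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's external formats; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.csv",
        "samples": outdir / "samples.tsv",
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "alignment": outdir / "alignment.tsv",
        "marker_lengths": outdir / "marker_lengths.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "truth_markers": outdir / "truth_markers.tsv",
    }
    write_dart_matrix(ds.genotypes, paths["genotypes"])
    write_sample_sheet(ds.sheet, paths["samples"])
    write_chrom_sizes(ds.panel.layout, paths["chrom_sizes"])
    emit_alignment_hits(ds.panel, ds.panel.cfg, paths["alignment"],
                        paths["marker_lengths"])
    ds.truth.events.to_csv(paths["truth_events"], sep="\t", index=False)
    ds.panel.markers.to_csv(paths["truth_markers"], sep="\t")
    return paths
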