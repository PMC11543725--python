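"""Windowed marker coverage and BC/parent coverage ratios.

The quantitative core of the detection method: chromosomes are tiled with
non-overlapping windows (1 Mb by default), placed markers scored present in a
sample are counted per window, counts are normalized by the panel-wide number
of markers assigned to the chromosome, and each BC line's normalized profile
is divided by its parent's.  Chromosome regions a BC line shares with the
parent haplotype then sit at ratio ~1 and regions it lost at ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import PRESENT, GenotypeMatrix, GenomeLayout, SampleSheet
from .partition import MarkerClass

__all__ = ["WindowGrid", "CoverageProfile", "RatioProfile", "make_windows",
           "count_present_markers", "ratio_profile", "density_matrix",
           "reference_sample_for", "profiles_to_frame", "ratios_to_frame"]

MARKER_SETS = (MarkerClass.WHEAT_SPECIFIC.value,
               MarkerClass.AEGILOPS_U.value,
               MarkerClass.AEGILOPS_M.value)


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping windows tiling every chromosome of a layout."""

    layout: GenomeLayout
    window_size: int

    def n_windows(self, chrom: str) -> int:
        L = self.layout.length_of(chrom)
        return -(-L // self.window_size)  # ceil division

    def bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays; the last window may be shorter."""
        L = self.layout.length_of(chrom)
        starts = np.arange(self.n_windows(chrom), dtype=np.int64) * self.window_size
        ends = np.minimum(starts + self.window_size, L)
        return starts, ends

    def window_of(self, position: int) -> int:
        return int(position) // self.window_size

    def chromosomes(self) -> list[str]:
        return self.layout.chromosomes()

    def keys(self, chrom: str) -> list[str]:
        starts, ends = self.bounds(chrom)
        return [f"{chrom}:{s}-{e}" for s, e in zip(starts, ends)]


def make_windows(layout: GenomeLayout, window_size: int = 1_000_000) -> WindowGrid:
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    return WindowGrid(layout, int(window_size))


@dataclass
class CoverageProfile:
    """Per-window marker counts of one sample for one marker set.

    ``normalized[c][k] = raw[c][k] / n_assigned[c]`` where ``n_assigned`` is
    the panel-wide number of markers placed on chromosome ``c`` (not the
    per-sample present count); chromosomes with no assigned markers are
    flagged uninformative.
    """

    sample_id: str
    marker_set: str
    grid: WindowGrid
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    n_assigned: dict[str, int]
    uninformative: set[str] = field(default_factory=set)


@dataclass
class RatioProfile:
    """Windowed BC/reference normalized-coverage ratio with informative mask."""

    bc_sample_id: str
    reference_sample_id: str
    marker_set: str
    grid: WindowGrid
    ratio: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]  # True where the reference has >= 1 marker


def count_present_markers(G: GenotypeMatrix, classes: pd.DataFrame,
                          placements: pd.DataFrame, grid: WindowGrid,
                          sample_id: str, marker_set: str) -> CoverageProfile:
    """Count placed markers of one set scored present in ``sample_id`` per window.

    A marker contributes to window ``k`` of its chromosome iff its position
    lies in ``[k*w, (k+1)*w)`` and its call is present; missing calls
    contribute nothing.
    """
    if marker_set not in MARKER_SETS:
        raise ValueError(f"unknown marker set {marker_set!r}")
    if sample_id not in G.calls.columns:
        raise KeyError(f"unknown sample {sample_id!r}")

    in_set = classes.index[classes["marker_class"] == marker_set]
    placed = placements[placements["marker_id"].isin(in_set)]
    row_idx = G.calls.index.get_indexer(placed["marker_id"])
    if (row_idx < 0).any():
        bad = placed["marker_id"].to_numpy()[row_idx < 0][0]
        raise KeyError(f"placed marker {bad!r} absent from the genotype matrix")
    present = G.calls[sample_id].to_numpy()[row_idx] == PRESENT
    chrom_arr = placed["chromosome"].to_numpy()
    pos_arr = placed["position"].to_numpy()

    raw: dict[str, np.ndarray] = {}
    normalized: dict[str, np.ndarray] = {}
    n_assigned: dict[str, int] = {}
    uninformative: set[str] = set()
    for chrom in grid.chromosomes():
        nw = grid.n_windows(chrom)
        on_chrom = chrom_arr == chrom
        n_assigned[chrom] = int(on_chrom.sum())
        if n_assigned[chrom] == 0:
            raw[chrom] = np.zeros(nw, dtype=np.int64)
            normalized[chrom] = np.zeros(nw, dtype=float)
            uninformative.add(chrom)
            continue
        win = pos_arr[on_chrom & present] // grid.window_size
        raw[chrom] = np.bincount(win, minlength=nw).astype(np.int64)
        normalized[chrom] = raw[chrom] / n_assigned[chrom]
    return CoverageProfile(sample_id, marker_set, grid, raw, normalized,
                           n_assigned, uninformative)


def ratio_profile(bc: CoverageProfile, ref: CoverageProfile) -> RatioProfile:
    """Windowed ratio of a BC profile to its reference parent profile.

    Windows where the reference has zero markers are masked (the ratio is
    undefined there), not treated as ratio 0 — this prevents false deletion
    calls in marker deserts such as pericentromeres.
    """
    if bc.grid is not ref.grid and (
            bc.grid.window_size != ref.grid.window_size
            or bc.grid.layout.table.shape != ref.grid.layout.table.shape):
        raise ValueError("BC and reference profiles use different window grids")
    if bc.marker_set != ref.marker_set:
        raise ValueError("BC and reference profiles use different marker sets")
    ratio: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for chrom in bc.grid.chromosomes():
        informative = ref.raw[chrom] > 0
        r = np.zeros_like(ref.normalized[chrom])
        np.divide(bc.normalized[chrom], ref.normalized[chrom], out=r, where=informative)
        r[~informative] = np.nan
        ratio[chrom] = r
        mask[chrom] = informative
    return RatioProfile(bc.sample_id, ref.sample_id, bc.marker_set, bc.grid, ratio, mask)


def density_matrix(profiles: list[CoverageProfile]) -> pd.DataFrame:
    """Markers-per-Mb matrix, windows (rows, ``chrom:start-end``) x samples."""
    if not profiles:
        return pd.DataFrame()
    grid = profiles[0].grid
    index, scale = [], []
    for chrom in grid.chromosomes():
        starts, ends = grid.bounds(chrom)
        index.extend(f"{chrom}:{s}-{e}" for s, e in zip(starts, ends))
        scale.append((ends - starts) / 1e6)
    mb = np.concatenate(scale)
    data = {}
    for prof in profiles:
        col = np.concatenate([prof.raw[c] for c in grid.chromosomes()])
        data[prof.sample_id] = col / mb
    return pd.DataFrame(data, index=pd.Index(index, name="window"))


def reference_sample_for(S: SampleSheet, bc_sample_id: str, marker_set: str) -> str:
    """The parent a BC line is compared against for a given marker set.

    Wheat-specific coverage is referenced against the recipient parent;
    alien-specific coverage against the donor parent of the BC line's own
    population (each donor accession carries its own haplotype).
    """
    if marker_set == MarkerClass.WHEAT_SPECIFIC.value:
        return S.recipient_parent
    pop = S.population_of(bc_sample_id)
    if pop is None:
        donors = S.donor_parents
        if len(donors) == 1:
            return donors[0]
        raise ValueError(
            f"BC line {bc_sample_id!r} has no population; cannot choose among "
            f"{len(donors)} donor parents")
    return S.donor_for_population(pop)


def profiles_to_frame(profiles: list[CoverageProfile], which: str = "raw") -> pd.DataFrame:
    """Raw or normalized coverage as a windows x samples DataFrame."""
    if not profiles:
        return pd.DataFrame()
    grid = profiles[0].grid
    index = [k for c in grid.chromosomes() for k in grid.keys(c)]
    data = {p.sample_id: np.concatenate([getattr(p, which)[c] for c in grid.chromosomes()])
            for p in profiles}
    return pd.DataFrame(data, index=pd.Index(index, name="window"))


def ratios_to_frame(ratios: list[RatioProfile]) -> pd.DataFrame:
    """Ratio profiles as a windows x BC-samples DataFrame (NaN where masked)."""
    if not ratios:
        return pd.DataFrame()
    grid = ratios[0].grid
    index = [k for c in grid.chromosomes() for k in grid.keys(c)]
    data = {r.bc_sample_id: np.concatenate([r.ratio[c] for c in grid.chromosomes()])
            for r in ratios}
    return pd.DataFrame(data, index=pd.Index(index, name="window"))
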