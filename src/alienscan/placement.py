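"""Chromosome placement of markers from tabular alignment best hits.

Marker sequences are aligned upstream (e.g. BLASTn against a reference
assembly); this module parses the standard 12-column tabular output,
normalizes coordinates to 0-based half-open with ``s_start < s_end``, applies
the best-hit filter (maximum E-value, minimum aligned fraction of the marker
sequence), picks one deterministic best hit per marker, orders markers along
chromosomes, and cross-checks placements against wheat/alien chromosome
addition-line genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .formats_io import (PRESENT, FormatError, GenotypeMatrix, GenomeLayout,
                         SampleSheet, chromosome_genome, chromosome_group)
from .partition import MarkerClass

__all__ = [
    "PlacementFilter", "read_alignment_tab", "read_marker_lengths",
    "select_best_hit", "place_markers", "order_markers",
    "annotate_class_consistency", "validate_with_additions",
    "write_placements_tsv", "read_placements_tsv",
]

_OUTFMT6_COLS = ["marker_id", "subject", "pident", "align_length", "mismatch",
                 "gapopen", "q_start", "q_end", "s_start_raw", "s_end_raw",
                 "evalue", "bitscore"]


@dataclass(frozen=True)
class PlacementFilter:
    """Hit-level exclusion rule applied before best-hit selection.

    A hit survives iff ``evalue <= max_evalue`` and
    ``align_length / marker_length >= min_aligned_fraction``.
    """

    max_evalue: float = 1e-6
    min_aligned_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_aligned_fraction <= 1):
            raise ValueError("min_aligned_fraction must be in (0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")


def read_alignment_tab(path: str | Path) -> pd.DataFrame:
    """Parse 12-column tabular alignment output (BLAST outfmt 6).

    Subject coordinates are converted from 1-based inclusive to 0-based
    half-open; minus-orientation hits (s_start > s_end) are normalized so
    ``s_start < s_end``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=_OUTFMT6_COLS)
    for col, typ in (("align_length", np.int64), ("s_start_raw", np.int64),
                     ("s_end_raw", np.int64), ("evalue", float), ("bitscore", float)):
        df[col] = df[col].astype(typ)
    lo = np.minimum(df["s_start_raw"], df["s_end_raw"])
    hi = np.maximum(df["s_start_raw"], df["s_end_raw"])
    df["s_start"] = lo - 1  # 1-based inclusive -> 0-based half-open
    df["s_end"] = hi
    if (df["align_length"] < 1).any():
        raise FormatError(f"{path}: alignment lengths must be >= 1")
    if (df["evalue"] < 0).any():
        raise FormatError(f"{path}: E-values must be >= 0")
    return df[["marker_id", "subject", "s_start", "s_end", "align_length", "evalue", "bitscore"]]


def read_marker_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker_id": str})
    if not {"marker_id", "length"} <= set(df.columns):
        raise FormatError(f"{path}: marker length table needs columns marker_id, length")
    return df.set_index("marker_id")["length"].astype(np.int64)


def _filter_hits(hits: pd.DataFrame, lengths: pd.Series, f: PlacementFilter) -> pd.DataFrame:
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"marker {bad!r} has non-positive length")
    mlen = hits["marker_id"].map(lengths)
    if mlen.isna().any():
        bad = hits.loc[mlen.isna(), "marker_id"].iloc[0]
        raise ValueError(f"no length known for marker {bad!r}")
    keep = (hits["evalue"] <= f.max_evalue) & \
           (hits["align_length"] / mlen >= f.min_aligned_fraction)
    return hits[keep]


def select_best_hit(hits: pd.DataFrame, marker_length: int,
                    f: PlacementFilter = PlacementFilter()) -> Optional[dict]:
    """Deterministic best hit for the hits of a single marker.

    Survivors of the filter are ranked by max bitscore, then min E-value,
    then lexicographically smallest subject chromosome, then smallest start.
    Returns ``{"marker_id", "chromosome", "position"}`` or None.
    """
    if marker_length <= 0:
        raise ValueError("marker_length must be > 0")
    if hits.empty:
        return None
    ids = hits["marker_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"hits belong to several markers: {sorted(ids)}")
    lengths = pd.Series({ids[0]: marker_length})
    placed = place_markers(hits, lengths, f)
    if placed.empty:
        return None
    row = placed.iloc[0]
    return {"marker_id": row["marker_id"], "chromosome": row["chromosome"],
            "position": int(row["position"])}


def place_markers(hits: pd.DataFrame, lengths: pd.Series,
                  f: PlacementFilter = PlacementFilter()) -> pd.DataFrame:
    """One placement per marker from its filtered best hit (vectorized).

    Position is the orientation-normalized hit start (lower coordinate).
    Markers with no surviving hit are absent from the result.
    """
    surv = _filter_hits(hits, lengths, f)
    if surv.empty:
        return pd.DataFrame(columns=["marker_id", "chromosome", "position"])
    ranked = surv.sort_values(
        ["marker_id", "bitscore", "evalue", "subject", "s_start"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
    )
    best = ranked.groupby("marker_id", sort=True).head(1)
    out = best[["marker_id", "subject", "s_start"]].rename(
        columns={"subject": "chromosome", "s_start": "position"})
    return out.reset_index(drop=True)


def order_markers(placements: pd.DataFrame) -> pd.DataFrame:
    """Fill the per-chromosome rank: 0..n-1 by position, ties by marker id."""
    df = placements.sort_values(["chromosome", "position", "marker_id"],
                                kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("chromosome").cumcount()
    return df


def annotate_class_consistency(placements: pd.DataFrame, classes: pd.DataFrame,
                               layout: GenomeLayout) -> pd.DataFrame:
    """Flag placements whose chromosome genome disagrees with the marker class.

    Disagreements are retained with ``class_consistent=False`` rather than
    dropped: when an alien marker set is placed against a syntenic proxy
    reference, cross-genome best hits are expected noise, and dropping them
    silently would bias windowed coverage.
    """
    expected = {MarkerClass.WHEAT_SPECIFIC.value: set("ABD"),
                MarkerClass.AEGILOPS_U.value: {"U"},
                MarkerClass.AEGILOPS_M.value: {"M", "D"}}
    df = placements.copy()
    cls = df["marker_id"].map(classes["marker_class"])
    genome = df["chromosome"].map(
        {c: layout.genome_of(c) for c in layout.chromosomes()})
    df["class_consistent"] = [
        (g in expected.get(k, set())) if isinstance(g, str) else False
        for k, g in zip(cls, genome)
    ]
    return df


def validate_with_additions(classes: pd.DataFrame, placements: pd.DataFrame,
                            G: GenotypeMatrix, S: SampleSheet) -> tuple[pd.Series, pd.DataFrame]:
    """Cross-check alien-marker placements against addition-line genotypes.

    An addition line carries one alien chromosome in the wheat background, so
    an alien marker placed on chromosome ``c`` should be present exactly in
    the addition line carrying ``c``'s homoeologous counterpart (same group,
    genome matching the marker class).  Flags per marker:

    - ``validated``: present only in the expected addition line;
    - ``contradicted``: present only in a single different addition line;
    - ``ambiguous``: present in two or more addition lines;
    - ``untestable``: no informative control exists, or the marker is present
      in no addition line (no positive evidence either way).

    Returns (per-marker flag Series, chromosome x flag confusion table).
    """
    additions = S.addition_controls
    alien = classes["marker_class"].isin(
        [MarkerClass.AEGILOPS_U.value, MarkerClass.AEGILOPS_M.value])
    placed = placements[placements["marker_id"].isin(classes.index[alien])]

    genome_of_class = {MarkerClass.AEGILOPS_U.value: "U", MarkerClass.AEGILOPS_M.value: "M"}
    add_ids = list(additions)
    add_key = {sid: (chromosome_group(additions[sid]), chromosome_genome(additions[sid]))
               for sid in add_ids}

    flags = {}
    for _, row in placed.iterrows():
        mid = row["marker_id"]
        chrom = row["chromosome"]
        marker_genome = genome_of_class[classes.at[mid, "marker_class"]]
        expected_key = (chromosome_group(chrom), marker_genome)
        informative = [sid for sid in add_ids if add_key[sid] == expected_key]
        present_in = [sid for sid in add_ids
                      if G.calls.at[mid, sid] == PRESENT] if add_ids else []
        if not informative or not present_in:
            flags[mid] = "untestable"
        elif len(present_in) >= 2:
            flags[mid] = "ambiguous"
        elif present_in[0] in informative:
            flags[mid] = "validated"
        else:
            flags[mid] = "contradicted"
    flag_series = pd.Series(flags, name="validation", dtype=object)
    flag_series.index.name = "marker_id"

    chrom_of = placed.set_index("marker_id")["chromosome"]
    confusion = pd.crosstab(flag_series.index.map(chrom_of), flag_series) \
        if len(flag_series) else pd.DataFrame()
    return flag_series, confusion


def write_placements_tsv(placements: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        placements.to_csv(fh, sep="\t", index=False)


def read_placements_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker_id": str, "chromosome": str})
    df["position"] = df["position"].astype(np.int64)
    return df
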