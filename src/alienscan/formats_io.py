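"""Readers and writers for the tabular formats the pipeline touches.

All genomic intervals are 0-based half-open internally.  Tabular alignment
input (1-based inclusive, BLAST outfmt 6) is converted at the read boundary;
BED output stays 0-based half-open.  Dominant marker calls use three states:
present (``1``), absent (``0``) and missing/low-quality (``-``).  Readers are
strict: malformed input is rejected with a coordinate, never silently
repaired.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PRESENT", "ABSENT", "MISSING", "FormatError", "Role",
    "SampleSheet", "GenotypeMatrix", "GenomeLayout",
    "read_dart_matrix", "write_dart_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_chrom_sizes", "write_chrom_sizes",
    "write_segments_bed", "write_events_tsv",
    "load_config", "config_hash", "chromosome_group", "chromosome_genome",
]

# Integer codes for dominant marker calls.
PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1

_TOKEN_TO_CALL = {"1": PRESENT, "0": ABSENT, "-": MISSING}
_CALL_TO_TOKEN = {PRESENT: "1", ABSENT: "0", MISSING: "-"}

WHEAT_GENOMES = ("A", "B", "D")
ALIEN_GENOMES = ("U", "M")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class Role(str, Enum):
    RECIPIENT_PARENT = "recipient_parent"
    DONOR_PARENT = "donor_parent"
    U_PROGENITOR = "u_progenitor"
    M_PROGENITOR = "m_progenitor"
    RECIPIENT_CONTROL = "recipient_control"
    ADDITION_CONTROL = "addition_control"
    BC_LINE = "bc_line"


def chromosome_group(name: str) -> int:
    """Homoeologous group parsed from a chromosome name like ``5M`` or ``3D``."""
    digits = "".join(c for c in name if c.isdigit())
    if not digits:
        raise FormatError(f"cannot parse homoeologous group from chromosome name {name!r}")
    return int(digits)


def chromosome_genome(name: str) -> str:
    """(Sub-)genome letter parsed from a chromosome name like ``5M``."""
    letters = "".join(c for c in name if c.isalpha())
    if not letters:
        raise FormatError(f"cannot parse genome from chromosome name {name!r}")
    return letters[0]


@dataclass
class SampleSheet:
    """Assignment of pipeline roles to genotyped samples.

    Columns: ``sample_id``, ``role``, ``carried_chromosome`` (addition
    controls only, e.g. ``3U``), ``population`` (BC lines and the donor
    parent that founded the population).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "role", "carried_chromosome", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in sample sheet")
        bad = set(t["role"]) - {r.value for r in Role}
        if bad:
            raise FormatError(f"unknown sample roles: {sorted(bad)}")
        n_recipient = (t["role"] == Role.RECIPIENT_PARENT.value).sum()
        if n_recipient != 1:
            raise FormatError(f"expected exactly one recipient_parent, found {n_recipient}")
        if (t["role"] == Role.DONOR_PARENT.value).sum() < 1:
            raise FormatError("sample sheet needs at least one donor_parent")
        for role in (Role.U_PROGENITOR, Role.M_PROGENITOR):
            if (t["role"] == role.value).sum() > 1:
                raise FormatError(f"at most one {role.value} allowed")
        add = t[t["role"] == Role.ADDITION_CONTROL.value]
        empty = add["carried_chromosome"].isna() | (add["carried_chromosome"] == "")
        if empty.any():
            sid = add.loc[empty, "sample_id"].iloc[0]
            raise FormatError(f"addition_control {sid!r} has no carried_chromosome")

    # -- role accessors -------------------------------------------------
    def _ids(self, role: Role) -> list[str]:
        return self.table.loc[self.table["role"] == role.value, "sample_id"].tolist()

    @property
    def recipient_parent(self) -> str:
        return self._ids(Role.RECIPIENT_PARENT)[0]

    @property
    def donor_parents(self) -> list[str]:
        return self._ids(Role.DONOR_PARENT)

    @property
    def u_progenitor(self) -> Optional[str]:
        ids = self._ids(Role.U_PROGENITOR)
        return ids[0] if ids else None

    @property
    def m_progenitor(self) -> Optional[str]:
        ids = self._ids(Role.M_PROGENITOR)
        return ids[0] if ids else None

    @property
    def recipient_controls(self) -> list[str]:
        return self._ids(Role.RECIPIENT_CONTROL)

    @property
    def bc_lines(self) -> list[str]:
        return self._ids(Role.BC_LINE)

    @property
    def addition_controls(self) -> dict[str, str]:
        """sample_id -> carried chromosome (e.g. ``3U``)."""
        add = self.table[self.table["role"] == Role.ADDITION_CONTROL.value]
        return dict(zip(add["sample_id"], add["carried_chromosome"]))

    def population_of(self, sample_id: str) -> Optional[str]:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        pop = row["population"].iloc[0]
        return None if (pd.isna(pop) or pop == "") else pop

    def donor_for_population(self, population: str) -> str:
        """The donor parent that founded a BC population."""
        t = self.table
        hit = t[(t["role"] == Role.DONOR_PARENT.value) & (t["population"] == population)]
        if hit.empty:
            raise KeyError(f"no donor_parent assigned to population {population!r}")
        return hit["sample_id"].iloc[0]


@dataclass
class GenotypeMatrix:
    """Dominant marker calls, markers x samples, int8-coded 1/0/-1."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.duplicated().any():
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise FormatError(f"duplicate marker id {dup!r}")
        if self.calls.columns.duplicated().any():
            dup = self.calls.columns[self.calls.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.calls.to_numpy()
        ok = np.isin(vals, (PRESENT, ABSENT, MISSING))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise FormatError(
                f"invalid call {vals[i, j]!r} at marker {self.calls.index[i]!r}, "
                f"sample {self.calls.columns[j]!r}"
            )

    @property
    def marker_ids(self) -> list[str]:
        return self.calls.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.calls.columns.tolist()

    def column(self, sample_id: str) -> np.ndarray:
        if sample_id not in self.calls.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.calls[sample_id].to_numpy()


@dataclass
class GenomeLayout:
    """Chromosome names, genomes, lengths, centromeres and homoeologous groups."""

    table: pd.DataFrame  # columns: name, genome, length, centromere, group

    def __post_init__(self) -> None:
        t = self.table
        required = {"name", "genome", "length", "centromere", "group"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"genome layout missing columns: {sorted(missing)}")
        if t["name"].duplicated().any():
            dup = t.loc[t["name"].duplicated(), "name"].iloc[0]
            raise FormatError(f"duplicate chromosome name {dup!r}")
        if (t["length"] <= 0).any():
            raise FormatError("chromosome lengths must be > 0")
        bad = ~((t["centromere"] > 0) & (t["centromere"] < t["length"]))
        if bad.any():
            name = t.loc[bad, "name"].iloc[0]
            raise FormatError(f"centromere of {name!r} must lie strictly inside (0, length)")
        bad_genome = set(t["genome"]) - set(WHEAT_GENOMES + ALIEN_GENOMES)
        if bad_genome:
            raise FormatError(f"unknown genomes: {sorted(bad_genome)}")
        self._by_name = t.set_index("name")

    def chromosomes(self, genomes: Optional[Iterable[str]] = None) -> list[str]:
        t = self.table
        if genomes is not None:
            t = t[t["genome"].isin(list(genomes))]
        return t["name"].tolist()

    def length_of(self, name: str) -> int:
        return int(self._by_name.at[name, "length"])

    def centromere_of(self, name: str) -> int:
        return int(self._by_name.at[name, "centromere"])

    def group_of(self, name: str) -> int:
        return int(self._by_name.at[name, "group"])

    def genome_of(self, name: str) -> str:
        return str(self._by_name.at[name, "genome"])

    def __contains__(self, name: str) -> bool:
        return name in self._by_name.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dart_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a DArT-style score CSV (first column marker id, header sample ids).

    Cells must be one of ``1``, ``0``, ``-``; anything else (including empty
    cells) is rejected with its coordinates.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a marker-id column plus >=1 sample column")
    marker_col = df.columns[0]
    markers = df[marker_col]
    if markers.duplicated().any():
        dup = markers[markers.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate marker id {dup!r}")
    body = df.set_index(marker_col)
    coded = np.empty(body.shape, dtype=np.int8)
    vals = body.to_numpy()
    for token, code in _TOKEN_TO_CALL.items():
        coded[vals == token] = code
    known = np.isin(vals, list(_TOKEN_TO_CALL))
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise FormatError(
            f"{path}: invalid call {vals[i, j]!r} at marker {body.index[i]!r}, "
            f"sample {body.columns[j]!r} (expected 1, 0 or -)"
        )
    calls = pd.DataFrame(coded, index=body.index.astype(str), columns=body.columns.astype(str))
    calls.index.name = "marker_id"
    return GenotypeMatrix(calls)


def write_dart_matrix(G: GenotypeMatrix, path: str | Path) -> None:
    out = G.calls.replace(_CALL_TO_TOKEN).astype(str)
    out.index.name = "marker_id"
    out.to_csv(path)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in ("carried_chromosome", "population"):
        if col not in df.columns:
            df[col] = ""
    return SampleSheet(df)


def write_sample_sheet(S: SampleSheet, path: str | Path) -> None:
    S.table.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read the chromosome sizes TSV (name, genome, length, centromere, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    try:
        for col in ("length", "centromere", "group"):
            df[col] = df[col].astype(np.int64)
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad chromosome sizes table: {exc}") from exc
    return GenomeLayout(df)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    layout.table.to_csv(path, sep="\t", index=False)


_CHROM_SORT_KEY = lambda c: (chromosome_genome(c), chromosome_group(c), c)  # noqa: E731


def write_segments_bed(calls: Sequence, path: str | Path, header: str | None = None) -> None:
    """Write segment or event calls as BED6 (0-based half-open).

    The name field is ``sample|state|size_Mb`` with the size to one decimal.
    Rows are sorted by chromosome then start.  Events contribute their donor
    and recipient segments, if any.
    """
    rows = []
    for call in calls:
        segs = []
        if hasattr(call, "donor_segment") or hasattr(call, "recipient_segment"):
            for seg in (getattr(call, "donor_segment", None), getattr(call, "recipient_segment", None)):
                if seg is not None:
                    segs.append(seg)
        else:
            segs.append(call)
        for seg in segs:
            if seg.start >= seg.end:
                raise FormatError(
                    f"segment {seg.chromosome}:{seg.start}-{seg.end}: start must be < end"
                )
            size_mb = (seg.end - seg.start) / 1e6
            rows.append((seg.chromosome, int(seg.start), int(seg.end),
                         f"{seg.sample_id}|{seg.state}|{size_mb:.1f}", 0, "."))
    rows.sort(key=lambda r: (_CHROM_SORT_KEY(r[0]), r[1]))
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname(sample|state|size_Mb)\tscore\tstrand\n")
        if header:
            fh.write(f"# {header}\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_events_tsv(events: Sequence, path: str | Path, header: str | None = None) -> None:
    """Write typed event calls as a TSV report."""
    cols = ["sample_id", "type", "homoeologous_group", "description", "low_confidence",
            "donor_chrom", "donor_start", "donor_end", "donor_size_mb",
            "recipient_chrom", "recipient_start", "recipient_end", "recipient_size_mb"]
    rows = []
    for ev in events:
        row = {
            "sample_id": ev.sample_id,
            "type": ev.type,
            "homoeologous_group": ev.homoeologous_group,
            "description": ev.description,
            "low_confidence": ev.low_confidence,
        }
        for side, seg in (("donor", ev.donor_segment), ("recipient", ev.recipient_segment)):
            if seg is not None:
                row[f"{side}_chrom"] = seg.chromosome
                row[f"{side}_start"] = int(seg.start)
                row[f"{side}_end"] = int(seg.end)
                row[f"{side}_size_mb"] = round(seg.size_mb, 1)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of a resolved configuration, for output provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
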