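import numpy as np
import pandas as pd
import pytest

from alienscan.formats_io import (ABSENT, MISSING, PRESENT, GenomeLayout,
                                  GenotypeMatrix, Role, SampleSheet)

MB = 1_000_000


def make_layout(rows):
    """rows: (name, genome, length, centromere, group)."""
    return GenomeLayout(pd.DataFrame(
        rows, columns=["name", "genome", "length", "centromere", "group"]))


def make_sheet(rows):
    """rows: (sample_id, role, carried_chromosome, population)."""
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "role", "carried_chromosome", "population"]))


def make_matrix(markers, samples, grid):
    """grid: list of per-marker call lists using 1/0/-1 codes."""
    return GenotypeMatrix(pd.DataFrame(
        np.array(grid, dtype=np.int8), index=pd.Index(markers, name="marker_id"),
        columns=samples))


@pytest.fixture
def tiny_layout():
    return make_layout([
        ("5M", "M", 70 * MB, 30 * MB, 5),
        ("5D", "D", 60 * MB, 25 * MB, 5),
        ("2U", "U", 65 * MB, 28 * MB, 2),
    ])


@pytest.fixture
def basic_sheet():
    """Minimal sheet with every role the partition stage needs."""
    return make_sheet([
        ("WP", Role.RECIPIENT_PARENT.value, "", ""),
        ("C1", Role.RECIPIENT_CONTROL.value, "", ""),
        ("DA", Role.DONOR_PARENT.value, "", "POP_A"),
        ("DB", Role.DONOR_PARENT.value, "", "POP_B"),
        ("PU", Role.U_PROGENITOR.value, "", ""),
        ("PM", Role.M_PROGENITOR.value, "", ""),
        ("BC1", Role.BC_LINE.value, "", "POP_A"),
    ])
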