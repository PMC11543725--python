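"""Partition dominant markers by parental genotype.

A Silico-DArT marker scores presence/absence of a restriction fragment, so a
marker that is present in the recipient wheat and absent in the wild donor
(or vice versa) is diagnostic for one side of the cross.  This module splits
the marker panel into wheat-specific, U-genome-specific and M-genome-specific
sets using the recipient parent, recipient controls, donor parent(s), and the
diploid U/M progenitors, and records an auditable exclusion reason for every
marker that is dropped.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .formats_io import ABSENT, MISSING, PRESENT, GenotypeMatrix, SampleSheet

__all__ = ["MarkerClass", "ExclusionReason", "partition_markers", "partition_summary",
           "write_classification_tsv", "read_classification_tsv"]


class MarkerClass(str, Enum):
    WHEAT_SPECIFIC = "wheat_specific"
    AEGILOPS_U = "aegilops_U"
    AEGILOPS_M = "aegilops_M"
    EXCLUDED = "excluded"


class ExclusionReason(str, Enum):
    LOW_QUALITY_PARENT = "low_quality_parent"
    NON_POLYMORPHIC_WHEAT_AEGILOPS = "non_polymorphic_wheat_aegilops"
    NON_SPECIFIC_U_M = "non_specific_U_M"
    ABSENT_EVERYWHERE = "absent_everywhere"


def partition_markers(G: GenotypeMatrix, S: SampleSheet) -> pd.DataFrame:
    """Classify every marker from parental/progenitor presence patterns.

    Rules, applied in order per marker:

    1. a missing call on the recipient parent or any donor parent excludes
       the marker (``low_quality_parent``);
    2. present in the recipient parent and all recipient controls, absent in
       all donor parents -> ``wheat_specific``;
    3. absent in the recipient parent and all recipient controls, present in
       at least one donor parent -> Aegilops-specific; the diploid
       progenitors then split it into ``aegilops_U`` (present in the U
       progenitor, absent in the M progenitor) or ``aegilops_M`` (the
       reverse); present in both or in neither -> ``non_specific_U_M``;
    4. present in every wheat and donor sample -> ``non_polymorphic_wheat_aegilops``;
       absent in every wheat and donor sample -> ``absent_everywhere``;
    5. anything else (no clean wheat/Aegilops contrast, e.g. a missing
       recipient-control call) -> ``non_polymorphic_wheat_aegilops``.

    Returns a DataFrame indexed by marker id with columns ``marker_class``,
    ``reason`` and one boolean ``in_<donor>`` presence flag per donor parent
    (so each BC line can later be compared against its own donor's haplotype).
    """
    for role, value in (("recipient_parent", S.recipient_parent),
                        ("u_progenitor", S.u_progenitor),
                        ("m_progenitor", S.m_progenitor)):
        if value is None:
            raise ValueError(f"sample sheet is missing required role: {role}")
    if not S.donor_parents:
        raise ValueError("sample sheet is missing required role: donor_parent")

    calls = G.calls
    rp = calls[S.recipient_parent].to_numpy()
    donors = calls[S.donor_parents].to_numpy()
    controls = (calls[S.recipient_controls].to_numpy()
                if S.recipient_controls else np.empty((len(calls), 0), dtype=np.int8))
    u_prog = calls[S.u_progenitor].to_numpy()
    m_prog = calls[S.m_progenitor].to_numpy()

    low_quality = (rp == MISSING) | (donors == MISSING).any(axis=1)
    wheat_all_present = (rp == PRESENT) & (controls == PRESENT).all(axis=1)
    wheat_all_absent = (rp == ABSENT) & (controls == ABSENT).all(axis=1)
    donor_any_present = (donors == PRESENT).any(axis=1)
    donor_all_present = (donors == PRESENT).all(axis=1)
    donor_all_absent = (donors == ABSENT).all(axis=1)

    wheat_specific = wheat_all_present & donor_all_absent
    aegilops = wheat_all_absent & donor_any_present
    u_specific = aegilops & (u_prog == PRESENT) & (m_prog == ABSENT)
    m_specific = aegilops & (m_prog == PRESENT) & (u_prog == ABSENT)

    n = len(calls)
    klass = np.full(n, MarkerClass.EXCLUDED.value, dtype=object)
    reason = np.full(n, ExclusionReason.NON_POLYMORPHIC_WHEAT_AEGILOPS.value, dtype=object)

    all_present = wheat_all_present & donor_all_present
    all_absent = wheat_all_absent & donor_all_absent
    reason[all_absent] = ExclusionReason.ABSENT_EVERYWHERE.value
    reason[aegilops] = ExclusionReason.NON_SPECIFIC_U_M.value

    for mask, cls in ((wheat_specific, MarkerClass.WHEAT_SPECIFIC),
                      (u_specific, MarkerClass.AEGILOPS_U),
                      (m_specific, MarkerClass.AEGILOPS_M)):
        klass[mask & ~low_quality] = cls.value
    # low quality overrides everything
    klass[low_quality] = MarkerClass.EXCLUDED.value
    reason[low_quality] = ExclusionReason.LOW_QUALITY_PARENT.value
    reason[klass != MarkerClass.EXCLUDED.value] = ""

    out = pd.DataFrame({"marker_class": klass, "reason": reason}, index=calls.index)
    out.index.name = "marker_id"
    for i, donor in enumerate(S.donor_parents):
        out[f"in_{donor}"] = donors[:, i] == PRESENT
    return out


def partition_summary(classes: pd.DataFrame) -> dict:
    """Counts per class and exclusion reason.

    Satisfies ``aegilops_total = aegilops_U + aegilops_M`` and
    ``wheat + U + M + excluded = total``.
    """
    cls = classes["marker_class"]
    counts = {c.value: int((cls == c.value).sum()) for c in MarkerClass}
    counts["aegilops_total"] = counts[MarkerClass.AEGILOPS_U.value] + counts[MarkerClass.AEGILOPS_M.value]
    counts["total"] = int(len(classes))
    excluded = classes[cls == MarkerClass.EXCLUDED.value]
    counts["excluded_by_reason"] = {
        r.value: int((excluded["reason"] == r.value).sum()) for r in ExclusionReason
    }
    return counts


def write_classification_tsv(classes: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        classes.to_csv(fh, sep="\t")


def read_classification_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker_id": str},
                     keep_default_na=False).set_index("marker_id")
    for col in df.columns:
        if col.startswith("in_"):
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df
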