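# Methods

## Problem and data model

`alienscan` detects chromatin of a wild relative (an allotetraploid
*Aegilops*-type donor carrying U and M sub-genomes) introgressed into
hexaploid bread wheat (A, B, D sub-genomes) in backcross (BC) pre-breeding
populations, using dominant genotyping-by-sequencing markers of the
Silico-DArT kind.  Each marker scores the presence (`1`) or absence (`0`) of
a genomic restriction fragment in a sample's reduced representation; a `-`
call means the genotype could not be scored reliably.  Dominant
presence/absence markers carry no dosage information, so the caller is
strictly two-state: a chromosome region is either detectably present or
absent in a line.  Monosomic versus disomic additions cannot be
distinguished computationally and are out of scope (in practice that
distinction comes from cytogenetics).

## Marker partition

A marker is informative only if it distinguishes the recipient wheat
haplotype from the donor's.  The partition uses the recipient parent,
optional recipient-control wheat genotypes, one or two donor-parent
accessions, and the diploid progenitors of the donor's U and M sub-genomes:

- markers with a `-` call on the recipient parent or any donor parent are
  excluded (`low_quality_parent`);
- wheat-specific: present in the recipient parent and every recipient
  control, absent in every donor parent;
- donor-specific: absent wheat-side and present in at least one donor
  parent, then assigned to U or M by the progenitor contrast; a marker
  present in both progenitors or in neither (including `-` progenitor
  calls) is excluded (`non_specific_U_M`);
- non-polymorphic (all present) and absent-everywhere markers are excluded.

Donor presence requires **at least one** donor accession rather than both:
the two accessions carry distinct haplotypes and requiring both would
discard accession-private markers.  Every donor-specific marker records a
per-donor presence flag so each BC line is later normalized against its own
population's donor parent.  Markers that fail both contrasts for any other
reason (e.g. a `-` call on a recipient control) fall into the
`non_polymorphic_wheat_aegilops` catch-all — the class enumeration is
exhaustive and exclusive by construction, which a property test enforces on
arbitrary call matrices.

## Placement

Marker sequences are assumed to have been aligned upstream (e.g. BLASTn);
the pipeline consumes standard 12-column tabular output.  Subject
coordinates are converted from 1-based inclusive to 0-based half-open at the
read boundary and minus-orientation hits are normalized so start < end; all
internal coordinates are 0-based half-open, and BED output keeps that
convention.  Hits are filtered by a maximum E-value (default 1e-6) and a
minimum aligned fraction of the marker sequence (default 0.5, i.e. a hit
covering exactly half the marker survives); the same filter applies to every
marker set and both knobs are exposed in configuration.  Among surviving
hits the best is chosen by maximal bitscore, then minimal E-value, then the
lexicographically smallest chromosome, then the smallest start — a total
order, so placement is invariant under permutation of the input.  A marker's
position is the normalized start of its best hit, and markers are ranked
along each chromosome by position (ties broken by marker id).

Placements whose chromosome genome disagrees with the marker's partition
class are retained with a warning flag rather than dropped: when an alien
set is placed against a syntenic proxy reference (e.g. M-genome markers
against the wheat D sub-genome, justified by preserved M–D collinearity),
cross-genome best hits are expected noise and dropping them would bias the
windowed denominators.

Placements are cross-checked against wheat/alien chromosome addition lines:
a U/M marker placed on chromosome c should be present exactly in the
addition line carrying c's homoeologous counterpart.  Presence in a single
wrong line is `contradicted`, in two or more lines `ambiguous`; a marker
present in no addition line is `untestable` (no positive evidence either
way) rather than contradicted, because assay dropout in a single control
line is common and should not impeach a placement.

## Windowed coverage and ratios

Chromosomes are tiled with non-overlapping windows (default 1 Mb; the last
window of a chromosome may be shorter).  For a sample and marker set, the
markers placed in each window and scored present are counted; `-` calls
contribute nothing.  Counts are normalized by the **panel-wide** number of
markers assigned to the chromosome — not the per-sample present count — so
the BC/parent ratio of normalized values equals the ratio of raw counts
wherever defined (a property test pins this to 1e-12).

Each BC line's normalized profile is divided by its reference parent's:
wheat-specific coverage against the recipient parent, donor-specific
coverage against the donor parent of the line's own population.  Windows
where the reference has zero markers are **masked**, not treated as ratio 0:
marker density drops sharply in pericentromeric regions (and rises toward
telomeres — the generator reproduces this), and an empty reference window
carries no evidence, so treating it as a deletion would produce systematic
false calls in marker deserts.  Shared regions sit at ratio ~1, lost or
never-inherited regions at ~0.

## Segmentation and breakpoints

Informative windows are thresholded (present iff ratio >= 0.5) and the
chromosome is labeled by an exact dynamic program that minimizes
(misclassified informative windows, number of runs) lexicographically,
subject to every maximal run containing at least `min_run` informative
windows (default 3).  The DP is exact — on any profile its labeling attains
the optimum of exhaustive enumeration, which the tests verify by brute force
on 12-window profiles — and deterministic, with remaining ties broken toward
the present state.  Sequences shorter than `min_run` collapse to a single
majority-vote run.  The default threshold and run length mean a single noisy
window can never seed an event.  Masked windows inherit the surrounding
segment; a masked gap between two different-state runs is split at its
midpoint, with the odd window going to the earlier segment.

Segment boundaries snap to window edges and are then refined with
marker-level evidence: each present/absent boundary moves to the midpoint
between the outermost present-called marker on the present side and the
nearest marker beyond it that supports absence (a non-present call, or any
placed marker already inside the absent segment).  The search is confined to
one window on each side of the boundary; with no qualifying marker the
window edge stands.  At typical panel densities this brings breakpoint error
from half a window to roughly half the local marker spacing.

## Event classification

Per sample, donor-side (U/M) segments are typed first:

- present fraction >= 0.95 of the chromosome **and no segmented absent
  run** -> whole-chromosome addition.  An absent run that survived
  segmentation already represents >= `min_run` windows of evidence, so it
  blocks the whole-addition call however small its fraction — otherwise
  deletions below 5% of the chromosome would be silently absorbed;
- presence confined to one arm (>= 0.9 of that arm, < 0.1 of the other)
  -> arm addition, labeled telosome when the proximal segment edge lies
  within one window of the centromere;
- a chromosome substantially present on both arms -> each absent segment is
  a terminal deletion (touching a telomere) or interstitial deletion;
- a sub-arm terminal present fragment, or an arm-level presence, is promoted
  to a translocation candidate when the same sample shows a recipient-side
  loss in the same homoeologous group.  M-genome donors pair only with
  D-sub-genome losses (M–D synteny is preserved); U-genome donors pair with
  any wheat genome of the group but carry a low-confidence flag (the U
  genome is internally rearranged, so group-based pairing overstates
  certainty).  Descriptions follow the standard translocation nomenclature,
  e.g. `T5DS·5DL-5ML` (intact recipient arm, partially retained arm, donor
  fragment), shortening to `T5DS-5ML` when the whole recipient arm is lost.

Unpaired recipient losses become terminal/interstitial deletions, or a
whole-chromosome absence when >= 0.95 of the chromosome is lost.  The
thresholds (0.5/3/0.95/0.9) are declared defaults exposed in configuration,
chosen for robustness rather than derived from data.

Caller specificity is defined against the sample's own baseline: comparing
a parent to itself gives ratio 1 on every informative window, and its own
marker set enters the caller as the side whose expectation is full presence,
so a flat profile yields zero events.  Donor chromatin counts as an
"addition" only relative to a wheat recipient background, i.e. when
screening BC lines.

Population summaries report, per population and donor chromosome, the
number and percentage of lines carrying any chromatin from it (any event
with a donor segment on that chromosome counts, including
deletion-on-addition calls), plus U-any/M-any aggregates.  Percentages are
**truncated** to one decimal, the package's reporting convention.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated.  Defaults:

| parameter | default | meaning |
|---|---|---|
| scale | 0.1 | chromosome lengths at 1/10 of wheat-like 300–800 Mb |
| groups | 7 | homoeologous groups per genome (A,B,D,U,M) |
| centromere | 0.35–0.5 of length | submetacentric chromosomes |
| marker counts | per-chromosome table | typical Silico-DArT panel yields per sub-genome (U ~7.7k, M ~4.3k, wheat ~9k total) |
| telomere_bias | 3 | density multiplier in the distal 25% of each arm |
| marker_length | 69 bp | typical sequenced tag length |
| ambiguous_fraction | 0.05 | alien markers present in both progenitors |
| both_donor_fraction | 0.7 | alien markers shared by the two donor accessions |
| n_bc | 40 | BC lines, split 35:44 across two populations |
| false_absent / false_present / missing | 0.02 / 0.005 / 0.01 | per-call noise |
| m_carrier_rate / u_carrier_rate | 0.85 / 0.15 | fraction of lines carrying M/U chromatin (M-chromatin is common, U rare, mimicking the unequal transmission of the two sub-genomes) |

The 1/10 scale keeps a full run at roughly 8 s on one CPU while preserving
>= 30 one-Mb windows per chromosome, so window-level logic is exercised at
realistic granularity; the methods were also checked at other marker scales.
Planted events (whole-chromosome additions, exact-arm additions/telosomes,
terminal deletions of 15–60% of an arm, interstitial deletions of 3–12 Mb,
reciprocal-loss translocations with 20–70%-of-arm fragments, whole
recipient-chromosome absences) each occupy their own homoeologous group
within a line so that pairing is unambiguous; every planted feature spans at
least four windows.  Missing-call noise applies to every sample — which is
what exercises the low-quality-parent exclusions — while presence flips
apply to BC lines only, since the parents define the contrasts.  An exactly
planted arm is a telosome by construction, so arm additions and telosomes
form a single category when calls are scored against truth.

Alignment hits are emitted with one full-length true hit per marker (half in
minus orientation), decoy hits on other chromosomes with strictly lower
bitscores at rate 0.2, and a 2% fraction of markers whose only hit covers
40% of the tag, which the placement filter must reject.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: linkage disequilibrium of genotyping errors
(noise is independent per call), restriction-site and methylation biases
beyond the telomere/centromere density gradient, segregation distortion and
meiotic structure (carrier rates are user-specified frequencies, not a
transmission model), reference-assembly errors, and paralog-induced
multi-mapping beyond simple random decoys.

## Numerical and degenerate-input choices

- All randomness derives from a single integer seed through named
  substreams; a fixed configuration reproduces outputs byte-for-byte.
- Best-hit and ordering ties are broken lexicographically (documented
  above); the segmentation DP's ties prefer fewer runs, then present.
- A chromosome with no assigned markers is flagged uninformative and
  produces neither ratios nor events; an all-masked chromosome produces no
  segments.
- Readers reject malformed input (duplicate ids, out-of-range centromeres,
  unknown call tokens, wrong column counts) with coordinates rather than
  repairing it.
- `SegmentCall` forbids empty intervals; BED output is sorted by chromosome
  then start regardless of input order.

## Known limitations

- Dosage (monosomic vs disomic) is invisible to dominant markers.
- Translocation pairing by homoeologous group cannot resolve which of two
  same-group losses (if both existed) received the donor fragment; the
  generator avoids this by construction and real cases need cytogenetic
  confirmation.
- Breakpoints inside reference marker deserts cannot be refined below
  window resolution.
- Intra-donor (U–M) rearrangements and gametocidal mechanisms are out of
  scope; the generator only reflects their population-level consequences as
  carrier frequencies.
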