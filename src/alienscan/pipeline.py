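"""File-level orchestration of the pipeline stages.

Each stage reads the outputs of the previous one from a run directory and
writes its own, so real genotype exports and real alignment files can be
substituted for synthetic ones at any stage boundary:

    simulate -> partition -> place -> coverage -> call [-> evaluate]

Stages are idempotent given identical inputs and configuration; every output
carries a header comment with the resolved-config hash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .coverage import (count_present_markers, density_matrix, make_windows,
                       profiles_to_frame, ratio_profile, ratios_to_frame,
                       reference_sample_for, MARKER_SETS, RatioProfile)
from .events import (CallerParams, EventCall, SegmentCall, classify_events,
                     population_summary, refine_breakpoints, segment_ratio)
from .formats_io import (config_hash, read_chrom_sizes, read_dart_matrix,
                         read_sample_sheet, write_events_tsv,
                         write_segments_bed)
from .partition import (MarkerClass, partition_markers, partition_summary,
                        read_classification_tsv, write_classification_tsv)
from .placement import (PlacementFilter, annotate_class_consistency,
                        order_markers, place_markers, read_alignment_tab,
                        read_marker_lengths, read_placements_tsv,
                        validate_with_additions, write_placements_tsv)
from .synthetic import NoiseConfig, SimConfig, simulate_dataset, write_dataset

log = logging.getLogger("alienscan")

_STAGE_INPUTS = {
    "partition": {"genotypes.csv": "simulate", "samples.tsv": "simulate"},
    "place": {"alignment.tsv": "simulate", "marker_lengths.tsv": "simulate"},
    "coverage": {"genotypes.csv": "simulate", "samples.tsv": "simulate",
                 "chrom_sizes.tsv": "simulate", "classification.tsv": "partition",
                 "placements.tsv": "place"},
    "call": {"genotypes.csv": "simulate", "samples.tsv": "simulate",
             "chrom_sizes.tsv": "simulate", "classification.tsv": "partition",
             "placements.tsv": "place",
             f"ratios_{MarkerClass.WHEAT_SPECIFIC.value}.tsv": "coverage"},
    "evaluate": {"truth_events.tsv": "simulate", "events.tsv": "call"},
}

DEFAULT_CONFIG: dict = {
    "window_size": 1_000_000,
    "placement": {"max_evalue": 1e-6, "min_aligned_fraction": 0.5},
    "caller": {"present_threshold": 0.5, "min_run": 3,
               "whole_chrom_fraction": 0.95, "arm_fraction": 0.9},
    "simulate": {},  # SimConfig field overrides
}


def resolve_config(overrides: Optional[dict] = None,
                   seed: Optional[int] = None,
                   window_size: Optional[int] = None) -> dict:
    """Layer user overrides (and CLI seed/window-size) over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg.setdefault("simulate", {})["seed"] = int(seed)
    if window_size is not None:
        cfg["window_size"] = int(window_size)
    return cfg


def _require(outdir: Path, stage: str) -> None:
    for fname, producer in _STAGE_INPUTS.get(stage, {}).items():
        if not (outdir / fname).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs {fname}; run the '{producer}' stage first "
                f"(or place the file in {outdir})")


def _sim_config(cfg: dict) -> SimConfig:
    params = dict(cfg.get("simulate") or {})
    noise = params.pop("noise", None)
    sim = SimConfig(**params)
    if noise is not None:
        sim = sim.with_noise(NoiseConfig(**noise))
    return sim


def _echo_config(cfg: dict, outdir: Path) -> str:
    h = config_hash(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": h, **cfg}, fh, sort_keys=True)
    log.info("resolved config (hash %s): %s", h, json.dumps(cfg, sort_keys=True))
    return h


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    _echo_config(cfg, outdir)
    sim = _sim_config(cfg)
    ds = simulate_dataset(sim)
    write_dataset(ds, outdir)
    log.info("simulated %d markers, %d samples", len(ds.panel.markers),
             len(ds.genotypes.sample_ids))
    return {"n_markers": len(ds.panel.markers),
            "n_samples": len(ds.genotypes.sample_ids),
            "n_truth_events": len(ds.truth.events)}


def stage_partition(cfg: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "partition")
    h = _echo_config(cfg, outdir)
    G = read_dart_matrix(outdir / "genotypes.csv")
    S = read_sample_sheet(outdir / "samples.tsv")
    classes = partition_markers(G, S)
    write_classification_tsv(classes, outdir / "classification.tsv",
                             header=f"config_hash={h}")
    summary = partition_summary(classes)
    with open(outdir / "partition_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("partition: %s", summary)
    return summary


def stage_place(cfg: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "place")
    h = _echo_config(cfg, outdir)
    hits = read_alignment_tab(outdir / "alignment.tsv")
    lengths = read_marker_lengths(outdir / "marker_lengths.tsv")
    pfilter = PlacementFilter(**cfg["placement"])
    placements = order_markers(place_markers(hits, lengths, pfilter))
    if (outdir / "classification.tsv").exists() and (outdir / "chrom_sizes.tsv").exists():
        classes = read_classification_tsv(outdir / "classification.tsv")
        layout = read_chrom_sizes(outdir / "chrom_sizes.tsv")
        placements = annotate_class_consistency(placements, classes, layout)
        if (outdir / "genotypes.csv").exists() and (outdir / "samples.tsv").exists():
            G = read_dart_matrix(outdir / "genotypes.csv")
            S = read_sample_sheet(outdir / "samples.tsv")
            flags, confusion = validate_with_additions(classes, placements, G, S)
            placements["validation"] = placements["marker_id"].map(flags).fillna("")
            confusion.to_csv(outdir / "validation_confusion.tsv", sep="\t")
    write_placements_tsv(placements, outdir / "placements.tsv",
                         header=f"config_hash={h}")
    log.info("placed %d markers", len(placements))
    return {"n_placed": len(placements)}


def stage_coverage(cfg: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "coverage")
    h = _echo_config(cfg, outdir)
    G = read_dart_matrix(outdir / "genotypes.csv")
    S = read_sample_sheet(outdir / "samples.tsv")
    layout = read_chrom_sizes(outdir / "chrom_sizes.tsv")
    classes = read_classification_tsv(outdir / "classification.tsv")
    placements = read_placements_tsv(outdir / "placements.tsv")
    grid = make_windows(layout, cfg["window_size"])

    info = {}
    for marker_set in MARKER_SETS:
        profiles = {sid: count_present_markers(G, classes, placements, grid,
                                               sid, marker_set)
                    for sid in G.sample_ids}
        plist = list(profiles.values())
        for name, frame in (("coverage_raw", profiles_to_frame(plist, "raw")),
                            ("coverage_normalized", profiles_to_frame(plist, "normalized")),
                            ("density", density_matrix(plist))):
            _write_matrix(frame, outdir / f"{name}_{marker_set}.tsv", h)
        ratios = [ratio_profile(profiles[sid],
                                profiles[reference_sample_for(S, sid, marker_set)])
                  for sid in S.bc_lines]
        _write_matrix(ratios_to_frame(ratios), outdir / f"ratios_{marker_set}.tsv", h)
        info[marker_set] = len(plist)
    return info


def _write_matrix(df: pd.DataFrame, path: Path, h: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={h}\n")
        df.to_csv(fh, sep="\t")


def _read_ratio_frame(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="window")


def _frame_to_ratio_profiles(df: pd.DataFrame, grid, marker_set: str,
                             references: dict[str, str]) -> list[RatioProfile]:
    """Rebuild per-chromosome ratio arrays from a windows x samples matrix."""
    chrom_of = np.array([k.split(":")[0] for k in df.index])
    out = []
    for sid in df.columns:
        col = df[sid].to_numpy(dtype=float)
        ratio, mask = {}, {}
        for chrom in grid.chromosomes():
            vals = col[chrom_of == chrom]
            ratio[chrom] = vals
            mask[chrom] = ~np.isnan(vals)
        out.append(RatioProfile(sid, references.get(sid, ""), marker_set,
                                grid, ratio, mask))
    return out


def stage_call(cfg: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "call")
    h = _echo_config(cfg, outdir)
    G = read_dart_matrix(outdir / "genotypes.csv")
    S = read_sample_sheet(outdir / "samples.tsv")
    layout = read_chrom_sizes(outdir / "chrom_sizes.tsv")
    classes = read_classification_tsv(outdir / "classification.tsv")
    placements = read_placements_tsv(outdir / "placements.tsv")
    grid = make_windows(layout, cfg["window_size"])
    params = CallerParams(**cfg["caller"])

    set_placements = {
        ms: placements[placements["marker_id"].isin(
            classes.index[classes["marker_class"] == ms])]
        for ms in MARKER_SETS
    }
    donor_segs: list[SegmentCall] = []
    recipient_segs: list[SegmentCall] = []
    for marker_set in MARKER_SETS:
        path = outdir / f"ratios_{marker_set}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage 'call' needs {path.name}; run the 'coverage' stage first")
        frame = _read_ratio_frame(path)
        refs = {sid: reference_sample_for(S, sid, marker_set) for sid in frame.columns}
        for rp in _frame_to_ratio_profiles(frame, grid, marker_set, refs):
            segs = segment_ratio(rp, params)
            segs = refine_breakpoints(segs, set_placements[marker_set], G,
                                      rp.bc_sample_id, grid)
            if marker_set == MarkerClass.WHEAT_SPECIFIC.value:
                recipient_segs.extend(segs)
            else:
                donor_segs.extend(segs)

    events = classify_events(donor_segs, recipient_segs, layout, params,
                             window_size=grid.window_size)
    write_segments_bed(donor_segs + recipient_segs, outdir / "segments.bed",
                       header=f"config_hash={h}")
    write_events_tsv(events, outdir / "events.tsv", header=f"config_hash={h}")
    summary = population_summary(events, S, layout)
    _write_matrix(summary.set_index("population"),
                  outdir / "population_summary.tsv", h)
    log.info("called %d events across %d BC lines", len(events), len(S.bc_lines))
    return {"n_events": len(events), "events": events,
            "donor_segments": donor_segs, "recipient_segments": recipient_segs,
            "summary": summary}


def read_events_tsv(path: str | Path) -> list[EventCall]:
    """Rebuild event calls from the events TSV report."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    events = []
    for _, row in df.iterrows():
        segs = {}
        for side, state in (("donor", "present"), ("recipient", "absent")):
            chrom = row.get(f"{side}_chrom", "")
            if chrom != "":
                segs[side] = SegmentCall(row["sample_id"], str(chrom),
                                         int(float(row[f"{side}_start"])),
                                         int(float(row[f"{side}_end"])), state)
        events.append(EventCall(
            row["sample_id"], row["type"], int(row["homoeologous_group"]),
            str(row["description"]),
            donor_segment=segs.get("donor"),
            recipient_segment=segs.get("recipient"),
            low_confidence=str(row["low_confidence"]).lower() in ("true", "1")))
    return events


def stage_evaluate(cfg: dict, outdir: str | Path,
                   events: Optional[list[EventCall]] = None) -> dict:
    outdir = Path(outdir)
    _require(outdir, "evaluate")
    layout = read_chrom_sizes(outdir / "chrom_sizes.tsv")
    truth = pd.read_csv(outdir / "truth_events.tsv", sep="\t",
                        keep_default_na=False,
                        na_values={"recipient_start": [""], "recipient_end": [""]})
    if events is None:
        events = read_events_tsv(outdir / "events.tsv")
    report = evaluation.match_events(events, truth, layout)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("evaluation: %s", report)
    return report


def run_all(cfg: dict, outdir: str | Path) -> dict:
    """simulate -> partition -> place -> coverage -> call -> evaluate."""
    outdir = Path(outdir)
    results = {"simulate": stage_simulate(cfg, outdir)}
    results["partition"] = stage_partition(cfg, outdir)
    results["place"] = stage_place(cfg, outdir)
    results["coverage"] = stage_coverage(cfg, outdir)
    call = stage_call(cfg, outdir)
    results["call"] = {"n_events": call["n_events"]}
    results["evaluate"] = stage_evaluate(cfg, outdir, events=call["events"])
    return results
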