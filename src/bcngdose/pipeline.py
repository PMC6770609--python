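"""End-to-end orchestration: simulate -> arm calls -> groups -> DE -> classes
-> NCDI -> enrichment, with a manifest of every stage's outputs.

The pipeline is driven by one structured config with three sections::

    simulation: {...}        # SimulationConfig fields
    analysis:   {...}        # AnalysisConfig fields (optional)
    group:      {chromosome: "8", mode: whole-gain, instability: all}
    enrichment: {regions: [...]}   # optional; defaults to the target chromosome

Every stage writes plain TSV and logs one structured line with its row
counts; the ground-truth files are written under ``truth/`` and are never
read back by any stage.  Re-running with the same config and seed
reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .armcalls import build_arm_call_matrix, cna_frequencies
from .chromdist import correlate_ncdi_cna, ncdi, ncdi_by_tpm_bin
from .config import (
    AnalysisConfig,
    ConfigurationError,
    SimulationConfig,
    config_hash,
    load_yaml_config,
)
from .diffexpr import ContrastSet, compute_tpm, run_contrasts
from .enrichment import run_table1
from .groups import select_control_group, select_gain_group
from .io import (
    write_annotation,
    write_counts,
    write_gene_set,
    write_metadata,
    write_seg,
    write_table,
)
from .simulate import simulate_cohort
from .taxonomy import biotype_partition, class_members, classify, venn_counts

log = logging.getLogger("bcngdose")

NCDI_CLASSES = ["positive_t", "negative_t", "over_t", "over_positive_t", "over_negative_t"]


@dataclass
class RunManifest:
    """Record of one pipeline run: config identity and per-stage outputs."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, str], counts: dict[str, int]) -> None:
        self.stages.append({"stage": stage, "outputs": outputs, "counts": counts})
        log.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        # outputs are recorded relative to the manifest's directory
        for stage in self.stages:
            for out in stage["outputs"].values():
                if not (path.parent / out).exists():
                    raise RuntimeError(f"declared output missing: {out}")


def _parse_config(config: dict) -> tuple[SimulationConfig, AnalysisConfig, dict, dict]:
    if not isinstance(config, dict) or "simulation" not in config:
        raise ConfigurationError("pipeline config must contain a 'simulation' section")
    sim = SimulationConfig.from_dict(config["simulation"])
    ana = AnalysisConfig.from_dict(config.get("analysis", {}))
    group = dict(config.get("group", {}))
    if "chromosome" not in group:
        raise ConfigurationError("pipeline config must name a target chromosome under 'group'")
    group.setdefault("mode", "whole-gain")
    group.setdefault("instability", "all")
    enr = dict(config.get("enrichment", {}))
    unknown = set(config) - {"simulation", "analysis", "group", "enrichment"}
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    return sim, ana, group, enr


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Execute every stage in dependency order; returns the run manifest."""
    if not isinstance(config, dict):
        config = load_yaml_config(config)
    sim_cfg, ana_cfg, group_cfg, enr_cfg = _parse_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    (out / "genesets").mkdir(exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), seed=sim_cfg.seed)

    # -- simulate ---------------------------------------------------------
    cohort = simulate_cohort(sim_cfg)
    paths = {
        "segments": out / "segments.seg.tsv",
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "metadata": out / "metadata.tsv",
        "catalog": out / "catalog.tsv",
    }
    write_seg(cohort.segments, paths["segments"])
    write_counts(cohort.counts, paths["counts"])
    write_annotation(cohort.annotation, paths["annotation"])
    write_metadata(cohort.metadata, paths["metadata"])
    cohort.catalog.to_tsv(paths["catalog"])
    for name, members in cohort.truth.gene_sets.items():
        p = out / "genesets" / f"{name}.txt"
        write_gene_set(members, p)
        paths[f"geneset_{name}"] = p
    write_table(cohort.truth.transcripts, out / "truth" / "transcripts.tsv")
    write_table(cohort.truth.events, out / "truth" / "events.tsv", index=False)
    manifest.record(
        "simulate", {k: str(Path(v).relative_to(out)) for k, v in paths.items()},
        {"samples": len(cohort.metadata), "transcripts": len(cohort.annotation),
         "segments": len(cohort.segments)},
    )

    # -- arm calls --------------------------------------------------------
    calls = build_arm_call_matrix(cohort.segments, cohort.catalog)
    tumours = cohort.tumour_samples
    freq = cna_frequencies(calls, tumours)
    calls_path = out / "arm_calls.tsv"
    freq_path = out / "cna_frequencies.tsv"
    summary = pd.DataFrame({
        "broad_cna_count": calls.broad_cna_count(),
        "karyotype": calls.karyotype(),
    })
    write_table(calls.calls, calls_path)
    write_table(freq, freq_path)
    write_table(summary, out / "karyotypes.tsv")
    manifest.record(
        "armcall",
        {"calls": calls_path.name, "frequencies": freq_path.name,
         "karyotypes": "karyotypes.tsv"},
        {"samples": len(calls.calls), "regions": len(calls.calls.columns)},
    )

    # -- groups -----------------------------------------------------------
    chromosome = str(group_cfg["chromosome"])
    selected = select_gain_group(
        calls, chromosome, group_cfg["mode"], cohort.metadata, group_cfg["instability"]
    )
    control = select_control_group(
        calls, chromosome, cohort.metadata, group_cfg["instability"]
    )
    groups_path = out / "groups.tsv"
    rows = [{"group": g.group_id, "sample": s} for g in (selected, control) for s in g.members]
    write_table(pd.DataFrame(rows, columns=["group", "sample"]), groups_path, index=False)
    manifest.record(
        "groups", {"groups": groups_path.name},
        {"selected": len(selected), "control": len(control)},
    )

    # -- differential expression -----------------------------------------
    contrast_set = ContrastSet(
        selected=selected.members, control=control.members, normals=cohort.normal_samples
    )
    de = run_contrasts(cohort.counts, contrast_set, min_cpm=ana_cfg.min_cpm)
    de_paths = {}
    for name, res in de.items():
        p = out / f"de_{name}.tsv"
        write_table(res.table, p)
        de_paths[name] = p.name
    manifest.record(
        "de", de_paths,
        {"transcripts_tested": len(de["FC1"].table),
         **{f"n_{k.lower()}": len(v.table) for k, v in de.items()}},
    )

    # -- transcript classes ----------------------------------------------
    assignment = classify(de["FC1"], de["FC2"], de["FC3"], de["FC4"], ana_cfg, cohort.annotation)
    classes_path = out / "classes.tsv"
    write_table(assignment, classes_path)
    venn = venn_counts(
        set(assignment.index[assignment["fc2"] > ana_cfg.overt_fc2_threshold]),
        set(assignment.index[assignment["fc3"] > 0]),
        set(assignment.index[assignment["fc4"] > 0]),
    )
    venn_path = out / "venn.tsv"
    write_table(pd.DataFrame([venn]), venn_path, index=False)
    for name, tbl in biotype_partition(assignment, cohort.annotation).items():
        write_table(tbl, out / f"classes_{name}.tsv")
    manifest.record(
        "classify", {"classes": classes_path.name, "venn": venn_path.name},
        {c: int(assignment[c].sum()) for c in NCDI_CLASSES},
    )

    # -- NCDI -------------------------------------------------------------
    ncdi_rows = []
    corr_rows = []
    for cls in NCDI_CLASSES:
        members = class_members(assignment, cls)
        if len(members) == 0:
            log.info("stage=ncdi class=%s skipped (empty)", cls)
            continue
        profile = ncdi(members, cohort.annotation, cohort.catalog)
        profile.insert(0, "class", cls)
        ncdi_rows.append(profile.reset_index())
        for direction in ("gain_pct", "loss_pct"):
            try:
                r = correlate_ncdi_cna(profile, freq[direction])
            except ValueError:
                continue
            corr_rows.append({"class": cls, "frequency": direction, "pearson_r": r})
    ncdi_path = out / "ncdi.tsv"
    write_table(pd.concat(ncdi_rows, ignore_index=True), ncdi_path, index=False)
    corr_path = out / "ncdi_cna_correlation.tsv"
    write_table(pd.DataFrame(corr_rows), corr_path, index=False)

    # TPM-binned NCDI for the target chromosome's last region (the gained
    # arm in iso/whole-gain designs) over the selected group's samples
    tpm = compute_tpm(
        cohort.counts.loc[assignment.index], cohort.annotation["length"]
    )
    summary_fn = pd.DataFrame.mean if ana_cfg.tpm_summary == "mean" else pd.DataFrame.median
    tpm_summary = summary_fn(tpm[selected.members], axis=1)
    target_region = cohort.catalog.regions_of(chromosome)[-1].region_id
    bin_rows = []
    for cls in ("over_t", "over_positive_t", "over_negative_t"):
        members = class_members(assignment, cls)
        if len(members) == 0:
            continue
        tbl = ncdi_by_tpm_bin(
            members, tpm_summary, ana_cfg.tpm_bin_edges, target_region,
            cohort.annotation, cohort.catalog,
        )
        tbl.insert(0, "class", cls)
        bin_rows.append(tbl.reset_index())
    tpm_path = out / "ncdi_tpm_bins.tsv"
    if bin_rows:
        write_table(pd.concat(bin_rows, ignore_index=True), tpm_path, index=False)
    else:
        write_table(pd.DataFrame(columns=["bin", "class", "ncdi"]), tpm_path, index=False)
    manifest.record(
        "ncdi",
        {"ncdi": ncdi_path.name, "correlations": corr_path.name, "tpm_bins": tpm_path.name},
        {"classes": len(ncdi_rows), "correlations": len(corr_rows)},
    )

    # -- enrichment -------------------------------------------------------
    regions = enr_cfg.get(
        "regions", [r.region_id for r in cohort.catalog.regions_of(chromosome)]
    )
    grid = run_table1(
        assignment, cohort.truth.gene_sets, cohort.annotation, cohort.catalog, regions
    )
    enrich_path = out / "enrichment.tsv"
    write_table(grid, enrich_path, index=False)
    manifest.record(
        "enrich", {"enrichment": enrich_path.name},
        {"cells": len(grid), "nc": int(grid["nc"].sum())},
    )

    manifest.to_json(out / "manifest.json")
    return manifest
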