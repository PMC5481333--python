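"""End-to-end run orchestration: simulate/ingest → extract → detect → call
→ expression → report, with a JSON run manifest.

A run is described by a small YAML (or dict) configuration::

    seed: 17
    control: normoxia
    comparisons:
      - {treated: acute, control: normoxia}
      - {treated: chronic, control: normoxia}
    thresholds: {dsi_min: 0.15, fdr_max: 0.01, min_support: 10, fc_min: 1.5}
    simulate: {n_genes: 200}       # or inputs: {gtf: ..., alignments: {...}}
    alignments: false              # realise + re-extract SAM when simulating

Identical configuration, inputs and seed give byte-identical output tables;
the manifest additionally records parameters, input checksums, stage timings
and record counts.
"""

from __future__ import annotations

import hashlib
import json
import time
from collections import Counter
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .annotation import build_annotation_index, read_gtf
from .events import detect_events, events_to_frame
from .expression import expression_table
from .junctions import (
    DEFAULT_MIN_OVERHANG,
    EvidenceTable,
    JunctionCounts,
    read_sj_tab,
    tabulate_sample,
)
from .report import build_summary, spliced_gene_set
from .si import (
    DEFAULT_DSI_MIN,
    DEFAULT_FDR_MAX,
    DEFAULT_MIN_SUPPORT,
    call_events,
    calls_to_frame,
)
from .simulate import ConfigurationError, config_from_mapping, simulate_dataset


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_thresholds(th: dict) -> dict:
    out = {
        "dsi_min": float(th.get("dsi_min", DEFAULT_DSI_MIN)),
        "fdr_max": float(th.get("fdr_max", DEFAULT_FDR_MAX)),
        "min_support": int(th.get("min_support", DEFAULT_MIN_SUPPORT)),
        "fc_min": float(th.get("fc_min", 1.5)),
        "min_overhang": int(th.get("min_overhang", DEFAULT_MIN_OVERHANG)),
    }
    if not 0 < out["dsi_min"] <= 1:
        raise ConfigurationError(f"dsi_min out of range (0,1]: {out['dsi_min']}")
    if not 0 < out["fdr_max"] < 1:
        raise ConfigurationError(f"fdr_max out of range (0,1): {out['fdr_max']}")
    if out["min_support"] < 1:
        raise ConfigurationError("min_support must be >= 1")
    if out["fc_min"] <= 1:
        raise ConfigurationError("fc_min must exceed 1")
    if out["min_overhang"] < 1:
        raise ConfigurationError("min_overhang must be >= 1")
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: run configuration must be a mapping")
    return cfg


def run_pipeline(config: dict, out_dir, seed: Optional[int] = None) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    ``seed`` overrides ``config['seed']`` when given.
    """
    t_all = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = _validate_thresholds(config.get("thresholds", {}))
    seed = int(config.get("seed", 0) if seed is None else seed)
    control = config.get("control", "normoxia")
    comparisons = config.get("comparisons") or []

    manifest: dict = {
        "tool": "deltasi",
        "version": __version__,
        "seed": seed,
        "thresholds": thresholds,
        "control": control,
        "stages": {},
        "inputs": {},
        "records": {},
    }

    timings: Dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 4)

        return _T()

    # ---- inputs ----------------------------------------------------------
    gene_counts: Dict[str, Counter] = {}
    with stage("inputs"):
        if "inputs" in config:
            inputs = config["inputs"]
            gtf = Path(inputs["gtf"])
            if not gtf.exists():
                raise FileNotFoundError(f"annotation not found: {gtf}")
            genes = read_gtf(gtf)
            index = build_annotation_index(genes)
            manifest["inputs"]["gtf"] = {"path": str(gtf), "sha256": _sha256(gtf)}
            jc = JunctionCounts(min_overhang=thresholds["min_overhang"])
            ev = EvidenceTable()
            if "alignments" in inputs:
                for sample, path in sorted(inputs["alignments"].items()):
                    p = Path(path)
                    if not p.exists():
                        raise FileNotFoundError(f"alignments not found: {p}")
                    sjc, sev, gct, _tally = tabulate_sample(
                        p, index, sample, thresholds["min_overhang"]
                    )
                    jc.merge(sjc)
                    for key, rec in sev._records.items():
                        ev._records[key] = rec
                    ev.strand.update(sev.strand)
                    gene_counts[sample] = gct
                    manifest["inputs"][f"alignments:{sample}"] = {
                        "path": str(p), "sha256": _sha256(p)
                    }
            elif "sj_tabs" in inputs:
                for sample, path in sorted(inputs["sj_tabs"].items()):
                    p = Path(path)
                    if not p.exists():
                        raise FileNotFoundError(f"junction table not found: {p}")
                    jc.merge(read_sj_tab(p, sample))
                    manifest["inputs"][f"sj_tab:{sample}"] = {
                        "path": str(p), "sha256": _sha256(p)
                    }
            else:
                raise ConfigurationError(
                    "inputs must provide 'alignments' or 'sj_tabs'"
                )
            jc.resolve_strands(index)
            truth = None
        else:
            sim_cfg = config_from_mapping(config.get("simulate", {}) or {})
            realise = bool(config.get("alignments", False))
            genes, truth, jc, ev, gene_counts, paths = simulate_dataset(
                sim_cfg, seed, out_dir=out, alignments=realise
            )
            index = build_annotation_index(genes)
            manifest["inputs"]["gtf"] = {
                "path": str(out / "annotation.gtf"),
                "sha256": _sha256(out / "annotation.gtf"),
            }
            if realise:
                # re-extract from the realised SAMs so the whole read path runs
                jc = JunctionCounts(min_overhang=thresholds["min_overhang"])
                ev = EvidenceTable()
                gene_counts = {}
                for sample, p in sorted(paths.items()):
                    sjc, sev, gct, _tally = tabulate_sample(
                        p, index, sample, thresholds["min_overhang"]
                    )
                    jc.merge(sjc)
                    for key, rec in sev._records.items():
                        ev._records[key] = rec
                    ev.strand.update(sev.strand)
                    gene_counts[sample] = gct

    jc.to_tsv(out / "junctions.tsv")
    ev.to_tsv(out / "intron_evidence.tsv")
    manifest["records"]["junctions"] = len(jc.keys())
    manifest["records"]["samples"] = jc.samples

    # ---- detect ----------------------------------------------------------
    with stage("detect"):
        events = detect_events(jc, ev, index, control_sample=control)
    events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
    manifest["records"]["candidate_events"] = len(events)

    # ---- call ------------------------------------------------------------
    calls_by_comparison = {}
    with stage("call"):
        for comp in comparisons:
            treated = comp["treated"]
            ctrl = comp.get("control", control)
            calls = call_events(
                events, jc, ev, ctrl, treated,
                dsi_min=thresholds["dsi_min"],
                fdr_max=thresholds["fdr_max"],
                min_support=thresholds["min_support"],
            )
            name = f"{treated}_vs_{ctrl}"
            calls_by_comparison[name] = calls
            calls_to_frame(calls).to_csv(out / f"calls_{name}.tsv", sep="\t", index=False)
            manifest["records"][f"significant_{name}"] = sum(
                1 for c in calls if c.significant
            )

    # ---- expression ------------------------------------------------------
    with stage("expression"):
        if gene_counts:
            gdf = pd.DataFrame(
                {sm: pd.Series(gene_counts[sm]) for sm in sorted(gene_counts)}
            ).fillna(0).astype(int)
            gdf.index.name = "gene_id"
            gdf.sort_index().to_csv(out / "gene_counts.tsv", sep="\t")
            for comp in comparisons:
                treated = comp["treated"]
                ctrl = comp.get("control", control)
                name = f"{treated}_vs_{ctrl}"
                expr = expression_table(
                    gene_counts, treated, ctrl, fc_min=thresholds["fc_min"]
                )
                expr.to_csv(out / f"expression_{name}.tsv", sep="\t")
                if name in calls_by_comparison:
                    spliced = spliced_gene_set(calls_by_comparison[name])
                    up = set(expr.index[expr["call"] == "up"])
                    down = set(expr.index[expr["call"] == "down"])
                    from .expression import expression_splicing_overlap

                    expression_splicing_overlap(up, down, spliced).to_csv(
                        out / f"overlap_{name}.tsv", sep="\t", index=False
                    )

    # ---- report ----------------------------------------------------------
    with stage("report"):
        summary = build_summary(calls_by_comparison)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    manifest["stages"] = timings
    manifest["stages"]["total"] = round(time.perf_counter() - t_all, 4)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
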