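"""End-to-end pipeline: simulate (or ingest) -> call -> classify ->
hotspots -> CIN metrics -> cohort statistics, with a reproducibility
manifest."""

from __future__ import annotations

import hashlib
import json
import os
import platform
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calling import call_cohort, profiles_to_frame
from .cin import cin_report, cin_report_frame, wgd_aneuploidy_association
from .fixtures import plan_fixture
from .genome import build_default_units, load_build, make_bins, read_bed
from .karyotype import (
    category_tally,
    focal_events_frame,
    karyotype_cohort,
    karyotypes_to_frame,
    tally_gains_losses,
)
from .recurrence import (
    NullModelConfig,
    count_alterations_per_unit,
    hotspot_test,
    hotspots_to_frame,
)
from .simulate import simulate_cohort, write_cohort
from .stats import (
    build_segment_event_table,
    gain_loss_bias_test,
    segment_event_totals,
)


@dataclass
class PipelineConfig:
    cohorts: tuple = ("HC", "NT", "TUM")
    seed: int = 123
    bin_size: int = 500_000
    n_sims: int = 10_000
    quantile: float = 0.90
    blacklist_path: Optional[str] = None
    out_dir: Optional[str] = None
    write_outputs: bool = False


@dataclass
class CohortResult:
    name: str
    plan: object
    counts: pd.DataFrame
    profiles: dict
    karyotypes: list
    hotspots: list
    cin_reports: list


def run_cohort(name, seed, units, grid, build, n_sims=10_000, quantile=0.90):
    """Simulate one fixture cohort and run it through calling,
    classification, recurrence and CIN metrics."""
    plan = plan_fixture(name, seed=seed)
    counts = simulate_cohort(plan, units, grid, build=build)
    dna = {n.nucleus_id: n.dna_content for n in plan.nuclei}
    profiles = call_cohort(counts, grid, dna_content=dna)
    meta = pd.DataFrame(
        [(n.nucleus_id, n.subject_id, n.group, n.sex) for n in plan.nuclei],
        columns=["nucleus_id", "subject_id", "group", "sex"],
    )
    karyotypes = karyotype_cohort(profiles, units, build, meta)
    cfg = NullModelConfig(n_sims=n_sims, p_unit=1.0 / len(units), quantile=quantile, seed=seed)
    recur = count_alterations_per_unit(karyotypes, [u.unit_id for u in units])
    hotspots = hotspot_test(recur, cfg)
    reports = cin_report(karyotypes, profiles)
    return CohortResult(name, plan, counts, profiles, karyotypes, hotspots, reports)


def run_pipeline(config: Optional[PipelineConfig] = None) -> dict:
    """Run every configured cohort end to end; returns a result bundle and
    (optionally) writes all tabular outputs plus a manifest."""
    config = config or PipelineConfig()
    build = load_build()
    units = build_default_units(build)
    blacklist = read_bed(config.blacklist_path) if config.blacklist_path else None
    grid = make_bins(build, config.bin_size, blacklist)

    results = {}
    summary = {}
    for name in config.cohorts:
        res = run_cohort(
            name, config.seed, units, grid, build,
            n_sims=config.n_sims, quantile=config.quantile,
        )
        results[name] = res
        n_gains, n_losses, per_unit, direction = tally_gains_losses(res.karyotypes)
        summary[name] = {
            "n_nuclei": len(res.karyotypes),
            "n_aneuploid": sum(k.is_aneuploid for k in res.karyotypes),
            "category_tally": category_tally(res.karyotypes),
            "n_gains": n_gains,
            "n_losses": n_losses,
            "flagged_units": [h.unit_id for h in res.hotspots if h.flagged],
        }

    bundle = {"results": results, "summary": summary, "units": units, "grid": grid, "build": build}

    if {"NT", "TUM"} <= set(results):
        karys = results["NT"].karyotypes + results["TUM"].karyotypes
        table = build_segment_event_table(karys)
        totals = segment_event_totals(table)
        bias = gain_loss_bias_test(totals["gain"], totals["loss"])
        assoc = wgd_aneuploidy_association(results["TUM"].karyotypes)
        bundle["nt_tum_events"] = totals
        bundle["gain_loss_bias"] = bias
        bundle["wgd_association"] = assoc

    if config.write_outputs and config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle, config: PipelineConfig):
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "package": "snkaryo",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "bin_size": config.bin_size,
        "n_sims": config.n_sims,
        "quantile": config.quantile,
        "cohorts": list(config.cohorts),
        "input_hashes": {},
        "outputs": [],
    }
    grid = bundle["grid"]
    for name, res in bundle["results"].items():
        paths = write_cohort(res.plan, res.counts, grid, config.out_dir)
        for key, p in paths.items():
            manifest["input_hashes"][os.path.basename(p)] = _sha256(p)
            manifest["outputs"].append(os.path.basename(p))
        for fname, frame in (
            (f"{name}_cn_matrix.tsv", profiles_to_frame(res.profiles, grid)),
            (f"{name}_karyotypes.tsv", karyotypes_to_frame(res.karyotypes)),
            (f"{name}_focal_events.tsv", focal_events_frame(res.karyotypes)),
            (f"{name}_hotspots.tsv", hotspots_to_frame(res.hotspots)),
            (f"{name}_cin.tsv", cin_report_frame(res.cin_reports)),
        ):
            out = os.path.join(config.out_dir, fname)
            frame.to_csv(out, sep="\t", index=False)
            manifest["outputs"].append(fname)
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, default=str)
    manifest["outputs"].append("summary.json")
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
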