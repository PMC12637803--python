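"""Synthetic single-nucleus binned read counts from explicit karyotype plans.

Emulates ultra-low-coverage (~0.15x) single-nucleus WGS: each nucleus has a
background ploidy (2n-5n), a list of copy-number events (whole chromosome,
whole unit, or focal), and read counts are drawn per retained bin from a
negative binomial whose expectation is proportional to the ground-truth copy
number under a library-size constraint (total expected reads do not depend
on ploidy -- relative coverage is all the assay sees, which is why the
simulator also emits a ``dna_content`` covariate standing in for the
DNA-stain signal used to sort nuclei).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import BinGrid, ChromosomeUnit, GenomeBuild, Interval

GROUPS = ("HC", "NT", "TUM")


@dataclass(frozen=True)
class KaryotypeEvent:
    """One planned copy-number event.

    scope: 'whole_chromosome' (target = chromosome name), 'whole_unit'
    (target = unit_id), or 'focal' (target = Interval spanning >= 3 bins).
    delta: signed copies added to the background.
    """

    scope: str
    target: Union[str, Interval]
    delta: int

    def __post_init__(self):
        if self.scope not in ("whole_chromosome", "whole_unit", "focal"):
            raise ValueError(f"unknown event scope {self.scope!r}")
        if self.delta == 0:
            raise ValueError("event delta must be non-zero")
        if self.scope == "focal" and not isinstance(self.target, Interval):
            raise ValueError("focal events target an Interval")


@dataclass
class NucleusPlan:
    nucleus_id: str
    subject_id: str
    group: str
    sex: str
    background_ploidy: int = 2
    events: list = field(default_factory=list)
    dna_content: Optional[float] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.background_ploidy not in (2, 3, 4, 5):
            raise ValueError("background ploidy must be 2..5")
        keys = [(e.scope, str(e.target)) for e in self.events]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.nucleus_id}: duplicate event targets")


@dataclass
class NoiseConfig:
    """Negative-binomial read-count noise.

    ``dispersion`` is the excess variance relative to Poisson as a fraction
    of the mean (NB1 convention): var = mu * (1 + dispersion). 0 gives the
    deterministic zero-noise limit.
    """

    mean_reads_per_bin: float = 100.0
    dispersion: float = 0.05
    seed: int = 123

    def __post_init__(self):
        if self.mean_reads_per_bin <= 0:
            raise ValueError("mean_reads_per_bin must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class CohortPlan:
    name: str
    nuclei: list
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self):
        ids = [n.nucleus_id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            raise ValueError("nucleus ids not unique")
        meta: dict = {}
        for n in self.nuclei:
            key = n.subject_id
            val = (n.group, n.sex)
            if meta.setdefault(key, val) != val:
                raise ValueError(f"inconsistent group/sex for subject {key}")


def x_baseline(sex: str, background_ploidy: int) -> int:
    """X copy number before events: females carry ``background`` copies,
    males half that, rounded up (2n male -> 1, 3n male -> 2)."""
    if sex == "F":
        return background_ploidy
    return max(1, (background_ploidy + 1) // 2)


def expand_plan_to_bin_cn(
    plan: NucleusPlan,
    units: Sequence[ChromosomeUnit],
    grid: BinGrid,
    build: Optional[GenomeBuild] = None,
) -> np.ndarray:
    """Ground-truth integer copy number per retained bin.

    Whole-chromosome events hit every retained bin of the chromosome,
    whole-unit events every bin of the unit, focal events only bins fully
    inside the interval. X bins start from the sex-specific baseline.
    """
    unit_by_id = {u.unit_id: u for u in units}
    chroms = grid.retained_chromosomes()
    cn = np.full(grid.n_retained, plan.background_ploidy, dtype=int)
    x_mask = chroms == "X"
    cn[x_mask] = x_baseline(plan.sex, plan.background_ploidy)

    starts = np.array([b.start for b, keep in zip(grid.bins, grid.retained) if keep])
    ends = np.array([b.end for b, keep in zip(grid.bins, grid.retained) if keep])

    for ev in plan.events:
        if ev.scope == "whole_chromosome":
            mask = chroms == str(ev.target)
            if not mask.any():
                raise ValueError(f"unknown chromosome {ev.target!r}")
        elif ev.scope == "whole_unit":
            if str(ev.target) in ("Xp", "Xq"):
                if build is None:
                    raise ValueError("X-arm events need the genome build")
                cen = build["X"].centromere
                span = (0, cen.start) if ev.target == "Xp" else (cen.end, build["X"].length)
                mid = (starts + ends) // 2
                mask = x_mask & (mid >= span[0]) & (mid < span[1])
            else:
                unit = unit_by_id.get(str(ev.target))
                if unit is None:
                    raise ValueError(f"unknown unit {ev.target!r}")
                mask = np.zeros(grid.n_retained, dtype=bool)
                mask[grid.retained_index_in_unit(unit)] = True
        else:  # focal
            iv = ev.target
            mask = (chroms == iv.chromosome) & (starts >= iv.start) & (ends <= iv.end)
            if mask.sum() < 3:
                raise ValueError(
                    f"focal event {iv} covers {int(mask.sum())} bins (< 3) at "
                    f"bin size {grid.bin_size}"
                )
        cn[mask] += ev.delta
    if (cn < 0).any():
        raise ValueError(f"{plan.nucleus_id}: events drive copy number below 0")
    return cn


@dataclass
class BinnedCounts:
    """Raw read counts per retained bin for one nucleus."""

    nucleus_id: str
    counts: np.ndarray
    grid: BinGrid

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.grid.n_retained:
            raise ValueError("counts length != retained bins")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() <= 0:
            raise ValueError("all-zero counts")


def simulate_counts(
    plan: NucleusPlan,
    units: Sequence[ChromosomeUnit],
    grid: BinGrid,
    noise: NoiseConfig,
    build: Optional[GenomeBuild] = None,
    rng: Optional[np.random.Generator] = None,
) -> BinnedCounts:
    """Draw one nucleus's binned counts.

    Expected count for bin b is ``mean_reads_per_bin * N * cn_b / sum(cn)``
    (library-size constrained), negative-binomial with the configured
    dispersion; ``dispersion == 0`` yields deterministic rounded
    expectations (zero-noise limit).
    """
    cn = expand_plan_to_bin_cn(plan, units, grid, build=build)
    total = cn.sum()
    if total == 0:
        raise ValueError("all-zero copy number")
    mu = noise.mean_reads_per_bin * grid.n_retained * cn / total
    if noise.dispersion == 0:
        counts = np.rint(mu).astype(int)
    else:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        # NB1: var = mu(1+d)  ->  size = mu/d, p = 1/(1+d)
        size = np.where(mu > 0, mu / noise.dispersion, 1.0)
        counts = np.where(
            mu > 0,
            rng.negative_binomial(size, 1.0 / (1.0 + noise.dispersion)),
            0,
        )
    return BinnedCounts(plan.nucleus_id, counts.astype(int), grid)


def simulate_cohort(
    plan: CohortPlan,
    units: Sequence[ChromosomeUnit],
    grid: BinGrid,
    build: Optional[GenomeBuild] = None,
) -> pd.DataFrame:
    """Counts for every nucleus in a cohort plan (retained bins x nuclei).

    One generator seeded from ``plan.noise.seed`` drives all nuclei in plan
    order, so the whole cohort is bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(plan.noise.seed)
    data = {}
    for nucleus in plan.nuclei:
        data[nucleus.nucleus_id] = simulate_counts(
            nucleus, units, grid, plan.noise, build=build, rng=rng
        ).counts
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Cohort I/O


def _bin_frame(grid: BinGrid) -> pd.DataFrame:
    rb = grid.retained_bins()
    return pd.DataFrame(
        {
            "chrom": [b.chromosome for b in rb],
            "start": [b.start for b in rb],
            "end": [b.end for b in rb],
        }
    )


def events_table(plan: CohortPlan) -> pd.DataFrame:
    """Long-format ground-truth event table for a cohort plan."""
    rows = []
    for n in plan.nuclei:
        for ev in n.events:
            if isinstance(ev.target, Interval):
                rows.append(
                    (n.nucleus_id, ev.scope, f"{ev.target.chromosome}:"
                     f"{ev.target.start}-{ev.target.end}",
                     ev.target.chromosome, ev.target.start, ev.target.end, ev.delta)
                )
            else:
                rows.append((n.nucleus_id, ev.scope, str(ev.target), "", -1, -1, ev.delta))
    return pd.DataFrame(
        rows,
        columns=["nucleus_id", "scope", "target", "chrom", "start", "end", "delta"],
    )


def write_cohort(plan: CohortPlan, counts: pd.DataFrame, grid: BinGrid, path: str) -> dict:
    """Write counts, metadata and ground-truth events as TSV; returns paths."""
    os.makedirs(path, exist_ok=True)
    paths = {
        "counts": os.path.join(path, f"{plan.name}_counts.tsv"),
        "metadata": os.path.join(path, f"{plan.name}_metadata.tsv"),
        "events": os.path.join(path, f"{plan.name}_events.tsv"),
    }
    out = pd.concat([_bin_frame(grid), counts.reset_index(drop=True)], axis=1)
    out.to_csv(paths["counts"], sep="\t", index=False)
    meta = pd.DataFrame(
        [
            (n.nucleus_id, n.subject_id, n.group, n.sex, n.background_ploidy, n.dna_content)
            for n in plan.nuclei
        ],
        columns=["nucleus_id", "subject_id", "group", "sex", "background_ploidy", "dna_content"],
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    events_table(plan).to_csv(paths["events"], sep="\t", index=False)
    return paths


def read_cohort(paths: dict):
    """Round-trip reader for :func:`write_cohort` output:
    returns (counts DataFrame, metadata DataFrame, events DataFrame)."""
    counts = pd.read_csv(paths["counts"], sep="\t")
    counts = counts.drop(columns=["chrom", "start", "end"])
    meta = pd.read_csv(paths["metadata"], sep="\t")
    events = pd.read_csv(
        paths["events"], sep="\t", keep_default_na=False,
        dtype={"chrom": str, "target": str},
    )
    return counts, meta, events
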