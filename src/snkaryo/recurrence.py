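"""Simulation-based recurrence null and recurrent-focal-region mapping.

Chromosome units altered more often than chance are identified against a
binomial null: each nucleus is assumed to alter any given unit with
probability 1/U (U = 38 units by default), alteration counts per unit are
simulated for the observed cohort size, and a unit is flagged when its
observed count exceeds the chosen quantile (default 90th percentile) of the
simulated counts. Both an empirical (add-one) tail probability against the
simulated draws and the exact binomial tail are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Interval, minimal_common_region
from .karyotype import NucleusKaryotype


@dataclass
class NullModelConfig:
    n_sims: int = 10_000
    p_unit: float = 1.0 / 38.0
    quantile: float = 0.90
    seed: int = 123

    def __post_init__(self):
        if not 0 < self.p_unit < 1:
            raise ValueError("p_unit must be in (0,1)")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0,1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class UnitRecurrence:
    unit_id: str
    n_altered: int
    n_nuclei: int

    def __post_init__(self):
        if not 0 <= self.n_altered <= self.n_nuclei:
            raise ValueError("n_altered out of range")


@dataclass
class HotspotResult:
    unit_id: str
    n_altered: int
    n_nuclei: int
    threshold: int
    empirical_p: float
    exact_binomial_p: float
    flagged: bool


def count_alterations_per_unit(
    karyotypes: Sequence[NucleusKaryotype],
    unit_ids: Sequence[str],
    include_focal: bool = True,
) -> list:
    """Number of nuclei with a non-neutral call (plus, by default, any focal
    event) on each unit."""
    n_nuclei = len(karyotypes)
    counts = {u: 0 for u in unit_ids}
    for k in karyotypes:
        altered = {c.unit_id for c in k.unit_calls if c.state != "neutral"}
        if include_focal:
            altered |= {ev.unit_id for ev in k.focal_events}
        for u in altered:
            if u in counts:
                counts[u] += 1
    return [UnitRecurrence(u, counts[u], n_nuclei) for u in unit_ids]


def simulate_null_draws(n_nuclei: int, cfg: NullModelConfig) -> np.ndarray:
    """The ``n_sims`` per-unit alteration counts drawn under the binomial
    null for a cohort of ``n_nuclei``."""
    rng = np.random.default_rng(cfg.seed)
    return rng.binomial(n_nuclei, cfg.p_unit, size=cfg.n_sims)


def simulate_null_threshold(
    n_nuclei: int, cfg: Optional[NullModelConfig] = None, draws: Optional[np.ndarray] = None
) -> int:
    """Nearest-rank quantile (default 90th percentile) of the simulated
    null counts; 0 nuclei trivially gives 0."""
    cfg = cfg or NullModelConfig()
    if n_nuclei == 0:
        return 0
    if draws is None:
        draws = simulate_null_draws(n_nuclei, cfg)
    return int(np.quantile(draws, cfg.quantile, method="inverted_cdf"))


def hotspot_test(
    recurrence: Sequence[UnitRecurrence],
    cfg: Optional[NullModelConfig] = None,
) -> list:
    """Flag units whose alteration count exceeds the simulated null
    threshold; report empirical and exact binomial tail probabilities."""
    cfg = cfg or NullModelConfig()
    if not recurrence:
        return []
    sizes = {r.n_nuclei for r in recurrence}
    if len(sizes) > 1:
        raise ValueError(f"inconsistent cohort sizes across units: {sorted(sizes)}")
    n_nuclei = sizes.pop()
    draws = simulate_null_draws(n_nuclei, cfg) if n_nuclei else np.zeros(cfg.n_sims, int)
    threshold = simulate_null_threshold(n_nuclei, cfg, draws=draws)
    out = []
    for r in recurrence:
        empirical_p = (1 + int((draws >= r.n_altered).sum())) / (cfg.n_sims + 1)
        exact_p = float(stats.binom.sf(r.n_altered - 1, n_nuclei, cfg.p_unit))
        out.append(
            HotspotResult(
                unit_id=r.unit_id,
                n_altered=r.n_altered,
                n_nuclei=n_nuclei,
                threshold=threshold,
                empirical_p=empirical_p,
                exact_binomial_p=exact_p,
                flagged=r.n_altered > threshold,
            )
        )
    return out


def hotspots_to_frame(results: Sequence[HotspotResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": h.unit_id,
                "n_altered": h.n_altered,
                "n_nuclei": h.n_nuclei,
                "threshold": h.threshold,
                "empirical_p": h.empirical_p,
                "exact_binomial_p": h.exact_binomial_p,
                "flagged": h.flagged,
            }
            for h in results
        ]
    )


def recurrent_focal_region(
    intervals: Sequence[Interval], min_support: int = 2
):
    """Minimal common region of focal-event intervals on one unit.

    Returns (Interval or None, support). Support is the number of events
    when the intersection chain is non-empty and >= min_support, else 0.
    """
    if not intervals:
        return None, 0
    region = minimal_common_region(list(intervals))
    if region is None or len(intervals) < min_support:
        return None, 0
    return region, len(intervals)


def read_gene_bed(path: str) -> pd.DataFrame:
    """BED4+ gene annotation -> DataFrame(chrom, start, end, name)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: gene BED needs >= 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty interval")
            rows.append((parts[0].removeprefix("chr"), start, end, parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def gene_overlap(
    region: Optional[Interval],
    annotation: pd.DataFrame,
    deduplicate: bool = False,
) -> pd.DataFrame:
    """Annotation records intersecting the region (0-based half-open),
    optionally deduplicated by gene name."""
    if region is None or annotation.empty:
        return annotation.iloc[0:0]
    hit = annotation[
        (annotation["chrom"] == region.chromosome)
        & (annotation["start"] < region.end)
        & (annotation["end"] > region.start)
    ]
    if deduplicate:
        hit = hit.drop_duplicates(subset="name")
    return hit.sort_values(["start", "end"]).reset_index(drop=True)
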