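"""Per-nucleus karyotype classification from integer copy-number profiles.

Each of the 38 autosomal chromosome units gets a call (loss / neutral /
gain) relative to the nucleus's modal ploidy; sub-arm deviant runs become
focal events; the nucleus is assigned one of seven karyotype categories
(euploid 2n; arm-level, chromosome-level, or both on a diploid background;
pure polyploid; arm-level or arm+chromosome on a polyploid background);
and X dosage is called separately against a sex-specific baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calling import CopyNumberProfile
from .genome import ChromosomeUnit, GenomeBuild, Interval

#: Fraction of a unit's retained bins that must share the deviant copy
#: number for a whole-unit (arm/chromosome) call; shorter deviant runs are
#: focal events.
WHOLE_UNIT_FRAC = 0.8


class Category(str, Enum):
    EUPLOID_2N = "EUPLOID_2N"
    ARM_2N = "ARM_2N"
    CHR_2N = "CHR_2N"
    ARM_CHR_2N = "ARM_CHR_2N"
    POLYPLOID_ONLY = "POLYPLOID_ONLY"
    ARM_POLYPLOID = "ARM_POLYPLOID"
    ARM_CHR_POLYPLOID = "ARM_CHR_POLYPLOID"


#: Category order used in printed tally tables.
CATEGORY_ORDER = [c.value for c in Category]


class XCall(str, Enum):
    NEUTRAL = "neutral"
    LOX = "LoX"
    X_GAIN = "X_gain"
    XP_GAIN = "Xp_gain"
    ANOMALY = "anomaly"


@dataclass
class UnitCall:
    unit_id: str
    integer_cn: int  # dominant CN over the unit's retained bins
    state: str  # 'loss' | 'neutral' | 'gain', relative to modal ploidy
    covered_fraction: float  # fraction of the unit's bins at integer_cn


@dataclass
class FocalEvent:
    interval: Interval
    delta: int  # signed copies relative to modal ploidy
    unit_id: str
    n_bins: int


@dataclass
class NucleusKaryotype:
    nucleus_id: str
    modal_ploidy: int
    unit_calls: list
    focal_events: list
    category: Category
    n_gains: int
    n_losses: int
    wgd: bool
    x_call: Optional[XCall] = None
    subject_id: Optional[str] = None
    group: Optional[str] = None
    sex: Optional[str] = None

    @property
    def is_aneuploid(self) -> bool:
        """Aneuploid for cohort summaries: any non-euploid-diploid category
        or any called focal event (X dosage is assessed separately)."""
        return self.category != Category.EUPLOID_2N or bool(self.focal_events)


def call_units(
    profile: CopyNumberProfile,
    units: Sequence[ChromosomeUnit],
    whole_unit_frac: float = WHOLE_UNIT_FRAC,
    min_bins: int = 3,
):
    """Per-unit dominant-CN calls plus sub-arm focal events.

    A unit is non-neutral when its dominant CN differs from the modal
    ploidy over >= ``whole_unit_frac`` of its retained bins. Contiguous
    deviant runs of >= ``min_bins`` bins covering less than that fraction
    are emitted as focal events.
    """
    grid = profile.grid
    rb = grid.retained_bins()
    unit_calls = []
    focal_events = []
    for unit in units:
        idx = grid.retained_index_in_unit(unit)
        if len(idx) == 0:
            warnings.warn(f"unit {unit.unit_id} has no retained bins; skipped", stacklevel=2)
            continue
        cn = profile.cn[idx]
        vals, counts = np.unique(cn, return_counts=True)
        dominant = int(vals[np.argmax(counts)])
        covered = float(counts.max() / len(idx))
        if dominant != profile.modal_ploidy and covered >= whole_unit_frac:
            state = "gain" if dominant > profile.modal_ploidy else "loss"
            call_cn = dominant
        else:
            # insufficient coverage for a whole-unit call: neutral at modal
            state = "neutral"
            call_cn = profile.modal_ploidy
            at_modal = counts[vals == call_cn]
            covered = float(at_modal[0] / len(idx)) if len(at_modal) else 1.0 / len(idx)
        unit_calls.append(UnitCall(unit.unit_id, call_cn, state, covered))
        if state == "neutral":
            # deviant runs inside a neutral unit -> focal events
            deviant = cn != profile.modal_ploidy
            for run_start, run_end in _runs(deviant):
                length = run_end - run_start
                if length >= min_bins and length < whole_unit_frac * len(idx):
                    lo = rb[idx[run_start]]
                    hi = rb[idx[run_end - 1]]
                    run_cn = int(np.bincount(cn[run_start:run_end]).argmax())
                    focal_events.append(
                        FocalEvent(
                            interval=Interval(unit.chromosome, lo.start, hi.end),
                            delta=run_cn - profile.modal_ploidy,
                            unit_id=unit.unit_id,
                            n_bins=length,
                        )
                    )
    return unit_calls, focal_events


def _runs(mask: np.ndarray):
    """(start, end) half-open index pairs of True runs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def chromosome_level_units(
    unit_calls: Sequence[UnitCall], units: Sequence[ChromosomeUnit]
) -> set:
    """Unit ids participating in chromosome-level aneuploidy: both arms of
    a two-armed chromosome non-neutral in the same direction with equal CN,
    or any non-neutral acrocentric whole-chromosome unit."""
    by_id = {u.unit_id: u for u in units}
    calls = {c.unit_id: c for c in unit_calls}
    out = set()
    by_chrom: dict = {}
    for c in unit_calls:
        unit = by_id[c.unit_id]
        if unit.acrocentric_whole:
            if c.state != "neutral":
                out.add(c.unit_id)
        else:
            by_chrom.setdefault(unit.chromosome, []).append(c)
    for chrom, arm_calls in by_chrom.items():
        if len(arm_calls) == 2:
            a, b = arm_calls
            if (
                a.state != "neutral"
                and a.state == b.state
                and a.integer_cn == b.integer_cn
            ):
                out.update((a.unit_id, b.unit_id))
    return out


def classify_nucleus(
    modal_ploidy: int,
    unit_calls: Sequence[UnitCall],
    units: Sequence[ChromosomeUnit],
) -> Category:
    """Assign the karyotype category from unit calls and modal ploidy."""
    chrom_level = chromosome_level_units(unit_calls, units)
    non_neutral = [c for c in unit_calls if c.state != "neutral"]
    has_chr = any(c.unit_id in chrom_level for c in non_neutral)
    has_arm = any(c.unit_id not in chrom_level for c in non_neutral)
    if modal_ploidy == 2:
        if not non_neutral:
            return Category.EUPLOID_2N
        if has_arm and has_chr:
            return Category.ARM_CHR_2N
        return Category.CHR_2N if has_chr else Category.ARM_2N
    if not non_neutral:
        return Category.POLYPLOID_ONLY
    return Category.ARM_CHR_POLYPLOID if has_chr else Category.ARM_POLYPLOID


def call_x_dosage(
    profile: CopyNumberProfile,
    sex: Optional[str],
    build: GenomeBuild,
    whole_unit_frac: float = WHOLE_UNIT_FRAC,
) -> Optional[XCall]:
    """X-dosage call against the sex-specific baseline.

    Baseline is the modal ploidy for females and half of it (rounded up)
    for males; whole-X departure below baseline is LoX in females and an
    anomaly in males; departure above is X gain, or Xp gain when only the
    p arm is elevated.
    """
    if sex not in ("F", "M"):
        warnings.warn("sex missing; X call omitted", stacklevel=2)
        return None
    grid = profile.grid
    xidx = grid.retained_index_on_chromosome("X")
    if len(xidx) == 0:
        return None
    baseline = profile.modal_ploidy if sex == "F" else max(1, (profile.modal_ploidy + 1) // 2)
    cen = build["X"].centromere
    rb = grid.retained_bins()
    mids = np.array([(rb[i].start + rb[i].end) // 2 for i in xidx])
    cn = profile.cn[xidx]

    def dominant(mask):
        if not mask.any():
            return baseline, 1.0
        vals, counts = np.unique(cn[mask], return_counts=True)
        return int(vals[np.argmax(counts)]), float(counts.max() / mask.sum())

    whole_cn, whole_frac = dominant(np.ones(len(xidx), bool))
    if whole_frac >= whole_unit_frac and whole_cn != baseline:
        if whole_cn < baseline:
            return XCall.LOX if sex == "F" else XCall.ANOMALY
        return XCall.X_GAIN
    p_cn, p_frac = dominant(mids < cen.start)
    q_cn, q_frac = dominant(mids >= cen.end)
    if p_frac >= whole_unit_frac and p_cn > baseline and q_cn == baseline:
        return XCall.XP_GAIN
    if p_frac >= whole_unit_frac and q_frac >= whole_unit_frac and (p_cn != baseline or q_cn != baseline):
        return XCall.ANOMALY
    return XCall.NEUTRAL


def karyotype_nucleus(
    profile: CopyNumberProfile,
    units: Sequence[ChromosomeUnit],
    build: GenomeBuild,
    sex: Optional[str] = None,
    subject_id: Optional[str] = None,
    group: Optional[str] = None,
    whole_unit_frac: float = WHOLE_UNIT_FRAC,
    min_bins: int = 3,
) -> NucleusKaryotype:
    """Full karyotype for one nucleus: unit calls, focal events, category,
    gain/loss tallies, WGD flag, X call."""
    unit_calls, focal_events = call_units(
        profile, units, whole_unit_frac=whole_unit_frac, min_bins=min_bins
    )
    category = classify_nucleus(profile.modal_ploidy, unit_calls, units)
    n_gains = sum(1 for c in unit_calls if c.state == "gain")
    n_losses = sum(1 for c in unit_calls if c.state == "loss")
    return NucleusKaryotype(
        nucleus_id=profile.nucleus_id,
        modal_ploidy=profile.modal_ploidy,
        unit_calls=unit_calls,
        focal_events=focal_events,
        category=category,
        n_gains=n_gains,
        n_losses=n_losses,
        wgd=profile.modal_ploidy >= 3,
        x_call=call_x_dosage(profile, sex, build, whole_unit_frac=whole_unit_frac),
        subject_id=subject_id,
        group=group,
        sex=sex,
    )


def karyotype_cohort(
    profiles: dict,
    units: Sequence[ChromosomeUnit],
    build: GenomeBuild,
    metadata: Optional[pd.DataFrame] = None,
    **kwargs,
) -> list:
    """Karyotype every profile; metadata (nucleus_id, subject_id, group,
    sex) is joined in when provided."""
    meta = {}
    if metadata is not None:
        meta = metadata.set_index("nucleus_id").to_dict("index")
    out = []
    for nid, prof in profiles.items():
        m = meta.get(nid, {})
        out.append(
            karyotype_nucleus(
                prof,
                units,
                build,
                sex=m.get("sex"),
                subject_id=m.get("subject_id"),
                group=m.get("group"),
                **kwargs,
            )
        )
    return out


def tally_gains_losses(karyotypes: Sequence[NucleusKaryotype]):
    """Cohort-wide gain/loss tallies of non-neutral unit calls.

    Returns (n_gains, n_losses, per-unit direction table). The table has
    one row per unit with gain/loss counts; nuclei are also summarized as
    gain-only / loss-only / mixed.
    """
    n_gains = sum(k.n_gains for k in karyotypes)
    n_losses = sum(k.n_losses for k in karyotypes)
    rows: dict = {}
    direction = {"gain_only": 0, "loss_only": 0, "mixed": 0}
    for k in karyotypes:
        for c in k.unit_calls:
            if c.state == "neutral":
                continue
            r = rows.setdefault(c.unit_id, {"gain": 0, "loss": 0})
            r[c.state] += 1
        if k.n_gains and k.n_losses:
            direction["mixed"] += 1
        elif k.n_gains:
            direction["gain_only"] += 1
        elif k.n_losses:
            direction["loss_only"] += 1
    table = pd.DataFrame(
        [(u, v["gain"], v["loss"]) for u, v in sorted(rows.items())],
        columns=["unit_id", "gains", "losses"],
    )
    return n_gains, n_losses, table, direction


def category_tally(karyotypes: Sequence[NucleusKaryotype]) -> dict:
    """Counts per karyotype category, in printed-table order."""
    out = {c: 0 for c in CATEGORY_ORDER}
    for k in karyotypes:
        out[k.category.value] += 1
    return out


def karyotypes_to_frame(karyotypes: Sequence[NucleusKaryotype]) -> pd.DataFrame:
    """Per-nucleus summary table."""
    return pd.DataFrame(
        [
            {
                "nucleus_id": k.nucleus_id,
                "subject_id": k.subject_id,
                "group": k.group,
                "sex": k.sex,
                "modal_ploidy": k.modal_ploidy,
                "category": k.category.value,
                "n_gains": k.n_gains,
                "n_losses": k.n_losses,
                "n_focal": len(k.focal_events),
                "wgd": k.wgd,
                "aneuploid": k.is_aneuploid,
                "x_call": k.x_call.value if k.x_call else "",
            }
            for k in karyotypes
        ]
    )


def unit_cn_matrix(
    karyotypes: Sequence[NucleusKaryotype],
) -> pd.DataFrame:
    """Per-unit integer CN vectors (nuclei x units), for distance and
    heterogeneity metrics."""
    data = {}
    for k in karyotypes:
        data[k.nucleus_id] = {c.unit_id: c.integer_cn for c in k.unit_calls}
    return pd.DataFrame(data).T


def focal_events_frame(karyotypes: Sequence[NucleusKaryotype]) -> pd.DataFrame:
    rows = []
    for k in karyotypes:
        for ev in k.focal_events:
            rows.append(
                {
                    "nucleus_id": k.nucleus_id,
                    "subject_id": k.subject_id,
                    "unit_id": ev.unit_id,
                    "chrom": ev.interval.chromosome,
                    "start": ev.interval.start,
                    "end": ev.interval.end,
                    "delta": ev.delta,
                    "n_bins": ev.n_bins,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["nucleus_id", "subject_id", "unit_id", "chrom", "start", "end", "delta", "n_bins"],
    )
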