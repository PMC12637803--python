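"""Genome build, chromosome-unit scheme, bin grid and interval arithmetic.

Everything downstream works on a fixed tiling of the reference genome into
equal-sized bins (default 500 kb) and a configurable set of *chromosome
units* -- the p and q arms of the two-armed autosomes plus one
whole-chromosome unit for each acrocentric autosome (13, 14, 15, 21, 22).
The default scheme excludes unit 6p, leaving 38 autosomal units, which is
the granularity at which aneuploidy calls, recurrence counts and the
binomial null model operate.

Coordinate conventions: all internal coordinates are 0-based half-open;
BED I/O is 0-based half-open; human-readable rendering is 1-based
inclusive (``chr16:14,817,633-16,845,164``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

DEFAULT_BIN_SIZE = 500_000
DEFAULT_EXCLUDED_UNITS = ("6p",)
#: Telomeric gap blacklisted at each chromosome end (GRCh37 gap annotation).
TELOMERE_GAP = 10_000


# ---------------------------------------------------------------------------
# Intervals


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chromosome}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def render(self) -> str:
        """1-based inclusive rendering matching printed report coordinates."""
        return f"chr{self.chromosome}:{self.start + 1:,}–{self.end:,}"


def intersect(a: Optional[Interval], b: Optional[Interval]) -> Optional[Interval]:
    """Intersection of two intervals; ``None`` when disjoint or on
    different chromosomes."""
    if a is None or b is None:
        return None
    if a.chromosome != b.chromosome:
        return None
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if start >= end:
        return None
    return Interval(a.chromosome, start, end)


def minimal_common_region(intervals: Sequence[Interval]) -> Optional[Interval]:
    """Fold of :func:`intersect` over a non-empty list of intervals on one
    chromosome -- the smallest genomic span shared by all of them."""
    if not intervals:
        raise ValueError("minimal_common_region requires at least one interval")
    chroms = {iv.chromosome for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    region: Optional[Interval] = intervals[0]
    for iv in intervals[1:]:
        region = intersect(region, iv)
        if region is None:
            return None
    return region


def length_mb(iv: Optional[Interval], decimals: int = 2) -> float:
    """Interval length in megabases, rounded.

    Uses the difference of the printed (1-based inclusive) endpoints, i.e.
    ``end - (start + 1)``, so that the rendered coordinates of an interval
    and its reported Mb length agree; an empty interval measures 0.
    """
    if iv is None:
        return 0.0
    return round((iv.end - iv.start - 1) / 1e6, decimals)


# ---------------------------------------------------------------------------
# Genome build


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: Interval


@dataclass(frozen=True)
class GenomeBuild:
    assembly_id: str
    chromosomes: tuple  # tuple[Chromosome, ...] in declaration order
    acrocentric: frozenset

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        for c in self.chromosomes:
            if c.length <= 0:
                raise ValueError(f"chromosome {c.name} has non-positive length")
            if not (0 <= c.centromere.start < c.centromere.end <= c.length):
                raise ValueError(f"centromere of {c.name} outside chromosome")

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [c.name for c in self.chromosomes]

    def autosomes(self) -> list:
        return [c for c in self.chromosomes if c.name not in ("X", "Y")]


def load_build(path: Optional[str] = None) -> GenomeBuild:
    """Load a genome build from JSON (default: packaged GRCh37)."""
    if path is None:
        text = (
            resources.files("snkaryo.data").joinpath("grch37.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    chroms = tuple(
        Chromosome(
            name=c["name"],
            length=int(c["length"]),
            centromere=Interval(c["name"], int(c["centromere"][0]), int(c["centromere"][1])),
        )
        for c in raw["chromosomes"]
    )
    return GenomeBuild(
        assembly_id=raw.get("assembly_id", "custom"),
        chromosomes=chroms,
        acrocentric=frozenset(raw.get("acrocentric", [])),
    )


# ---------------------------------------------------------------------------
# Chromosome units


@dataclass(frozen=True)
class ChromosomeUnit:
    unit_id: str
    chromosome: str
    span: Interval
    acrocentric_whole: bool = False


def build_default_units(
    build: GenomeBuild,
    excluded_unit_ids: Sequence[str] = DEFAULT_EXCLUDED_UNITS,
    expected_count: Optional[int] = 38,
) -> list:
    """p/q units for two-armed autosomes plus whole-chromosome units for the
    acrocentrics, in karyotype order, minus ``excluded_unit_ids``.

    With the default exclusion (6p) this yields the 38 autosomal units used
    throughout; a different count under a custom configuration only warns.
    """
    units: list = []
    for chrom in build.autosomes():
        if chrom.name in build.acrocentric:
            units.append(
                ChromosomeUnit(
                    unit_id=chrom.name,
                    chromosome=chrom.name,
                    span=Interval(chrom.name, 0, chrom.length),
                    acrocentric_whole=True,
                )
            )
        else:
            units.append(
                ChromosomeUnit(
                    unit_id=f"{chrom.name}p",
                    chromosome=chrom.name,
                    span=Interval(chrom.name, 0, chrom.centromere.start),
                )
            )
            units.append(
                ChromosomeUnit(
                    unit_id=f"{chrom.name}q",
                    chromosome=chrom.name,
                    span=Interval(chrom.name, chrom.centromere.end, chrom.length),
                )
            )
    known = {u.unit_id for u in units}
    unknown = set(excluded_unit_ids) - known
    if unknown:
        raise ValueError(f"unknown excluded unit ids: {sorted(unknown)}")
    units = [u for u in units if u.unit_id not in set(excluded_unit_ids)]
    if expected_count is not None and len(units) != expected_count:
        warnings.warn(
            f"unit scheme has {len(units)} units, expected {expected_count}",
            stacklevel=2,
        )
    return units


def x_units(build: GenomeBuild) -> list:
    """Xp/Xq units (kept out of the default autosomal scheme)."""
    x = build["X"]
    return [
        ChromosomeUnit("Xp", "X", Interval("X", 0, x.centromere.start)),
        ChromosomeUnit("Xq", "X", Interval("X", x.centromere.end, x.length)),
    ]


def load_units(path: str) -> list:
    """Load a custom unit scheme from JSON:
    ``[{unit_id, chromosome, start, end, acrocentric_whole}, ...]``."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        ChromosomeUnit(
            unit_id=u["unit_id"],
            chromosome=u["chromosome"],
            span=Interval(u["chromosome"], int(u["start"]), int(u["end"])),
            acrocentric_whole=bool(u.get("acrocentric_whole", False)),
        )
        for u in raw
    ]


# ---------------------------------------------------------------------------
# Bin grid


@dataclass
class BinGrid:
    """Fixed tiling of the genome into ``bin_size`` bins.

    ``retained`` masks out bins overlapping the blacklist; all per-nucleus
    count and copy-number vectors are indexed by retained bin.
    """

    bin_size: int
    bins: list  # list[Interval], genome order
    retained: np.ndarray  # bool per bin

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=bool)
        if len(self.retained) != len(self.bins):
            raise ValueError("retained mask length != number of bins")
        self._chrom = np.array([b.chromosome for b in self.bins])
        self._mid = np.array([(b.start + b.end) // 2 for b in self.bins])

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def retained_bins(self) -> list:
        return [b for b, keep in zip(self.bins, self.retained) if keep]

    def retained_chromosomes(self) -> np.ndarray:
        """Chromosome name per retained bin, in genome order."""
        return self._chrom[self.retained]

    def retained_index_in_unit(self, unit: ChromosomeUnit) -> np.ndarray:
        """Indices (into the retained-bin vector) of bins whose midpoint
        falls inside the unit span."""
        chrom = self._chrom[self.retained]
        mid = self._mid[self.retained]
        mask = (chrom == unit.chromosome) & (mid >= unit.span.start) & (mid < unit.span.end)
        return np.flatnonzero(mask)

    def retained_index_on_chromosome(self, name: str) -> np.ndarray:
        return np.flatnonzero(self._chrom[self.retained] == name)


def default_blacklist(build: GenomeBuild) -> list:
    """Centromere plus telomeric-gap intervals for every chromosome.

    Mirrors the packaged ``blacklist_grch37.bed``; users may supply their own
    BED instead.
    """
    out = []
    for c in build.chromosomes:
        out.append(Interval(c.name, 0, TELOMERE_GAP))
        out.append(c.centromere)
        out.append(Interval(c.name, c.length - TELOMERE_GAP, c.length))
    return out


def read_bed(path: str) -> list:
    """Read BED3+ into intervals (leading ``chr`` stripped from names)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            chrom = parts[0].removeprefix("chr")
            out.append(Interval(chrom, start, end))
    return out


def make_bins(
    build: GenomeBuild,
    bin_size: int = DEFAULT_BIN_SIZE,
    blacklist: Optional[Sequence[Interval]] = None,
) -> BinGrid:
    """Tile every chromosome left-to-right into ``bin_size`` bins (last bin
    of a chromosome may be short) and mask bins overlapping the blacklist."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not build.chromosomes:
        raise ValueError("empty genome build")
    if blacklist is None:
        blacklist = default_blacklist(build)
    by_chrom: dict = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chromosome, []).append(iv)

    bins: list = []
    retained: list = []
    for chrom in build.chromosomes:
        n = math.ceil(chrom.length / bin_size)
        black = by_chrom.get(chrom.name, [])
        for i in range(n):
            b = Interval(chrom.name, i * bin_size, min((i + 1) * bin_size, chrom.length))
            bins.append(b)
            retained.append(not any(b.overlaps(iv) for iv in black))
    return BinGrid(bin_size=bin_size, bins=bins, retained=np.asarray(retained, bool))
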