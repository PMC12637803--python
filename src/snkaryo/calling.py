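"""Integer copy-number calling from binned counts.

A minimal, self-contained equivalent of the binned single-cell CNV calling
stage: mean-normalize the counts, segment each chromosome, scan a grid of
ploidy multipliers for the one that makes all segment means land on integers
(lowest sum-of-squares to the nearest integer), and round.

Segmentation is two-pass. Recursive binary splitting on a standardized
mean-gap statistic captures arm- and chromosome-scale structure; it has no
power for events a few bins long (a 5-bin dip moves the mean of half a
chromosome by ~1%), so each resulting segment is then scanned for short
interior windows (3 to ``max_focal_bins`` bins) whose mean deviates from the
rest of the segment, using a variance model proportional to the local level
(counts are close to Poisson at this depth) and conservative acceptance so
that a euploid genome essentially never yields a false focal segment.

An optional DNA-content covariate (the stain signal used to sort nuclei)
breaks the inherent aliasing of relative coverage: a flat profile is equally
consistent with 2n, 3n, 4n, ...; without the covariate the smallest
consistent ploidy is reported.

Externally-called integer CN matrices can be supplied downstream instead;
nothing after this module depends on how the profile was produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import BinGrid
from .simulate import BinnedCounts

#: Ploidy-multiplier grid searched by :func:`fit_ploidy`.
PLOIDY_GRID = np.round(np.arange(1.50, 6.0001, 0.05), 2)
#: Relative sum-of-squares tolerance for near-optimal multipliers.
SSE_REL_TOL = 1.05
#: A multiplier is integer-consistent when segment means covering >= 95% of
#: well-supported bins land within this distance of an integer copy number
#: (bin-weighted majority: one noisy short segment cannot veto the true
#: ploidy, while an alias that misplaces a whole arm is rejected).
INTEGER_CONSISTENCY_TOL = 0.2
CONSISTENCY_BIN_FRACTION = 0.95
#: ... and its per-bin sse must stay below this (rms deviation ~0.07): a
#: true ploidy under read noise scores ~0.001, a coherent wrong alias that
#: parks every segment 0.1-0.2 away from integers scores ~0.02.
CONSISTENCY_MAX_SSE_PER_BIN = 0.005
#: Minimum bins for a segment to vote in the integer-consistency check.
CONSISTENCY_MIN_BINS = 8

MIN_RETAINED_BINS = 50
#: Acceptance threshold (standard errors) for the short-window focal scan;
#: calibrated so a euploid genome at default noise yields ~0 false windows
#: while 4-5-bin heterozygous deletions are found essentially always.
FOCAL_PENALTY = 6.5
#: Largest event (bins) searched by the window scan; longer events are the
#: binary-split pass's job.
MAX_FOCAL_BINS = 24
#: Binary splits that would create a side shorter than this need to clear
#: FOCAL_PENALTY instead of the ordinary penalty: noise-selected micro
#: fragments otherwise round to spurious copy numbers.
SHORT_SIDE_BINS = 12


@dataclass
class NormalizedProfile:
    nucleus_id: str
    ratios: np.ndarray
    grid: BinGrid
    mean_count: float = 1.0  # mean raw count per retained bin

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        if abs(self.ratios.mean() - 1.0) > 1e-9:
            raise ValueError("normalized ratios must average to 1")


@dataclass
class Segment:
    chromosome: str
    start_idx: int  # retained-bin index, genome-wide
    end_idx: int  # half-open
    mean_ratio: float
    integer_cn: Optional[int] = None

    @property
    def n_bins(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class PloidyFit:
    multiplier: float
    sse: float
    candidates: np.ndarray = field(default_factory=lambda: np.array([]))
    used_dna_content: bool = False


@dataclass
class CopyNumberProfile:
    nucleus_id: str
    cn: np.ndarray  # integer CN per retained bin
    segments: list
    modal_ploidy: int
    grid: BinGrid
    fit: Optional[PloidyFit] = None


def normalize(counts: BinnedCounts, min_bins: int = MIN_RETAINED_BINS) -> NormalizedProfile:
    """Counts divided by their mean over retained bins."""
    c = np.asarray(counts.counts, dtype=float)
    if len(c) < min_bins:
        raise ValueError(f"need >= {min_bins} retained bins, got {len(c)}")
    mean = c.mean()
    if mean <= 0:
        raise ValueError("all-zero counts")
    return NormalizedProfile(counts.nucleus_id, c / mean, counts.grid, mean_count=float(mean))


def _sigma_from_diffs(x: np.ndarray) -> float:
    """Robust per-bin noise scale from successive differences."""
    if len(x) < 2:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6744897501960817 / np.sqrt(2.0))


def _best_split(x: np.ndarray, sigma: float, min_bins: int):
    """Best single split by the standardized mean-gap statistic.

    Returns (index, statistic); index i splits x into x[:i], x[i:]. With
    sigma == 0 (noiseless input) any nonzero gap is infinitely significant;
    the argmax is then taken on the raw standardized gap with a tiny scale
    so the largest gap still wins.
    """
    n = len(x)
    if n < 2 * min_bins:
        return None, 0.0
    cs = np.cumsum(x)
    total = cs[-1]
    i = np.arange(min_bins, n - min_bins + 1)
    mean_l = cs[i - 1] / i
    mean_r = (total - cs[i - 1]) / (n - i)
    gap = np.abs(mean_l - mean_r)
    se = np.sqrt(1.0 / i + 1.0 / (n - i))
    stat = gap / (max(sigma, 1e-12) * se)
    k = int(np.argmax(stat))
    return int(i[k]), float(stat[k])


def _split_binary(x, offset, sigma, min_bins, penalty, focal_penalty, out):
    idx, stat = _best_split(x, sigma, min_bins)
    accept = idx is not None and stat > penalty
    if accept and min(idx, len(x) - idx) < SHORT_SIDE_BINS:
        accept = stat > focal_penalty
    if not accept:
        out.append((offset, offset + len(x)))
        return
    _split_binary(x[:idx], offset, sigma, min_bins, penalty, focal_penalty, out)
    _split_binary(x[idx:], offset + idx, sigma, min_bins, penalty, focal_penalty, out)


def _best_window(x: np.ndarray, var_scale: float, min_bins: int, max_len: int):
    """Most deviant interior window of x by a variance-weighted gap
    statistic (variance proportional to level: var(bin) = var_scale * level).

    Returns (i, j, z) with the window x[i:j].
    """
    n = len(x)
    best = (None, None, 0.0)
    if n < min_bins + 8:
        return best
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    for length in range(min_bins, min(max_len, n - 8) + 1):
        i = np.arange(0, n - length + 1)
        s_w = cs[i + length] - cs[i]
        mean_w = s_w / length
        mean_r = (total - s_w) / (n - length)
        v_w = var_scale * np.maximum(mean_w, 0.05 * mean_r.mean() + 1e-12)
        v_r = var_scale * np.maximum(mean_r, 1e-12)
        z = np.abs(mean_w - mean_r) / np.sqrt(v_w / length + v_r / (n - length))
        k = int(np.argmax(z))
        if z[k] > best[2]:
            best = (int(i[k]), int(i[k] + length), float(z[k]))
    return best


def _refine_window(x: np.ndarray, i: int, j: int, var_scale: float, pad: int = 5):
    """ML boundary refinement under a two-level Gaussian model with
    level-proportional variance var(bin) = var_scale * level."""
    n = len(x)
    best = None
    for i2 in range(max(0, i - pad), min(i + pad, j - 1) + 1):
        for j2 in range(max(i2 + 2, j - pad), min(n, j + pad) + 1):
            w = x[i2:j2]
            rest = np.concatenate([x[:i2], x[j2:]])
            if len(rest) < 2:
                continue
            mw, mr = max(w.mean(), 1e-9), max(rest.mean(), 1e-9)
            misfit = ((w - mw) ** 2).sum() / mw + ((rest - mr) ** 2).sum() / mr
            ll = -misfit / (2.0 * max(var_scale, 1e-12)) - 0.5 * (
                len(w) * np.log(mw) + len(rest) * np.log(mr)
            )
            if best is None or ll > best[0]:
                best = (ll, i2, j2)
    return best[1], best[2]


def _scan_focal(x, offset, var_scale, min_bins, focal_penalty, max_len, out, depth=0):
    """Recursively peel off significant short windows inside a segment."""
    i, j, z = _best_window(x, var_scale, min_bins, max_len)
    if i is None or z <= focal_penalty or depth > 6:
        out.append((offset, offset + len(x)))
        return
    i, j = _refine_window(x, i, j, var_scale)
    if i > 0:
        _scan_focal(x[:i], offset, var_scale, min_bins, focal_penalty, max_len, out, depth + 1)
    out.append((offset + i, offset + j))
    if j < len(x):
        _scan_focal(x[j:], offset + j, var_scale, min_bins, focal_penalty, max_len, out, depth + 1)


def _polish_short_segments(
    x: np.ndarray, bounds: list, var_scale: float, min_bins: int, max_len: int
) -> list:
    """Re-fit the boundaries of short segments by local two-level ML.

    The binary pass can capture a strong short event with boundaries off by
    a few bins (its split statistic is not a boundary estimator); each short
    segment is re-refined jointly with its flanking neighborhood.
    """
    polished = sorted(bounds)
    for k in range(len(polished)):
        a, b = polished[k]
        if not (min_bins <= b - a <= max_len):
            continue
        lo = polished[k - 1][0] if k > 0 else a
        hi = polished[k + 1][1] if k + 1 < len(polished) else b
        if hi - lo <= b - a:  # no flanking context
            continue
        pad = max(5, b - a)  # boundaries can be off by the event's own size
        i, j = _refine_window(x[lo:hi], a - lo, b - lo, var_scale, pad=pad)
        i, j = lo + i, lo + j
        if k == 0:  # outer boundaries are fixed: no neighbor to absorb them
            i = a
        if k + 1 == len(polished):
            j = b
        if j - i < min_bins or (i, j) == (a, b):
            continue
        polished[k] = (i, j)
        if k > 0:
            polished[k - 1] = (polished[k - 1][0], i)
        if k + 1 < len(polished):
            polished[k + 1] = (j, polished[k + 1][1])
    return [(a, b) for a, b in polished if b > a]


def segment_profile(
    norm: NormalizedProfile,
    min_bins: int = 3,
    penalty: float = 3.0,
    focal_penalty: float = FOCAL_PENALTY,
    max_focal_bins: int = MAX_FOCAL_BINS,
) -> list:
    """Segment a normalized profile, independently per chromosome.

    Pass 1: recursive binary splits accepted when the standardized gap
    between the flanking means exceeds ``penalty`` (noise scale estimated
    robustly from genome-wide successive differences). Pass 2: each segment
    is scanned for deviant interior windows of ``min_bins`` to
    ``max_focal_bins`` bins accepted above ``focal_penalty`` standard
    errors. Deterministic; depends only on genome order.
    """
    chroms = norm.grid.retained_chromosomes()
    sigma = _sigma_from_diffs(norm.ratios)
    # variance of a ratio ~ var_scale * level; mean_count rescales ratio
    # noise back to the count scale where the Poisson-like model lives
    var_scale = sigma**2 if sigma > 0 else 0.0
    segments: list = []
    for chrom in dict.fromkeys(chroms):  # preserve genome order
        idx = np.flatnonzero(chroms == chrom)
        x = norm.ratios[idx]
        pieces: list = []
        _split_binary(x, 0, sigma, min_bins, penalty, focal_penalty, pieces)
        refined: list = []
        for a, b in pieces:
            if var_scale > 0:
                _scan_focal(
                    x[a:b], a, var_scale, min_bins, focal_penalty, max_focal_bins, refined
                )
            else:
                refined.append((a, b))
        if var_scale > 0:
            refined = _polish_short_segments(x, refined, var_scale, min_bins, max_focal_bins)
        for a, b in sorted(refined):
            segments.append(
                Segment(chrom, int(idx[0]) + a, int(idx[0]) + b, float(x[a:b].mean()))
            )
    return segments


def fit_ploidy(
    segments: Sequence[Segment],
    dna_content: Optional[float] = None,
    grid_values: np.ndarray = PLOIDY_GRID,
) -> PloidyFit:
    """Grid-search the ploidy multiplier mapping segment mean ratios onto
    integer copy numbers.

    sse(m) = sum over bins of (m * segment_mean - nearest integer)^2. The
    candidate set contains every multiplier within ``SSE_REL_TOL`` of the
    optimum, plus every *integer-consistent* multiplier (all segments of
    >= CONSISTENCY_MIN_BINS bins within INTEGER_CONSISTENCY_TOL of an
    integer) -- without the latter, read noise makes the smallest alias the
    unique near-optimum and polyploid nuclei would be unreachable. The
    covariate, when given, picks the candidate nearest to it; otherwise the
    smallest candidate wins (conservative against 2n/4n aliasing).
    """
    means = np.array([s.mean_ratio for s in segments])
    nbins = np.array([s.n_bins for s in segments])
    scaled = grid_values[:, None] * means[None, :]
    dev = scaled - np.rint(scaled)
    sse = (dev**2 * nbins[None, :]).sum(axis=1)

    big = nbins >= CONSISTENCY_MIN_BINS
    if big.any():
        ok = np.abs(dev[:, big]) <= INTEGER_CONSISTENCY_TOL
        frac = (ok * nbins[big][None, :]).sum(axis=1) / nbins[big].sum()
        consistent = (frac >= CONSISTENCY_BIN_FRACTION) & (
            sse / nbins.sum() <= CONSISTENCY_MAX_SSE_PER_BIN
        )
    else:
        consistent = np.zeros(len(grid_values), dtype=bool)
    min_sse = float(sse.min())
    near_opt = sse <= SSE_REL_TOL * min_sse + 1e-12
    cand_mask = near_opt | consistent
    # contiguous runs of admissible multipliers are one alias each; the
    # run's sse-argmin represents it (a flat profile yields one run per
    # integer multiple, a structured profile isolates the true scale)
    candidates = []
    idx = np.flatnonzero(cand_mask)
    run_start = 0
    for k in range(1, len(idx) + 1):
        if k == len(idx) or idx[k] != idx[k - 1] + 1:
            run = idx[run_start:k]
            candidates.append(grid_values[run[np.argmin(sse[run])]])
            run_start = k
    candidates = np.array(candidates)

    if dna_content is not None:
        pick = candidates[np.argmin(np.abs(candidates - dna_content))]
        used = True
    else:
        pick = candidates.min()
        used = False
    return PloidyFit(
        multiplier=float(pick),
        sse=float(sse[np.flatnonzero(grid_values == pick)[0]]),
        candidates=candidates,
        used_dna_content=used,
    )


def call_integer_cn(
    nucleus_id: str,
    segments: Sequence[Segment],
    fit: PloidyFit,
    grid: BinGrid,
) -> CopyNumberProfile:
    """Round ``multiplier * mean_ratio`` per segment and assign per-bin CN."""
    n = sum(s.n_bins for s in segments)
    cn = np.empty(n, dtype=int)
    for seg in segments:
        value = int(np.rint(fit.multiplier * seg.mean_ratio))
        if value < 0:
            warnings.warn(f"{nucleus_id}: segment CN < 0 clamped to 0", stacklevel=2)
            value = 0
        seg.integer_cn = value
        cn[seg.start_idx : seg.end_idx] = value
    # modal ploidy over autosomal bins (X dosage is sex-dependent and
    # handled separately)
    chroms = grid.retained_chromosomes()
    auto = chroms != "X"
    vals, counts = np.unique(cn[auto] if auto.any() else cn, return_counts=True)
    modal = int(vals[np.argmax(counts)])
    return CopyNumberProfile(nucleus_id, cn, list(segments), modal, grid, fit)


def call_nucleus(
    counts: BinnedCounts,
    dna_content: Optional[float] = None,
    min_bins: int = 3,
    penalty: float = 3.0,
    focal_penalty: float = FOCAL_PENALTY,
) -> CopyNumberProfile:
    """normalize -> segment -> fit ploidy -> integer CN for one nucleus."""
    norm = normalize(counts)
    segments = segment_profile(
        norm, min_bins=min_bins, penalty=penalty, focal_penalty=focal_penalty
    )
    fit = fit_ploidy(segments, dna_content=dna_content)
    return call_integer_cn(counts.nucleus_id, segments, fit, counts.grid)


def call_cohort(
    counts: pd.DataFrame,
    grid: BinGrid,
    dna_content: Optional[dict] = None,
    min_bins: int = 3,
    penalty: float = 3.0,
    focal_penalty: float = FOCAL_PENALTY,
) -> dict:
    """Call every nucleus column of a counts matrix; returns
    ``{nucleus_id: CopyNumberProfile}``. Nuclei are independent, so results
    do not depend on column order."""
    dna_content = dna_content or {}
    profiles = {}
    for col in counts.columns:
        bc = BinnedCounts(col, counts[col].to_numpy(), grid)
        profiles[col] = call_nucleus(
            bc,
            dna_content.get(col),
            min_bins=min_bins,
            penalty=penalty,
            focal_penalty=focal_penalty,
        )
    return profiles


def profiles_from_frame(frame: pd.DataFrame, grid: BinGrid) -> dict:
    """Rebuild per-nucleus profiles from an integer CN matrix (the format
    written by :func:`profiles_to_frame`, or an externally-called matrix on
    the same bin grid). Segments are reconstructed as maximal constant-CN
    runs; modal ploidy is the autosomal per-bin mode."""
    chroms = grid.retained_chromosomes()
    auto = chroms != "X"
    out = {}
    for col in frame.columns:
        if col in ("chrom", "start", "end"):
            continue
        cn = frame[col].to_numpy(dtype=int)
        if len(cn) != grid.n_retained:
            raise ValueError(f"{col}: CN vector length != retained bins")
        segments = []
        start = 0
        for i in range(1, len(cn) + 1):
            if i == len(cn) or cn[i] != cn[i - 1] or chroms[i] != chroms[i - 1]:
                segments.append(
                    Segment(chroms[start], start, i, float(cn[start]), int(cn[start]))
                )
                start = i
        vals, counts = np.unique(cn[auto] if auto.any() else cn, return_counts=True)
        modal = int(vals[np.argmax(counts)])
        out[col] = CopyNumberProfile(col, cn, segments, modal, grid)
    return out


def profiles_to_frame(profiles: dict, grid: BinGrid) -> pd.DataFrame:
    """Integer CN matrix (retained bins x nuclei) with bin coordinates."""
    rb = grid.retained_bins()
    cols = {
        "chrom": [b.chromosome for b in rb],
        "start": [b.start for b in rb],
        "end": [b.end for b in rb],
    }
    cols.update({nid: prof.cn for nid, prof in profiles.items()})
    return pd.DataFrame(cols)
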