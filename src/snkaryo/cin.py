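"""Chromosomal-instability metrics per subject or sample.

None of these scores has a universally fixed formula in the single-cell
literature; the definitions used here are:

* structural score -- total number of copy-number breakpoints (transitions
  between consecutive retained bins within a chromosome whose integer CN
  differs), summed over a subject's nuclei. A whole-arm event contributes
  one transition, a focal event two, a whole-chromosome event none.
* aneuploidy score -- sum over nuclei and units of |unit CN - 2|, measured
  against the fixed diploid reference (not the nucleus's own modal ploidy)
  so that polyploid nuclei contribute one count per unit.
* heterogeneity score -- mean pairwise Hamming distance between the
  per-unit CN vectors of a subject's nuclei (0 for a single nucleus).
* ANCA -- average number of copy-number alterations (non-neutral unit calls
  plus focal events) per nucleus, averaged over all nuclei of a sample.
* CIN score -- fraction of a sample's nuclei whose per-unit CN vector
  deviates from the sample's modal (element-wise mode) vector at >= 1 unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CopyNumberProfile
from .karyotype import Category, NucleusKaryotype, unit_cn_matrix


@dataclass
class CINReport:
    subject_id: str
    group: Optional[str]
    n_nuclei: int
    fraction_aneuploid: float
    structural_score: int
    aneuploidy_score: int
    heterogeneity_score: float
    anca: float
    cin_score: float


@dataclass
class AssociationResult:
    table: np.ndarray  # 2x2: rows wgd yes/no, cols aneuploid yes/no
    odds_ratio: float  # conditional MLE; nan when degenerate
    ci_low: float
    ci_high: float
    p_value: float
    odds_ratio_haldane: float  # +0.5 fallback, always finite


def structural_score(profiles: Sequence[CopyNumberProfile]) -> int:
    """Total CN breakpoints within chromosomes, summed over nuclei."""
    total = 0
    for prof in profiles:
        chroms = prof.grid.retained_chromosomes()
        same_chrom = chroms[1:] == chroms[:-1]
        jumps = prof.cn[1:] != prof.cn[:-1]
        total += int((same_chrom & jumps).sum())
    return total


def aneuploidy_score(
    karyotypes: Sequence[NucleusKaryotype], reference_ploidy: int = 2
) -> int:
    """Sum over nuclei and units of |unit CN - reference|."""
    return int(
        sum(
            abs(c.integer_cn - reference_ploidy)
            for k in karyotypes
            for c in k.unit_calls
        )
    )


def heterogeneity_score(karyotypes: Sequence[NucleusKaryotype]) -> float:
    """Mean pairwise Hamming distance between per-unit CN vectors."""
    if len(karyotypes) < 2:
        return 0.0
    mat = unit_cn_matrix(karyotypes).to_numpy()
    dists = [
        float((mat[i] != mat[j]).sum()) for i, j in combinations(range(len(mat)), 2)
    ]
    return float(np.mean(dists))


def anca(karyotypes: Sequence[NucleusKaryotype]) -> float:
    """Average number of copy-number alterations per nucleus (non-neutral
    unit calls + focal events), over ALL nuclei including euploid ones."""
    if not karyotypes:
        raise ValueError("empty sample")
    total = sum(k.n_gains + k.n_losses + len(k.focal_events) for k in karyotypes)
    return total / len(karyotypes)


def cin_score(karyotypes: Sequence[NucleusKaryotype]) -> float:
    """Fraction of nuclei deviating from the sample's modal per-unit CN
    vector at one or more units."""
    if not karyotypes:
        raise ValueError("empty sample")
    mat = unit_cn_matrix(karyotypes).to_numpy()
    modal = stats.mode(mat, axis=0, keepdims=False).mode
    deviant = (mat != modal).any(axis=1)
    return float(deviant.mean())


def fraction_aneuploid(karyotypes: Sequence[NucleusKaryotype]) -> float:
    if not karyotypes:
        raise ValueError("empty sample")
    return sum(k.is_aneuploid for k in karyotypes) / len(karyotypes)


def cin_report(
    karyotypes: Sequence[NucleusKaryotype],
    profiles: dict,
    by: str = "subject_id",
) -> list:
    """Per-subject (or per-group) CIN metrics."""
    groups: dict = {}
    for k in karyotypes:
        key = getattr(k, by) or "all"
        groups.setdefault(key, []).append(k)
    out = []
    for key in sorted(groups):
        ks = groups[key]
        profs = [profiles[k.nucleus_id] for k in ks]
        out.append(
            CINReport(
                subject_id=key,
                group=ks[0].group,
                n_nuclei=len(ks),
                fraction_aneuploid=fraction_aneuploid(ks),
                structural_score=structural_score(profs),
                aneuploidy_score=aneuploidy_score(ks),
                heterogeneity_score=heterogeneity_score(ks),
                anca=anca(ks),
                cin_score=cin_score(ks),
            )
        )
    return out


def cin_report_frame(reports: Sequence[CINReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def distance_separation(
    cohort_a: Sequence[NucleusKaryotype],
    cohort_b: Sequence[NucleusKaryotype],
    n_permutations: int = 999,
    seed: int = 123,
):
    """Euclidean-distance separation between two cohorts' per-unit CN
    vectors.

    Statistic: mean between-group distance minus mean within-group
    distance; permutation p from label shuffles. A one-way ANOVA on each
    nucleus's distance to its own group centroid is reported alongside.
    Returns a dict with the distance matrix, statistic, permutation p, and
    ANOVA (F, p).
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("each group needs >= 2 nuclei")
    mat_a = unit_cn_matrix(cohort_a).to_numpy(dtype=float)
    mat_b = unit_cn_matrix(cohort_b).to_numpy(dtype=float)
    mat = np.vstack([mat_a, mat_b])
    labels = np.array([0] * len(mat_a) + [1] * len(mat_b))
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    def gap(lab):
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(len(lab), k=1)
        within = dist[iu][same[iu]]
        between = dist[iu][~same[iu]]
        return float(between.mean() - within.mean())

    observed = gap(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if gap(perm) >= observed:
            count += 1
    p_perm = (1 + count) / (n_permutations + 1)

    cent_a = mat_a.mean(axis=0)
    cent_b = mat_b.mean(axis=0)
    d_a = np.sqrt(((mat_a - cent_a) ** 2).sum(axis=1))
    d_b = np.sqrt(((mat_b - cent_b) ** 2).sum(axis=1))
    if np.allclose(d_a, d_a[0]) and np.allclose(d_b, d_b[0]) and np.isclose(d_a.mean(), d_b.mean()):
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = stats.f_oneway(d_a, d_b)
    return {
        "distance_matrix": dist,
        "statistic": observed,
        "p_permutation": p_perm,
        "anova_F": float(f_stat),
        "anova_p": float(p_anova),
    }


def wgd_aneuploidy_association(karyotypes: Sequence[NucleusKaryotype]) -> AssociationResult:
    """Association between whole-genome duplication (modal ploidy >= 3) and
    aneuploidy (any non-neutral unit call), as a 2x2 exact test.

    Odds ratio by conditional MLE with exact CI (Fisher's framework); a
    Haldane-Anscombe (+0.5) estimate is reported as well since the exact OR
    is infinite/undefined with zero cells.
    """
    table = np.zeros((2, 2), dtype=int)
    for k in karyotypes:
        aneu = (k.n_gains + k.n_losses) > 0
        table[0 if k.wgd else 1, 0 if aneu else 1] += 1
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        ha = _haldane_or(table)
        return AssociationResult(table, float("nan"), float("nan"), float("nan"), 1.0, ha)
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    p = float(stats.fisher_exact(table)[1])
    return AssociationResult(
        table=table,
        odds_ratio=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=p,
        odds_ratio_haldane=_haldane_or(table),
    )


def _haldane_or(table: np.ndarray) -> float:
    a, b, c, d = (table + 0.5).ravel()
    return float(a * d / (b * c))
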