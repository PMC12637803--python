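"""Cohort-level hypothesis tests.

Thin, explicitly-labeled wrappers over standard tests: exact binomial (and
chi-square) tests for gain-versus-loss bias, Mann-Whitney U for euploid
versus aneuploid subject comparisons, one-way ANOVA / t tests for
aneuploidy-fraction bar charts, plus the (nucleus, unit) segment-event
accounting table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .karyotype import NucleusKaryotype


@dataclass
class GroupComparison:
    test_name: str
    groups: tuple
    statistic: float
    p_value: float
    n: tuple


def build_segment_event_table(karyotypes: Sequence[NucleusKaryotype]) -> pd.DataFrame:
    """One row per (nucleus, unit) with its gain/loss/no_change class.

    The grand total is n_nuclei x U "evaluated" events; the "informative"
    subset is the gain+loss rows.
    """
    rows = []
    for k in karyotypes:
        for c in k.unit_calls:
            cls = {"gain": "gain", "loss": "loss", "neutral": "no_change"}[c.state]
            rows.append((k.nucleus_id, k.group, c.unit_id, cls))
    return pd.DataFrame(rows, columns=["nucleus_id", "group", "unit_id", "class"])


def segment_event_totals(table: pd.DataFrame) -> dict:
    counts = table["class"].value_counts().to_dict()
    out = {c: int(counts.get(c, 0)) for c in ("gain", "loss", "no_change")}
    out["evaluated"] = len(table)
    out["informative"] = out["gain"] + out["loss"]
    return out


def gain_loss_bias_test(
    n_gains: int, n_losses: int, sided: str = "two-sided", method: str = "binomial"
) -> GroupComparison:
    """Are gains and losses equally likely?

    Exact binomial test of n_gains successes in n_gains+n_losses trials at
    p = 0.5 (two-sided by the minimum-likelihood convention), or a
    chi-square goodness-of-fit variant.
    """
    n = n_gains + n_losses
    if n < 1:
        raise ValueError("no gain/loss events to test")
    if method == "binomial":
        res = stats.binomtest(n_gains, n, p=0.5, alternative=sided)
        return GroupComparison(
            "exact_binomial", ("gain", "loss"), float(res.proportion_estimate), float(res.pvalue), (n_gains, n_losses)
        )
    if method == "chi2":
        chi2, p = stats.chisquare([n_gains, n_losses])
        return GroupComparison("chi_square", ("gain", "loss"), float(chi2), float(p), (n_gains, n_losses))
    raise ValueError(f"unknown method {method!r}")


def classify_subjects(karyotypes: Sequence[NucleusKaryotype]) -> pd.DataFrame:
    """Per-subject summary: euploid subjects have zero nuclei in every
    aneuploid category; others are aneuploid."""
    rows = []
    by_subject: dict = {}
    for k in karyotypes:
        by_subject.setdefault(k.subject_id, []).append(k)
    for subj, ks in sorted(by_subject.items(), key=lambda kv: str(kv[0])):
        n_aneu = sum(k.is_aneuploid for k in ks)
        affected = [k.n_gains + k.n_losses for k in ks]
        rows.append(
            {
                "subject_id": subj,
                "n_nuclei": len(ks),
                "n_aneuploid": n_aneu,
                "subject_class": "euploid" if n_aneu == 0 else "aneuploid",
                "affected_per_nucleus": float(np.mean(affected)),
                "prop_euploid": 1.0 - n_aneu / len(ks),
            }
        )
    return pd.DataFrame(rows)


def subject_class_comparison(subject_table: pd.DataFrame) -> list:
    """Mann-Whitney U between euploid and aneuploid subjects on
    affected-chromosomes-per-nucleus and proportion of euploid nuclei.

    Exact when sample sizes are small and tie-free, otherwise the normal
    approximation with tie correction (scipy's automatic policy).
    """
    eup = subject_table[subject_table["subject_class"] == "euploid"]
    ane = subject_table[subject_table["subject_class"] == "aneuploid"]
    out = []
    for var in ("affected_per_nucleus", "prop_euploid"):
        if len(eup) == 0 or len(ane) == 0:
            continue
        u, p = stats.mannwhitneyu(eup[var], ane[var], alternative="two-sided")
        out.append(
            GroupComparison(
                f"mann_whitney_{var}", ("euploid", "aneuploid"), float(u), float(p), (len(eup), len(ane))
            )
        )
    return out


def fraction_aneuploid_comparison(
    groups: dict, test: str = "anova"
) -> GroupComparison:
    """One-way ANOVA (or two-sample t test) on per-subject aneuploid
    fractions across cohorts. ``groups`` maps group name -> array of
    per-subject fractions."""
    names = tuple(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    if test == "anova":
        f, p = stats.f_oneway(*samples)
        return GroupComparison("one_way_anova", names, float(f), float(p), tuple(map(len, samples)))
    if test == "t":
        if len(samples) != 2:
            raise ValueError("t test needs exactly 2 groups")
        t, p = stats.ttest_ind(*samples)
        return GroupComparison("t_test", names, float(t), float(p), tuple(map(len, samples)))
    raise ValueError(f"unknown test {test!r}")
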