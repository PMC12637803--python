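#!/usr/bin/env python
"""Cohort-level hypothesis tests.

Builds the (nucleus, unit) segment-event table for the 96 NT+TUM nuclei,
tests gain-versus-loss bias (exact binomial and chi-square), compares
euploid versus aneuploid healthy-control subjects (Mann-Whitney), and runs
the one-way ANOVA on per-subject aneuploid fractions across cohorts.
"""

import argparse
import pathlib

import pandas as pd

from snkaryo.calling import profiles_from_frame
from snkaryo.genome import build_default_units, load_build, make_bins
from snkaryo.karyotype import karyotype_cohort, tally_gains_losses
from snkaryo.stats import (
    build_segment_event_table,
    classify_subjects,
    fraction_aneuploid_comparison,
    gain_loss_bias_test,
    segment_event_totals,
    subject_class_comparison,
)

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default=str(BASE / "stats"))
    args = ap.parse_args()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    build = load_build()
    units = build_default_units(build)
    grid = make_bins(build)
    karys = {}
    for name in ("HC", "NT", "TUM"):
        frame = pd.read_csv(BASE / "calls" / f"{name}_cn_matrix.tsv", sep="\t")
        meta = pd.read_csv(BASE / "cohorts" / f"{name}_metadata.tsv", sep="\t")
        karys[name] = karyotype_cohort(profiles_from_frame(frame, grid), units, build, meta)

    # segment-event accounting over the 96 matched-patient nuclei
    table = build_segment_event_table(karys["NT"] + karys["TUM"])
    table.to_csv(out / "nt_tum_segment_events.tsv", sep="\t", index=False)
    totals = segment_event_totals(table)
    print(f"NT+TUM segment events: {totals['evaluated']} evaluated "
          f"({totals['gain']} gains, {totals['loss']} losses, "
          f"{totals['no_change']} unchanged)")
    bias = gain_loss_bias_test(totals["gain"], totals["loss"])
    print(f"gain-vs-loss exact binomial: p = {bias.p_value:.3g}")

    for name in ("HC", "NT", "TUM"):
        g, l, _, _ = tally_gains_losses(karys[name])
        res = gain_loss_bias_test(g, l)
        chi = gain_loss_bias_test(g, l, method="chi2")
        print(f"{name}: {g} gains / {l} losses; exact p {res.p_value:.3f}, "
              f"chi-square p {chi.p_value:.3f}")

    subjects = classify_subjects(karys["HC"])
    subjects.to_csv(out / "hc_subject_classes.tsv", sep="\t", index=False)
    for comp in subject_class_comparison(subjects):
        print(f"HC euploid vs aneuploid subjects, {comp.test_name}: "
              f"U = {comp.statistic:.1f}, p = {comp.p_value:.4f}")

    fractions = {
        name: classify_subjects(karys[name])
        .assign(frac=lambda d: 1 - d["prop_euploid"])["frac"]
        .tolist()
        for name in ("HC", "NT", "TUM")
    }
    anova = fraction_aneuploid_comparison(fractions)
    print(f"per-subject aneuploid fraction ANOVA across cohorts: "
          f"F = {anova.statistic:.2f}, p = {anova.p_value:.4f}")


if __name__ == "__main__":
    main()
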