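#!/usr/bin/env python
"""Classify each nucleus into the seven karyotype categories.

Reads the CN matrices from 02_call_copy_number.py, derives per-unit calls,
focal events, categories, gain/loss tallies, WGD flags and X-dosage calls,
and prints the cohort category tables alongside the published ones.
"""

import argparse
import pathlib

import pandas as pd

from snkaryo.calling import profiles_from_frame
from snkaryo.genome import build_default_units, load_build, make_bins
from snkaryo.karyotype import (
    CATEGORY_ORDER,
    category_tally,
    focal_events_frame,
    karyotype_cohort,
    karyotypes_to_frame,
    tally_gains_losses,
)

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"
PUBLISHED = {
    "HC": [89, 10, 0, 3, 2, 1, 0],
    "NT": [41, 7, 0, 1, 0, 1, 1],
    "TUM": [23, 0, 10, 6, 1, 1, 4],
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--calls", default=str(BASE / "calls"))
    ap.add_argument("--cohorts", default=str(BASE / "cohorts"))
    ap.add_argument("--out", default=str(BASE / "karyotypes"))
    args = ap.parse_args()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    build = load_build()
    units = build_default_units(build)
    grid = make_bins(build)
    for name in ("HC", "NT", "TUM"):
        frame = pd.read_csv(f"{args.calls}/{name}_cn_matrix.tsv", sep="\t")
        meta = pd.read_csv(f"{args.cohorts}/{name}_metadata.tsv", sep="\t")
        profiles = profiles_from_frame(frame, grid)
        karys = karyotype_cohort(profiles, units, build, meta)
        karyotypes_to_frame(karys).to_csv(out / f"{name}_karyotypes.tsv", sep="\t", index=False)
        focal_events_frame(karys).to_csv(out / f"{name}_focal_events.tsv", sep="\t", index=False)
        tally = category_tally(karys)
        got = [tally[c] for c in CATEGORY_ORDER]
        gains, losses, per_unit, direction = tally_gains_losses(karys)
        per_unit.to_csv(out / f"{name}_unit_direction.tsv", sep="\t", index=False)
        aneu = sum(k.is_aneuploid for k in karys)
        print(f"{name}: {aneu}/{len(karys)} aneuploid ({100*aneu/len(karys):.1f}%)")
        print(f"  categories {dict(zip(CATEGORY_ORDER, got))}")
        print(f"  published  {dict(zip(CATEGORY_ORDER, PUBLISHED[name]))}")
        print(f"  gains/losses {gains}/{losses}; direction mix {direction}")


if __name__ == "__main__":
    main()
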