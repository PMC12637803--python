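#!/usr/bin/env python
"""Generate the three synthetic single-nucleus cohorts.

Writes, per cohort (HC = healthy controls, NT = GBM non-tumor regions,
TUM = GBM tumors): binned read counts (retained 500 kb bins x nuclei),
nucleus metadata (subject, group, sex, DNA content), and the ground-truth
event table. Ground-truth karyotype composition reproduces the published
cohort tables (105/51/45 nuclei; 15.2%/19.6%/48.9% aneuploid).
"""

import argparse
import pathlib

from snkaryo.fixtures import plan_fixture
from snkaryo.genome import build_default_units, load_build, make_bins
from snkaryo.simulate import simulate_cohort, write_cohort

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "cohorts"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--out", default=str(OUT))
    args = ap.parse_args()

    build = load_build()
    units = build_default_units(build)
    grid = make_bins(build)
    print(f"bin grid: {grid.n_bins} bins, {grid.n_retained} retained; {len(units)} units")
    for name in ("HC", "NT", "TUM"):
        plan = plan_fixture(name, seed=args.seed)
        counts = simulate_cohort(plan, units, grid, build=build)
        paths = write_cohort(plan, counts, grid, args.out)
        n_events = sum(len(p.events) for p in plan.nuclei)
        print(f"{name}: {len(plan.nuclei)} nuclei, {n_events} planned events -> {paths['counts']}")


if __name__ == "__main__":
    main()
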