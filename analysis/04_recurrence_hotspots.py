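#!/usr/bin/env python
"""Identify recurrently altered chromosome units and the 16p minimal region.

For each cohort, counts nuclei altered per unit (whole-unit calls plus
focal events), simulates the binomial null (10,000 draws, p = 1/38, 90th
percentile, seeded), flags units exceeding the threshold, and maps the
minimal common region of the called 16p focal deletions.
"""

import argparse
import pathlib

import pandas as pd

from snkaryo.calling import profiles_from_frame
from snkaryo.genome import Interval, build_default_units, length_mb, load_build, make_bins
from snkaryo.karyotype import karyotype_cohort
from snkaryo.recurrence import (
    NullModelConfig,
    count_alterations_per_unit,
    hotspot_test,
    hotspots_to_frame,
    recurrent_focal_region,
)

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--sims", type=int, default=10_000)
    ap.add_argument("--quantile", type=float, default=0.90)
    ap.add_argument("--out", default=str(BASE / "recurrence"))
    args = ap.parse_args()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    build = load_build()
    units = build_default_units(build)
    grid = make_bins(build)
    cfg = NullModelConfig(
        n_sims=args.sims, p_unit=1 / len(units), quantile=args.quantile, seed=args.seed
    )
    for name in ("HC", "NT", "TUM"):
        frame = pd.read_csv(BASE / "calls" / f"{name}_cn_matrix.tsv", sep="\t")
        meta = pd.read_csv(BASE / "cohorts" / f"{name}_metadata.tsv", sep="\t")
        karys = karyotype_cohort(profiles_from_frame(frame, grid), units, build, meta)
        recur = count_alterations_per_unit(karys, [u.unit_id for u in units])
        hits = hotspot_test(recur, cfg)
        hotspots_to_frame(hits).to_csv(out / f"{name}_hotspots.tsv", sep="\t", index=False)
        flagged = [h for h in hits if h.flagged]
        print(f"{name}: threshold {hits[0].threshold} of {hits[0].n_nuclei} nuclei; flagged:",
              {h.unit_id: (h.n_altered, f"p={h.exact_binomial_p:.2e}") for h in flagged})

        focal_16p = [
            ev.interval
            for k in karys
            for ev in k.focal_events
            if ev.unit_id == "16p" and ev.delta < 0
        ]
        if focal_16p:
            region, support = recurrent_focal_region(focal_16p)
            if region:
                print(f"  16p focal deletions: {len(focal_16p)} nuclei; minimal common "
                      f"region {region.render()} ({length_mb(region)} Mb, support {support})")
                with open(out / f"{name}_16p_minimal_region.tsv", "w") as fh:
                    fh.write("chrom\tstart_1based\tend\tlength_mb\tsupport\n")
                    fh.write(
                        f"{region.chromosome}\t{region.start + 1}\t{region.end}"
                        f"\t{length_mb(region)}\t{support}\n"
                    )


if __name__ == "__main__":
    main()
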