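#!/usr/bin/env python
"""Per-subject chromosomal-instability metrics and cohort contrasts.

Computes structural, aneuploidy and heterogeneity scores, ANCA and CIN
score per subject; the WGD x aneuploidy association in tumors; and the
Euclidean-distance separation between non-tumor and tumor karyotypes.
"""

import argparse
import json
import pathlib

import pandas as pd

from snkaryo.calling import profiles_from_frame
from snkaryo.cin import (
    anca,
    cin_report,
    cin_report_frame,
    cin_score,
    distance_separation,
    wgd_aneuploidy_association,
)
from snkaryo.genome import build_default_units, load_build, make_bins
from snkaryo.karyotype import karyotype_cohort

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--out", default=str(BASE / "cin"))
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
        profiles = profiles_from_frame(frame, grid)
        karys[name] = karyotype_cohort(profiles, units, build, meta)
        reports = cin_report(karys[name], profiles)
        cin_report_frame(reports).to_csv(out / f"{name}_cin.tsv", sep="\t", index=False)

    print(f"ANCA: TUM {anca(karys['TUM']):.2f} vs NT {anca(karys['NT']):.2f} "
          f"vs HC {anca(karys['HC']):.2f}")
    print(f"CIN score: TUM {cin_score(karys['TUM']):.2f} vs NT {cin_score(karys['NT']):.2f}")

    assoc = wgd_aneuploidy_association(karys["TUM"])
    print(f"WGD x aneuploidy (TUM): table {assoc.table.tolist()}, "
          f"OR {assoc.odds_ratio:.2f} (95% CI {assoc.ci_low:.2f}-{assoc.ci_high:.2f}), "
          f"Fisher p {assoc.p_value:.4f}")
    sep = distance_separation(karys["NT"], karys["TUM"], n_permutations=999, seed=args.seed)
    print(f"NT vs TUM Euclidean separation: statistic {sep['statistic']:.2f}, "
          f"permutation p {sep['p_permutation']:.3f}, "
          f"ANOVA on centroid distances p {sep['anova_p']:.3g}")
    with open(out / "associations.json", "w") as fh:
        json.dump(
            {
                "wgd_aneuploidy": {
                    "table": assoc.table.tolist(),
                    "odds_ratio": assoc.odds_ratio,
                    "ci": [assoc.ci_low, assoc.ci_high],
                    "p": assoc.p_value,
                    "odds_ratio_haldane": assoc.odds_ratio_haldane,
                },
                "nt_tum_distance": {
                    "statistic": sep["statistic"],
                    "p_permutation": sep["p_permutation"],
                    "anova_F": sep["anova_F"],
                    "anova_p": sep["anova_p"],
                },
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
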