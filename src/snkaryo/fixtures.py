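"""Packaged fixture cohorts.

Three synthetic cohorts of NeuN-negative glial nuclei whose ground-truth
karyotype composition reproduces the published category tables:

* HC  -- 105 nuclei / 12 healthy-control subjects: 89 euploid 2n, 10 with
  arm-level events, 3 with arm+chromosome events, 2 pure 3n, 1 arm event in
  3n; 28 unit-level events (10 gains / 18 losses); four nuclei in four
  subjects carry the two printed 16p13.11 focal deletions.
* NT  -- 51 nuclei / 6 GBM non-tumor regions: 41 euploid, 7 arm-level,
  1 arm+chromosome, 1 arm in 3n, 1 arm+chromosome in 3n; 28 events
  (5 gains / 23 losses); 16p altered in 8/51 nuclei.
* TUM -- 45 nuclei / 6 GBM tumors: 23 euploid, 10 chromosome-level,
  6 arm+chromosome, 1 pure 3n, 1 arm in 3n, 2 arm+chromosome in 3n,
  2 in 4n/5n; 140 events (35 gains / 105 losses); the +7/-10 signature in
  30-40% of each subject's aneuploid nuclei, 7p gains skewed to male
  subjects, 11p/11q losses to female subjects, and chromosome-X loss in
  two-thirds of one female tumor's nuclei.

Which unit carries which event is not derivable from published text; the
assignment below is a deterministic, documented choice drawn from the
published per-arm frequency lists (healthy-control events restricted to the
arms reported at <=2% plus the 16p/20q hotspots; tumors enriched for
7p/10p/10q/11p/11q/13) while keeping every non-recurrent unit below the
cohort's binomial null threshold.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .genome import Interval
from .simulate import CohortPlan, KaryotypeEvent, NoiseConfig, NucleusPlan

#: The two printed 16p13.11 deletion intervals (0-based half-open; they
#: render 1-based inclusive as chr16:14,310,885-16,845,164 and
#: chr16:14,817,633-17,356,860).
FOCAL_16P_A = Interval("16", 14_310_884, 16_845_164)
FOCAL_16P_B = Interval("16", 14_817_632, 17_356_860)


def _chrom(name: str, delta: int) -> KaryotypeEvent:
    return KaryotypeEvent("whole_chromosome", name, delta)


def _arm(unit_id: str, delta: int) -> KaryotypeEvent:
    return KaryotypeEvent("whole_unit", unit_id, delta)


def _focal(iv: Interval, delta: int) -> KaryotypeEvent:
    return KaryotypeEvent("focal", iv, delta)


# subject -> (sex, number of nuclei)
HC_SUBJECTS = {
    "HC1": ("M", 9), "HC2": ("M", 9), "HC3": ("M", 9), "HC4": ("M", 8),
    "HC5": ("M", 9), "HC6": ("F", 8), "HC7": ("F", 9), "HC8": ("M", 8),
    "HC9": ("M", 9), "HC10": ("F", 9), "HC11": ("F", 9), "HC12": ("F", 9),
}
NT_SUBJECTS = {
    "NT1": ("M", 9), "NT2": ("M", 9), "NT3": ("M", 9),
    "NT4": ("F", 8), "NT5": ("F", 8), "NT6": ("F", 8),
}
TUM_SUBJECTS = {
    "TUM1": ("M", 8), "TUM2": ("M", 8), "TUM3": ("M", 8),
    "TUM4": ("F", 6), "TUM5": ("F", 8), "TUM6": ("F", 7),
}

# Aneuploid nucleus specifications: (subject, background ploidy, events).
HC_ANEUPLOID = [
    ("HC1", 2, [_arm("10p", -1), _arm("18p", -1), _focal(FOCAL_16P_A, -1)]),
    ("HC1", 3, [_arm("16p", -1)]),
    ("HC1", 3, []),
    ("HC2", 2, [_arm("16p", -1), _arm("17p", -1)]),
    ("HC2", 2, [_arm("16p", -1), _arm("3p", -1)]),
    ("HC3", 2, [_arm("6q", -1), _focal(FOCAL_16P_B, -1)]),
    ("HC5", 2, [_arm("6q", -1), _arm("18q", -1), _focal(FOCAL_16P_A, -1)]),
    ("HC7", 2, [_arm("3p", -1), _focal(FOCAL_16P_A, -1)]),
    ("HC9", 2, [_arm("20q", +1), _arm("3q", +1)]),
    ("HC9", 2, [_arm("20q", +1), _arm("16p", +1)]),
    ("HC10", 2, [_arm("20p", +1), _arm("3q", +1)]),
    ("HC10", 3, []),
    ("HC11", 2, [_arm("16p", +1), _arm("20q", +1)]),
    ("HC11", 2, [_chrom("14", -1), _arm("18p", -1), _chrom("15", -1)]),
    ("HC12", 2, [_chrom("21", -1), _arm("18q", -1), _arm("10p", -1), _arm("17p", -1)]),
    ("HC12", 2, [_chrom("22", +1), _arm("20q", +1)]),
]

NT_ANEUPLOID = [
    ("NT1", 2, [_arm("16p", -1), _arm("4p", -1), _arm("20p", -1), _arm("8q", -1)]),
    ("NT1", 2, [_arm("16p", -1), _arm("5p", -1), _arm("12p", -1)]),
    ("NT2", 2, [_arm("16p", -1), _arm("9p", -1)]),
    ("NT3", 2, [_arm("16p", -1), _arm("10p", -1), _arm("12q", -1)]),
    ("NT3", 2, [_arm("16p", -1), _arm("11p", -1), _arm("9p", -1)]),
    ("NT4", 2, [_arm("16p", +1), _arm("20q", +1), _arm("8q", +1), _arm("17q", +1)]),
    ("NT5", 2, [_arm("12p", -1), _arm("17q", -1), _arm("16q", -1)]),
    ("NT5", 2, [_chrom("14", -1), _arm("16p", -1), _arm("20p", +1)]),
    ("NT6", 3, [_arm("16p", -1)]),
    ("NT6", 3, [_chrom("15", -1), _arm("12q", -1)]),
]

TUM_ANEUPLOID = [
    # TUM1 (male): 6 aneuploid, 2 carry the +7/-10 signature
    ("TUM1", 2, [_chrom("7", +1), _chrom("10", -1), _chrom("9", -1), _chrom("22", -1)]),
    ("TUM1", 2, [_chrom("7", +1), _chrom("10", -1), _arm("17p", -1), _arm("1q", -1)]),
    ("TUM1", 2, [_chrom("13", -1), _chrom("18", -1), _chrom("12", -1), _chrom("21", -1)]),
    ("TUM1", 2, [_chrom("4", -1), _chrom("14", -1), _chrom("17", -1), _chrom("13", -1)]),
    ("TUM1", 2, [_chrom("13", -1), _arm("8p", -1), _arm("9q", -1), _arm("2q", -1),
                 _arm("7p", +1), _arm("9p", +1)]),
    ("TUM1", 3, [_chrom("1", -1), _arm("2p", -1), _arm("5q", -1), _chrom("21", -1),
                 _chrom("13", -1)]),
    # TUM2 (male): 5 aneuploid, 2 carriers
    ("TUM2", 2, [_chrom("7", +1), _chrom("10", -1), _chrom("14", -1), _chrom("18", -1),
                 _chrom("3", -1)]),
    ("TUM2", 2, [_chrom("7", +1), _chrom("10", -1), _arm("16q", -1), _arm("1p", -1),
                 _arm("2p", -1), _arm("1q", -1)]),
    ("TUM2", 2, [_chrom("13", -1), _chrom("15", -1), _chrom("2", -1), _chrom("19", -1)]),
    ("TUM2", 2, [_chrom("20", +1), _chrom("21", +1), _chrom("19", +1), _chrom("3", +1),
                 _chrom("22", +1), _chrom("15", +1)]),
    ("TUM2", 3, [_arm("3q", -1), _arm("5p", -1), _arm("8q", -1), _arm("6q", +1),
                 _arm("16q", +1)]),
    # TUM3 (male): 3 aneuploid, 1 carrier
    ("TUM3", 2, [_chrom("7", +1), _chrom("10", -1), _arm("4p", -1), _arm("16p", -1),
                 _arm("6q", -1), _arm("20q", -1)]),
    ("TUM3", 2, [_chrom("18", -1), _chrom("15", -1), _chrom("4", -1), _chrom("5", -1)]),
    ("TUM3", 3, []),
    # TUM4 (female): autosomally euploid; carries the LoX burden (below)
    # TUM5 (female): 5 aneuploid, 2 carriers (one with the full +7/-10)
    ("TUM5", 2, [_chrom("7", +1), _chrom("10", -1), _chrom("13", -1), _chrom("8", -1)]),
    ("TUM5", 2, [_chrom("10", -1), _chrom("11", -1), _arm("16p", -1), _arm("20p", -1),
                 _arm("8q", -1), _arm("17q", -1)]),
    ("TUM5", 2, [_chrom("11", -1), _chrom("13", -1)]),
    ("TUM5", 3, [_chrom("12", -1), _arm("1p", -1), _arm("4q", -1), _arm("6q", +1),
                 _arm("16q", +1), _chrom("13", -1)]),
    ("TUM5", 4, [_chrom("11", -1), _chrom("13", -1), _arm("2q", -1), _arm("9p", -1),
                 _arm("17q", -1)]),
    # TUM6 (female): 3 aneuploid, 1 carrier
    ("TUM6", 2, [_chrom("10", -1), _chrom("11", -1), _arm("17p", -1), _arm("16p", -1),
                 _arm("12q", -1), _arm("9q", -1)]),
    ("TUM6", 2, [_chrom("19", +1), _chrom("20", +1), _chrom("22", +1), _chrom("14", +1)]),
    ("TUM6", 5, [_chrom("5", +1), _arm("3p", -1), _arm("8p", -1), _arm("12p", -1),
                 _chrom("13", -1)]),
]

# X-dosage events on otherwise-euploid nuclei: subject -> number of nuclei.
LOX_NUCLEI = {"HC": {"HC7": 1}, "NT": {}, "TUM": {"TUM4": 4, "TUM5": 3, "TUM6": 2}}
XP_GAIN_NUCLEI = {"HC": {"HC9": 1}, "NT": {"NT2": 1}, "TUM": {}}

_COHORTS = {
    "HC": (HC_SUBJECTS, HC_ANEUPLOID),
    "NT": (NT_SUBJECTS, NT_ANEUPLOID),
    "TUM": (TUM_SUBJECTS, TUM_ANEUPLOID),
}


def plan_fixture(
    cohort_name: str,
    seed: int = 123,
    noise: Optional[NoiseConfig] = None,
) -> CohortPlan:
    """Build the fixture cohort plan for ``HC``, ``NT`` or ``TUM``.

    ``seed`` drives read-count noise and the dna_content jitter; the
    karyotype composition itself is fixed data.
    """
    if cohort_name not in _COHORTS:
        raise ValueError(f"unknown cohort {cohort_name!r}; expected one of {list(_COHORTS)}")
    subjects, aneuploid = _COHORTS[cohort_name]
    if noise is None:
        noise = NoiseConfig(seed=seed)

    per_subject: dict = {s: [] for s in subjects}
    for subj, bg, events in aneuploid:
        per_subject[subj].append((bg, list(events)))

    lox = dict(LOX_NUCLEI[cohort_name])
    xp = dict(XP_GAIN_NUCLEI[cohort_name])

    rng = np.random.default_rng(seed)
    nuclei = []
    for subj, (sex, size) in subjects.items():
        specs = per_subject[subj]
        if len(specs) > size:
            raise ValueError(f"{subj}: more aneuploid nuclei than cohort size")
        specs = specs + [(2, []) for _ in range(size - len(specs))]
        for i, (bg, events) in enumerate(specs, 1):
            autosomal = any(not _is_x_event(e) for e in events)
            if not autosomal:
                if lox.get(subj, 0) > 0:
                    events = events + [_chrom("X", -1)]
                    lox[subj] -= 1
                elif xp.get(subj, 0) > 0:
                    events = events + [_arm("Xp", +1)]
                    xp[subj] -= 1
            nuclei.append(
                NucleusPlan(
                    nucleus_id=f"{subj}_n{i:02d}",
                    subject_id=subj,
                    group=cohort_name,
                    sex=sex,
                    background_ploidy=bg,
                    events=events,
                    dna_content=float(bg + rng.normal(0.0, 0.1)),
                )
            )
    leftover = {s: k for s, k in {**lox, **xp}.items() if k > 0}
    if leftover:
        raise ValueError(f"could not place X events: {leftover}")
    return CohortPlan(name=cohort_name, nuclei=nuclei, noise=noise)


def _is_x_event(ev: KaryotypeEvent) -> bool:
    return str(ev.target) in ("X", "Xp", "Xq")
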