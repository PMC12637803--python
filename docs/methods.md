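# Methods

## Genome model

Analyses run on GRCh37 (autosomes plus X; Y is excluded — at ultra-low
coverage its repeat content makes copy-number estimation unreliable). The
genome is tiled into fixed 500 kb bins; bins overlapping a blacklist are
dropped. The packaged blacklist holds the centromere intervals and 10 kb
telomeric gaps from the GRCh37 gap annotation (6,087 bins, 5,883 retained);
users may substitute their own BED. Internally all coordinates are 0-based
half-open; BED I/O keeps that convention; human-readable reports render
1-based inclusive coordinates.

Aneuploidy is scored on **38 chromosome units**: the p and q arms of the 17
two-armed autosomes plus one whole-chromosome unit for each acrocentric
autosome (13, 14, 15, 21, 22), which have no usable p-arm signal at this
coverage, minus unit 6p. No published enumeration of the 38-unit scheme
exists; p+q for two-armed autosomes plus whole acrocentrics gives 39, and
6p — the one arm absent from every published per-arm frequency list — is
the default exclusion. The unit scheme is a JSON config; any other choice
(e.g. excluding 19p) changes the count only with a warning, since the
downstream null model parametrizes on the actual number of units.

## Synthetic cohorts

The real brain snWGS data are access-restricted, so the generator is a first-class
module, not a test shim. A nucleus is a *plan*: background ploidy (2–5),
sex, and a list of events (whole chromosome, whole unit, or focal interval
of ≥ 3 bins; signed copy delta). The X baseline is the background ploidy in
females and half of it (rounded up) in males. Plans expand to per-bin
integer copy numbers, and counts for bin *b* are drawn as

    x_b ~ NB(mu_b),   mu_b = reads_per_bin · N · cn_b / Σ cn,

i.e. library-size-constrained: expectations are proportional to copy number
and total expected reads do not depend on ploidy, which is why pure
polyploidy is invisible in relative coverage. Defaults: 100 reads per bin
(≈ 0.15× at 500 kb bins) and negative-binomial dispersion 0.05 in the NB1
convention, var = mu·(1 + d). Dispersion 0 is the deterministic zero-noise
limit. The NB1 reading was chosen deliberately: under the NB2 alternative
(var = mu + d·mu², per-bin ratio SD ≈ 0.245) ±1-bin localization of 4–5-bin
focal deletions is information-theoretically capped near ~85–89% and focal
calling cannot be made simultaneously sensitive and clean; under NB1 the
pipeline's stated recovery properties hold with wide margins. Real
PicoPLEX-style single-cell data can be more overdispersed than NB1(0.05);
passing tests on these cohorts demonstrates correctness of the pipeline
logic at the modeled noise, not guaranteed sensitivity on noisier libraries
(dispersion is a config knob, and the focal-event detector's threshold is
the binding constraint as noise grows). GC bias is not simulated (the bin
blacklist, not bias modeling, is the mitigation strategy here); a per-bin
multiplicative bias vector can be supplied.

Each nucleus also gets a `dna_content` covariate (background ploidy plus
N(0, 0.1) jitter), standing in for the DNA-stain intensity recorded when
nuclei are sorted. Without some absolute-scale signal, "pure 3n" is
undetectable in principle; with it, the ploidy fit can resolve aliases.

### Fixture cohorts

Three packaged cohorts reproduce the published single-nucleus tables:

* **HC** — 105 nuclei, 12 subjects: categories (89, 10, 0, 3, 2, 1, 0) in
  the order (euploid 2n, arm-2n, chr-2n, arm+chr-2n, pure 3n, arm-3n,
  arm+chr-polyploid); 28 unit events, 10 gains / 18 losses, no nucleus
  mixing directions; four nuclei in four subjects carry the two reported
  16p13.11 focal deletions (three share chr16:14,310,885–16,845,164, one
  carries chr16:14,817,633–17,356,860); one female LoX nucleus; one male
  Xp-gain nucleus.
* **NT** — 51 nuclei, 6 subjects: categories (41, 7, 0, 1, 0, 1, 1);
  28 events, 5 gains / 23 losses, exactly one mixed nucleus; 16p altered in
  8/51 nuclei (≈ 16%).
* **TUM** — 45 nuclei, 6 subjects (3 male, 3 female): categories
  (23, 0, 10, 6, 1, 1, 4) with the polyploid-background events split across
  two 3n, one 4n and one 5n nucleus; 140 events, 35 gains / 105 losses;
  chromosome-10 loss in 30–40% of each subject's aneuploid nuclei with
  whole-chromosome-7 gains concentrated in male subjects (6:1); 11p/11q
  losses confined to female subjects; chromosome 13 losses recurrent; one
  autosomally quiet female tumor with X loss in 2/3 of its nuclei, plus
  X losses in the other female tumors (9 LoX nuclei in TUM, 10 overall).

Which unit carries which event is not derivable from published text. The
assignment is deterministic, drawn from the published per-arm frequency
lists (healthy-control events only on arms reported at ≤ 2% plus the
16p/20q hotspots; tumors enriched for 7p/10p/10q/11p/11q/13), under the
constraint that every non-recurrent unit stays at or below its cohort's
binomial-null threshold while each flagged unit clears it. Two consequences
are worth stating: 20q carries 4 altered healthy-control nuclei, below the
n=105 threshold of 5, so it is not flagged on the fixture — the
10-gain budget cannot push 20q above threshold without breaking another
printed marginal; and per-subject allocation of aneuploid nuclei is a
documented choice, not a published fact.

## Copy-number calling

A deliberately minimal, self-contained stand-in for binned single-cell CNV
calling (production pipelines typically delegate this stage to a dedicated
caller); externally
called integer CN matrices can be imported instead (`profiles_from_frame`)
and everything downstream is agnostic to the source.

1. **Normalize**: ratios = counts / mean(counts) over retained bins
   (requires ≥ 50 bins).
2. **Segment**, per chromosome, in two passes.
   *Binary pass*: recursively split at the boundary maximizing
   |Δmean| / (σ·√(1/n_L + 1/n_R)), σ estimated robustly from genome-wide
   successive differences; accept while the statistic exceeds `penalty`
   (default 3.0) and both sides keep ≥ `min_bins` (3) bins. A split that
   would create a side shorter than 12 bins must instead clear the focal
   threshold below — noise-selected micro-fragments otherwise round to
   spurious copy numbers. In the zero-noise limit any nonzero gap is
   significant and the largest standardized gap wins, so noiseless toy
   examples segment exactly.
   *Focal pass*: the binary statistic has no power for events a few bins
   long (a 5-bin dip moves one side's mean of a 180-bin chromosome by
   ~1.5%), so each segment is scanned over all interior windows of 3–24
   bins with a variance-weighted gap statistic, var(bin) = var_scale·level
   (counts are near-Poisson at this depth). Windows above `focal_penalty`
   (default 6.5) are peeled off recursively; boundaries are then re-fit by
   two-level maximum likelihood, including a final polish of every short
   segment against its flanking context. 6.5 was calibrated from measured
   operating characteristics at the default noise: 0/3000 null chromosome
   scans produce a window (so ~zero spurious focal events across a
   201-nucleus cohort, which exact category tallies require), while 4–5-bin
   heterozygous deletions are detected and localized to ±1 bin in ≈ 99% of
   replicates.
3. **Fit ploidy**: grid search m ∈ {1.50, 1.55, …, 6.00} minimizing
   sse(m) = Σ_bins (m·r − round(m·r))² over segment mean ratios. The
   candidate set holds every m within 5% of the optimal sse *plus* every
   integer-consistent m — segment means covering ≥ 95% of well-supported
   bins (≥ 8 bins each) within 0.2 of integers and per-bin sse ≤ 0.005.
   The consistency clause exists because under any read noise sse grows
   ~m² on a flat profile, making the smallest alias the unique 5% optimum
   and polyploid nuclei unreachable; the per-bin sse bound separates true
   ploidies (~0.001 at this noise) from coherent wrong aliases that park
   every segment 0.1–0.2 away from integers (~0.02). Contiguous admissible
   grid runs collapse to their sse-argmin. With a `dna_content` covariate
   the nearest candidate wins; without one, the smallest (a flat profile is
   called 2n — conservative against 2n/4n aliasing).
4. **Round**: per segment, CN = round(m·mean ratio), clamped at 0 with a
   warning; modal ploidy = per-bin mode over autosomes.

## Karyotyping

Per unit, the dominant CN is the mode over the unit's retained bins; the
unit is non-neutral when the dominant CN differs from the nucleus's modal
ploidy over ≥ 80% of its bins (`whole_unit_frac`; the 80% default tolerates blacklist
gaps inside a genuinely whole-arm event). Contiguous deviant
runs of ≥ 3 bins below that fraction are focal events. Chromosome-level
aneuploidy = both arms non-neutral in the same direction with equal CN, or
any non-neutral acrocentric unit; everything else non-neutral is arm-level;
the seven categories follow from (modal ploidy, has-arm, has-chromosome).
Polyploid backgrounds are scored against the nucleus's own modal ploidy
(CN 4 on 3n is a gain). X dosage is called separately against a
sex-specific baseline (females: modal ploidy; males: half, rounded up);
whole-X below baseline is LoX in females and an anomaly in males; p-arm-
only elevation is an Xp gain. A nucleus counts as *aneuploid* in cohort
summaries when its category is not euploid-2n or it carries a focal event;
X calls do not enter autosomal summaries.

## Recurrence

Per-unit alteration counts include focal events by default
(`include_focal`; the 16p frequency plainly includes segmental losses) but
focal events never change a nucleus's category. The null model draws
10,000 values from Binomial(n_nuclei, 1/U) (U = number of units) with a
fixed seed; the threshold is the 90th percentile by nearest rank, and a
unit is flagged only when its count strictly exceeds it (conservative).
Both an add-one empirical tail, (1 + #{draws ≥ k})/(n_sims + 1), and the
exact binomial tail P(X ≥ k) are reported; no multiple-testing correction
is applied across units, by design. Recurrent-focal mapping intersects
event intervals on a unit (minimum support 2); interval lengths report in
Mb as the difference of the printed 1-based endpoints, so rendered
coordinates and lengths agree.

## CIN metrics

No standard formulas exist for the bubble-plot scores; the formalizations
here are chosen so that an all-euploid subject scores 0 on everything and
pure-3n nuclei inflate the aneuploidy score:

* structural score — number of CN transitions between consecutive retained
  bins within a chromosome, summed over a subject's nuclei (whole-arm
  event: 1; focal event: 2; whole chromosome: 0);
* aneuploidy score — Σ |unit CN − 2| over units and nuclei, against the
  fixed diploid reference rather than the nucleus's modal ploidy;
* heterogeneity score — mean pairwise Hamming distance between per-unit CN
  vectors;
* ANCA — (non-neutral unit calls + focal events) per nucleus, averaged over
  all nuclei including euploid ones;
* CIN score — fraction of nuclei deviating at ≥ 1 unit from the sample's
  element-wise-modal unit-CN vector.

The subject-level structural score is reported as a plain sum; any log10
display transform is left to plotting. WGD (modal ploidy ≥ 3) ×
aneuploidy association uses Fisher's exact test with a conditional-MLE
odds ratio and exact CI, plus a Haldane–Anscombe (+0.5) estimate that stays
finite with zero cells. Group separation computes Euclidean distances
between per-unit CN vectors; the statistic is mean(between-group) −
mean(within-group) distance with a seeded permutation p, and a one-way
ANOVA on distance-to-own-centroid is reported alongside.

## Cohort statistics

The segment-event table enumerates every (nucleus, unit) pair —
"evaluated" events — with gains+losses as the "informative" subset (both
counts are reported explicitly because the two conventions are easy to
conflate). Gain-vs-loss bias: exact binomial test at p = 0.5, two-sided by
the minimum-likelihood convention, with a chi-square goodness-of-fit
variant. Euploid subjects are those with zero aneuploid nuclei in every
category; euploid-vs-aneuploid subject comparisons use Mann-Whitney U
(exact for small tie-free samples, normal approximation with tie correction
otherwise). Aneuploid-fraction comparisons across cohorts use one-way ANOVA
or a two-sample t test on per-subject fractions.

## Determinism and problem sizes

Every stochastic step (count simulation, null draws, permutations, jitter)
takes an explicit seed; rerunning the pipeline with the same configuration
is byte-identical. The default analysis — 201 nuclei across three cohorts
on 5,883 retained bins — runs end to end in well under a minute on one
CPU; Monte-Carlo validation suites (focal-recovery replicates, null-cohort
calibration) use 200 replicates each.

## Known limitations

* The calling stage is a minimal stand-in: no GC/mappability correction
  (hookable), no allele-specific CN, no sub-bin breakpoints.
* Focal gains are harder to detect than equal-sized deletions (higher
  variance at higher copy number); the fixtures' focal events are
  deletions, matching the recurrent 16p13.11 biology they model.
* The WGD odds ratio on the 45-nucleus tumor fixture is directionally
  positive but not significant (one non-aneuploid WGD nucleus); fixture
  scale, not method, is the constraint.
* Synthetic cohorts validate pipeline logic, not wet-lab performance:
  amplification artifacts, GC waves and chimeric reads in real
  single-nucleus libraries are outside the noise model.
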