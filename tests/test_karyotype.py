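"""Karyotype classification, category tallies, gain/loss accounting, X calls."""

import numpy as np
import pytest

from snkaryo import karyotype as kt
from snkaryo.calling import CopyNumberProfile, Segment
from snkaryo.genome import Chromosome, GenomeBuild, Interval, build_default_units, make_bins
from snkaryo.karyotype import Category, XCall


@pytest.fixture(scope="module")
def small_genome():
    """Two two-armed chromosomes + one acrocentric + X, 20 bins per arm."""
    arm = 20 * 500_000
    chroms = tuple(
        [
            Chromosome("7", 2 * arm, Interval("7", arm - 1, arm + 1)),
            Chromosome("16", 2 * arm, Interval("16", arm - 1, arm + 1)),
            Chromosome("13", 2 * arm, Interval("13", arm - 1, arm + 1)),
            Chromosome("X", 2 * arm, Interval("X", arm - 1, arm + 1)),
        ]
    )
    build = GenomeBuild("toy", chroms, frozenset(["13"]))
    units = build_default_units(build, excluded_unit_ids=[], expected_count=None)
    grid = make_bins(build, 500_000, blacklist=[])
    return build, units, grid


def profile_from_cn(grid, cn, modal=2):
    cn = np.asarray(cn, dtype=int)
    segs = []
    chroms = grid.retained_chromosomes()
    start = 0
    for i in range(1, len(cn) + 1):
        if i == len(cn) or cn[i] != cn[i - 1] or chroms[i] != chroms[i - 1]:
            segs.append(Segment(chroms[start], start, i, float(cn[start:i].mean()), int(cn[start])))
            start = i
    return CopyNumberProfile("n", cn, segs, modal, grid)


def bins_of(grid, chrom, arm=None):
    idx = grid.retained_index_on_chromosome(chrom)
    if arm == "p":
        return idx[: len(idx) // 2]
    if arm == "q":
        return idx[len(idx) // 2 :]
    return idx


class TestCallUnits:
    def test_all_neutral_on_flat_diploid(self, small_genome):
        build, units, grid = small_genome
        cn = np.full(grid.n_retained, 2)
        calls, focal = kt.call_units(profile_from_cn(grid, cn), units)
        assert all(c.state == "neutral" for c in calls)
        assert focal == []

    def test_whole_arm_loss_is_a_unit_loss(self, small_genome):
        build, units, grid = small_genome
        cn = np.full(grid.n_retained, 2)
        cn[bins_of(grid, "16", "p")] = 1
        calls, focal = kt.call_units(profile_from_cn(grid, cn), units)
        call = next(c for c in calls if c.unit_id == "16p")
        assert call.state == "loss" and call.integer_cn == 1
        assert call.covered_fraction == 1.0
        assert focal == []

    def test_short_run_is_focal_not_unit(self, small_genome):
        build, units, grid = small_genome
        cn = np.full(grid.n_retained, 2)
        idx = bins_of(grid, "16", "p")
        cn[idx[5:10]] = 1  # 5 of 20 arm bins
        calls, focal = kt.call_units(profile_from_cn(grid, cn), units)
        assert next(c for c in calls if c.unit_id == "16p").state == "neutral"
        assert len(focal) == 1
        ev = focal[0]
        assert (ev.unit_id, ev.delta, ev.n_bins) == ("16p", -1, 5)

    def test_gain_relative_to_polyploid_modal(self, small_genome):
        """CN 4 on a 3n background is a gain against the nucleus's own
        modal ploidy."""
        build, units, grid = small_genome
        cn = np.full(grid.n_retained, 3)
        cn[bins_of(grid, "7")] = 4
        calls, _ = kt.call_units(profile_from_cn(grid, cn, modal=3), units)
        assert {c.unit_id for c in calls if c.state == "gain"} == {"7p", "7q"}


class TestClassify:
    def build_karyotype(self, small_genome, cn, modal=2):
        build, units, grid = small_genome
        prof = profile_from_cn(grid, cn, modal)
        calls, _ = kt.call_units(prof, units)
        return kt.classify_nucleus(modal, calls, units)

    def test_category_matrix(self, small_genome):
        build, units, grid = small_genome
        flat2 = np.full(grid.n_retained, 2)
        cases = []
        # single arm loss -> ARM_2N
        cn = flat2.copy(); cn[bins_of(grid, "16", "p")] = 1
        cases.append((cn, 2, Category.ARM_2N))
        # both arms of chr7 gained equally -> CHR_2N
        cn = flat2.copy(); cn[bins_of(grid, "7")] = 3
        cases.append((cn, 2, Category.CHR_2N))
        # acrocentric loss counts as chromosome-level
        cn = flat2.copy(); cn[bins_of(grid, "13")] = 1
        cases.append((cn, 2, Category.CHR_2N))
        # chromosome + lone arm -> ARM_CHR_2N
        cn = flat2.copy(); cn[bins_of(grid, "13")] = 1; cn[bins_of(grid, "16", "p")] = 1
        cases.append((cn, 2, Category.ARM_CHR_2N))
        # flat triploid -> POLYPLOID_ONLY
        cases.append((np.full(grid.n_retained, 3), 3, Category.POLYPLOID_ONLY))
        # triploid with arm loss -> ARM_POLYPLOID
        cn = np.full(grid.n_retained, 3); cn[bins_of(grid, "16", "p")] = 2
        cases.append((cn, 3, Category.ARM_POLYPLOID))
        # triploid with chromosome loss + arm -> ARM_CHR_POLYPLOID
        cn = np.full(grid.n_retained, 3)
        cn[bins_of(grid, "13")] = 2; cn[bins_of(grid, "16", "q")] = 2
        cases.append((cn, 3, Category.ARM_CHR_POLYPLOID))
        for cn, modal, expect in cases:
            assert self.build_karyotype(small_genome, cn, modal) == expect

    def test_opposite_arm_changes_are_not_chromosome_level(self, small_genome):
        build, units, grid = small_genome
        cn = np.full(grid.n_retained, 2)
        cn[bins_of(grid, "7", "p")] = 3
        cn[bins_of(grid, "7", "q")] = 1
        assert self.build_karyotype(small_genome, cn) == Category.ARM_2N


class TestXDosage:
    def x_profile(self, small_genome, x_cn, modal=2):
        build, units, grid = small_genome
        cn = np.full(grid.n_retained, modal)
        cn[bins_of(grid, "X")] = x_cn
        return build, profile_from_cn(grid, cn, modal)

    def test_female_neutral_and_lox(self, small_genome):
        build, prof = self.x_profile(small_genome, 2)
        assert kt.call_x_dosage(prof, "F", build) == XCall.NEUTRAL
        build, prof = self.x_profile(small_genome, 1)
        assert kt.call_x_dosage(prof, "F", build) == XCall.LOX

    def test_male_baseline_and_anomaly(self, small_genome):
        build, prof = self.x_profile(small_genome, 1)
        assert kt.call_x_dosage(prof, "M", build) == XCall.NEUTRAL
        build, prof = self.x_profile(small_genome, 0)
        assert kt.call_x_dosage(prof, "M", build) == XCall.ANOMALY

    def test_xp_only_gain(self, small_genome):
        build, units, grid = small_genome
        cn = np.full(grid.n_retained, 2)
        xp = bins_of(grid, "X")[: len(bins_of(grid, "X")) // 2]
        cn[xp] = 3
        prof = profile_from_cn(grid, cn)
        assert kt.call_x_dosage(prof, "F", build) == XCall.XP_GAIN

    def test_missing_sex_warns_and_omits(self, small_genome):
        build, prof = self.x_profile(small_genome, 2)
        with pytest.warns(UserWarning, match="sex missing"):
            assert kt.call_x_dosage(prof, None, build) is None


class TestCohortTallies:
    @pytest.mark.parametrize(
        "cohort,expected",
        [
            ("HC", [89, 10, 0, 3, 2, 1, 0]),
            ("TUM", [23, 0, 10, 6, 1, 1, 4]),
            ("NT", [41, 7, 0, 1, 0, 1, 1]),
        ],
    )
    def test_category_tallies_match_printed_tables(self, cohorts, cohort, expected):
        tally = kt.category_tally(cohorts[cohort].karyotypes)
        assert [tally[c] for c in kt.CATEGORY_ORDER] == expected

    @pytest.mark.parametrize(
        "cohort,gains,losses",
        [("HC", 10, 18), ("TUM", 35, 105), ("NT", 5, 23)],
    )
    def test_gain_loss_tallies(self, cohorts, cohort, gains, losses):
        ng, nl, table, direction = kt.tally_gains_losses(cohorts[cohort].karyotypes)
        assert (ng, nl) == (gains, losses)
        assert table["gains"].sum() == gains and table["losses"].sum() == losses

    def test_hc_nuclei_never_mix_directions(self, cohorts):
        _, _, _, direction = kt.tally_gains_losses(cohorts["HC"].karyotypes)
        assert direction["mixed"] == 0

    def test_all_euploid_cohort_tallies_zero(self, cohorts):
        euploid = [k for k in cohorts["HC"].karyotypes if not k.is_aneuploid]
        ng, nl, table, _ = kt.tally_gains_losses(euploid)
        assert (ng, nl) == (0, 0) and table.empty

    def test_category_rederivation_round_trip(self, cohorts, units):
        """Stored category always re-derives from stored unit calls."""
        for res in cohorts.values():
            for k in res.karyotypes:
                assert kt.classify_nucleus(k.modal_ploidy, k.unit_calls, units) == k.category

    def test_gain_loss_conservation(self, cohorts):
        """Every non-neutral unit call appears exactly once in the tally."""
        for res in cohorts.values():
            ng, nl, _, _ = kt.tally_gains_losses(res.karyotypes)
            non_neutral = sum(
                1 for k in res.karyotypes for c in k.unit_calls if c.state != "neutral"
            )
            assert ng + nl == non_neutral

    def test_lox_only_in_females(self, cohorts):
        for res in cohorts.values():
            for k in res.karyotypes:
                if k.x_call == XCall.LOX:
                    assert k.sex == "F"

    def test_lox_counts_match_fixture_design(self, cohorts):
        lox = {
            name: sum(k.x_call == XCall.LOX for k in res.karyotypes)
            for name, res in cohorts.items()
        }
        assert lox == {"HC": 1, "NT": 0, "TUM": 9}
        tum4 = [k for k in cohorts["TUM"].karyotypes if k.subject_id == "TUM4"]
        assert sum(k.x_call == XCall.LOX for k in tum4) / len(tum4) == pytest.approx(2 / 3)

    def test_xp_gains_present_in_both_hc_and_nt(self, cohorts):
        assert any(k.x_call == XCall.XP_GAIN for k in cohorts["HC"].karyotypes)
        assert any(k.x_call == XCall.XP_GAIN for k in cohorts["NT"].karyotypes)
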