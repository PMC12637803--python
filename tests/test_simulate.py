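"""Synthetic-cohort generator: plan expansion, count model, fixtures, I/O."""

import numpy as np
import pandas as pd
import pytest

from snkaryo import fixtures as fx
from snkaryo import genome as gn
from snkaryo import simulate as sim

ACRO = {"13", "14", "15", "21", "22"}


def unit_level_events(plan_nucleus, unit_ids):
    """Expand a plan's autosomal events to (unit_id, delta) pairs."""
    out = []
    for ev in plan_nucleus.events:
        t = str(ev.target)
        if t in ("X", "Xp", "Xq") or ev.scope == "focal":
            continue
        if ev.scope == "whole_chromosome":
            targets = [t] if t in ACRO else [t + "p", t + "q"]
        else:
            targets = [t]
        out.extend((u, ev.delta) for u in targets if u in unit_ids)
    return out


class TestExpandPlan:
    def test_euploid_plan_is_flat(self, units, grid, build):
        plan = sim.NucleusPlan("n", "s", "HC", "M", 2, [])
        cn = sim.expand_plan_to_bin_cn(plan, units, grid, build=build)
        auto = grid.retained_chromosomes() != "X"
        assert (cn[auto] == 2).all()
        assert (cn[~auto] == 1).all()  # male X baseline

    def test_arm_loss_hits_only_that_arm(self, units, grid, build):
        ev = sim.KaryotypeEvent("whole_unit", "16p", -1)
        plan = sim.NucleusPlan("n", "s", "HC", "F", 2, [ev])
        cn = sim.expand_plan_to_bin_cn(plan, units, grid, build=build)
        u16p = next(u for u in units if u.unit_id == "16p")
        idx = grid.retained_index_in_unit(u16p)
        assert (cn[idx] == 1).all()
        mask = np.ones(len(cn), bool)
        mask[idx] = False
        assert (cn[mask] == 2).all()

    def test_whole_chromosome_gain_on_triploid(self, units, grid, build):
        ev = sim.KaryotypeEvent("whole_chromosome", "7", +1)
        plan = sim.NucleusPlan("n", "s", "TUM", "F", 3, [ev])
        cn = sim.expand_plan_to_bin_cn(plan, units, grid, build=build)
        chroms = grid.retained_chromosomes()
        assert (cn[chroms == "7"] == 4).all()
        auto = (chroms != "X") & (chroms != "7")
        assert (cn[auto] == 3).all()

    def test_negative_copy_number_rejected(self, units, grid, build):
        ev = sim.KaryotypeEvent("whole_chromosome", "7", -3)
        plan = sim.NucleusPlan("n", "s", "HC", "F", 2, [ev])
        with pytest.raises(ValueError, match="below 0"):
            sim.expand_plan_to_bin_cn(plan, units, grid, build=build)

    def test_too_short_focal_event_rejected(self, units, grid, build):
        ev = sim.KaryotypeEvent("focal", gn.Interval("16", 14_500_000, 15_400_000), -1)
        plan = sim.NucleusPlan("n", "s", "HC", "F", 2, [ev])
        with pytest.raises(ValueError, match="< 3"):
            sim.expand_plan_to_bin_cn(plan, units, grid, build=build)


class TestCounts:
    def test_zero_dispersion_is_deterministic_rounding(self, units, grid, build):
        plan = sim.NucleusPlan("n", "s", "HC", "F", 2, [])
        noise = sim.NoiseConfig(mean_reads_per_bin=100, dispersion=0.0)
        c = sim.simulate_counts(plan, units, grid, noise, build=build)
        assert (c.counts == 100).all()

    def test_bit_reproducible_for_fixed_seed(self, units, grid, build):
        plan = sim.NucleusPlan("n", "s", "HC", "F", 2, [])
        noise = sim.NoiseConfig(seed=7)
        a = sim.simulate_counts(plan, units, grid, noise, build=build)
        b = sim.simulate_counts(plan, units, grid, noise, build=build)
        assert (a.counts == b.counts).all()

    def test_arm_loss_halves_relative_coverage(self, units, grid, build):
        """Monte-Carlo oracle: mean count ratio of a CN-1 arm vs genome ~ 0.5."""
        ev = sim.KaryotypeEvent("whole_unit", "1q", -1)
        plan = sim.NucleusPlan("n", "s", "HC", "F", 2, [ev])
        rng = np.random.default_rng(42)
        noise = sim.NoiseConfig()
        u1q = next(u for u in units if u.unit_id == "1q")
        idx = grid.retained_index_in_unit(u1q)
        arm, rest = [], []
        for _ in range(30):  # ~7,400 arm bins total
            c = sim.simulate_counts(plan, units, grid, noise, build=build, rng=rng).counts
            arm.append(c[idx].mean())
            mask = np.ones(len(c), bool)
            mask[idx] = False
            mask &= grid.retained_chromosomes() != "X"
            rest.append(c[mask].mean())
        ratio = np.mean(arm) / np.mean(rest)
        se = np.std(np.array(arm) / np.mean(rest)) / np.sqrt(len(arm))
        assert abs(ratio - 0.5) < 3 * max(se, 1e-3)

    def test_pure_triploid_profile_is_flat(self, units, grid, build):
        """Ploidy cancels in relative counts: a 3n genome has the same
        expected per-bin counts as 2n (library-size constraint)."""
        p2 = sim.NucleusPlan("a", "s", "HC", "F", 2, [])
        p3 = sim.NucleusPlan("b", "s", "HC", "F", 3, [])
        noise = sim.NoiseConfig(dispersion=0.0)
        c2 = sim.simulate_counts(p2, units, grid, noise, build=build).counts
        c3 = sim.simulate_counts(p3, units, grid, noise, build=build).counts
        auto = grid.retained_chromosomes() != "X"
        assert np.allclose(c2[auto], c3[auto])

    def test_expected_counts_proportional_to_cn(self, units, grid, build):
        """Regression of mean count on ground-truth CN: R^2 > 0.99 at low
        dispersion."""
        events = [
            sim.KaryotypeEvent("whole_chromosome", "7", +1),
            sim.KaryotypeEvent("whole_chromosome", "10", -1),
            sim.KaryotypeEvent("whole_unit", "4p", +2),
        ]
        plan = sim.NucleusPlan("n", "s", "TUM", "F", 2, events)
        noise = sim.NoiseConfig(dispersion=0.01, seed=5)
        truth = sim.expand_plan_to_bin_cn(plan, units, grid, build=build)
        rng = np.random.default_rng(5)
        reps = np.mean(
            [
                sim.simulate_counts(plan, units, grid, noise, build=build, rng=rng).counts
                for _ in range(5)
            ],
            axis=0,
        )
        means = [reps[truth == k].mean() for k in (1, 2, 3, 4)]
        r = np.corrcoef([1, 2, 3, 4], means)[0, 1]
        assert r**2 > 0.99


class TestFixtures:
    @pytest.mark.parametrize(
        "name,n,n_subjects,n_aneuploid,n_events,n_gains,n_losses",
        [
            ("HC", 105, 12, 16, 28, 10, 18),
            ("NT", 51, 6, 10, 28, 5, 23),
            ("TUM", 45, 6, 22, 140, 35, 105),
        ],
    )
    def test_fixture_ground_truth_marginals(
        self, units, name, n, n_subjects, n_aneuploid, n_events, n_gains, n_losses
    ):
        plan = fx.plan_fixture(name)
        assert len(plan.nuclei) == n
        assert len({p.subject_id for p in plan.nuclei}) == n_subjects
        unit_ids = {u.unit_id for u in units}
        aneu = [
            p
            for p in plan.nuclei
            if p.background_ploidy > 2
            or any(str(e.target) not in ("X", "Xp", "Xq") for e in p.events)
        ]
        assert len(aneu) == n_aneuploid
        deltas = [
            d
            for p in plan.nuclei
            for _, d in unit_level_events(p, unit_ids)
        ]
        assert len(deltas) == n_events
        assert sum(d > 0 for d in deltas) == n_gains
        assert sum(d < 0 for d in deltas) == n_losses

    def test_hc_aneuploid_nuclei_never_mix_gains_and_losses(self, units):
        unit_ids = {u.unit_id for u in units}
        for p in fx.plan_fixture("HC").nuclei:
            deltas = {d for _, d in unit_level_events(p, unit_ids)}
            deltas |= {e.delta for e in p.events if e.scope == "focal"}
            assert not ({+1} <= deltas and {-1} & deltas)

    def test_hc_carries_the_four_printed_16p_deletions(self):
        plan = fx.plan_fixture("HC")
        carriers = {
            p.subject_id: e.target
            for p in plan.nuclei
            for e in p.events
            if e.scope == "focal"
        }
        assert set(carriers) == {"HC1", "HC3", "HC5", "HC7"}
        assert carriers["HC3"] == fx.FOCAL_16P_B
        assert all(carriers[s] == fx.FOCAL_16P_A for s in ("HC1", "HC5", "HC7"))

    def test_nt_16p_frequency_at_least_14_percent(self, units):
        plan = fx.plan_fixture("NT")
        with_16p = sum(
            any(str(e.target) == "16p" for e in p.events) for p in plan.nuclei
        )
        assert with_16p / len(plan.nuclei) >= 0.14

    def test_tum_signature_in_30_to_40_percent_of_aneuploid_nuclei(self, units):
        """Chromosome-10 loss (the clonal GBM signature anchor) is carried
        by 30-40% of each tumor subject's aneuploid nuclei."""
        plan = fx.plan_fixture("TUM")
        by_subject = {}
        for p in plan.nuclei:
            autosomal = any(str(e.target) not in ("X", "Xp", "Xq") for e in p.events)
            if autosomal or p.background_ploidy > 2:
                by_subject.setdefault(p.subject_id, []).append(p)
        for subj, nuclei in by_subject.items():
            if subj == "TUM4":  # autosomally euploid subject
                continue
            carriers = sum(
                any(e.scope == "whole_chromosome" and e.target == "10" for e in p.events)
                for p in nuclei
            )
            assert 0.30 <= carriers / len(nuclei) <= 0.40, subj

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError, match="unknown cohort"):
            fx.plan_fixture("ZZ")

    def test_dna_content_tracks_background_ploidy(self):
        plan = fx.plan_fixture("TUM", seed=3)
        for p in plan.nuclei:
            assert abs(p.dna_content - p.background_ploidy) < 0.5


class TestCohortIO:
    def test_round_trip(self, tmp_path, units, build):
        plan = fx.plan_fixture("NT", seed=9)
        b = gn.load_build()
        g = gn.make_bins(b)
        counts = sim.simulate_cohort(plan, units, g, build=build)
        paths = sim.write_cohort(plan, counts, g, str(tmp_path))
        counts2, meta, events = sim.read_cohort(paths)
        assert list(counts2.columns) == list(counts.columns)
        assert (counts2.to_numpy() == counts.to_numpy()).all()
        assert len(meta) == len(plan.nuclei)
        assert len(events) == sum(len(p.events) for p in plan.nuclei)
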