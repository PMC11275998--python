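"""Tests for greedy density-constrained scheduling and cycle arithmetic.

The greedy rule is re-implemented here as a deliberately naive oracle
(pure-python interval counting, no shared code with the scheduler) and the
two are compared exhaustively on small instances.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prmkit.errors import ValidationError
from prmkit.library_io import write_inclusion_list
from prmkit.rt_alignment import IDENTITY_MAP, RTMap
from prmkit.scheduler import (
    REJECT_DENSITY,
    REJECT_INELIGIBLE,
    REJECT_PROTEIN_CAP,
    Schedule,
    ScheduleConfig,
    build_schedule,
    density_profile,
    make_window,
    max_injection_time,
    points_per_peak,
    tier_assay,
)

from conftest import make_candidate, random_instance

CONFIG = ScheduleConfig(gradient_end=50.0)


# ---------------------------------------------------------------------------
# Independent oracle: a naive replay of the stated greedy rule.
# ---------------------------------------------------------------------------

def oracle_greedy(candidates, max_density, cap, gradient_end, width=5.0):
    """Naive greedy replay. Windows are [start, stop); density is checked by
    counting overlaps at every window start among placed windows."""
    placed = []  # (start, stop, candidate)
    counts = {}
    rejected = {}
    for cand in candidates:
        if not cand.eligible:
            rejected[cand] = "ineligible"
            continue
        rt = cand.entry.retention_time
        if rt < 0.0 or rt > gradient_end:
            rejected[cand] = "ineligible"
            continue
        start = max(0.0, rt - width / 2)
        stop = min(gradient_end, rt + width / 2)
        if not cand.forced and not any(
            counts.get(p, 0) < cap for p in cand.target_proteins
        ):
            rejected[cand] = "protein_cap"
            continue
        # check concurrency at every candidate probe point inside the window
        probes = [start] + [
            s for s, e, _ in placed if start <= s < stop
        ]
        ok = True
        for t in probes:
            concurrent = 1 + sum(1 for s, e, _ in placed if s <= t < e)
            if concurrent > max_density:
                ok = False
                break
        if not ok:
            rejected[cand] = "density"
            continue
        placed.append((start, stop, cand))
        if not cand.forced:
            for p in cand.target_proteins:
                counts[p] = counts.get(p, 0) + 1
    return [c for _, _, c in placed], rejected


def build(candidates, max_density, cap, gradient_end, **kwargs):
    config = ScheduleConfig(
        gradient_end=gradient_end,
        max_density=max_density,
        per_protein_cap=cap,
        allow_any_cap=True,
        **kwargs,
    )
    return build_schedule(candidates, IDENTITY_MAP, config)


class TestScheduleConfig:
    def test_cap_range_enforced(self):
        with pytest.raises(ValidationError):
            ScheduleConfig(gradient_end=50.0, per_protein_cap=2)

    def test_cap_override(self):
        config = ScheduleConfig(
            gradient_end=50.0, per_protein_cap=2, allow_any_cap=True
        )
        assert config.per_protein_cap == 2

    def test_gradient_validated(self):
        with pytest.raises(ValidationError):
            ScheduleConfig(gradient_end=0.0, gradient_start=10.0)


class TestMakeWindow:
    def test_centered(self):
        assert make_window(20.0, CONFIG) == (17.5, 22.5)

    def test_clamped_not_reextended(self):
        assert make_window(1.0, CONFIG) == (0.0, 3.5)

    def test_outside_gradient_none(self):
        assert make_window(60.0, CONFIG) is None


class TestBuildSchedule:
    def test_single_candidate_scheduled(self):
        schedule = build([make_candidate()], 10, 3, 50.0)
        assert len(schedule.targets) == 1
        assert schedule.rejections == {}

    def test_density_two_of_three_overlapping(self):
        cands = [
            make_candidate(sequence="AK", score=30.0, rt=20.0),
            make_candidate(sequence="BK", score=20.0, rt=20.0, proteins=("P2",)),
            make_candidate(sequence="CK", score=10.0, rt=20.0, proteins=("P3",)),
        ]
        schedule = build(cands, 2, 3, 50.0)
        scheduled = {t.candidate.entry.bare_sequence for t in schedule.targets}
        assert scheduled == {"AK", "BK"}
        assert schedule.rejections[cands[2]] == REJECT_DENSITY
        # oracle agrees
        placed, rejected = oracle_greedy(cands, 2, 3, 50.0)
        assert {c.entry.bare_sequence for c in placed} == scheduled

    def test_protein_cap_top_three_of_four(self):
        cands = [
            make_candidate(sequence=f"S{i}K", score=float(40 - i), rt=5.0 + 10 * i)
            for i in range(4)
        ]
        schedule = build(cands, 10, 3, 50.0)
        assert len(schedule.targets) == 3
        assert schedule.rejections[cands[3]] == REJECT_PROTEIN_CAP
        placed, rejected = oracle_greedy(cands, 10, 3, 50.0)
        assert len(placed) == 3 and rejected[cands[3]] == "protein_cap"

    def test_abutting_windows_half_open(self):
        cands = [
            make_candidate(sequence="AK", score=2.0, rt=12.5),  # [10, 15)
            make_candidate(sequence="BK", score=1.0, rt=17.5, proteins=("P2",)),
        ]
        schedule = build(cands, 1, 3, 50.0)
        assert len(schedule.targets) == 2

    def test_forced_bypasses_protein_cap_not_density(self):
        cands = [
            make_candidate(sequence=f"S{i}K", score=float(40 - i), rt=5.0 + 10 * i)
            for i in range(3)
        ] + [
            make_candidate(sequence="FORCEDK", score=0.0, rt=45.0, forced=True)
        ]
        # forced first per ranking contract
        cands = [cands[-1]] + cands[:-1]
        schedule = build(cands, 10, 3, 50.0)
        assert len(schedule.targets) == 4  # cap would have stopped at 3

        dense = [
            make_candidate(sequence=f"D{i}K", score=50.0, rt=20.0, proteins=(f"Q{i}",))
            for i in range(2)
        ] + [make_candidate(sequence="FORCED2K", score=0.0, rt=20.0, forced=True)]
        schedule = build(dense, 2, 3, 50.0)
        forced = [c for c in schedule.rejections if c.forced]
        assert len(forced) == 1
        assert schedule.rejections[forced[0]] == REJECT_DENSITY

    def test_ineligible_candidate_rejected(self):
        cand = make_candidate(eligible=False)
        schedule = build([cand], 10, 3, 50.0)
        assert schedule.rejections[cand] == REJECT_INELIGIBLE

    def test_rt_outside_gradient_ineligible(self):
        cand = make_candidate(rt=60.0)
        schedule = build([cand], 10, 3, 50.0)
        assert schedule.rejections[cand] == REJECT_INELIGIBLE

    def test_rt_map_applied(self):
        cand = make_candidate(rt=10.0)
        rt_map = RTMap(kind="affine", slope=1.1, intercept=2.0)
        config = ScheduleConfig(gradient_end=50.0)
        schedule = build_schedule([cand], rt_map, config)
        assert schedule.targets[0].aligned_rt == pytest.approx(13.0)
        assert schedule.targets[0].window_start == pytest.approx(10.5)

    def test_multi_protein_credits_all(self):
        cands = [
            make_candidate(
                sequence=f"M{i}K", score=float(10 - i), rt=5.0 + 8 * i,
                proteins=("P1", "P2"),
            )
            for i in range(3)
        ] + [
            make_candidate(sequence="XTRAK", score=1.0, rt=45.0, proteins=("P2",)),
        ]
        schedule = build(cands, 10, 3, 50.0)
        # P2 was credited by all three multi-protein peptides -> at cap
        assert schedule.rejections[cands[3]] == REJECT_PROTEIN_CAP

    def test_empty_input_empty_schedule(self):
        schedule = build([], 10, 3, 50.0)
        assert schedule.targets == [] and schedule.rejections == {}


class TestDensityProfile:
    def test_disjoint_windows(self):
        cands = [
            make_candidate(sequence="AK", rt=5.0),
            make_candidate(sequence="BK", rt=40.0, proteins=("P2",)),
        ]
        schedule = build(cands, 10, 3, 50.0)
        profile = density_profile(schedule)
        assert max(c for _, c in profile) == 1

    def test_k_identical_windows(self):
        k = 4
        cands = [
            make_candidate(sequence=f"S{i}K", rt=20.0, proteins=(f"P{i}",))
            for i in range(k)
        ]
        schedule = build(cands, 10, 3, 50.0)
        profile = density_profile(schedule)
        assert max(c for _, c in profile) == k

    def test_empty_schedule_empty_profile(self):
        schedule = build([], 10, 3, 50.0)
        assert density_profile(schedule) == []


class TestMaxInjectionTime:
    def test_paper_1ng_tier(self):
        assert max_injection_time(2.0, 10, 0) == 200.0

    def test_paper_10ng_tier(self):
        assert max_injection_time(2.0, 20, 5) == 95.0

    def test_single_target(self):
        assert max_injection_time(2.0, 1, 0) == 2000.0

    def test_zero_density_domain_error(self):
        with pytest.raises(ValidationError):
            max_injection_time(2.0, 0, 0)

    def test_floored_at_one_ms(self):
        assert max_injection_time(0.1, 100, 5) == 1.0

    def test_requested_over_budget_requires_override(self):
        # the 100 ng tier: 50 ms at density 50 exceeds the 35 ms budget
        with pytest.raises(ValidationError):
            max_injection_time(2.0, 50, 5, requested=50.0)
        assert max_injection_time(2.0, 50, 5, requested=50.0, override=True) == 50.0

    def test_requested_within_budget(self):
        assert max_injection_time(2.0, 10, 0, requested=150.0) == 150.0


class TestPointsPerPeak:
    def test_paper_setting(self):
        assert points_per_peak(15.0, 2.0) == 7.5

    def test_equal_widths(self):
        assert points_per_peak(10.0, 10.0) == 1.0

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            points_per_peak(0.0, 2.0)


class TestTierAssay:
    def test_single_tier_equals_build_schedule(self):
        cands, density, cap, g_end = random_instance(seed=5, max_candidates=60)
        config = ScheduleConfig(
            gradient_end=g_end, max_density=density,
            per_protein_cap=cap, allow_any_cap=True,
        )
        [tiered] = tier_assay(cands, IDENTITY_MAP, [config])
        direct = build_schedule(cands, IDENTITY_MAP, config)
        assert [t.candidate for t in tiered.targets] == [
            t.candidate for t in direct.targets
        ]

    def test_three_tiers_monotone_counts(self):
        cands, _, _, g_end = random_instance(seed=9, max_candidates=300)
        tiers = [
            ScheduleConfig(gradient_end=g_end, max_density=d) for d in (50, 20, 10)
        ]
        schedules = tier_assay(cands, IDENTITY_MAP, tiers)
        counts = [len(s.targets) for s in schedules]
        assert counts == sorted(counts, reverse=True)

    def test_unordered_tiers_rejected(self):
        tiers = [
            ScheduleConfig(gradient_end=50.0, max_density=d) for d in (10, 50)
        ]
        with pytest.raises(ValidationError):
            tier_assay([], IDENTITY_MAP, tiers)

    def test_empty_bank_empty_schedules(self):
        tiers = [
            ScheduleConfig(gradient_end=50.0, max_density=d) for d in (50, 20, 10)
        ]
        schedules = tier_assay([], IDENTITY_MAP, tiers)
        assert all(s.targets == [] for s in schedules)


class TestSchedulerProperties:
    @pytest.mark.parametrize("seed", range(40))
    def test_density_soundness_and_conservation(self, seed):
        cands, density, cap, g_end = random_instance(seed, max_candidates=120)
        schedule = build(cands, density, cap, g_end)
        profile = density_profile(schedule)
        assert max((c for _, c in profile), default=0) <= density
        assert len(schedule.targets) + len(schedule.rejections) == len(cands)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_oracle_on_small_instances(self, seed):
        cands, density, cap, g_end = random_instance(seed + 1000, max_candidates=12)
        schedule = build(cands, density, cap, g_end)
        placed, rejected = oracle_greedy(cands, density, cap, g_end)
        assert [t.candidate for t in schedule.targets] == placed
        assert {c: r for c, r in schedule.rejections.items()} == rejected

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_max_density(self, seed):
        cands, _, cap, g_end = random_instance(seed + 2000, max_candidates=150)
        previous = -1
        for density in (1, 2, 5, 10, 20):
            schedule = build(cands, density, cap, g_end)
            assert len(schedule.targets) >= previous
            previous = len(schedule.targets)

    def test_deterministic_byte_identical_inclusion_lists(self, tmp_path):
        cands, density, cap, g_end = random_instance(seed=77, max_candidates=100)
        paths = []
        for name in ("a.csv", "b.csv"):
            schedule = build(list(cands), density, cap, g_end)
            path = tmp_path / name
            write_inclusion_list(schedule, str(path))
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    @pytest.mark.parametrize("seed", range(15))
    def test_greedy_local_optimality(self, seed):
        """Removing any scheduled target never makes a higher-scored rejected
        target feasible under replay of the greedy rule."""
        cands, density, cap, g_end = random_instance(seed + 3000, max_candidates=12)
        schedule = build(cands, density, cap, g_end)
        scheduled = [t.candidate for t in schedule.targets]
        density_rejected = [
            c for c, r in schedule.rejections.items() if r == "density"
        ]
        for removed in scheduled:
            remaining = [c for c in cands if c is not removed]
            replay, _ = oracle_greedy(remaining, density, cap, g_end)
            for cand in density_rejected:
                if cand.score > removed.score:
                    # a higher-scored candidate rejected before `removed` was
                    # placed cannot become feasible by removing it
                    assert (cand in replay) is False
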