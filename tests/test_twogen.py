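"""Offspring allocation, sex assignment and F2 projection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavipes import (
    ClutchConfig,
    ClutchSizeDistribution,
    FertilityModel,
    FounderOutcome,
    HostEggRecord,
    allocate_offspring,
    assign_sexes,
    compare_scenarios,
    fertility_of_clutch,
    project_f2,
    project_from_frequencies,
    read_founders_csv,
    table_to_founders,
    write_founders_csv,
)

from conftest import make_founder


def feasible_multisets(total, n_hosts, support, max_clutch=7):
    """Brute-force enumeration of clutch-size multisets (the oracle)."""
    out = set()
    for k in range(1, n_hosts + 1):
        for combo in itertools.combinations_with_replacement(
            [s for s in support if s <= max_clutch], k
        ):
            if sum(combo) == total:
                out.add(tuple(sorted(combo)))
    return out


class TestAllocation:
    def test_zero_offspring_empty(self):
        dist = ClutchSizeDistribution({1: 1.0})
        assert allocate_offspring(0, 6, dist) == []

    def test_forced_singletons(self):
        dist = ClutchSizeDistribution({1: 1.0})
        assert allocate_offspring(12, 12, dist) == [1] * 12

    @pytest.mark.parametrize("mode", ["expected", "sampled"])
    def test_unique_feasible_solution(self, mode):
        dist = ClutchSizeDistribution({3: 0.5, 4: 0.5})
        sizes = allocate_offspring(7, 2, dist, mode=mode, seed=5)
        assert sorted(sizes) == [3, 4]

    def test_infeasible_total_raises(self):
        dist = ClutchSizeDistribution({1: 1.0})
        with pytest.raises(ValueError, match="infeasible"):
            allocate_offspring(50, 6, dist)

    @given(
        total=st.integers(0, 40),
        n_hosts=st.integers(0, 12),
        weights=st.lists(st.floats(0.01, 1.0), min_size=7, max_size=7),
    )
    @settings(derandomize=True, max_examples=150)
    def test_expected_mode_conserves_offspring(self, total, n_hosts, weights):
        if total > n_hosts * 7:
            return
        dist = ClutchSizeDistribution(dict(zip(range(1, 8), weights)))
        sizes = allocate_offspring(total, n_hosts, dist, mode="expected")
        assert sum(sizes) == total
        assert len(sizes) <= n_hosts
        assert all(1 <= s <= 7 for s in sizes)

    @pytest.mark.parametrize("total,n_hosts", [(7, 2), (10, 4), (5, 3)])
    def test_sampled_mode_stays_in_feasible_set(self, total, n_hosts):
        dist = ClutchSizeDistribution({2: 0.3, 3: 0.4, 4: 0.3})
        oracle = feasible_multisets(total, n_hosts, [2, 3, 4])
        for seed in range(50):
            sizes = allocate_offspring(total, n_hosts, dist, mode="sampled",
                                       seed=seed)
            assert tuple(sorted(sizes)) in oracle

    def test_sampled_mode_reproducible(self):
        dist = ClutchSizeDistribution({1: 0.2, 2: 0.5, 3: 0.3})
        a = allocate_offspring(11, 6, dist, mode="sampled", seed=99)
        b = allocate_offspring(11, 6, dist, mode="sampled", seed=99)
        assert a == b

    def test_sampled_mode_matches_sequence_law(self):
        # independent oracle: enumerate the sequential truncated-draw
        # process and condition on reaching the exact total (restarts
        # discard dead-end sequences)
        dist = ClutchSizeDistribution({3: 0.5, 4: 0.5})
        total, n_hosts = 7, 2

        def sequence_probs(remaining, slots, prefix, prob, acc):
            if remaining == 0:
                acc[tuple(prefix)] = acc.get(tuple(prefix), 0.0) + prob
                return
            if slots == 0:
                return
            support = [s for s in dist.sizes if s <= remaining]
            if not support:
                return
            mass = sum(dist.weights[s] for s in support)
            for s in support:
                sequence_probs(remaining - s, slots - 1, prefix + [s],
                               prob * dist.weights[s] / mass, acc)

        acc = {}
        sequence_probs(total, n_hosts, [], 1.0, acc)
        z = sum(acc.values())
        oracle = {k: v / z for k, v in acc.items()}  # {(3,4):1/3, (4,3):2/3}
        assert oracle[(3, 4)] == pytest.approx(1 / 3)

        draws = [
            tuple(allocate_offspring(total, n_hosts, dist, mode="sampled", seed=s))
            for s in range(600)
        ]
        frac = np.mean([d == (3, 4) for d in draws])
        # 3 MC standard errors around 1/3
        assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 600)


class TestSexAssignment:
    def test_single_clutch_paper_ratio(self):
        [cfg] = assign_sexes([4], p_female=0.25)
        assert (cfg.size, cfg.females) == (4, 1)

    def test_extremes(self):
        assert all(c.females == 0 for c in assign_sexes([2, 2], p_female=0.0))
        [cfg] = assign_sexes([7], p_female=1.0)
        assert cfg.females == 7

    def test_expected_total_and_spread(self):
        cfgs = assign_sexes([3, 3, 2], p_female=0.25)
        # 8 offspring -> 2 females, one each in the two largest clutches
        assert [c.females for c in cfgs] == [1, 1, 0]
        assert sum(c.females for c in cfgs) == round(0.25 * 8)

    def test_wrapping_when_more_females_than_clutches(self):
        cfgs = assign_sexes([2, 2], p_female=1.0)
        assert [c.females for c in cfgs] == [2, 2]

    def test_sampled_mode_seeded(self):
        a = assign_sexes([4, 4, 4], 0.25, mode="sampled", seed=1)
        b = assign_sexes([4, 4, 4], 0.25, mode="sampled", seed=1)
        assert a == b

    def test_invalid_p_female(self):
        with pytest.raises(ValueError):
            assign_sexes([2], p_female=1.5)


class TestProjection:
    def test_four_singleton_clutches_one_female(self, default_model):
        founder = make_founder([(1, 1), (1, 0), (1, 0), (1, 0)])
        r = project_f2(founder, default_model)
        assert r.f1_fertility == 4
        assert r.f2_fertility == 19  # one female from a clutch of 1

    def test_no_parasitized_hosts(self, default_model):
        founder = FounderOutcome("f", "g", [
            HostEggRecord("native", "usual_plant", False)
        ])
        r = project_f2(founder, default_model)
        assert (r.f1_fertility, r.f2_fertility) == (0, 0)
        assert r.mean_offspring_fertility is None

    def test_fictitious_clutch_spends_eggs_but_adds_nothing(self, default_model):
        founder = FounderOutcome("f", "g", [
            HostEggRecord("native", "usual_plant", True,
                          ClutchConfig(4, 1), True),
            HostEggRecord("fictitious", "fictitious_plant", True,
                          ClutchConfig(3, 1), False),
        ])
        r = project_f2(founder, default_model)
        assert r.f1_eggs_laid == 7
        assert r.f1_fertility == 4
        assert r.f2_fertility == 18  # 1 female x (20 - sqrt(4))

    def test_matches_bruteforce_on_random_founders(self, rng, default_model):
        from conftest import random_founder
        for _ in range(200):
            founder = random_founder(rng)
            r = project_f2(founder, default_model)
            brute = sum(
                fertility_of_clutch(h.clutch.size, default_model)
                for h in founder.hosts
                for _f in range(h.clutch.females)
            )
            assert r.f2_fertility == brute

    def test_equal_f1_different_f2(self, default_model):
        # same 12 emerged offspring, 3 females each; the spread-out
        # founder projects higher F2 (the two-generation scenario logic)
        spread = make_founder([(1, 1)] * 3 + [(1, 0)] * 9)
        packed = make_founder([(4, 1)] * 3)
        ps, pp = project_f2(spread, default_model), project_f2(packed, default_model)
        assert ps.f1_fertility == pp.f1_fertility == 12
        assert ps.f2_fertility > pp.f2_fertility


class TestCompareScenarios:
    def test_identical_groups_zero_percent(self, default_model):
        g = [make_founder([(2, 1), (3, 1)])]
        out = compare_scenarios({"a": g, "b": g}, default_model)
        assert out["percent_difference_per_offspring"]["a_vs_b"] == pytest.approx(0)

    def test_singletons_vs_quads(self, default_model):
        a = [make_founder([(1, 1)] * 4)]
        b = [make_founder([(4, 4)])]
        out = compare_scenarios({"a": a, "b": b}, default_model)
        # per-offspring means 19 vs 18
        assert out["groups"]["a"]["mean_offspring_fertility"] == pytest.approx(19)
        assert out["groups"]["b"]["mean_offspring_fertility"] == pytest.approx(18)
        assert out["percent_difference_per_offspring"]["a_vs_b"] == pytest.approx(
            (19 - 18) / 18 * 100
        )
        assert out["percent_difference_per_offspring"]["b_vs_a"] == pytest.approx(
            (18 - 19) / 19 * 100
        )

    def test_ratio_of_sums_convention(self, default_model):
        # founder with no females must not drag the group mean to NaN
        g = [make_founder([(1, 1)]), make_founder([(4, 0)])]
        out = compare_scenarios({"a": g, "b": [make_founder([(1, 1)])]},
                                default_model)
        assert out["groups"]["a"]["mean_offspring_fertility"] == pytest.approx(19)

    def test_zero_female_group_warns_and_excluded(self, default_model):
        a = [make_founder([(2, 0)])]
        b = [make_founder([(2, 1)])]
        with pytest.warns(UserWarning, match="no emerged females"):
            out = compare_scenarios({"a": a, "b": b}, default_model)
        assert out["percent_difference_per_offspring"] == {}

    def test_needs_two_groups(self, default_model):
        with pytest.raises(ValueError):
            compare_scenarios({"a": [make_founder([(1, 1)])]}, default_model)


class TestFrequencyProjection:
    def test_degenerate_frequencies_recover_fertility_gap(self, default_model):
        out = project_from_frequencies(
            {
                "small": ClutchSizeDistribution({1: 1.0}),
                "large": ClutchSizeDistribution({4: 1.0}),
            },
            default_model,
            n_clutches=100,
        )
        pct = out["percent_difference_per_offspring"]
        assert pct["small_vs_large"] == pytest.approx((19 - 18) / 18 * 100)


class TestTidyCsv:
    def test_round_trip(self, tmp_path, default_model):
        founders = [
            make_founder([(2, 1), (3, 0)], founder_id="a", group="g1"),
            FounderOutcome("b", "g2", [
                HostEggRecord("fictitious", "fictitious_plant", True,
                              ClutchConfig(2, 1), False),
                HostEggRecord("native", "usual_plant", False),
            ]),
        ]
        path = tmp_path / "data.csv"
        write_founders_csv(founders, path)
        back = table_to_founders(read_founders_csv(path))
        assert back == founders

    def test_bad_boolean_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "founder_id,group,substrate,host_species,parasitized,"
            "clutch_size,n_females,emerged\n"
            "a,g,usual_plant,native,yes,2,1,true\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_founders_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("founder_id,group\na,g\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_founders_csv(path)
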