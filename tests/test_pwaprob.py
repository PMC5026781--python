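"""PWA-consistent history enumeration and probability factorization."""

import math

import pytest

from indelhist import (AncestrySeq, Del, Ins, build_pwa, canonical_homology,
                       decompose_regions, enumerate_global_histories,
                       enumerate_local_histories, min_events, pwa_prob_direct,
                       pwa_prob_factorized, region_mult_factor)
from indelhist.pwaprob import _region_min
from indelhist.ratemodel import make_builtin_model


def _state(L):
    return AncestrySeq(range(1, L + 1))


class TestMinEvents:
    def test_worked_example_needs_two_events(self, example_pwa, dawg_model):
        assert min_events(example_pwa, dawg_model) == 2

    def test_gapless_alignment_needs_none(self, dawg_model):
        pwa = build_pwa(_state(4), _state(4))
        assert min_events(pwa, dawg_model) == 0

    def test_long_run_split_by_deletion_cutoff(self):
        m = make_builtin_model("homogeneous", {"g_I": [0.1, 0.1],
                                               "g_D": [0.1, 0.1]})
        pwa = build_pwa(_state(7), AncestrySeq([1, 7]))  # 5-site deletion run
        assert min_events(pwa, m) == 3  # ceil(5 / 2)

    def test_degenerate_cutoff_errors(self, example_pwa):
        m = make_builtin_model("homogeneous", {"g_I": [], "g_D": [0.1] * 3})
        with pytest.raises(ValueError):
            min_events(example_pwa, m)

    def test_matches_exhaustive_search_on_small_instances(self, dawg_model):
        # oracle: smallest N at which the global enumeration is nonempty
        for desc in ([1, 2, 3, 4], [1, 4], [1, 2, 8, 9, 3, 4], [4]):
            pwa = build_pwa(_state(4), AncestrySeq(desc))
            claimed = min_events(pwa, dawg_model)
            for n in range(claimed + 1):
                enum = enumerate_global_histories(dawg_model, pwa, N_max=n)
                assert bool(len(enum)) == (n == claimed)


class TestEnumerateLocalHistories:
    def test_parsimonious_deletion_zone(self, example_pwa, dawg_model):
        dec = decompose_regions(example_pwa, dawg_model)
        del_zone = dec.regions[1]
        hists = enumerate_local_histories(dawg_model, example_pwa, del_zone, 1)
        assert [h.ops for h in hists] == [(Del(2, 4),)]

    def test_parsimonious_insertion_zone(self, example_pwa, dawg_model):
        dec = decompose_regions(example_pwa, dawg_model)
        ins_zone = dec.regions[3]
        hists = enumerate_local_histories(dawg_model, example_pwa, ins_zone, 1)
        assert [h.ops for h in hists] == [(Ins(6, 3),)]

    def test_empty_region_admits_only_empty_history_at_budget_zero(
            self, example_pwa, dawg_model):
        dec = decompose_regions(example_pwa, dawg_model)
        assert [h.ops for h in
                enumerate_local_histories(dawg_model, example_pwa,
                                          dec.regions[0], 0)] == [()]

    def test_budget_two_adds_verified_nonparsimonious_histories(
            self, example_pwa, dawg_model):
        from indelhist.indelops import apply_history

        dec = decompose_regions(example_pwa, dawg_model)
        del_zone = dec.regions[1]
        hists = enumerate_local_histories(dawg_model, example_pwa, del_zone, 2)
        assert (Del(2, 4),) in {h.ops for h in hists}
        assert any(len(h.ops) == 2 and all(not op.is_ins for op in h.ops)
                   for h in hists)  # split deletions
        # an insert-then-delete decomposition needs one more event: deleting
        # the three originals plus anything inserted exceeds the cutoff
        assert not any(any(op.is_ins for op in h.ops) for h in hists)
        hists3 = enumerate_local_histories(dawg_model, example_pwa, del_zone, 3)
        assert any(any(op.is_ins for op in h.ops) for h in hists3)
        for h in hists:
            final = apply_history(h.initial, h.ops).final
            # the zone's target: ancestor sites 2-4 gone, nothing new kept,
            # everything outside the zone untouched
            assert final.ids == (1, 5, 6, 7)

    def test_all_enumerated_histories_replay_to_zone_target(self, example_pwa,
                                                            dawg_model):
        from indelhist.indelops import apply_history

        dec = decompose_regions(example_pwa, dawg_model)
        for region in dec.regions:
            n0 = _region_min(example_pwa, dawg_model, region)
            for h in enumerate_local_histories(dawg_model, example_pwa,
                                               region, n0 + 1):
                final = apply_history(h.initial, h.ops).final
                # PASs all survive and the zone content matches the target
                assert set(final.ids) >= {1, 5, 6, 7}

    def test_invisible_round_trips_in_gapless_zone(self, dawg_model):
        pwa = build_pwa(_state(2), _state(2))
        dec = decompose_regions(pwa, dawg_model)
        mid = dec.regions[1]  # between the two preserved sites
        hists = enumerate_local_histories(dawg_model, pwa, mid, 2)
        assert hists[0].ops == ()
        assert all(len(h.ops) in (0, 2) for h in hists)
        assert len(hists) > 1  # insert-then-delete round trips present


class TestEnumerateGlobalHistories:
    def test_worked_example_minimal_budget_gives_the_two_histories(
            self, example_pwa, dawg_model):
        enum = enumerate_global_histories(dawg_model, example_pwa, N_max=2)
        assert {h.ops for h in enum.histories} == {
            (Del(2, 4), Ins(3, 3)), (Ins(6, 3), Del(2, 4))}
        assert len(enum.groups) == 1  # one LHS class

    def test_gapless_alignment_has_only_the_null_history(self, dawg_model):
        pwa = build_pwa(_state(3), _state(3))
        enum = enumerate_global_histories(dawg_model, pwa, N_max=0)
        assert len(enum.groups) == 1
        assert [h.ops for h in enum.histories] == [()]

    def test_budget_below_minimum_reports_diagnostic(self, example_pwa,
                                                     dawg_model):
        enum = enumerate_global_histories(dawg_model, example_pwa, N_max=1)
        assert enum.groups == []
        assert "below minimum" in enum.diagnostics["note"]

    def test_every_history_replays_to_target_and_counts_match(
            self, example_pwa, dawg_model):
        from indelhist import class_size

        enum = enumerate_global_histories(dawg_model, example_pwa, N_max=3)
        target = canonical_homology(example_pwa)
        for lhs, hists in enum.groups:
            assert len(hists) == class_size(lhs)
            for h in hists:
                final = h.replay().final
                assert canonical_homology(build_pwa(h.initial, final)) == target
        seen = [h.ops for h in enum.histories]
        assert len(seen) == len(set(seen))  # no duplicates across classes


class TestPwaProbDirect:
    def test_gapless_alignment_at_budget_zero_is_null_probability(
            self, dawg_model):
        from indelhist import null_history_prob

        pwa = build_pwa(_state(3), _state(3))
        rep = pwa_prob_direct(dawg_model, pwa, 0.0, 1.0, N_max=0)
        assert rep.total.value == pytest.approx(
            null_history_prob(dawg_model, _state(3), 0.0, 1.0).value)

    def test_per_history_and_per_class_routes_agree(self, example_pwa,
                                                    dawg_model):
        rep = pwa_prob_direct(dawg_model, example_pwa, 0.0, 1.0, N_max=3)
        assert rep.by_history == pytest.approx(rep.by_class, rel=1e-12)

    def test_probability_nondecreasing_in_budget(self, example_pwa,
                                                 dawg_model):
        vals = [pwa_prob_direct(dawg_model, example_pwa, 0.0, 1.0,
                                N_max=n).total.value for n in (2, 3, 4)]
        assert vals[0] < vals[1] <= vals[2] * (1 + 1e-12)
        rep = pwa_prob_direct(dawg_model, example_pwa, 0.0, 1.0, N_max=2)
        assert vals[1] - vals[0] < rep.truncation_bound

    def test_reachable_homologies_sum_below_one(self, single_site_model):
        """Direct probabilities over all homology classes reachable with two
        events stay below unit mass."""
        from indelhist.indelops import TokenSource, apply_op

        m, s0, T = single_site_model, _state(2), 0.3
        src = TokenSource.after(s0)  # shared counter keeps tokens globally fresh
        finals = {s0.ids: s0}
        frontier = [s0]
        for _ in range(2):
            nxt = []
            for st in frontier:
                for op, _ in m.enumerate_channels(st):
                    s2, _ = apply_op(st, op, src)
                    if s2.ids not in finals:
                        finals[s2.ids] = s2
                    nxt.append(s2)
            frontier = nxt
        total = 0.0
        seen = set()
        for sf in finals.values():
            pwa = build_pwa(s0, sf)
            key = canonical_homology(pwa)
            if key in seen:
                continue
            seen.add(key)
            n0 = min_events(pwa, m)
            total += pwa_prob_direct(m, pwa, 0.0, T,
                                     N_max=max(n0, 2)).total.value
        assert 0.9 < total < 1.0 + 1e-9


class TestRegionMultFactor:
    def test_empty_region_factor_is_one(self, example_pwa, dawg_model):
        dec = decompose_regions(example_pwa, dawg_model)
        f = region_mult_factor(dawg_model, example_pwa, dec.regions[0],
                               0.0, 1.0, 0)
        assert f.value == 1.0

    def test_insertion_zone_factor_is_its_local_factor(self, example_pwa,
                                                       dawg_model, ancestor7):
        from indelhist import local_mult_factor

        dec = decompose_regions(example_pwa, dawg_model)
        f = region_mult_factor(dawg_model, example_pwa, dec.regions[3],
                               0.0, 1.0, 1)
        mu = local_mult_factor(dawg_model, ancestor7, [Ins(6, 3)], 0.0, 1.0)
        assert f.value == pytest.approx(mu.value, rel=1e-14)

    def test_factor_monotone_in_budget(self, example_pwa, dawg_model):
        dec = decompose_regions(example_pwa, dawg_model)
        f1 = region_mult_factor(dawg_model, example_pwa, dec.regions[1],
                                0.0, 1.0, 1)
        f2 = region_mult_factor(dawg_model, example_pwa, dec.regions[1],
                                0.0, 1.0, 2)
        assert f2.value > f1.value


class TestPwaProbFactorized:
    @pytest.mark.parametrize("family", ["dawg", "long_indel"])
    def test_matched_truncation_equals_direct(self, family, example_pwa,
                                              dawg_model, long_indel_model):
        model = {"dawg": dawg_model, "long_indel": long_indel_model}[family]
        dec = decompose_regions(example_pwa, model)
        budgets = [_region_min(example_pwa, model, r) + 1 for r in dec.regions]
        d = pwa_prob_direct(model, example_pwa, 0.0, 1.0, per_region=budgets)
        f = pwa_prob_factorized(model, example_pwa, 0.0, 1.0,
                                n_max_per_region=budgets)
        assert abs(f.total.value / d.total.value - 1.0) < 1e-9

    def test_gapless_alignment_reduces_to_overall_factor(self, dawg_model):
        pwa = build_pwa(_state(3), _state(3))
        rep = pwa_prob_factorized(dawg_model, pwa, 0.0, 1.0,
                                  n_max_per_region=0)
        assert rep.total.value == pytest.approx(rep.overall)

    def test_flanked_model_gap_shrinks_toward_the_cutoff(self, flanked_model):
        """Non-factorability: the two routes disagree for short sequences and
        the disagreement shrinks as the length approaches the deletion
        cutoff (where the exit rate turns affine again)."""
        gaps = []
        for L in (4, 5, 6):
            s = _state(L)
            desc = AncestrySeq([t for t in s.ids if t not in (2, L)])
            pwa = build_pwa(s, desc)  # two single-site deletions, two zones
            dec = decompose_regions(pwa, flanked_model)
            budgets = [_region_min(pwa, flanked_model, r) for r in dec.regions]
            d = pwa_prob_direct(flanked_model, pwa, 0.0, 1.0,
                                per_region=budgets)
            f = pwa_prob_factorized(flanked_model, pwa, 0.0, 1.0,
                                    n_max_per_region=budgets)
            gaps.append(abs(f.total.value / d.total.value - 1.0))
        assert gaps[0] > 1e-4
        assert gaps[0] > gaps[1] > gaps[2]

    def test_condition_check_attached_on_request(self, example_pwa,
                                                 dawg_model):
        rep = pwa_prob_factorized(dawg_model, example_pwa, 0.0, 1.0,
                                  n_max_per_region=1, check=True)
        assert rep.conditions and all(c.passed for c in rep.conditions)
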