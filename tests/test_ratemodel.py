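"""Rate models: exit rates, channels, increments, and condition probes."""

import math

import numpy as np
import pytest

from indelhist import AncestrySeq, Del, Ins, build_pwa, decompose_regions
from indelhist.ratemodel import (TimeProfile, make_builtin_model,
                                 model_from_config, model_to_config)


def _state(L):
    return AncestrySeq(range(1, L + 1))


class TestBuiltinConstruction:
    def test_long_indel_unit_ratio_forces_equal_rates(self):
        mu = [0.1, 0.0459, 0.0287, 0.0203, 0.0155]  # ~ l^-1.7 shape
        m = make_builtin_model("long_indel",
                               {"lambda_1": 0.1, "mu_1": 0.1, "mu": mu})
        assert m.g_I == m.g_D

    def test_long_indel_detailed_balance_value(self):
        m = make_builtin_model("long_indel",
                               {"lambda_1": 0.05, "mu_1": 0.1,
                                "mu": [0.1, 0.03, 0.01]})
        assert m.g_I[1] == pytest.approx(0.5 ** 2 * 0.03, abs=1e-15)

    def test_long_indel_ratio_law_all_lengths(self):
        m = make_builtin_model("long_indel",
                               {"lambda_1": 0.08, "mu_1": 0.1,
                                "mu": [0.1, 0.05, 0.02, 0.01]})
        for l in range(1, 5):
            assert m.g_I[l - 1] / m.g_D[l - 1] == pytest.approx(0.8 ** l)

    def test_long_indel_whole_sequence_channel_on_empty_state(self):
        m = make_builtin_model("long_indel",
                               {"lambda_1": 0.05, "mu_1": 0.1,
                                "mu": [0.1, 0.03, 0.01]})
        rho = 0.5
        expected_l1 = rho * (1 * 0.1 + 2 * 0.03 + 3 * 0.01)
        assert m.r_I(0, 1, AncestrySeq([])) == pytest.approx(expected_l1)
        chans = m.enumerate_channels(AncestrySeq([]))
        assert all(op.is_ins and op.a == 0 for op, _ in chans)

    def test_flanked_sticking_out_deletion_rate_is_zero(self, flanked_model):
        s = _state(3)
        assert flanked_model.r_D(0, 2, s) == 0.0
        assert flanked_model.r_D(2, 4, s) == 0.0
        assert flanked_model.r_D(2, 3, s) > 0.0

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            make_builtin_model("homogeneous", {"g_I": [-0.1], "g_D": [0.1]})

    def test_overlapping_tracked_regions_rejected(self):
        with pytest.raises(ValueError):
            make_builtin_model(
                "region_hetero",
                {"g_I": [0.1], "g_D": [0.1],
                 "regions": [{"anchor": [1, 3]}, {"anchor": [3, 5]}]},
                initial_state=_state(6))


class TestExitRate:
    def test_homogeneous_exit_rate_is_affine(self, dawg_model):
        A, B = dawg_model.affine_coeffs()
        values = {L: dawg_model.exit_rate(_state(L)) for L in range(1, 31)}
        for L, v in values.items():
            assert v == pytest.approx(A * L + B, abs=1e-12)

    def test_dawg_affine_coefficients_from_rate_sums(self, dawg_model):
        A, B = dawg_model.affine_coeffs()
        assert A == pytest.approx(sum(dawg_model.g_I) + sum(dawg_model.g_D))
        assert B == pytest.approx(
            sum(l * g for l, g in enumerate(dawg_model.g_D))
            - sum(dawg_model.g_I) + sum(dawg_model.g_IL) + sum(dawg_model.g_IR))

    def test_zero_rate_model_has_zero_exit(self):
        m = make_builtin_model("homogeneous", {"g_I": [0.0], "g_D": [0.0]})
        assert m.exit_rate(_state(5)) == 0.0

    def test_flanked_exit_rate_matches_both_branch_formulas(self, flanked_model):
        m = flanked_model
        gI, gD = m.g_I, m.g_D
        for L in range(1, 12):
            s = _state(L)
            expected = ((L - 1) * sum(gI) + 2 * sum(gI)
                        + sum((L - l + 1) * gD[l - 1]
                              for l in range(1, min(L, m.L_D_CO) + 1)))
            assert m.exit_rate(s) == pytest.approx(expected, abs=1e-12)

    def test_flanked_affine_only_at_or_above_cutoff(self, flanked_model):
        m = flanked_model
        A = sum(m.g_I) + sum(m.g_D)
        B = (-sum(l * g for l, g in enumerate(m.g_D)) - sum(m.g_I)
             + sum(m.g_IL) + sum(m.g_IR))
        # affine from one below the cutoff (the missing term carries a zero
        # weight at L = L_D_CO - 1), bent further down
        for L in range(m.L_D_CO - 1, m.L_D_CO + 5):
            assert m.exit_rate(_state(L)) == pytest.approx(A * L + B, abs=1e-12)
        for L in range(1, m.L_D_CO - 1):
            assert m.exit_rate(_state(L)) != pytest.approx(A * L + B, abs=1e-9)


class TestChannels:
    def test_hand_enumerated_two_site_single_length_model(self):
        a, d = 0.07, 0.11
        m = make_builtin_model("homogeneous", {"g_I": [a], "g_D": [d]})
        chans = dict(m.enumerate_channels(_state(2)))
        assert chans == {Ins(0, 1): a, Ins(1, 1): a, Ins(2, 1): a,
                         Del(1, 1): d, Del(2, 2): d}
        assert sum(chans.values()) == pytest.approx(3 * a + 2 * d)
        A, B = m.affine_coeffs()
        assert (A, B) == (a + d, a)

    def test_empty_state_deletion_only_model_has_no_channels(self):
        m = make_builtin_model("homogeneous", {"g_I": [0.0], "g_D": [0.3]})
        assert m.enumerate_channels(AncestrySeq([])) == []
        assert m.exit_rate(AncestrySeq([])) == 0.0

    def test_effective_deletion_aggregates_sticking_out_raw_channels(self):
        m = make_builtin_model("homogeneous", {"g_I": [0.1] * 3,
                                               "g_D": [0.2, 0.1, 0.05]})
        s = _state(2)
        chans = dict(m.enumerate_channels(s))
        # raw ranges with clipped action (1,2): (1,2),(0,2),(1,3),(0,3),(-1,..)?
        raw = [(1, 2), (0, 2), (1, 3), (0, 3)]
        expected = sum(m.g_D[xe - xb] for xb, xe in raw
                       if xe - xb + 1 <= m.L_D_CO)
        assert chans[Del(1, 2)] == pytest.approx(expected)
        assert chans[Del(1, 2)] == pytest.approx(m.op_rate(s, Del(1, 2)))

    def test_channel_conservation_over_random_models_and_states(self, rng):
        for _ in range(500):
            kind = ["homogeneous", "flanked"][int(rng.integers(0, 2))]
            nI, nD = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            m = make_builtin_model(kind, {"g_I": rng.uniform(0, 0.3, nI).tolist(),
                                          "g_D": rng.uniform(0, 0.3, nD).tolist()})
            s = _state(int(rng.integers(0, 9)))
            total = sum(r for _, r in m.enumerate_channels(s))
            assert total == pytest.approx(m.exit_rate(s), rel=1e-12, abs=1e-15)


class TestExitRateIncrements:
    def test_homogeneous_increment_is_A_times_length_change(self, dawg_model):
        A, _ = dawg_model.affine_coeffs()
        s = _state(6)
        assert dawg_model.delta_exit(s, Ins(3, 2)) == pytest.approx(2 * A)
        assert dawg_model.delta_exit(s, Del(2, 4)) == pytest.approx(-3 * A)

    def test_zero_rate_model_increment_is_zero(self):
        m = make_builtin_model("homogeneous", {"g_I": [0.0], "g_D": [0.0]})
        assert m.delta_exit(_state(4), Del(2, 2)) == 0.0

    def test_flanked_increment_matches_double_evaluation(self, flanked_model):
        s = _state(3)
        from indelhist.indelops import apply_op

        s2, _ = apply_op(s, Del(2, 2))
        expected = flanked_model.exit_rate(s2) - flanked_model.exit_rate(s)
        assert flanked_model.delta_exit(s, Del(2, 2)) == pytest.approx(expected)

    def test_double_increment_vanishes_for_homogeneous_models(self, dawg_model,
                                                              rng):
        for _ in range(100):
            L = int(rng.integers(5, 10))
            s = _state(L)
            op1 = Del(2, 2) if rng.uniform() < 0.5 else Ins(1, 2)
            op2 = Del(L - 1, L - 1) if rng.uniform() < 0.5 else Ins(L - 1, 1)
            assert dawg_model.delta_delta_exit(s, op1, op2) == pytest.approx(
                0.0, abs=1e-12)

    def test_double_increment_nonzero_for_short_flanked_sequences(
            self, flanked_model):
        s = _state(4)  # shorter than the deletion cutoff
        assert abs(flanked_model.delta_delta_exit(s, Del(2, 2), Del(4, 4))) > 1e-6

    def test_region_hetero_increments_in_different_regions_commute(self):
        m = make_builtin_model(
            "region_hetero",
            {"g_I": [0.05], "g_D": [0.05],
             "regions": [{"anchor": [2, 3], "delta_g_I": [0.1],
                          "delta_g_D": [0.1]},
                         {"anchor": [6, 7], "delta_g_I": [0.2],
                          "delta_g_D": [0.2]}]},
            initial_state=_state(8))
        s = _state(8)
        assert m.delta_delta_exit(s, Del(2, 2), Del(6, 6)) == pytest.approx(
            0.0, abs=1e-12)


class TestCheckConditions:
    def test_dawg_model_passes_both_conditions(self, dawg_model):
        reports = dawg_model.check_conditions(n_states=30, seed=1)
        assert all(r.passed for r in reports)
        assert {r.condition for r in reports} == {"i", "ii"}

    def test_flanked_model_fails_locality_of_increments_only(self,
                                                             flanked_model):
        r_i, r_ii = flanked_model.check_conditions(n_states=40, lengths=(2, 4),
                                                   seed=1)
        assert r_i.passed
        assert not r_ii.passed and len(r_ii.witnesses) > 0

    def test_region_hetero_passes_with_merged_region_probes(self):
        m = make_builtin_model(
            "region_hetero",
            {"g_I": [0.05, 0.02], "g_D": [0.05, 0.02],
             "regions": [{"anchor": [2, 3], "delta_g_I": [0.1, 0.04],
                          "delta_g_D": [0.1, 0.04]}]},
            initial_state=_state(10))
        reports = m.check_conditions(n_states=30, lengths=(8, 10), seed=2)
        assert all(r.passed for r in reports)


class TestRegionMergeHook:
    def test_interior_pas_of_tracked_region_is_not_a_delimiter(self):
        init = _state(8)
        m = make_builtin_model(
            "region_hetero",
            {"g_I": [0.05], "g_D": [0.05],
             "regions": [{"anchor": [2, 6], "delta_g_I": [0.1],
                          "delta_g_D": [0.1]}]},
            initial_state=init)
        pwa = build_pwa(init, AncestrySeq([1, 2, 4, 6, 7, 8]))
        dec = decompose_regions(pwa, m)
        assert 4 not in dec.delimiters  # interior to the tracked region
        assert set(dec.delimiters) == {1, 2, 6, 7, 8}
        plain = decompose_regions(pwa)
        assert 4 in plain.delimiters

    def test_deletion_bridged_regions_merge(self):
        init = _state(8)
        m = make_builtin_model(
            "region_hetero",
            {"g_I": [0.05] * 4, "g_D": [0.05] * 4,
             "regions": [{"anchor": [2, 3]}, {"anchor": [5, 6]}]},
            initial_state=init)
        # one deletion wipes 3..5, bridging both tracked regions
        pwa = build_pwa(init, AncestrySeq([1, 2, 6, 7, 8]))
        dec = decompose_regions(pwa, m)
        assert 2 in dec.delimiters and 6 in dec.delimiters


class TestTimeProfiles:
    def test_piecewise_profile_integrates_exactly(self):
        p = TimeProfile("piecewise", breakpoints=[0.5], values=[1.0, 3.0])
        assert p.integral(0.0, 1.0) == pytest.approx(2.0)
        assert p.factor(0.25) == 1.0 and p.factor(0.75) == 3.0

    def test_profile_scales_all_rates(self, dawg_model):
        from indelhist.ratemodel import DawgModel

        m = DawgModel(0.1, [0.5, 0.3, 0.2], 0.1, [0.5, 0.3, 0.2],
                      profile=TimeProfile("constant", value=2.0))
        s = _state(5)
        assert m.exit_rate(s, 0.3) == pytest.approx(
            2.0 * dawg_model.exit_rate(s, 0.3))


class TestConfigRoundTrip:
    @pytest.mark.parametrize("kind,params,initial", [
        ("homogeneous", {"g_I": [0.1, 0.05], "g_D": [0.2]}, None),
        ("dawg", {"lambda_I": 0.1, "f_I": [0.6, 0.4],
                  "lambda_D": 0.2, "f_D": [1.0]}, None),
        ("long_indel", {"lambda_1": 0.05, "mu_1": 0.1,
                        "mu": [0.1, 0.03, 0.01]}, None),
        ("flanked", {"g_I": [0.1], "g_D": [0.2, 0.1]}, None),
        ("region_hetero", {"g_I": [0.1], "g_D": [0.2],
                           "regions": [{"anchor": [2, 3], "delta_g_I": [0.05],
                                        "delta_g_D": [0.0]}]},
         list(range(1, 7))),
    ])
    def test_config_echo(self, kind, params, initial):
        cfg = {"family": kind, "params": params}
        if initial:
            cfg["regions_initial_state"] = initial
        m = model_from_config(cfg)
        cfg2 = model_to_config(m)
        m2 = model_from_config(cfg2)
        s = _state(6)
        assert m2.exit_rate(s) == pytest.approx(m.exit_rate(s))
        assert model_to_config(m2) == cfg2

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            model_from_config({"family": "dawg", "params": {}, "bogus": 1})
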