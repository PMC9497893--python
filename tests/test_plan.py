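"""Planner unit and property tests: channel grouping with replication,
interleaving, path planning, and parameter accounting."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from igpconv import (
    IneligibleLayerError, LayerSpec, baseline_params, channel_groups,
    count_macs, count_params, grouped_params, interleave_permutation,
    is_eligible, make_substitution_plan, plan_from_json, plan_paths,
    plan_to_json, table1_row,
)
from conftest import TABLE1


class TestChannelGroups:
    @pytest.mark.parametrize("n,ch,expected", [
        # worked replication example: last group wraps to the first channels
        (14, 4, [[0, 1, 2, 3], [4, 5, 6, 7], [8, 9, 10, 11], [12, 13, 0, 1]]),
        (8, 4, [[0, 1, 2, 3], [4, 5, 6, 7]]),       # exact divisibility
        (7, 3, [[0, 1, 2], [3, 4, 5], [6, 0, 1]]),  # deficit d = 2
        (5, 5, [[0, 1, 2, 3, 4]]),                  # single full group
    ])
    def test_examples(self, n, ch, expected):
        assert channel_groups(n, ch) == expected

    @given(n=st.integers(1, 600), ch=st.integers(1, 64))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, n, ch):
        groups = channel_groups(n, ch)
        g = math.ceil(n / ch)
        d = g * ch - n
        assert len(groups) == g
        assert 0 <= d < ch
        assert all(len(gr) == ch for gr in groups)
        covered = set().union(*map(set, groups))
        assert covered == set(range(n))
        # only the last group may repeat indices
        for gr in groups[:-1]:
            assert len(set(gr)) == ch


class TestInterleave:
    @pytest.mark.parametrize("n,expected", [
        (10, [0, 2, 4, 6, 8, 1, 3, 5, 7, 9]),
        (1, [0]),
        (7, [0, 2, 4, 6, 1, 3, 5]),  # odd n: extra channel in the first block
    ])
    def test_examples(self, n, expected):
        assert interleave_permutation(n) == expected

    @given(n=st.integers(1, 4096))
    @settings(max_examples=300, deadline=None)
    def test_bijection_and_structure(self, n):
        perm = interleave_permutation(n)
        assert sorted(perm) == list(range(n))
        half = (n + 1) // 2
        assert all(p % 2 == 0 for p in perm[:half])
        assert all(p % 2 == 1 for p in perm[half:])


class TestPlanPaths:
    @pytest.mark.parametrize("ic,f,ch,main_g,main_fg,extra_g", [
        (14, 10, 4, 4, 2, 2),
        (160, 3840, 16, 10, 384, 0),
        (1152, 320, 16, 72, 4, 32),
    ])
    def test_examples(self, ic, f, ch, main_g, main_fg, extra_g):
        main, extra = plan_paths(ic, f, ch)
        assert (main.groups, main.filters_per_group) == (main_g, main_fg)
        if extra_g == 0:
            assert extra is None
        else:
            assert (extra.groups, extra.filters_per_group) == (extra_g, 1)
            assert extra.input_groups == main.input_groups[:extra_g]

    def test_degenerate_all_filters_in_extra_path(self):
        # more groups than filters: the main path carries zero filters
        main, extra = plan_paths(1152, 320, 2)
        assert (main.groups, main.filters_per_group) == (576, 0)
        assert (extra.groups, extra.filters_per_group) == (320, 1)
        assert extra.groups <= main.groups

    def test_degenerate_widen_gives_one_filter_per_group(self):
        main, extra = plan_paths(1152, 320, 2, degenerate="widen")
        assert main.filters_per_group >= 1
        assert main.width == math.ceil(1152 / 320)
        total = main.total_filters + (extra.total_filters if extra else 0)
        assert total == 320

    def test_single_group_never_replicates(self):
        main, extra = plan_paths(24, 48, 32)
        assert main.groups == 1 and main.width == 24


class TestEligibility:
    @pytest.mark.parametrize("ic,f,ch,expected", [
        (14, 10, 4, True),
        (4, 10, 4, False),     # ch > ic/2
        (14, 10, 6, False),    # ch > f/2
        (14, 10, 5, True),     # ch == f/2 boundary (rule is <=)
        (64, 10, 5, True),
    ])
    def test_examples(self, ic, f, ch, expected):
        assert is_eligible(LayerSpec(ic, f, ch)) is expected

    def test_ineligible_spec_is_rejected(self):
        with pytest.raises(IneligibleLayerError):
            make_substitution_plan(LayerSpec(14, 10, 8))

    def test_non_strict_requires_two_groups(self):
        make_substitution_plan(LayerSpec(20, 480, 16), require_eligible=False)
        with pytest.raises(IneligibleLayerError):
            make_substitution_plan(LayerSpec(16, 480, 16),
                                   require_eligible=False)


class TestSubstitutionPlan:
    @pytest.mark.parametrize("spec,expected", sorted(TABLE1.items()))
    def test_reference_table_rows(self, spec, expected):
        row = table1_row(LayerSpec(*spec))
        got = (row["GK1"], row["FgK1"], row["GK2"], row["GL1"], row["FgL1"],
               row["GL2"], row["Total"], row["Percent"])
        assert got == expected

    def test_l_layer_only_when_narrowing(self):
        assert make_substitution_plan(LayerSpec(3840, 640, 16)).has_l
        assert not make_substitution_plan(LayerSpec(192, 1152, 16)).has_l

    def test_param_count_at_eligibility_boundary_equals_baseline(self):
        # ch == ic/2 with ic >= f: 2*f*(ic/2) == ic*f
        spec = LayerSpec(40, 40, 20)
        plan = make_substitution_plan(spec)
        assert count_params(plan) == baseline_params(spec)

    def test_grouped_params_inverse_in_groups(self):
        assert grouped_params(64, 128, 8) == 64 * 128 // 8
        with pytest.raises(ValueError):
            grouped_params(14, 10, 4)

    def test_macs_scale_with_positions(self):
        plan = make_substitution_plan(LayerSpec(14, 10, 4))
        assert count_macs(plan, 1, 1) == 80
        assert count_macs(plan, 2, 3) == 480
        assert baseline_params(LayerSpec(14, 10, 4)) == 140

    def test_exact_divisibility_degenerates_to_plain_grouped(self):
        # ch | ic, ch | f, ic < f: a single grouped conv, no extras,
        # no replication, no layer L
        plan = make_substitution_plan(LayerSpec(64, 128, 16))
        assert plan.k2 is None and not plan.has_l
        for gr in plan.k1.input_groups:
            assert len(set(gr)) == len(gr)

    def test_json_roundtrip(self):
        plan = make_substitution_plan(LayerSpec(14, 10, 4))
        again = plan_from_json(plan_to_json(plan))
        assert again == plan


def _check_invariants(ic, f, ch):
    spec = LayerSpec(ic, f, ch)
    plan = make_substitution_plan(spec)
    k_filters = sum(p.total_filters for p in plan.k_paths)
    assert k_filters == f, "filter conservation in layer K"
    if plan.has_l:
        l_filters = sum(p.total_filters for p in plan.l_paths)
        assert l_filters == f, "filter conservation in layer L"
        assert sorted(plan.interleave_perm) == list(range(f))
        assert count_params(plan) == 2 * f * ch
    else:
        assert count_params(plan) == f * ch
    if plan.k1.filters_per_group >= 1 and plan.k2 is not None:
        assert plan.k2.groups < plan.k1.groups, "extra path smaller than main"
    if plan.has_l and plan.l2 is not None:
        assert plan.l2.groups < plan.l1.groups


class TestSweepInvariants:
    def test_exhaustive_small_sweep(self):
        for ch in (2, 4, 8, 16, 32):
            for ic in range(2 * ch, 65):
                for f in range(2 * ch, 65):
                    _check_invariants(ic, f, ch)

    @given(
        ch=st.sampled_from([2, 4, 8, 16, 32]),
        ic=st.integers(4, 512),
        f=st.integers(4, 512),
    )
    @settings(max_examples=300, deadline=None)
    def test_sampled_sweep(self, ch, ic, f):
        if not is_eligible(LayerSpec(ic, f, ch)):
            return
        _check_invariants(ic, f, ch)

    def test_param_count_monotone_in_ch(self):
        for ic, f in [(256, 192), (160, 3840), (1152, 320)]:
            counts = [
                count_params(make_substitution_plan(LayerSpec(ic, f, ch)))
                for ch in (2, 4, 8, 16, 32)
                if is_eligible(LayerSpec(ic, f, ch))
            ]
            assert counts == sorted(counts)
            assert len(set(counts)) == len(counts)
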