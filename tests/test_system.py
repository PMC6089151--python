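"""Tests for C-index scoring of cuts, n* selection, and system assembly."""

import numpy as np
import pytest

from eaccd import (
    BuildConfig,
    CIndexCurve,
    FactorScheme,
    GroupAssignment,
    SurvivalRecord,
    SyntheticSpec,
    build_combinations,
    build_prognostic_system,
    c_index_curve,
    c_index_of_grouping,
    evaluate_external_grouping,
    generate,
    group_risk_scores,
    select_nstar,
    three_tier_spec,
)
from eaccd.exceptions import EaccdError, PipelineError

from helpers import grouping_partition


def dataset_two_groups(rate_a=0.1, rate_b=0.2, n=2000, seed=0):
    rng = np.random.default_rng(seed)
    recs = [
        SurvivalRecord(float(t), 1, ("X",)) for t in rng.exponential(1 / rate_a, n)
    ] + [
        SurvivalRecord(float(t), 1, ("Y",)) for t in rng.exponential(1 / rate_b, n)
    ]
    scheme = FactorScheme(("F",), (("X", "Y"),))
    return build_combinations(recs, scheme, min_cases=1)


class TestRiskScores:
    def test_higher_hazard_gets_higher_score(self):
        ds = dataset_two_groups()
        groups = GroupAssignment(k=2, group_of=(0, 1))
        scores = group_risk_scores(ds, groups, horizon=60.0)
        assert scores[ds.index_of("Y")] > scores[ds.index_of("X")]

    def test_identical_member_sets_share_score(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, 300)
        recs = [SurvivalRecord(float(x), 1, ("X",)) for x in t] + [
            SurvivalRecord(float(x), 1, ("Y",)) for x in t
        ]
        ds = build_combinations(recs, FactorScheme(("F",), (("X", "Y"),)), min_cases=1)
        scores = group_risk_scores(ds, GroupAssignment(k=2, group_of=(0, 1)), 60.0)
        assert scores[0] == scores[1]

    def test_single_group_and_bad_horizon(self):
        ds = dataset_two_groups()
        single = GroupAssignment(k=1, group_of=(0, 0))
        assert group_risk_scores(ds, single, 60.0).shape == (1,)
        with pytest.raises(EaccdError):
            group_risk_scores(ds, single, 0.0)


class TestCIndexOfGrouping:
    def test_single_group_is_exactly_half(self):
        ds = dataset_two_groups()
        assert c_index_of_grouping(ds, GroupAssignment(k=1, group_of=(0, 0)), 60.0) == 0.5

    def test_two_exponential_groups_match_pair_mixture_closed_form(self):
        # Between-group pairs are concordant w.p. l2/(l1+l2) = 0.8; within-
        # group pairs are risk-tied (0.5).  With equal sizes and no
        # censoring the expected C is the pair-count-weighted mixture.
        n = 2000
        ds = dataset_two_groups(rate_a=0.05, rate_b=0.2, n=n, seed=3)
        c = c_index_of_grouping(ds, GroupAssignment(k=2, group_of=(0, 1)), 60.0)
        n_within = 2 * n * (n - 1) / 2
        n_between = n * n
        expected = (0.5 * n_within + 0.8 * n_between) / (n_within + n_between)
        assert c == pytest.approx(expected, abs=0.03)

    def test_label_permutation_invariance(self):
        ds = dataset_two_groups(seed=4)
        a = c_index_of_grouping(ds, GroupAssignment(k=2, group_of=(0, 1)), 60.0)
        b = c_index_of_grouping(ds, GroupAssignment(k=2, group_of=(1, 0)), 60.0)
        assert a == b


class TestSelectNStar:
    @pytest.mark.parametrize(
        "values,tol,expected",
        [
            ((0.50, 0.70, 0.70), 0.0, 2),
            ((0.50, 0.7290, 0.7295), 0.001, 2),
            ((0.60, 0.60, 0.60), 0.0, 1),
        ],
    )
    def test_plateau_rule(self, values, tol, expected):
        curve = CIndexCurve(ks=tuple(range(1, len(values) + 1)), values=values)
        sel = select_nstar(curve, tol)
        assert sel.n_star == expected
        assert sel.c_max == max(values)

    def test_negative_tolerance_rejected(self):
        curve = CIndexCurve(ks=(1,), values=(0.5,))
        with pytest.raises(EaccdError):
            select_nstar(curve, -0.1)


class TestBuildSystem:
    def test_three_tier_recovery_single_seed(self):
        spec = three_tier_spec(seed=0)
        records, truth = generate(spec)
        system = build_prognostic_system(
            records, spec.scheme, BuildConfig(min_cases=100, tolerance=0.01)
        )
        assert system.selection.n_star == 3
        assert grouping_partition(system.labels, system.groups.group_of) == (
            grouping_partition(truth.keys(), truth.values())
        )
        # curve starts at 0.5 and k=n point equals singleton grouping C
        assert system.curve.values[0] == 0.5
        assert system.c_index == system.curve.value_at(3)
        # group 1 must have the best survival at five years
        s60 = [km.survival_at(60.0) for km in system.km_per_group]
        assert s60 == sorted(s60, reverse=True)

    def test_identical_distributions_plateau_at_one_group(self):
        scheme = FactorScheme(("F",), (("X", "Y"),))
        spec = SyntheticSpec(
            scheme=scheme,
            hazards={"X": 0.05, "Y": 0.05},
            n_per_combination=50_000,
            censoring_rate=0.01,
            admin_cutoff=132.0,
            seed=0,
        )
        records, _ = generate(spec)
        system = build_prognostic_system(
            records, scheme, BuildConfig(min_cases=100, tolerance=0.005)
        )
        # n=2 forces learned(1,2) = 1/2; the C curve is flat at 0.5 up to
        # Monte-Carlo noise, so the plateau rule stops at a single group
        assert system.selection.n_star == 1

    def test_determinism_same_seed_same_output(self):
        spec = three_tier_spec(seed=5)
        records, _ = generate(spec)
        cfg = BuildConfig(min_cases=100, tolerance=0.01)
        s1 = build_prognostic_system(records, spec.scheme, cfg)
        s2 = build_prognostic_system(records, spec.scheme, cfg)
        assert s1.group_table() == s2.group_table()
        assert s1.curve == s2.curve
        assert s1.dendrogram == s2.dendrogram

    def test_forced_k_override(self):
        spec = three_tier_spec(seed=1)
        records, _ = generate(spec)
        system = build_prognostic_system(
            records, spec.scheme, BuildConfig(min_cases=100, force_k=5)
        )
        assert system.selection.n_star == 5
        assert system.selection.forced
        assert system.groups.k == 5

    def test_stage_named_failure(self):
        recs = [SurvivalRecord(1.0, 1, ("X",)), SurvivalRecord(2.0, 1, ("X",))]
        scheme = FactorScheme(("F",), (("X",),))
        with pytest.raises(PipelineError) as err:
            build_prognostic_system(recs, scheme, BuildConfig(min_cases=1))
        assert err.value.stage == "combinations"


class TestCIndexCurve:
    def test_mismatched_labels_rejected(self):
        spec = three_tier_spec(seed=2)
        records, _ = generate(spec)
        system = build_prognostic_system(
            records, spec.scheme, BuildConfig(min_cases=100, tolerance=0.01)
        )
        ds = dataset_two_groups()
        with pytest.raises(EaccdError):
            c_index_curve(ds, system.dendrogram, 60.0)


@pytest.fixture(scope="module")
def built():
    spec = three_tier_spec(seed=3)
    records, truth = generate(spec)
    system = build_prognostic_system(
        records, spec.scheme, BuildConfig(min_cases=100, tolerance=0.01)
    )
    ds = build_combinations(records, spec.scheme, min_cases=100)
    return spec, truth, system, ds


class TestExternalGrouping:
    def test_mapping_equal_to_learned_cut_gives_identical_c(self, built):
        _, _, system, ds = built
        mapping = {lab: str(g) for lab, g in zip(system.labels, system.groups.group_of)}
        res = evaluate_external_grouping(ds, mapping, system.horizon)
        assert res.c_index == system.c_index

    def test_scrambled_mapping_scores_lower_than_planted(self, built):
        _, truth, system, ds = built
        planted = evaluate_external_grouping(ds, truth, system.horizon)
        rng = np.random.default_rng(0)
        tiers = list(truth.values())
        rng.shuffle(tiers)
        scrambled = dict(zip(truth.keys(), tiers))
        res = evaluate_external_grouping(ds, scrambled, system.horizon)
        assert res.c_index < planted.c_index

    def test_single_group_mapping_is_half(self, built):
        _, truth, system, ds = built
        mapping = {lab: "all" for lab in ds.labels}
        assert evaluate_external_grouping(ds, mapping, system.horizon).c_index == 0.5

    def test_missing_labels_listed(self, built):
        _, truth, system, ds = built
        mapping = {lab: "g" for lab in list(ds.labels)[:-2]}
        with pytest.raises(EaccdError) as err:
            evaluate_external_grouping(ds, mapping, system.horizon)
        for lab in list(ds.labels)[-2:]:
            assert lab in str(err.value)
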