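"""Filtering, scoring, the set-cover objective, greedy vs oracle, Bayes."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dxcover.diagnosis import (
    PatientCase,
    bayes_posteriors,
    bayes_score,
    brute_force_cover,
    cover_weight,
    eligible_candidates,
    greedy_cover,
    rank_differential,
    single_score,
)
from dxcover.errors import IneligibleExplanationError, QueryError
from dxcover.kb import AgeGroup, Sex

from conftest import make_kb, random_instance


def case(observed, **kw):
    return PatientCase(case_id="t", observed=frozenset(observed), **kw)


class TestEligibility:
    def test_region_mismatch_excludes(self):
        kb = make_kb(
            {"D1": {"F1": 1.0}, "D2": {"F1": 0.5}},
            D1={"regions": frozenset({"Africa"})},
        )
        c = case({"F1"}, regions=frozenset({"NorthAmerica"}))
        assert eligible_candidates(kb, c) == {"D2"}
        # including the explanation's region restores it
        c2 = case({"F1"}, regions=frozenset({"NorthAmerica", "Africa"}))
        assert eligible_candidates(kb, c2) == {"D1", "D2"}

    def test_negated_observed_finding_excludes(self):
        kb = make_kb({"malaria": {"fever": 1.0, "rash": -1.0}, "measles": {"rash": 0.9}})
        assert eligible_candidates(kb, case({"rash"})) == {"measles"}
        assert eligible_candidates(kb, case({"fever"})) == {"malaria", "measles"}

    def test_age_and_sex_constraints(self):
        kb = make_kb(
            {"D1": {"F1": 1.0}, "D2": {"F1": 1.0}, "D3": {"F1": 1.0}},
            D1={"age_groups": frozenset({AgeGroup.INFANT})},
            D2={"sex": Sex.FEMALE_ONLY},
        )
        c = case({"F1"}, age_months=360, sex="MALE")
        assert eligible_candidates(kb, c) == {"D3"}

    def test_unspecified_fields_impose_no_filter(self):
        kb = make_kb(
            {"D1": {"F1": 1.0}},
            D1={
                "regions": frozenset({"Asia"}),
                "age_groups": frozenset({AgeGroup.CHILD}),
                "sex": Sex.MALE_ONLY,
            },
        )
        assert eligible_candidates(kb, case({"F1"})) == {"D1"}

    def test_unknown_observed_finding_is_query_error(self):
        kb = make_kb({"D1": {"F1": 1.0}})
        with pytest.raises(QueryError, match="F9"):
            eligible_candidates(kb, case({"F9"}))

    def test_metamorphic_negation_removes_exactly_one_candidate(self):
        """Adding a -1 link for an observed finding removes that candidate
        and leaves every other score untouched."""
        rng = np.random.default_rng(42)
        kb, c = random_instance(rng)
        base = {
            r.explanation_id: r.score
            for r in rank_differential(kb, c, k=50).candidates
        }
        victim = sorted(eligible_candidates(kb, c))[0]
        fid = sorted(c.observed)[0]
        from dxcover.kb import Association

        kb.associations = [
            a
            for a in kb.associations
            if not (a.explanation_id == victim and a.finding_id == fid)
        ]
        kb.associations.append(
            Association(explanation_id=victim, finding_id=fid, weight=-1.0)
        )
        kb.reindex()
        after = {
            r.explanation_id: r.score
            for r in rank_differential(kb, c, k=50).candidates
        }
        assert victim not in after
        for eid, score in after.items():
            assert score == base[eid]


class TestScores:
    def test_single_score_sums_positive_overlap(self):
        kb = make_kb({"D1": {"F1": 1.0, "F2": 0.5}})
        assert single_score(kb, "D1", case({"F1", "F2"})) == 1.5
        assert single_score(kb, "D1", case(set())) == 0.0

    def test_no_overlap_scores_zero(self):
        kb = make_kb({"D1": {"F1": 1.0}, "D2": {"F2": 0.4}})
        assert single_score(kb, "D1", case({"F2"})) == 0.0

    def test_ineligible_explanation_rejected(self):
        kb = make_kb({"D1": {"F1": 1.0, "F2": -1.0}, "D2": {"F2": 0.4}})
        with pytest.raises(IneligibleExplanationError):
            single_score(kb, "D1", case({"F2"}))

    def test_cover_weight_examples(self):
        kb = make_kb({"d1": {"F1": 1.0}, "d2": {"F1": 0.6, "F2": 0.4}})
        c = case({"F1", "F2"})
        assert cover_weight(kb, ["d1"], c) == 1.0
        assert cover_weight(kb, ["d1", "d2"], c) == pytest.approx(1.4)
        assert cover_weight(kb, ["d1", "d2"], case(set())) == 0.0
        assert cover_weight(kb, [], c) == 0.0


class TestGreedyCover:
    def test_single_full_cover(self):
        kb = make_kb({"D1": {"F1": 1.0, "F2": 1.0, "F3": 1.0}})
        res = greedy_cover(kb, case({"F1", "F2", "F3"}))
        assert res.members == ("D1",)
        assert res.cover_value == 3.0

    def test_complementary_pair_both_picked(self):
        kb = make_kb(
            {"A": {"F1": 1.0, "F2": 1.0}, "B": {"F3": 0.8, "F4": 0.8}}
        )
        res = greedy_cover(kb, case({"F1", "F2", "F3", "F4"}))
        assert res.members == ("A", "B")  # larger gain first
        assert res.gain_trace == (2.0, pytest.approx(1.6))
        assert res.cover_value == pytest.approx(3.6)

    def test_ties_broken_by_id(self):
        kb = make_kb({"B": {"F1": 1.0}, "A": {"F1": 1.0}})
        res = greedy_cover(kb, case({"F1"}), max_size=1)
        assert res.members == ("A",)

    def test_no_eligible_candidates_is_empty_not_error(self):
        kb = make_kb({"D1": {"F1": -1.0}})
        res = greedy_cover(kb, case({"F1"}))
        assert res.members == ()
        assert res.cover_value == 0.0

    def test_gain_trace_non_increasing_and_sums_to_cover(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            kb, c = random_instance(rng)
            res = greedy_cover(kb, c, max_size=4)
            assert all(
                res.gain_trace[i] >= res.gain_trace[i + 1] - 1e-12
                for i in range(len(res.gain_trace) - 1)
            )
            assert res.cover_value == pytest.approx(sum(res.gain_trace))
            assert res.cover_value == pytest.approx(
                cover_weight(kb, res.members, c)
            )

    def test_greedy_meets_submodular_guarantee(self):
        """Greedy cover value is at least (1 - 1/e) of the brute-force
        optimum on random instances."""
        bound = 1.0 - 1.0 / math.e
        rng = np.random.default_rng(11)
        for _ in range(50):
            kb, c = random_instance(rng)
            g = greedy_cover(kb, c, max_size=3)
            opt = brute_force_cover(kb, c, max_size=3)
            assert g.cover_value >= bound * opt.cover_value - 1e-9


class TestBruteForce:
    def test_single_explanation_instance(self):
        kb = make_kb({"D1": {"F1": 0.9}})
        res = brute_force_cover(kb, case({"F1"}))
        assert res.members == ("D1",)

    def test_all_zero_weights_prefer_empty_set(self):
        kb = make_kb({"D1": {"F1": 0.0}, "D2": {"F1": 0.0}})
        res = brute_force_cover(kb, case({"F1"}))
        assert res.members == ()
        assert res.cover_value == 0.0

    def test_smaller_set_preferred_at_equal_cover(self):
        kb = make_kb({"A": {"F1": 1.0, "F2": 1.0}, "B": {"F1": 1.0}, "C": {"F2": 1.0}})
        res = brute_force_cover(kb, case({"F1", "F2"}), max_size=2)
        assert res.members == ("A",)

    def test_guard_refuses_large_instances(self):
        kb = make_kb({f"D{i:02d}": {"F1": 0.5} for i in range(21)})
        with pytest.raises(QueryError, match="greedy"):
            brute_force_cover(kb, case({"F1"}))


class TestRankDifferential:
    def test_single_match(self):
        kb = make_kb({"D1": {"F1": 1.0}, "D2": {"F2": 1.0}})
        diff = rank_differential(kb, case({"F1"}))
        assert [c.explanation_id for c in diff.candidates] == ["D1"]

    def test_zero_scores_omitted(self):
        kb = make_kb({"D1": {"F1": 1.0}, "D2": {"F2": 1.0}})
        diff = rank_differential(kb, case({"F1"}))
        assert all(c.score > 0 for c in diff.candidates)

    def test_ties_share_group_and_sort_by_id(self):
        kb = make_kb({"B": {"F1": 0.5}, "A": {"F1": 0.5}, "C": {"F1": 0.9}})
        diff = rank_differential(kb, case({"F1"}))
        ids = [c.explanation_id for c in diff.candidates]
        assert ids == ["C", "A", "B"]
        assert diff.candidates[1].tie_group == diff.candidates[2].tie_group
        assert diff.candidates[0].tie_group != diff.candidates[1].tie_group

    def test_truncation_and_tie_cut_flag(self):
        kb = make_kb({"A": {"F1": 0.9}, "B": {"F1": 0.5}, "C": {"F1": 0.5}})
        diff = rank_differential(kb, case({"F1"}), k=2)
        assert len(diff.candidates) == 2
        assert diff.tie_cut_flag  # C has the same score as the last shown B
        diff1 = rank_differential(kb, case({"F1"}), k=1)
        assert not diff1.tie_cut_flag

    def test_matches_exhaustive_sort_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            kb, c = random_instance(rng)
            diff = rank_differential(kb, c, k=100)
            expected = sorted(
                (
                    (eid, single_score(kb, eid, c))
                    for eid in eligible_candidates(kb, c)
                ),
                key=lambda t: (-t[1], t[0]),
            )
            expected = [(e, s) for e, s in expected if s > 0]
            assert [(c_.explanation_id, c_.score) for c_ in diff.candidates] == expected

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        kb, c = random_instance(rng)
        assert rank_differential(kb, c) == rank_differential(kb, c)


class TestCoverObjectiveProperties:
    def test_monotone_and_submodular(self):
        """m(D) never decreases when D grows, and marginal gains shrink."""
        rng = np.random.default_rng(19)
        for _ in range(100):
            kb, c = random_instance(rng, n_explanations=6, n_findings=8)
            eids = sorted(kb.explanations)
            k = int(rng.integers(0, 4))
            d_small = list(rng.choice(eids, size=k, replace=False))
            extra = [e for e in eids if e not in d_small]
            d_big = d_small + list(
                rng.choice(extra, size=int(rng.integers(1, len(extra) + 1)), replace=False)
            )
            assert cover_weight(kb, d_small, c) <= cover_weight(kb, d_big, c) + 1e-12
            addition = [e for e in eids if e not in d_big]
            if not addition:
                continue
            d = addition[0]
            gain_small = cover_weight(kb, d_small + [d], c) - cover_weight(kb, d_small, c)
            gain_big = cover_weight(kb, d_big + [d], c) - cover_weight(kb, d_big, c)
            assert gain_big <= gain_small + 1e-12


class TestBayes:
    def test_single_candidate_posterior_is_one(self):
        kb = make_kb({"D1": {"F1": 1.0}})
        assert bayes_score(kb, "D1", case({"F1"})) == 1.0

    def test_hand_normalized_two_candidates(self):
        kb = make_kb({"A": {"F1": 0.8}, "B": {"F1": 0.2}})
        c = case({"F1"})
        assert bayes_score(kb, "A", c) == pytest.approx(0.8)
        assert bayes_score(kb, "B", c) == pytest.approx(0.2)

    def test_empty_observed_returns_prior(self):
        kb = make_kb({"A": {"F1": 0.8}, "B": {"F1": 0.2}})
        post = bayes_posteriors(kb, case(set()), priors={"A": 0.7, "B": 0.3})
        assert post["A"] == pytest.approx(0.7)
        assert post["B"] == pytest.approx(0.3)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            kb, c = random_instance(rng)
            post = bayes_posteriors(kb, c)
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_floor_prevents_hard_zero(self):
        kb = make_kb({"A": {"F1": 1.0}, "B": {"F1": 1.0, "F2": 1.0}})
        post = bayes_posteriors(kb, case({"F1", "F2"}))
        assert post["A"] > 0.0
        assert post["B"] > post["A"]
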