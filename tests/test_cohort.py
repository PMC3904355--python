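import numpy as np
import pytest

from conftest import make_pair, random_cohort
from oracles import brute_force_risk
from specdiv import (
    RiskConfig,
    TransplantPair,
    UndefinedResultError,
    UnorientedMismatch,
    extract_mismatches,
    high_counts_filter,
    relative_risk,
    run_risk_pipeline,
    stratify_by_severity,
    subsampled_rate,
    symmetrized_rate,
    tally_mismatches,
)
from specdiv.cohort import MismatchTally, OrientationTally, OrientedMismatch


class TestExtractMismatches:
    def test_identical_sequences_empty(self):
        assert extract_mismatches("ACDEF", "ACDEF") == []

    def test_single_mismatch_position_99(self):
        patient = "A" * 98 + "F" + "A" * 2
        donor = "A" * 98 + "Y" + "A" * 2
        assert extract_mismatches(patient, donor) == [OrientedMismatch(99, "F", "Y")]

    def test_cooccurring_mismatches(self):
        patient = "A" * 76 + "N" + "AA" + "K" + "A" * 5
        donor = "A" * 76 + "S" + "AA" + "N" + "A" * 5
        assert extract_mismatches(patient, donor) == [
            OrientedMismatch(77, "N", "S"),
            OrientedMismatch(80, "K", "N"),
        ]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            extract_mismatches("ACD", "AC")


class TestTallyMismatches:
    def test_single_orientation(self):
        pairs = [
            make_pair(f"p{i}", "A" * 72 + "A" + "A" * 3, "A" * 72 + "T" + "A" * 3, 0)
            for i in range(3)
        ]
        tallies = tally_mismatches(pairs)
        um = UnorientedMismatch.of(73, "A", "T")
        assert set(tallies) == {um}
        assert tallies[um].orientation("A", "T").count == 3
        assert tallies[um].orientation("T", "A").count == 0

    def test_pair_with_two_mismatches_in_two_tallies(self):
        pair = make_pair("p", "NKAAA", "SNAAA", 1)
        tallies = tally_mismatches([pair])
        assert set(tallies) == {
            UnorientedMismatch.of(1, "N", "S"),
            UnorientedMismatch.of(2, "K", "N"),
        }
        for t in tallies.values():
            assert t.total_count == 1
            assert t.carrier_deaths == 1

    def test_allele_pair_grouping_unordered(self):
        p1 = make_pair("p1", "AC", "AA", 0, patient_allele="X", donor_allele="Y")
        p2 = make_pair("p2", "AA", "AC", 1, patient_allele="Y", donor_allele="X")
        tallies = tally_mismatches([p1, p2])
        um = UnorientedMismatch.of(2, "A", "C")
        groups1 = tallies[um].orientation("C", "A").groups
        groups2 = tallies[um].orientation("A", "C").groups
        assert list(groups1) == [("X", "Y")]
        assert list(groups2) == [("X", "Y")]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cohort = random_cohort(rng)
            tallies = tally_mismatches(cohort)
            brute = brute_force_risk(cohort, threshold=1)
            got = {
                (t.mismatch.position, t.mismatch.res_a, t.mismatch.res_b): (
                    t.oriented_counts
                )
                for t in tallies.values()
                if min(t.oriented_counts) >= 1
            }
            expected = {
                k: (v["count_or1"], v["count_or2"]) for k, v in brute.items()
            }
            assert got == expected

    def test_conservation(self):
        rng = np.random.default_rng(1)
        cohort = random_cohort(rng, n_pairs=25)
        tallies = tally_mismatches(cohort)
        total_from_tallies = sum(t.total_count for t in tallies.values())
        total_from_pairs = sum(len(p.mismatches()) for p in cohort)
        assert total_from_tallies == total_from_pairs


def _tally_from_rates(counts_deaths: dict) -> MismatchTally:
    """Build a tally directly; keys are (patient_res, donor_res)."""
    um = UnorientedMismatch.of(1, "A", "T")
    t = MismatchTally(mismatch=um)
    for (pr, dr), (count, deaths, group) in counts_deaths.items():
        o = OrientationTally()
        outcomes = [1] * deaths + [0] * (count - deaths)
        for i, d in enumerate(outcomes):
            o.pair_ids.append(f"{pr}{dr}{i}")
            o.deaths += d
            o.groups.setdefault(group, []).append(d)
        t.orientations[(pr, dr)] = o
    return t


class TestSymmetrizedRate:
    def test_max_of_two(self):
        t = _tally_from_rates(
            {("A", "T"): (2, 1, ("x", "y")), ("T", "A"): (2, 2, ("x", "y"))}
        )
        assert symmetrized_rate(t) == 1.0

    def test_single_orientation(self):
        t = _tally_from_rates({("A", "T"): (10, 3, ("x", "y"))})
        assert symmetrized_rate(t) == pytest.approx(0.3)

    def test_equal_rates_idempotent(self):
        t = _tally_from_rates(
            {("A", "T"): (4, 2, ("x", "y")), ("T", "A"): (2, 1, ("x", "y"))}
        )
        assert symmetrized_rate(t) == pytest.approx(0.5)

    def test_empty_undefined(self):
        t = MismatchTally(mismatch=UnorientedMismatch.of(1, "A", "T"))
        with pytest.raises(UndefinedResultError):
            symmetrized_rate(t)


class TestSubsampledRate:
    def test_identity_when_groups_below_cap(self):
        t = _tally_from_rates(
            {("A", "T"): (8, 3, ("x", "y")), ("T", "A"): (5, 1, ("x", "z"))}
        )
        raw = symmetrized_rate(t)
        for seed in (0, 1, 99):
            assert subsampled_rate(t, cap=10, reps=50, seed=seed) == pytest.approx(raw)

    def test_two_group_hypergeometric_expectation(self):
        # group of 4 (2 deaths) + group of 20 (0 deaths), cap 10:
        # every replicate draws 4 + 10 pairs, expected deaths 2 + 0
        um = UnorientedMismatch.of(1, "A", "T")
        t = MismatchTally(mismatch=um)
        o = OrientationTally()
        for i, d in enumerate([1, 1, 0, 0]):
            o.pair_ids.append(f"a{i}")
            o.deaths += d
            o.groups.setdefault(("g1a", "g1b"), []).append(d)
        for i in range(20):
            o.pair_ids.append(f"b{i}")
            o.groups.setdefault(("g2a", "g2b"), []).append(0)
        t.orientations[("A", "T")] = o
        rate = subsampled_rate(t, cap=10, reps=2000, seed=5)
        assert rate == pytest.approx(2 / 14, abs=1e-12)

    def test_stochastic_group_matches_expectation(self):
        # one group of 30 pairs with 12 deaths, cap 10:
        # E[deaths drawn] = 10 * 12/30 = 4, so E[rate] = 0.4
        t = _tally_from_rates({("A", "T"): (30, 12, ("x", "y"))})
        reps = 4000
        rate = subsampled_rate(t, cap=10, reps=reps, seed=7)
        # per-replicate variance of a hypergeometric draw / 10
        var = 10 * 0.4 * 0.6 * (30 - 10) / (30 - 1) / 100
        se = np.sqrt(var / reps)
        assert abs(rate - 0.4) < 3 * se

    def test_deterministic_per_seed(self):
        t = _tally_from_rates({("A", "T"): (30, 12, ("x", "y"))})
        assert subsampled_rate(t, 10, 200, 3) == subsampled_rate(t, 10, 200, 3)
        assert subsampled_rate(t, 10, 200, 3) != subsampled_rate(t, 10, 200, 4)

    def test_convergence_rate(self):
        # std over seeds shrinks as 1/sqrt(reps)
        t = _tally_from_rates({("A", "T"): (40, 15, ("x", "y"))})
        stds = []
        for reps in (100, 400, 1600):
            vals = [subsampled_rate(t, 10, reps, s) for s in range(30)]
            stds.append(np.std(vals))
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.5)
        assert stds[1] / stds[2] == pytest.approx(2.0, rel=0.5)

    def test_empty_undefined(self):
        t = MismatchTally(mismatch=UnorientedMismatch.of(1, "A", "T"))
        with pytest.raises(UndefinedResultError):
            subsampled_rate(t, 10, 10, 0)


class TestRelativeRisk:
    def test_hand_example(self, hand_cohort):
        um = UnorientedMismatch.of(5, "A", "C")
        config = RiskConfig(high_counts_threshold=1, subsample_cap=10,
                            subsample_reps=100, seed=0)
        rec = relative_risk(um, hand_cohort, config, rate_mode="raw")
        assert rec.rate_symmetrized == 1.0
        assert rec.rate_complement == pytest.approx(1 / 3)
        assert rec.relative_risk == pytest.approx(3.0)
        assert rec.count_or1 == 2 and rec.count_or2 == 2
        assert rec.rate_oriented_1 == pytest.approx(0.5)
        assert rec.rate_oriented_2 == pytest.approx(1.0)

    def test_mismatch_in_every_pair_undefined(self):
        pairs = [make_pair(f"p{i}", "AC", "AA", i % 2) for i in range(4)]
        config = RiskConfig(high_counts_threshold=1, seed=0)
        rec = relative_risk(UnorientedMismatch.of(2, "A", "C"), pairs, config)
        assert rec.relative_risk is None
        assert rec.rate_complement is None

    def test_equal_rates_give_unity(self):
        pairs = [
            make_pair("p1", "AC", "AA", 1),
            make_pair("p2", "AC", "AA", 0),
            make_pair("p3", "AD", "AA", 1),
            make_pair("p4", "AD", "AA", 0),
        ]
        config = RiskConfig(high_counts_threshold=1, seed=0)
        rec = relative_risk(UnorientedMismatch.of(2, "A", "C"), pairs, config,
                            rate_mode="raw")
        assert rec.relative_risk == pytest.approx(1.0)

    def test_absent_mismatch_rejected(self, hand_cohort):
        config = RiskConfig(high_counts_threshold=1, seed=0)
        with pytest.raises(ValueError, match="not present"):
            relative_risk(UnorientedMismatch.of(9, "W", "Y"), hand_cohort, config)


class TestHighCountsFilter:
    def _tallies(self, c1, c2):
        t = _tally_from_rates(
            {("A", "T"): (c1, 0, ("x", "y")), ("T", "A"): (c2, 0, ("x", "y"))}
        )
        return {t.mismatch: t}

    def test_both_above_kept(self):
        assert len(high_counts_filter(self._tallies(120, 105), 100)) == 1

    def test_one_below_dropped(self):
        assert len(high_counts_filter(self._tallies(120, 80), 100)) == 0

    def test_threshold_one_keeps_bidirectional(self):
        assert len(high_counts_filter(self._tallies(1, 1), 1)) == 1
        single = _tally_from_rates({("A", "T"): (5, 0, ("x", "y"))})
        assert len(high_counts_filter({single.mismatch: single}, 1)) == 0


class TestStratifyBySeverity:
    def test_exclude_high(self):
        pairs = [
            make_pair(f"p{i}", "AC", "AA", 0,
                      severity="high" if i < 3 else "low")
            for i in range(10)
        ]
        kept = stratify_by_severity(pairs, {"high"})
        assert len(kept) == 7
        assert all(p.severity == "low" for p in kept)

    def test_exclude_nothing_is_identity(self):
        pairs = [make_pair("p", "AC", "AA", 0)]
        assert stratify_by_severity(pairs, set()) == pairs

    def test_exclude_all_empties(self):
        pairs = [make_pair("p", "AC", "AA", 0)]
        assert stratify_by_severity(pairs, {"low", "intermediate", "high"}) == []
        with pytest.raises(UndefinedResultError):
            run_risk_pipeline(
                pairs,
                RiskConfig(high_counts_threshold=1, seed=0,
                           exclude_severities=frozenset(
                               {"low", "intermediate", "high"})),
            )

    def test_unknown_label_rejected_at_load(self):
        with pytest.raises(ValueError, match="severity"):
            TransplantPair("p", "X", "Y", "AC", "AA", 0, "critical")
        with pytest.raises(ValueError):
            stratify_by_severity([], {"severe"})


class TestRunRiskPipeline:
    def test_deterministic(self, hand_cohort):
        config = RiskConfig(high_counts_threshold=1, subsample_reps=100, seed=3)
        r1 = run_risk_pipeline(hand_cohort, config)
        r2 = run_risk_pipeline(hand_cohort, config)
        assert r1 == r2

    def test_hand_cohort_full_output(self, hand_cohort):
        config = RiskConfig(high_counts_threshold=1, subsample_reps=50, seed=0)
        records = run_risk_pipeline(hand_cohort, config, rate_mode="raw")
        by_key = {
            (r.mismatch.position, r.mismatch.res_a, r.mismatch.res_b): r
            for r in records
        }
        brute = brute_force_risk(hand_cohort, threshold=1)
        assert set(by_key) == set(brute)
        rec = by_key[(5, "A", "C")]
        assert rec.relative_risk == pytest.approx(3.0)

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            cohort = random_cohort(rng)
            # cap larger than any group so adjusted == raw
            config = RiskConfig(high_counts_threshold=1, subsample_cap=1000,
                                subsample_reps=5, seed=1)
            records = run_risk_pipeline(cohort, config, rate_mode="adjusted")
            brute = brute_force_risk(cohort, threshold=1)
            got = {
                (r.mismatch.position, r.mismatch.res_a, r.mismatch.res_b): r
                for r in records
            }
            assert set(got) == set(brute)
            for key, exp in brute.items():
                rec = got[key]
                assert rec.rate_symmetrized == pytest.approx(exp["rate_symmetrized"])
                assert rec.rate_adjusted == pytest.approx(exp["rate_symmetrized"])
                if exp["relative_risk"] is None:
                    assert rec.relative_risk is None
                else:
                    assert rec.relative_risk == pytest.approx(exp["relative_risk"])

    def test_debiasing_moves_adjusted_rate(self):
        # one allele pair contributes 200 pairs with atypical outcomes
        # (all deaths); a second contributes 10 pairs with none.
        pairs = []
        for i in range(200):
            pairs.append(make_pair(f"big{i}", "AC", "AA", 1,
                                   patient_allele="C*03:03",
                                   donor_allele="C*03:04"))
        for i in range(10):
            pairs.append(make_pair(f"small{i}", "AC", "AA", 0,
                                   patient_allele="C*03:03",
                                   donor_allele="C*07:01"))
        um = UnorientedMismatch.of(2, "A", "C")
        tallies = tally_mismatches(pairs)
        raw = symmetrized_rate(tallies[um])
        adjusted = subsampled_rate(tallies[um], cap=10, reps=500, seed=0)
        dedup_rate = 0.5  # 10 deaths + 0 deaths over 20 pairs after capping
        assert raw == pytest.approx(200 / 210)
        assert adjusted == pytest.approx(dedup_rate, abs=1e-12)
        assert abs(adjusted - dedup_rate) < abs(raw - dedup_rate)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_risk_pipeline([], RiskConfig(seed=0))


class TestTransplantPairValidation:
    def test_matched_pair_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            make_pair("p", "AC", "AC", 0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            make_pair("p", "AC", "ACD", 0)

    def test_bad_death_rejected(self):
        with pytest.raises(ValueError, match="death"):
            make_pair("p", "AC", "AA", 2)
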