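"""Scoring components against hand computations and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest

from ppirank.datamodel import CONTROL_GROUP, PurificationTable, Run, ValidationError
from ppirank.datamodel import collect_pair_evidence
from ppirank.scoring import (
    ScoringConfig,
    compass_wd,
    compass_z,
    freq_repro_term,
    nsaf,
    nsaf_mean,
    ppirank_score,
    score_all,
    variance_weight,
)

SQRT3 = math.sqrt(3.0)  # CV of a (c, 0, 0, 0) cross-bait profile, population std


def mini_table(run_preys, lengths, controls=1):
    """One-bait helper: run_preys maps run_id -> {prey: sc}."""
    runs = [Run(r, "X", False, "X", "") for r in run_preys]
    runs += [Run(f"c{i}", CONTROL_GROUP, True) for i in range(controls)]
    counts = {(r, p): sc for r, d in run_preys.items() for p, sc in d.items()}
    return PurificationTable(runs, counts, lengths)


class TestNSAF:
    def test_single_detected_prey_normalizes_to_one(self):
        t = mini_table({"r1": {"P1": 7}}, {"P1": 100})
        assert nsaf(t, "r1") == {"P1": 1.0}

    def test_equal_saf_symmetry(self):
        t = mini_table({"r1": {"P1": 10, "P2": 5}}, {"P1": 100, "P2": 50})
        values = nsaf(t, "r1")
        assert values["P1"] == pytest.approx(0.5) and values["P2"] == pytest.approx(0.5)

    def test_matches_independent_normalization_oracle(self):
        rng = np.random.default_rng(7)
        preys = {f"P{i}": int(rng.integers(50, 2000)) for i in range(20)}
        scs = {p: int(rng.integers(1, 40)) for p in preys}
        t = mini_table({"r1": scs}, preys)
        got = nsaf(t, "r1")
        saf = np.array([scs[p] / preys[p] for p in sorted(preys)])
        expected = saf / saf.sum()
        for p, e in zip(sorted(preys), expected):
            assert got[p] == pytest.approx(e, abs=1e-12)

    def test_empty_run_warns(self):
        t = mini_table({"r1": {"P1": 5}, "r2": {}}, {"P1": 100})
        with pytest.warns(UserWarning, match="no detected preys"):
            assert nsaf(t, "r2") == {}

    def test_sums_to_one_on_toy(self, toy_table):
        for run in toy_table.runs:
            if toy_table.run_counts(run.run_id):
                assert sum(nsaf(toy_table, run.run_id).values()) == pytest.approx(1.0, abs=1e-12)


class TestNSAFMean:
    def test_mean_includes_zero_replicates(self):
        # replicate r1: target has NSAF 3/10 vs filler 7/10; absent in r2, r3
        t = mini_table(
            {"r1": {"Q": 3, "R": 7}, "r2": {"R": 7}, "r3": {"R": 7}},
            {"Q": 10, "R": 10},
        )
        assert nsaf_mean(t, "X", "Q") == pytest.approx(0.1)

    def test_absent_prey_is_zero(self, toy_table):
        assert nsaf_mean(toy_table, "B", "PX") == 0.0

    def test_matches_per_replicate_oracle(self, toy_table):
        for prey in ("PX", "PALL", "PU"):
            per_run = []
            for run_id in toy_table.bait_groups["A"]:
                values = nsaf(toy_table, run_id)
                per_run.append(values.get(prey, 0.0))
            assert nsaf_mean(toy_table, "A", prey) == pytest.approx(np.mean(per_run))


class TestVarianceWeight:
    def test_constant_profile_gives_unit_weight(self, toy_table):
        assert variance_weight(toy_table, "PALL") == 1.0

    def test_single_group_prey_population_convention(self, toy_table):
        # PU: per-group means (8, 0, 0, 0) -> CV = sqrt(3) under population std
        assert variance_weight(toy_table, "PU") == pytest.approx(SQRT3)

    def test_threshold_branch(self, toy_table):
        # PLOW: means (5, 5, 5, 3) -> CV = sqrt(0.75)/4.5 < 1
        cfg0 = ScoringConfig(w_threshold=0.0)
        cfg1 = ScoringConfig(w_threshold=1.0)
        cv = math.sqrt(0.75) / 4.5
        assert variance_weight(toy_table, "PLOW", cfg0) == pytest.approx(cv)
        assert variance_weight(toy_table, "PLOW", cfg1) == 1.0

    def test_undetected_prey_unit_weight(self, toy_table):
        assert variance_weight(toy_table, "PCTL") == 1.0

    def test_sample_convention(self, toy_table):
        cfg = ScoringConfig(std_convention="sample")
        x = np.array([8.0, 0, 0, 0])
        assert variance_weight(toy_table, "PU", cfg) == pytest.approx(
            np.std(x, ddof=1) / x.mean()
        )


class TestCompassZ:
    def test_constant_prey_is_zero(self, toy_table):
        assert compass_z(toy_table, "A", "PALL") == 0.0

    def test_unique_prey_hand_value(self, toy_table):
        # x = (8,0,0,0): mean 2, population std sqrt(12)
        assert compass_z(toy_table, "A", "PU") == pytest.approx(6 / math.sqrt(12))

    def test_standardization_identity(self, toy_table):
        total = sum(compass_z(toy_table, g, "PU") for g in toy_table.bait_groups)
        assert total == pytest.approx(0.0, abs=1e-12)


class TestCompassWD:
    def test_undetected_pair_is_zero(self, toy_table):
        assert compass_wd(toy_table, "B", "PU") == 0.0

    def test_everywhere_prey_reduces_to_sqrt_sc(self, toy_table):
        # PALL: W = 1 and K/Σf = 1, so WD = sqrt(mean SC) regardless of N
        assert compass_wd(toy_table, "C", "PALL") == pytest.approx(math.sqrt(5))

    def test_matches_formula_oracle(self, toy_table):
        for group, prey in [("A", "PU"), ("A", "PX"), ("D", "PLOW"), ("A", "PSING")]:
            pair = collect_pair_evidence(toy_table, group, prey)
            k = toy_table.n_bait_groups
            sigma_f = len(toy_table.detected_groups(prey))
            w = variance_weight(toy_table, prey)
            expected = math.sqrt(pair.mean_sc * ((k / sigma_f) * w) ** pair.detect_count)
            assert compass_wd(toy_table, group, prey) == pytest.approx(expected)


class TestFreqReproTerm:
    def test_fully_reproducible_unique_prey(self, toy_table):
        # PU unique to A, detected in all 3 replicates: term = W * K
        pair = collect_pair_evidence(toy_table, "A", "PU")
        assert freq_repro_term(pair, toy_table) == pytest.approx(SQRT3 * 4)

    def test_one_of_three_replicates_takes_cube_root(self, toy_table):
        pair = collect_pair_evidence(toy_table, "A", "PSING")
        assert freq_repro_term(pair, toy_table) == pytest.approx(SQRT3 * 4 ** (1 / 3))

    def test_everywhere_prey_reduces_to_weight(self, toy_table):
        pair = collect_pair_evidence(toy_table, "B", "PALL")
        assert freq_repro_term(pair, toy_table) == pytest.approx(
            variance_weight(toy_table, "PALL")
        )

    def test_undetected_pair_is_contract_violation(self, toy_table):
        pair = collect_pair_evidence(toy_table, "B", "PU")
        with pytest.raises(ValidationError):
            freq_repro_term(pair, toy_table)

    def test_joint_exponent_mode(self, toy_table):
        cfg = ScoringConfig(exponent_mode="joint")
        pair = collect_pair_evidence(toy_table, "A", "PSING")
        assert freq_repro_term(pair, toy_table, cfg) == pytest.approx(
            (SQRT3 * 4) ** (1 / 3)
        )


class TestPPIRankScore:
    def test_undetected_pair_scores_zero(self, toy_table):
        pair = collect_pair_evidence(toy_table, "B", "PU")
        assert ppirank_score(pair, toy_table, fdr=0.1) == 0.0

    def test_zero_fdr_reduces_to_abundance_times_term(self, toy_table):
        pair = collect_pair_evidence(toy_table, "A", "PU")
        expected = nsaf_mean(toy_table, "A", "PU") * freq_repro_term(pair, toy_table)
        assert ppirank_score(pair, toy_table, fdr=0.0) == pytest.approx(expected)

    def test_composition_identity(self, toy_table):
        """Score equals NSAF̄ × (1−FDR)^T × W × (K/Σf)^R piece by piece."""
        for group, prey in [("A", "PX"), ("A", "PU"), ("C", "PLOW")]:
            pair = collect_pair_evidence(toy_table, group, prey)
            fdr = 0.2
            t = len(pair.sc_replicates)
            expected = (
                nsaf_mean(toy_table, group, prey)
                * (1 - fdr) ** t
                * freq_repro_term(pair, toy_table)
            )
            assert ppirank_score(pair, toy_table, fdr) == pytest.approx(expected)

    def test_fdr_outside_range_rejected(self, toy_table):
        pair = collect_pair_evidence(toy_table, "A", "PU")
        with pytest.raises(ValidationError):
            ppirank_score(pair, toy_table, fdr=0.7)


class TestScoreAll:
    def test_one_row_per_detected_pair(self, toy_table):
        scores = score_all(toy_table)
        expected = sum(
            len(toy_table.detected_preys(g)) for g in toy_table.bait_groups
        )
        assert len(scores.frame) == expected
        # control-only preys never scored
        assert "PCTL" not in set(scores.frame["prey"])

    def test_filters_flag_not_drop(self, toy_table):
        scores = score_all(toy_table)
        df = scores.frame
        flagged = df[df["filtered"]]
        assert set(flagged["prey"]) == {"PONE"}  # the all-singleton SC pattern
        ranks = df.loc[~df["filtered"], "rank"]
        assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_batch_matches_single_pair_recomputation(self, toy_table):
        from ppirank import control_stats

        scores = score_all(toy_table)
        for row in scores.frame.itertuples(index=False):
            pair = collect_pair_evidence(toy_table, row.bait, row.prey)
            result = control_stats.ranksum_p(pair.sc_replicates, pair.sc_controls)
            fdr = control_stats.fdr_from_p(result.p_value)
            assert row.p == result.p_value
            assert row.fdr == fdr
            assert row.ppirank == ppirank_score(pair, toy_table, fdr)
            assert row.nsaf == nsaf_mean(toy_table, row.bait, row.prey)
            assert row.w == variance_weight(toy_table, row.prey)
            assert row.z == compass_z(toy_table, row.bait, row.prey)
            assert row.wd == compass_wd(toy_table, row.bait, row.prey)

    def test_input_order_invariance(self, toy_table):
        shuffled_runs = list(reversed(toy_table.runs))
        counts = {
            (r.run_id, p): sc
            for r in toy_table.runs
            for p, sc in toy_table.run_counts(r.run_id).items()
        }
        reordered_counts = dict(reversed(list(counts.items())))
        # keep run order per group identical; only count insertion order changes
        other = PurificationTable(toy_table.runs, reordered_counts, toy_table.prey_lengths)
        a = score_all(toy_table).frame.reset_index(drop=True)
        b = score_all(other).frame.reset_index(drop=True)
        assert a.equals(b)

    def test_no_controls_is_actionable_error(self):
        t = PurificationTable(
            [Run("r1", "X", False, "X", "")], {("r1", "P1"): 5}, {"P1": 100}
        )
        with pytest.raises(ValidationError, match="negative controls"):
            score_all(t)

    def test_few_replicates_warns(self):
        t = mini_table({"r1": {"P1": 5}}, {"P1": 100}, controls=2)
        with pytest.warns(UserWarning, match="three biological replicates"):
            score_all(t)

    def test_rank_ties_broken_deterministically(self, toy_table):
        df = score_all(toy_table).frame
        kept = df[~df["filtered"]].sort_values("rank")
        keys = list(zip(-kept["ppirank"], kept["bait"], kept["prey"]))
        assert keys == sorted(keys)


class TestScoringConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ScoringConfig(w_threshold=1.0, std_convention="sample")
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(path))
        assert ScoringConfig.from_yaml(str(path)) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("nonsense: 1\n", encoding="utf-8")
        with pytest.raises(ValidationError, match="nonsense"):
            ScoringConfig.from_yaml(str(path))

    def test_unconventional_threshold_flagged(self):
        with pytest.warns(UserWarning, match="w_threshold"):
            ScoringConfig(w_threshold=0.5)
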