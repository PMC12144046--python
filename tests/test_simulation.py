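from __future__ import annotations

import numpy as np
import pytest

from pairworth import (
    Outcome,
    PreferenceModel,
    SimulationConfig,
    SimulationRun,
    determine_cutoff,
    generate_choices,
    scenario,
    select_best_run,
    simulate_from_complete,
    simulate_positions,
    summarize_ci,
)
from pairworth.simulation import (
    EmptyResultError,
    SimulationConfigError,
    SimulationResult,
    mask_target,
    missing_cells,
    randomize_unknowns,
)


@pytest.fixture(scope="module")
def wide_outcomes():
    """Complete thresholded outcomes from a well-separated 5-option truth."""
    ds = generate_choices(scenario("WIDE_VALENCE", seed=5))
    return PreferenceModel.from_dataset(ds, 0.5).outcomes


class TestConfigValidation:
    def test_target_excluded_from_tested_against(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(target="X", tested_against=("X", "A"))

    @pytest.mark.parametrize("kwargs", [
        {"runs": 0},
        {"intransitivity_cutoff": 1.5},
        {"tie_probability": 1.0},
    ])
    def test_out_of_range_fields(self, kwargs):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(target="X", **kwargs)


class TestRandomizeUnknowns:
    def test_nothing_missing_returns_input(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O1", "O2", "O3", "O5"))
        rng = np.random.default_rng(0)
        options = [f"O{i}" for i in range(1, 6)]
        subjects = [f"S{i}" for i in range(1, 12)]
        out = randomize_unknowns(wide_outcomes, cfg, rng, options, subjects)
        assert out == list(wide_outcomes)

    def test_fills_exactly_the_missing_cells(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O1", "O2", "O3"))
        masked = mask_target(wide_outcomes, "O4", cfg.tested_against)
        options = [f"O{i}" for i in range(1, 6)]
        subjects = [f"S{i}" for i in range(1, 12)]
        assert len(missing_cells(masked, "O4", options, subjects)) == 11
        completed = randomize_unknowns(
            masked, cfg, np.random.default_rng(0), options, subjects
        )
        added = [o for o in completed if o not in masked]
        assert len(added) == 11
        assert all(set(o.pair) == {"O4", "O5"} for o in added)
        assert all(o.result is not Outcome.TIE for o in added)

    def test_reproducible_from_seed(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O1", "O2"))
        masked = mask_target(wide_outcomes, "O4", cfg.tested_against)
        options = [f"O{i}" for i in range(1, 6)]
        subjects = [f"S{i}" for i in range(1, 12)]
        a = randomize_unknowns(masked, cfg, np.random.default_rng(9), options, subjects)
        b = randomize_unknowns(masked, cfg, np.random.default_rng(9), options, subjects)
        c = randomize_unknowns(masked, cfg, np.random.default_rng(10), options, subjects)
        assert a == b
        assert a != c

    def test_ties_only_when_enabled(self, wide_outcomes):
        cfg = SimulationConfig(
            target="O4", tested_against=(), randomize_ties=True, tie_probability=0.9
        )
        masked = mask_target(wide_outcomes, "O4", ())
        options = [f"O{i}" for i in range(1, 6)]
        subjects = [f"S{i}" for i in range(1, 12)]
        completed = randomize_unknowns(
            masked, cfg, np.random.default_rng(2), options, subjects
        )
        added = [o for o in completed if o not in masked]
        assert any(o.result is Outcome.TIE for o in added)

    def test_unknown_target_rejected(self, wide_outcomes):
        cfg = SimulationConfig(target="NOPE")
        with pytest.raises(SimulationConfigError):
            randomize_unknowns(
                wide_outcomes, cfg, np.random.default_rng(0),
                [f"O{i}" for i in range(1, 6)], ["S1"],
            )


class TestSimulatePositions:
    def test_complete_tested_against_is_degenerate(self, wide_outcomes):
        cfg = SimulationConfig(
            target="O3", tested_against=("O1", "O2", "O4", "O5"), runs=10, seed=1
        )
        result = simulate_from_complete(wide_outcomes, cfg)
        assert result.true_positive_frequency == 1.0
        positions = {r.position for r in result.runs}
        assert positions == {result.true_position}

    def test_deterministic_for_fixed_seed(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O2", "O3"), runs=30, seed=3)
        r1 = simulate_from_complete(wide_outcomes, cfg)
        r2 = simulate_from_complete(wide_outcomes, cfg)
        assert r1.to_json() == r2.to_json()

    def test_position_frequencies_form_distribution(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O2",), runs=40, seed=4)
        result = simulate_from_complete(wide_outcomes, cfg)
        assert sum(result.position_frequencies.values()) == pytest.approx(1.0)
        assert all(1 <= p <= 5 for p in result.position_frequencies)
        assert result.true_positive_frequency == pytest.approx(
            result.true_positive_count / len(result.runs)
        )

    def test_modal_position_matches_truth(self, wide_outcomes):
        cfg = SimulationConfig(
            target="O4", tested_against=("O1", "O2", "O3"), runs=200, seed=6
        )
        result = simulate_from_complete(wide_outcomes, cfg)
        modal = max(result.position_frequencies.items(), key=lambda kv: kv[1])[0]
        assert modal == result.true_position

    def test_informed_retains_only_below_cutoff(self, wide_outcomes):
        cfg = SimulationConfig(
            target="O4", tested_against=("O2",), runs=60, seed=7,
            informed=True, intransitivity_cutoff=0.1,
        )
        result = simulate_from_complete(wide_outcomes, cfg)
        assert result.runs, "filter should retain at least one run here"
        assert result.discarded_runs > 0, "filter should discard some runs here"
        assert all(r.i_ratio <= 0.1 for r in result.runs)
        assert result.discarded_runs == 60 - len(result.runs)

    def test_informed_cutoff_zero_on_transitive_data_discards_nothing(self):
        # a perfectly separated forced-choice truth with complete testing:
        # nothing is randomized and every run is fully transitive
        from pairworth import GeneratorSpec, Style

        ds = generate_choices(
            GeneratorSpec(
                worth_true=(0.9, 0.08, 0.02),
                n_subjects=6,
                trials_per_pair=1,
                style=Style.FORCED_CHOICE,
                noise=0.0,
                seed=0,
            )
        )
        outcomes = PreferenceModel.from_dataset(ds, 0.5).outcomes
        cfg = SimulationConfig(
            target="O2", tested_against=("O1", "O3"), runs=10, seed=0,
            informed=True, intransitivity_cutoff=0.0,
        )
        result = simulate_from_complete(outcomes, cfg)
        assert result.discarded_runs == 0

    def test_empty_informed_result_raises(self, wide_outcomes):
        # narrow data are heavily intransitive; a cutoff of 0 rejects all runs
        ds = generate_choices(scenario("NARROW_VALENCE", seed=2))
        outcomes = PreferenceModel.from_dataset(ds, 0.5).outcomes
        cfg = SimulationConfig(
            target="O2", tested_against=("O1",), runs=5, seed=0,
            informed=True, intransitivity_cutoff=0.0,
        )
        with pytest.raises(EmptyResultError):
            simulate_from_complete(outcomes, cfg)


class TestSelectBestRun:
    def _result(self, runs):
        cfg = SimulationConfig(target="X", runs=len(runs))
        res = SimulationResult(config=cfg, options=["X", "Y"], runs=runs)
        return res

    def test_lexicographic_order(self):
        runs = [
            SimulationRun(0, {"X": 0.5}, 1, 0.05, 40.0),
            SimulationRun(1, {"X": 0.5}, 1, 0.00, 45.0),
            SimulationRun(2, {"X": 0.5}, 1, 0.00, 31.0),
        ]
        assert select_best_run(self._result(runs)).run_index == 2

    def test_single_run(self):
        runs = [SimulationRun(0, {"X": 0.5}, 1, 0.1, 50.0)]
        assert select_best_run(self._result(runs)) is runs[0]

    def test_tie_broken_by_run_index(self):
        runs = [
            SimulationRun(1, {"X": 0.5}, 1, 0.0, 30.0),
            SimulationRun(0, {"X": 0.5}, 1, 0.0, 30.0),
        ]
        assert select_best_run(self._result(runs)).run_index == 0

    def test_matches_full_sort_oracle(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O2",), runs=100, seed=8)
        result = simulate_from_complete(wide_outcomes, cfg)
        expected = sorted(result.runs, key=lambda r: (r.i_ratio, r.ce, r.run_index))[0]
        assert select_best_run(result) == expected

    def test_empty_raises(self):
        cfg = SimulationConfig(target="X")
        with pytest.raises(EmptyResultError):
            select_best_run(SimulationResult(config=cfg, options=["X"], runs=[]))


class TestSummarizeCI:
    def test_constant_worth_zero_width(self):
        runs = [SimulationRun(i, {"X": 0.4, "Y": 0.6}, 1, 0.0, 0.0) for i in range(5)]
        mean, lo, hi = summarize_ci(runs)
        assert lo["X"] == hi["X"] == mean["X"] == 0.4

    def test_width_shrinks_with_root_k(self):
        rng = np.random.default_rng(0)
        base = [
            SimulationRun(i, {"X": float(0.4 + v)}, 1, 0.0, 0.0)
            for i, v in enumerate(rng.normal(0, 0.05, size=50))
        ]
        doubled = base + [
            SimulationRun(50 + r.run_index, dict(r.worth), 1, 0.0, 0.0) for r in base
        ]
        _, lo1, hi1 = summarize_ci(base)
        _, lo2, hi2 = summarize_ci(doubled)
        w1 = hi1["X"] - lo1["X"]
        w2 = hi2["X"] - lo2["X"]
        # duplicating every run halves the variance estimate's sqrt(k) factor
        # (sd unchanged up to ddof, k doubled)
        assert w2 == pytest.approx(w1 / np.sqrt(2), rel=0.02)

    def test_matches_independent_recomputation(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O2", "O3"), runs=40, seed=9)
        result = simulate_from_complete(wide_outcomes, cfg)
        xs = np.array([r.worth["O4"] for r in result.runs])
        half = 1.959963984540054 * xs.std(ddof=1) / np.sqrt(len(xs))
        assert result.mean_worth["O4"] == pytest.approx(xs.mean())
        assert result.ci_lower["O4"] == pytest.approx(xs.mean() - half)
        assert result.ci_upper["O4"] == pytest.approx(xs.mean() + half)

    def test_needs_two_runs(self):
        with pytest.raises(ValueError):
            summarize_ci([SimulationRun(0, {"X": 0.5}, 1, 0.0, 0.0)])


class TestDetermineCutoff:
    def test_complete_testing_needs_one_run(self, wide_outcomes):
        cfg = SimulationConfig(target="O3", tested_against=("O1", "O2", "O4", "O5"))
        assert determine_cutoff(wide_outcomes, cfg, max_runs=16) == (1, False)

    def test_separable_truth_terminates(self, wide_outcomes):
        cfg = SimulationConfig(target="O2", tested_against=("O1", "O3", "O4"), seed=1)
        masked = mask_target(wide_outcomes, "O2", cfg.tested_against)
        runs, ambiguous = determine_cutoff(masked, cfg, max_runs=256)
        assert not ambiguous
        assert runs <= 256

    def test_exactly_symmetric_options_are_ambiguous(self):
        # A and B are exactly interchangeable in the observed data (each
        # splits 4:4 against C; A-vs-B unobserved), so no number of
        # randomized completions can separate the target from B
        from pairworth import BinaryOutcome

        outcomes = []
        for s in range(8):
            res = Outcome.A_WINS if s < 4 else Outcome.B_WINS
            outcomes.append(BinaryOutcome(f"S{s}", "A", "C", res))
            outcomes.append(BinaryOutcome(f"S{s}", "B", "C", res))
        cfg = SimulationConfig(target="A", tested_against=("C",), seed=3)
        runs, ambiguous = determine_cutoff(
            outcomes, cfg, max_runs=16,
            options=["A", "B", "C"], subjects=[f"S{s}" for s in range(8)],
        )
        assert ambiguous
        assert runs == 16


class TestReportTable:
    def test_table_columns_match_reporting_convention(self, wide_outcomes):
        cfg = SimulationConfig(target="O4", tested_against=("O2", "O3"), runs=30, seed=2)
        table = simulate_from_complete(wide_outcomes, cfg).to_table()
        assert list(table.columns) == [
            "Item",
            "Simulated position",
            "Worth value",
            "I-ratio",
            "CE (%)",
            "Frequency of true positives",
            "No. of true positives",
            "Tested against",
        ]
        row = table.iloc[0]
        assert row["Item"] == "O4"
        assert row["Tested against"] == "O2, O3"
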