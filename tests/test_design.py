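"""Trial design generation and behavioral quantities."""

import numpy as np
import pandas as pd
import pytest

from morphrsa.design import (
    MORPH_PAIRS,
    PRIOR_MORPH_COMBOS,
    DesignConfig,
    DesignError,
    PrecisionTable,
    TrialTable,
    assimilation_index,
    compute_precision,
    generate_block_design,
    split_partial_rts,
    _stimulus_identities,
)
from morphrsa.simulate import simulate_behavior


def max_run_lengths(trials: TrialTable) -> dict[str, int]:
    """Run-length oracle: scan the sequence per identity."""
    out = {}
    for ident in "ABCD":
        best = run = 0
        for stim in trials.data["stimulus"]:
            if ident in _stimulus_identities(stim):
                run += 1
                best = max(best, run)
            else:
                run = 0
        out[ident] = best
    return out


class TestBlockDesign:
    def test_composition_matches_study_design(self, block):
        counts = block.condition_counts()
        assert counts == {"match": 16, "partial": 48, "mismatch": 12,
                          "catch": 12, "neutral": 16, "neutral_catch": 3,
                          "null": 36}
        assert len(block.experimental) == 107

    def test_partial_trials_cover_all_combinations_uniformly(self, block):
        partial = block.partial
        combos = partial.groupby(["prior", "stimulus"]).size()
        assert len(combos) == 12
        assert set(combos.index) == set(PRIOR_MORPH_COMBOS)
        assert (combos == 4).all()

    def test_partial_morph_always_contains_prior(self, block):
        for _, row in block.partial.iterrows():
            assert row["prior"] in row["stimulus"].split("+")

    def test_deterministic_for_fixed_seed(self, design_config):
        a = generate_block_design(design_config, seed=5)
        b = generate_block_design(design_config, seed=5)
        assert a.data.equals(b.data)
        c = generate_block_design(design_config, seed=6)
        assert not a.data.equals(c.data)

    @pytest.mark.parametrize("seed", range(8))
    def test_run_length_constraints_hold(self, design_config, seed):
        trials = generate_block_design(design_config, seed=seed)
        assert max(max_run_lengths(trials).values()) <= design_config.max_identity_run
        null_runs = (trials.data["condition"] == "null").astype(int)
        run = best = 0
        for v in null_runs:
            run = run + 1 if v else 0
            best = max(best, run)
        assert best <= design_config.max_null_run

    def test_unsatisfiable_constraints_raise(self):
        cfg = DesignConfig(n_match=30, n_partial=0, n_mismatch=0, n_catch=0,
                           n_neutral=0, n_neutral_catch=0, n_null=0,
                           max_identity_run=2, identities=("A",),
                           max_attempts=50)
        with pytest.raises(DesignError, match="constraint"):
            generate_block_design(cfg, seed=0)

    def test_tsv_round_trip(self, block, tmp_path):
        path = tmp_path / "block.tsv"
        block.to_tsv(path)
        back = TrialTable.from_tsv(path)
        assert back.data["condition"].equals(block.data["condition"])
        assert back.data["stimulus"].equals(block.data["stimulus"])

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = DesignConfig(n_match=8, response_window_ms=1200.0)
        path = tmp_path / "design.yaml"
        cfg.to_yaml(path)
        assert DesignConfig.from_yaml(path) == cfg


class TestPrecision:
    def test_eq3_arithmetic_identity(self, block):
        beh = simulate_behavior(0.4, block, seed=9)
        table = compute_precision(beh, mode="keyed")
        for _, row in table.data.iterrows():
            assert row["n"] == row["n_prior"] + row["n_otherpart"]
            if row["n"] > 0:
                expected = (row["n_prior"] - row["n_otherpart"]) / row["n"]
                assert row["precision"] == pytest.approx(expected)
                assert -1.0 <= row["precision"] <= 1.0

    def test_boundary_values(self, block):
        always = compute_precision(simulate_behavior(1.0, block, seed=1,
                                                     invalid_rate=0.0))
        assert (always.data["precision"] == 1.0).all()
        never = compute_precision(simulate_behavior(-1.0, block, seed=1,
                                                    invalid_rate=0.0))
        assert (never.data["precision"] == -1.0).all()

    def test_worked_example_six_two_two(self):
        # 6 expected, 2 unexpected, 2 invalid responses -> (6-2)/8 = 0.5
        rows = []
        responses = ["A"] * 6 + ["B"] * 2 + ["C"] * 2
        for i, resp in enumerate(responses):
            rows.append({"trial_index": i, "block": 0, "condition": "partial",
                         "prior": "A", "stimulus": "A+B", "response": resp,
                         "rt_ms": 700.0, "valid": True})
        table = compute_precision(TrialTable(pd.DataFrame(rows)))
        assert table.get("A", "A+B") == pytest.approx(0.5)
        assert table.data.iloc[0]["n"] == 8

    def test_slow_responses_excluded(self):
        rows = [{"trial_index": i, "block": 0, "condition": "partial",
                 "prior": "A", "stimulus": "A+B", "response": "A",
                 "rt_ms": rt, "valid": True}
                for i, rt in enumerate([500, 500, 2000, 2000])]
        table = compute_precision(TrialTable(pd.DataFrame(rows)),
                                  response_window_ms=1500.0)
        assert table.data.iloc[0]["n"] == 2

    def test_empty_key_warns_and_reports_missing(self):
        rows = [{"trial_index": 0, "block": 0, "condition": "partial",
                 "prior": "A", "stimulus": "A+B", "response": "C",
                 "rt_ms": 600.0, "valid": True}]
        with pytest.warns(UserWarning, match="missing"):
            table = compute_precision(TrialTable(pd.DataFrame(rows)))
        assert np.isnan(table.get("A", "A+B"))

    def test_constant_table_covers_all_pairs(self):
        table = PrecisionTable.constant(0.3)
        assert all(table.get("x", p) == 0.3 for p in MORPH_PAIRS)


class TestAssimilationIndex:
    def test_boundaries(self, block):
        assert assimilation_index(
            simulate_behavior(1.0, block, seed=0, invalid_rate=0.0)) == 100.0
        assert assimilation_index(
            simulate_behavior(-1.0, block, seed=0, invalid_rate=0.0)) == 0.0

    def test_invariant_to_trial_order_and_null_trials(self, block):
        beh = simulate_behavior(0.5, block, seed=4)
        base = assimilation_index(beh)
        shuffled = TrialTable(beh.data.sample(frac=1, random_state=0))
        assert assimilation_index(shuffled) == pytest.approx(base)
        no_null = TrialTable(beh.data[beh.data["condition"] != "null"])
        assert assimilation_index(no_null) == pytest.approx(base)

    def test_closed_form_under_response_model(self, design_config):
        # E[index] = 50 + 50 w for the linear response model
        w = 0.35
        blocks = [generate_block_design(design_config, seed=s, block=s)
                  for s in range(4)]
        vals = [
            assimilation_index(TrialTable.concat(
                [simulate_behavior(w, b, seed=100 * r + b.data["block"].iloc[0],
                                   invalid_rate=0.0) for b in blocks]))
            for r in range(40)
        ]
        assert np.mean(vals) == pytest.approx(50 + 50 * w, abs=3.0)

    def test_no_valid_partials_raises(self, block):
        empty = TrialTable(block.data[block.data["condition"] == "null"])
        with pytest.raises(ValueError):
            assimilation_index(empty)


class TestRtSplit:
    def test_recovers_generator_means(self, design_config):
        blocks = [generate_block_design(design_config, seed=s, block=s)
                  for s in range(4)]
        confirm, contrast = zip(*[
            split_partial_rts(TrialTable.concat(
                [simulate_behavior(0.3, b, seed=7 * r + i)
                 for i, b in enumerate(blocks)]))
            for r in range(20)
        ])
        assert np.mean(confirm) == pytest.approx(670.0, abs=15.0)
        assert np.mean(contrast) == pytest.approx(784.0, abs=15.0)

    def test_empty_subset_raises(self, block):
        beh = simulate_behavior(1.0, block, seed=2, invalid_rate=0.0)
        with pytest.raises(ValueError, match="subset"):
            split_partial_rts(beh)
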