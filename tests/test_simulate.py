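"""Synthetic cohort generator: behavior, encoding, reproducibility, I/O."""

import numpy as np
import pytest

from morphrsa.design import PrecisionTable, compute_precision
from morphrsa.rdm import kendall_tau_a, neural_rdm, neutral_by_partial_cells
from morphrsa.hypotheses import build_hypothesis_rdm
from morphrsa.simulate import (
    SimulationConfig,
    encoding_matrix,
    jitter_bank,
    calibrate_morphs,
    read_cohort,
    simulate_behavior,
    simulate_cohort,
    simulate_patterns,
    write_cohort,
)


class TestSimulateBehavior:
    def test_full_prior_use_closes_loop_with_precision(self, block):
        beh = simulate_behavior(1.0, block, seed=3, invalid_rate=0.0)
        prec = compute_precision(beh)
        assert (prec.data["precision"] == 1.0).all()

    def test_no_prior_use_gives_chance_rate(self, design_config, block):
        # expected-response rate over 4 blocks x 48 partials within binomial CI
        from morphrsa.design import TrialTable, generate_block_design

        blocks = [generate_block_design(design_config, seed=s, block=s)
                  for s in range(4)]
        trials = TrialTable.concat(
            [simulate_behavior(0.0, b, seed=50 + i, invalid_rate=0.0)
             for i, b in enumerate(blocks)])
        partial = trials.partial
        rate = (partial["response"] == partial["prior"]).mean()
        n = len(partial)
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_fixed_seed_reproducible(self, block):
        a = simulate_behavior(0.4, block, seed=8)
        b = simulate_behavior(0.4, block, seed=8)
        assert a.data.equals(b.data)

    def test_precision_estimator_unbiased(self, design_config):
        # |bias| < 0.02 over replicate subjects at ~16 valid trials per pair
        from morphrsa.design import TrialTable, generate_block_design

        w = 0.4
        blocks = [generate_block_design(design_config, seed=s, block=s)
                  for s in range(2)]
        est = []
        for r in range(400):
            trials = TrialTable.concat(
                [simulate_behavior(w, b, seed=1000 + 2 * r + i,
                                   invalid_rate=0.0)
                 for i, b in enumerate(blocks)])
            est.append(compute_precision(trials).data["precision"].mean())
        assert abs(np.mean(est) - w) < 0.02

    def test_invalid_w_rejected(self, block):
        with pytest.raises(ValueError):
            simulate_behavior(1.5, block)


class TestEncoding:
    def test_isometry_preserves_pattern_correlations(self, rng):
        dim, n_vox = 32, 64
        w = encoding_matrix(dim, n_vox, rng)
        vecs = rng.random((6, dim))
        centered = vecs - vecs.mean(axis=1, keepdims=True)
        proj = centered @ w.T
        np.testing.assert_allclose(np.corrcoef(proj), np.corrcoef(vecs),
                                   atol=1e-10)

    def test_small_voxel_count_falls_back_to_gaussian(self, rng):
        w = encoding_matrix(64, 20, rng)
        assert w.shape == (20, 64)

    def test_subject_specific_matrices_differ(self, bank):
        prec = PrecisionTable.constant(0.3)
        a = simulate_patterns(bank, "input", prec, seed=1)
        b = simulate_patterns(bank, "input", prec, seed=2)
        assert not np.allclose(a.matrix, b.matrix)


class TestSimulatePatterns:
    def test_noiseless_input_patterns_reproduce_hypothesis_rdm(self, bank):
        prec = PrecisionTable.constant(0.3)
        pat = simulate_patterns(bank, "input", prec, n_voxels=200,
                                noise_sd=0.0, seed=5)
        nrdm = neural_rdm(pat)
        hyp = build_hypothesis_rdm(bank, prec, "input")
        np.testing.assert_allclose(nrdm.matrix, hyp.matrix, atol=1e-8)

    def test_pe_data_prefer_pe_model(self, bank):
        prec = PrecisionTable.constant(0.4)
        cells = None
        diffs = []
        for seed in range(20):
            pat = simulate_patterns(bank, "PE", prec, n_voxels=200,
                                    noise_sd=2.0, seed=seed)
            nrdm = neural_rdm(pat)
            if cells is None:
                cells = neutral_by_partial_cells(nrdm.labels)
            pe = build_hypothesis_rdm(bank, prec, "PE")
            sh = build_hypothesis_rdm(bank, prec, "sharpening")
            nv = nrdm.cells(cells)
            diffs.append(kendall_tau_a(nv, pe.cells(cells))
                         - kendall_tau_a(nv, sh.cells(cells)))
        assert np.mean(diffs) > 0.05

    def test_negative_noise_rejected(self, bank):
        with pytest.raises(ValueError):
            simulate_patterns(bank, "input", PrecisionTable.constant(0.3),
                              noise_sd=-1.0)

    def test_feature_subsampling_changes_patterns(self, bank):
        prec = PrecisionTable.constant(0.3)
        full = simulate_patterns(bank, "input", prec, seed=3, feature_frac=1.0)
        sub = simulate_patterns(bank, "input", prec, seed=3, feature_frac=0.3)
        assert full.matrix.shape == sub.matrix.shape
        assert not np.allclose(full.matrix, sub.matrix)


class TestSubjectVariability:
    def test_jitter_zero_is_identity(self, bank):
        assert jitter_bank(bank, 0.0, seed=1) is bank

    def test_jitter_preserves_nonnegativity_and_morph_convexity(self, bank):
        jb = jitter_bank(bank, 0.8, seed=2)
        for vec in jb.identity_features.values():
            assert vec.min() >= 0
        np.testing.assert_allclose(
            jb.morph("A+B"), 0.5 * jb.identity("A") + 0.5 * jb.identity("B"))

    def test_morph_calibration_moves_morphs_only(self, bank):
        cb = calibrate_morphs(bank, 0.15, seed=3)
        for name in bank.identity_features:
            np.testing.assert_array_equal(cb.identity(name),
                                          bank.identity(name))
        assert not np.allclose(cb.morph("A+B"), bank.morph("A+B"))


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_subjects=3, seed=42)
    return simulate_cohort(cfg)


class TestCohort:
    def test_bit_reproducible(self, cohort):
        again = simulate_cohort(SimulationConfig(n_subjects=3, seed=42))
        for a, b in zip(cohort.subjects, again.subjects):
            assert a.w_true == b.w_true
            assert a.trials.data.equals(b.trials.data)
            for region in a.patterns:
                for hemi in a.patterns[region]:
                    np.testing.assert_array_equal(
                        a.patterns[region][hemi].matrix,
                        b.patterns[region][hemi].matrix)

    def test_ground_truth_record(self, cohort):
        gt = cohort.ground_truth
        assert gt["mechanism"] == "PE"
        assert len(gt["w_true"]) == 3
        for sub in cohort.subjects:
            assert gt["w_true"][sub.subject_id] == sub.w_true

    def test_behavioral_precision_tracks_true_w(self, cohort):
        for sub in cohort.subjects:
            est = sub.precision_est.data["precision"].mean()
            assert abs(est - sub.w_true) < 0.3

    def test_write_read_round_trip(self, cohort, tmp_path):
        out = tmp_path / "cohort"
        write_cohort(cohort, out)
        back = read_cohort(out)
        assert back.config == cohort.config
        assert back.ground_truth["w_true"] == cohort.ground_truth["w_true"]
        for a, b in zip(cohort.subjects, back.subjects):
            np.testing.assert_array_equal(
                a.patterns["region1"]["bilateral"].matrix,
                b.patterns["region1"]["bilateral"].matrix)
            assert a.trials.data["response"].equals(b.trials.data["response"])

    def test_per_subject_designs_when_not_shared(self):
        cfg = SimulationConfig(n_subjects=2, seed=1, share_design=False)
        cohort = simulate_cohort(cfg)
        a, b = cohort.subjects
        assert not a.trials.data["stimulus"].equals(b.trials.data["stimulus"])
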