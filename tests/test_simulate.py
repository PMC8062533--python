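import io

import numpy as np
import pandas as pd
import pytest

from atacmotif.formats import reverse_complement, write_bed, write_fasta
from atacmotif.simulate import (
    SyntheticTruth,
    default_activities,
    generate_acs_set,
    make_tss_table,
    sample_motif_collection,
    sample_pwm,
    simulate_counts,
    simulate_expression,
    simulate_study,
)


class TestSamplePwm:
    def test_maximal_ic_forces_point_mass(self):
        pwm = sample_pwm(4, 2.0, seed=1)
        assert ((pwm.probabilities.max(axis=0) > 0.999).all())

    def test_deterministic_given_seed(self):
        a = sample_pwm(6, 1.0, seed=7)
        b = sample_pwm(6, 1.0, seed=7)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_mean_ic_near_request(self):
        pwm = sample_pwm(8, 1.0, seed=3)
        mean_ic = pwm.information_content().mean()
        assert 0.8 <= mean_ic <= 1.2

    def test_columns_normalized(self):
        pwm = sample_pwm(10, 1.5, seed=4)
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("width", [3, 26])
    def test_width_out_of_range(self, width):
        with pytest.raises(ValueError):
            sample_pwm(width, 1.0, seed=0)


class TestGenerateAcsSet:
    def test_zero_planting_probability(self):
        pwms = sample_motif_collection(3, seed=1)
        _, _, truth = generate_acs_set(50, pwms=pwms, planting_prob=0.0, seed=2)
        assert truth.match_truth.sum() == 0

    def test_planting_rate_binomial(self):
        pwms = [sample_pwm(8, 1.2, seed=1, motif_id="m")]
        _, _, truth = generate_acs_set(100, pwms=pwms, planting_prob=0.3, seed=3)
        total = truth.match_truth.sum()
        sd = np.sqrt(100 * 0.3 * 0.7)
        assert abs(total - 30) <= 3 * sd

    def test_same_seed_byte_identical(self):
        pwms = sample_motif_collection(4, seed=9)
        out = []
        for _ in range(2):
            seqs, regions, _ = generate_acs_set(30, pwms=pwms,
                                                planting_prob=0.2, seed=11)
            fa, bed = io.StringIO(), io.StringIO()
            write_fasta(seqs, fa)
            write_bed(regions, bed)
            out.append((fa.getvalue(), bed.getvalue()))
        assert out[0] == out[1]

    def test_planted_instances_present_verbatim(self):
        pwms = sample_motif_collection(4, seed=5)
        seqs, _, truth = generate_acs_set(40, pwms=pwms, planting_prob=0.4,
                                          seed=6)
        seq_by_id = dict(seqs)
        assert truth.planted_instances
        for acs_id, motif_id, pos, strand, word in truth.planted_instances:
            assert seq_by_id[acs_id][pos:pos + len(word)] == word

    def test_linear_activity_model_holds_exactly(self):
        pwms = sample_motif_collection(5, seed=7)
        beta = default_activities(5, 3, seed=8)
        _, _, truth = generate_acs_set(60, pwms=pwms, planting_prob=0.3,
                                       activities=beta, noise_sd=0.4, seed=9)
        reconstructed = truth.match_truth @ beta + np.asarray(truth.noise)
        np.testing.assert_allclose(reconstructed, truth.acs_log2fc_true,
                                   atol=1e-12)

    def test_motif_wider_than_sequence_rejected(self):
        pwms = [sample_pwm(20, 1.0, seed=1)]
        with pytest.raises(ValueError, match="width"):
            generate_acs_set(10, length_range=(15, 18), pwms=pwms, seed=0)


class TestSimulateCounts:
    def _truth(self, log2fc):
        return SyntheticTruth(seed=0, acs_ids=[f"a{i}" for i in range(len(log2fc))],
                              acs_log2fc_true=list(log2fc))

    def test_poisson_limit_index_of_dispersion(self):
        truth = self._truth(np.zeros(3000))
        counts = simulate_counts(truth, 3, baseline_logmean_sd=0.0, seed=1,
                                 dispersion=0.0, mean_count=100,
                                 lib_factor_sd=0.0)
        y = counts.to_numpy(dtype=float)
        iod = (y.var(axis=1, ddof=1) / y.mean(axis=1)).mean()
        assert 0.9 <= iod <= 1.1

    def test_group_mean_ratio_tracks_log2fc(self):
        truth = self._truth(np.ones(4000))
        counts = simulate_counts(truth, 3, seed=2, dispersion=0.1,
                                 mean_count=200, lib_factor_sd=0.0)
        adult = counts.filter(like="adult").to_numpy().mean()
        p10 = counts.filter(like="P10").to_numpy().mean()
        assert adult / p10 == pytest.approx(2.0, rel=0.05)

    def test_moment_estimator_recovers_dispersion(self):
        truth = self._truth(np.zeros(5000))
        counts = simulate_counts(truth, 3, baseline_logmean_sd=1.0, seed=3,
                                 dispersion=0.4, mean_count=100,
                                 lib_factor_sd=0.0)
        y = counts.to_numpy(dtype=float)
        mu = y.mean(axis=1)
        var = y.var(axis=1, ddof=1)
        # regress var - mu on mu^2 through the origin: slope ~ phi
        phi_hat = np.sum((var - mu) * mu**2) / np.sum(mu**4)
        assert 0.3 <= phi_hat <= 0.5

    def test_deterministic_and_integral(self):
        truth = self._truth(np.zeros(100))
        a = simulate_counts(truth, 3, seed=4)
        b = simulate_counts(self._truth(np.zeros(100)), 3, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert (a.to_numpy() >= 0).all()
        assert np.issubdtype(a.to_numpy().dtype, np.integer)


class TestSimulateExpression:
    def _setup(self, n=60, seed=0):
        pwms = sample_motif_collection(3, seed=seed)
        seqs, regions, truth = generate_acs_set(
            n, pwms=pwms, planting_prob=0.3,
            activities=[0.8, -0.8, 0.5], noise_sd=0.5, seed=seed + 1)
        tss = make_tss_table(regions, seed=seed + 2)
        links = {r.id: f"gene_{i + 1:05d}" for i, r in enumerate(regions)}
        fc = pd.Series(truth.acs_log2fc_true, index=truth.acs_ids)
        return tss, links, fc

    def test_pure_enhancers_perfectly_correlated(self):
        tss, links, fc = self._setup()
        table = simulate_expression(tss, links, fc, role_design=(1.0, 0.0),
                                    noise_sd=0.0, seed=3)
        genes = [links[a] for a in fc.index]
        r = np.corrcoef(fc.to_numpy(), table.loc[genes, "log2fc"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_pure_repressors_perfectly_anticorrelated(self):
        tss, links, fc = self._setup()
        table = simulate_expression(tss, links, fc, role_design=(0.0, 1.0),
                                    noise_sd=0.0, seed=3)
        genes = [links[a] for a in fc.index]
        r = np.corrcoef(fc.to_numpy(), table.loc[genes, "log2fc"])[0, 1]
        assert r == pytest.approx(-1.0)

    def test_unknown_gene_rejected(self):
        tss, links, fc = self._setup()
        links[list(links)[0]] = "nonexistent"
        with pytest.raises(KeyError):
            simulate_expression(tss, links, fc, seed=0)

    def test_bad_fractions_rejected(self):
        tss, links, fc = self._setup()
        with pytest.raises(ValueError):
            simulate_expression(tss, links, fc, role_design=(0.8, 0.5), seed=0)


class TestTruthAndStudy:
    def test_truth_json_round_trip(self):
        study = simulate_study(n_acs=40, n_motifs=4, n_active=2, seed=5)
        truth = study["truth"]
        again = SyntheticTruth.from_json(truth.to_json())
        assert again == truth

    def test_study_differential_fraction_controllable(self):
        study = simulate_study(n_acs=800, n_motifs=30, n_active=8, seed=6)
        fc = np.asarray(study["truth"].acs_log2fc_true)
        frac = (np.abs(fc) > 0.5) .mean()
        assert 0.1 <= frac <= 0.45  # "about 20%" regime

    def test_study_regenerates_identically(self):
        a = simulate_study(n_acs=30, n_motifs=4, n_active=2, seed=7)
        b = simulate_study(n_acs=30, n_motifs=4, n_active=2, seed=7)
        assert a["sequences"] == b["sequences"]
        pd.testing.assert_frame_equal(a["counts"], b["counts"])
        pd.testing.assert_frame_equal(a["gene_table"], b["gene_table"])

    def test_activities_include_both_signs(self):
        beta = default_activities(20, 6, seed=8)
        assert (beta > 0).any() and (beta < 0).any()
        assert (beta != 0).sum() == 6
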