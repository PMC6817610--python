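"""Binarization, Bernoulli-HMM training/decoding, model comparison, enrichment."""

import numpy as np
import pytest

from omicsforge import chromatin as ch, io, synthetic
from omicsforge.io import FeatureAnnotation, SignalTrack

from conftest import hmm_posteriors_bruteforce, poisson_tail_exact


def _binary(mat, marks=None, bin_size=200, chrom="chr1"):
    mat = np.asarray(mat, dtype=np.uint8)
    marks = marks or [f"m{j}" for j in range(mat.shape[1])]
    return ch.BinarizedMarks(
        marks=list(marks), calls={chrom: mat}, bin_size=bin_size,
        chrom_sizes={chrom: mat.shape[0] * bin_size},
    )


class TestBinarize:
    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 5.0])
    def test_cutoff_matches_exact_tail_sum(self, lam):
        c = ch.poisson_cutoff(lam, 1e-4)
        assert poisson_tail_exact(c, lam) <= 1e-4
        assert poisson_tail_exact(c - 1, lam) > 1e-4

    def test_unit_rate_cutoff_is_seven(self):
        assert ch.poisson_cutoff(1.0, 1e-4) == 7

    def _track(self, counts, mark="m", bin_size=200):
        counts = np.asarray(counts, dtype=float)
        return SignalTrack(mark, {"chr1": len(counts) * bin_size}, bin_size,
                           {"chr1": counts})

    def test_all_zero_track_all_absent(self):
        binary = ch.binarize({"m": self._track([0, 0, 0, 0])})
        assert binary.calls["chr1"].sum() == 0

    def test_threshold_one_calls_everything_present(self):
        binary = ch.binarize({"m": self._track([0, 1, 5, 2])}, p_threshold=1.0)
        assert binary.calls["chr1"].sum() == 4

    def test_clear_peaks_called(self):
        counts = [0, 1, 0, 30, 0, 1, 28, 0]
        binary = ch.binarize({"m": self._track(counts)})
        np.testing.assert_array_equal(
            binary.calls["chr1"][:, 0], [0, 0, 0, 1, 0, 0, 1, 0]
        )

    def test_mismatched_binning_rejected(self):
        a = self._track([1, 2, 3], mark="a")
        b = self._track([1, 2, 3], mark="b", bin_size=100)
        with pytest.raises(ValueError, match="binning"):
            ch.binarize({"a": a, "b": b})


class TestLearnModel:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(0)
        x = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(np.uint8)
        model, _ = ch.learn_model(_binary(x), n_states=1)
        np.testing.assert_allclose(model.emissions[0], x.mean(axis=0), atol=1e-9)

    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(5)
        x = (rng.random((400, 4)) < 0.3).astype(np.uint8)
        _, traces = ch.learn_model(_binary(x), n_states=3, seed=1, n_restarts=2,
                                   max_iter=50)
        for trace in traces:
            assert (np.diff(trace) >= -1e-8).all()

    def test_fewer_bins_than_states_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            ch.learn_model(_binary(np.zeros((2, 2))), n_states=5)

    def test_parameter_recovery_small(self):
        # moderate-size recovery check; the full-size run lives in acceptance
        tracks, _, truth = synthetic.simulate_chromatin(n_bins=6000, seed=11)
        binary = ch.binarize(tracks)
        model, _ = ch.learn_model(binary, n_states=3, seed=11, n_restarts=2)
        E_true = np.array(truth.hmm_emissions)
        perm = ch.match_states(model.emissions, E_true)
        assert np.abs(model.emissions[perm] - E_true).mean() < 0.05

    def test_restart_determinism(self):
        rng = np.random.default_rng(2)
        x = (rng.random((300, 3)) < 0.4).astype(np.uint8)
        m1, t1 = ch.learn_model(_binary(x), n_states=2, seed=3)
        m2, t2 = ch.learn_model(_binary(x), n_states=2, seed=3)
        np.testing.assert_array_equal(m1.emissions, m2.emissions)
        assert t1 == t2


class TestDecoding:
    def _random_model(self, rng, S, M):
        E = rng.uniform(0.1, 0.9, (S, M))
        T = rng.random((S, S)) + 0.1
        T /= T.sum(axis=1, keepdims=True)
        pi = rng.random(S) + 0.1
        pi /= pi.sum()
        return ch.ChromatinModel([f"m{j}" for j in range(M)], E, T, pi)

    def test_posteriors_match_exhaustive_path_sum(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            S = int(rng.integers(1, 4))
            M = int(rng.integers(1, 4))
            T_len = int(rng.integers(1, 9))
            model = self._random_model(rng, S, M)
            x = (rng.random((T_len, M)) < 0.5).astype(np.uint8)
            binary = _binary(x, marks=model.marks)
            gamma = ch.posterior_marginals(model, binary)["chr1"]
            ll = ch.sequence_loglik(model, binary)
            post_o, ll_o = hmm_posteriors_bruteforce(
                x, model.initial, model.transitions, model.emissions
            )
            np.testing.assert_allclose(gamma, post_o, atol=1e-10)
            assert ll == pytest.approx(ll_o, abs=1e-10)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        model = self._random_model(rng, 3, 4)
        x = (rng.random((200, 4)) < 0.5).astype(np.uint8)
        gamma = ch.posterior_marginals(model, _binary(x, marks=model.marks))["chr1"]
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_near_deterministic_model_recovers_states(self):
        # each state emits its own private mark
        eps = 1e-6
        E = np.full((3, 3), eps)
        np.fill_diagonal(E, 1 - eps)
        T = np.full((3, 3), 0.1)
        np.fill_diagonal(T, 0.8)
        model = ch.ChromatinModel(["a", "b", "c"], E, T, np.full(3, 1 / 3))
        path = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 2])
        x = np.eye(3, dtype=np.uint8)[path]
        binary = _binary(x, marks=model.marks)
        for rule in ("posterior_max", "viterbi"):
            seg = ch.segment(model, binary, rule=rule)
            np.testing.assert_array_equal(seg.states["chr1"], path + 1)

    def test_mark_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        model = self._random_model(rng, 2, 2)
        binary = _binary(np.zeros((5, 2)), marks=["x", "y"])
        with pytest.raises(ValueError, match="mark"):
            ch.segment(model, binary)

    def test_segmentation_bed_round_trip(self, tmp_path):
        rng = np.random.default_rng(21)
        model = self._random_model(rng, 3, 3)
        x = (rng.random((50, 3)) < 0.5).astype(np.uint8)
        binary = _binary(x, marks=model.marks)
        seg = ch.segment(model, binary)
        path = tmp_path / "seg.bed"
        io.write_segmentation_bed(seg, path)
        back = io.read_segmentation_bed(path, bin_size=200,
                                        chrom_sizes=binary.chrom_sizes)
        np.testing.assert_array_equal(back.states["chr1"], seg.states["chr1"])


class TestCompareModels:
    def _model(self, E):
        E = np.asarray(E, dtype=float)
        S = E.shape[0]
        T = np.full((S, S), 1 / S)
        return ch.ChromatinModel([f"m{j}" for j in range(E.shape[1])], E, T,
                                 np.full(S, 1 / S))

    def test_model_vs_itself_all_one(self):
        m = self._model([[0.9, 0.1, 0.5], [0.2, 0.8, 0.3]])
        df, summary = ch.compare_models(m, m)
        np.testing.assert_allclose(df.max_correlation, 1.0)
        assert summary["min"] == pytest.approx(1.0)

    def test_permuted_state_order_all_one(self):
        E = np.array([[0.9, 0.1, 0.5], [0.2, 0.8, 0.3], [0.4, 0.4, 0.9]])
        df, _ = ch.compare_models(self._model(E[[2, 0, 1]]), self._model(E))
        np.testing.assert_allclose(df.max_correlation, 1.0)

    def test_matching_state_scores_one_regardless_of_others(self):
        ref = self._model([[0.9, 0.1, 0.5], [0.2, 0.8, 0.3]])
        cand = self._model([[0.9, 0.1, 0.5], [0.55, 0.51, 0.52]])
        df, _ = ch.compare_models(cand, ref)
        assert df.max_correlation.iloc[0] == pytest.approx(1.0)

    def test_constant_emission_vector_is_na(self):
        cand = self._model([[0.5, 0.5, 0.5]])
        ref = self._model([[0.9, 0.1, 0.5]])
        df, _ = ch.compare_models(cand, ref)
        assert np.isnan(df.max_correlation.iloc[0])

    def test_differing_mark_sets_rejected(self):
        a = self._model([[0.9, 0.1]])
        b = ch.ChromatinModel(["x", "y"], np.array([[0.9, 0.1]]),
                              np.ones((1, 1)), np.ones(1))
        with pytest.raises(ValueError, match="mark"):
            ch.compare_models(a, b)

    def test_state_sweep_recovers_generating_state_count(self):
        tracks, _, _ = synthetic.simulate_chromatin(n_bins=4000, seed=19)
        binary = ch.binarize(tracks)
        models = {
            n: ch.learn_model(binary, n_states=n, seed=19, n_restarts=2)[0]
            for n in (2, 3, 4, 5)
        }
        chosen, table = ch.recommend_n_states(models)
        assert chosen == 3
        row3 = table.set_index("n_states").loc[3]
        assert row3.min_max_corr >= 0.95


class TestOverlapEnrichment:
    def _seg(self, states, n_states):
        states = np.asarray(states)
        return ch.Segmentation(
            states={"chr1": states}, bin_size=200,
            chrom_sizes={"chr1": len(states) * 200}, n_states=n_states,
        )

    def test_whole_genome_feature_fold_one_everywhere(self):
        seg = self._seg([1, 1, 2, 3, 2, 1, 3, 3, 2, 1], 3)
        ann = FeatureAnnotation.from_records([{
            "chrom": "chr1", "start": 0, "end": 2000, "feature_class": "intergenic",
        }])
        table = ch.overlap_enrichment(seg, ann)
        np.testing.assert_allclose(table.fold["intergenic"], 1.0)

    def test_hundred_bin_worked_example(self):
        # state 1 occupies bins 0-9; feature covers bins 0-4 and 50-54
        states = np.full(100, 2)
        states[:10] = 1
        ann = FeatureAnnotation.from_records([
            {"chrom": "chr1", "start": 0, "end": 1000, "feature_class": "promoter"},
            {"chrom": "chr1", "start": 10000, "end": 11000, "feature_class": "promoter"},
        ])
        table = ch.overlap_enrichment(self._seg(states, 2), ann)
        assert table.fold.loc["E1", "promoter"] == pytest.approx(5.0)

    def test_absent_state_is_na(self):
        seg = self._seg([1, 1, 1, 1], 2)  # state 2 never used
        ann = FeatureAnnotation.from_records([
            {"chrom": "chr1", "start": 0, "end": 400, "feature_class": "exon"},
        ])
        table = ch.overlap_enrichment(seg, ann)
        assert np.isnan(table.fold.loc["E2", "exon"])

    def test_partial_bin_overlap_counts_the_bin(self):
        seg = self._seg([1, 2], 2)
        ann = FeatureAnnotation.from_records([
            {"chrom": "chr1", "start": 190, "end": 210, "feature_class": "exon"},
        ])
        table = ch.overlap_enrichment(seg, ann)
        # 20-bp feature straddles the bin boundary at 200: both bins overlap
        assert table.overlap_bins.loc["E1", "exon"] == 1
        assert table.overlap_bins.loc["E2", "exon"] == 1

    def test_unknown_chromosome_rejected(self):
        seg = self._seg([1, 2], 2)
        ann = FeatureAnnotation.from_records([
            {"chrom": "chrZ", "start": 0, "end": 100, "feature_class": "exon"},
        ])
        with pytest.raises(ValueError, match="chrZ"):
            ch.overlap_enrichment(seg, ann)

    def test_mark_columns_use_present_bins(self):
        seg = self._seg([1, 1, 2, 2], 2)
        binary = _binary(np.array([[1], [1], [0], [0]]), marks=["H3K4me3"])
        ann = FeatureAnnotation.from_records([
            {"chrom": "chr1", "start": 0, "end": 200, "feature_class": "exon"},
        ])
        table = ch.overlap_enrichment(seg, ann, marks=binary)
        assert table.fold.loc["E1", "H3K4me3"] == pytest.approx(2.0)
        assert table.fold.loc["E2", "H3K4me3"] == pytest.approx(0.0)
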