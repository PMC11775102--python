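"""Chromatin-state HMM: binarization, EM fitting, decoding, pooling."""

import math

import numpy as np
import pytest

from chromenv.genome import GenomeAssembly
from chromenv.hmm import (
    DEFAULT_POOLING_MAP,
    STATES_13,
    STATES_18,
    BinarizedTracks,
    Segmentation,
    StateModel,
    binarize_track,
    categorize_state,
    decode_segmentation,
    fit_state_model,
    pool_states,
    posterior_marginals,
    sequence_log_likelihood,
)
from chromenv.simulate import default_state_model, simulate_state_tracks


def exact_poisson_tail(k, lam):
    """P(X >= k) by direct summation of the pmf (independent oracle)."""
    if k <= 0:
        return 1.0
    below = sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(k))
    return 1.0 - below


class TestBinarize:
    def test_zero_count_never_flagged(self):
        assert binarize_track(np.zeros(5, dtype=int), global_rate=3.0).sum() == 0

    def test_threshold_matches_exact_tail(self):
        lam, thr = 1.0, 1e-4
        k_min = next(k for k in range(1, 50) if exact_poisson_tail(k, lam) <= thr)
        counts = np.arange(0, 20)
        flags = binarize_track(counts, lam, thr)
        assert (flags == (counts >= k_min)).all()

    @pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
    def test_per_bin_agreement_with_oracle(self, lam):
        counts = np.arange(0, 40)
        flags = binarize_track(counts, lam)
        want = np.array([exact_poisson_tail(int(k), lam) <= 1e-4 for k in counts])
        assert (flags.astype(bool) == want).all()

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            binarize_track(np.array([0.5, 1.0]), 1.0)


def two_state_tracks(rng, n_bins=50_000, p_emit=(0.9, 0.1), self_t=0.97):
    model = StateModel(
        np.array([[p_emit[0]], [p_emit[1]]]),
        np.array([[self_t, 1 - self_t], [1 - self_t, self_t]]),
        np.array([0.5, 0.5]),
        ["m1"],
    )
    path = np.empty(n_bins, dtype=int)
    path[0] = 0
    u = rng.random(n_bins)
    for t in range(1, n_bins):
        path[t] = path[t - 1] if u[t] < self_t else 1 - path[t - 1]
    marks = (rng.random((n_bins, 1)) < np.array(p_emit)[path][:, None]).astype(np.uint8)
    tracks = BinarizedTracks(200, ["m1"], {"chr1": marks})
    return model, tracks, path


class TestFit:
    def test_single_state_closed_form(self, rng):
        mat = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(np.uint8)
        tracks = BinarizedTracks(200, ["a", "b", "c"], {"chr1": mat})
        model = fit_state_model(tracks, n_states=1, seed=0)
        assert np.allclose(model.emission[0], mat.mean(axis=0))

    def test_loglik_monotone_and_deterministic(self, rng):
        _, tracks, _ = two_state_tracks(rng, n_bins=3000)
        m1 = fit_state_model(tracks, 2, seed=11, max_iter=40, n_restarts=2)
        m2 = fit_state_model(tracks, 2, seed=11, max_iter=40, n_restarts=2)
        lls = np.array(m1.log_likelihoods)
        assert (np.diff(lls) >= -1e-6 * np.abs(lls[:-1])).all()
        assert np.array_equal(m1.emission, m2.emission)
        assert np.array_equal(m1.transition, m2.transition)

    def test_two_state_recovery(self, rng):
        truth, tracks, _ = two_state_tracks(rng, n_bins=50_000)
        model = fit_state_model(tracks, 2, seed=3, n_restarts=3)
        cost = np.abs(model.emission - truth.emission[:, None][[0, 1]].reshape(2, 1)[None])
        # match states by emissions
        d00 = abs(model.emission[0, 0] - 0.9) + abs(model.emission[1, 0] - 0.1)
        d01 = abs(model.emission[0, 0] - 0.1) + abs(model.emission[1, 0] - 0.9)
        order = [0, 1] if d00 <= d01 else [1, 0]
        fitted = model.emission[order, 0]
        assert abs(fitted[0] - 0.9) < 0.05 and abs(fitted[1] - 0.1) < 0.05

    def test_degenerate_all_zero_flagged(self):
        tracks = BinarizedTracks(200, ["m1"], {"chr1": np.zeros((300, 1), dtype=np.uint8)})
        model = fit_state_model(tracks, 2, seed=0, max_iter=5, n_restarts=1)
        assert model.fit_report["degenerate"]


class TestDecode:
    def test_simulation_accuracy(self, rng):
        truth, tracks, path = two_state_tracks(rng, n_bins=20_000)
        seg = decode_segmentation(truth, tracks, state_labels=["s0", "s1"])
        decoded = np.concatenate([
            np.repeat(label, (e - s) // 200) for label, s, e in seg.runs["chr1"]
        ])
        acc = (decoded == np.array(["s0", "s1"])[path]).mean()
        assert acc >= 0.95

    def test_posteriors_sum_to_one(self, rng):
        truth, tracks, _ = two_state_tracks(rng, n_bins=2000)
        post = posterior_marginals(truth, tracks)["chr1"]
        assert np.abs(post.sum(axis=1) - 1).max() <= 1e-8

    def test_identical_emissions_still_tiles(self):
        model = StateModel(np.array([[0.5], [0.5]]),
                          np.array([[0.9, 0.1], [0.1, 0.9]]),
                          np.array([0.5, 0.5]), ["m1"])
        mat = np.random.default_rng(0).integers(0, 2, size=(100, 1)).astype(np.uint8)
        tracks = BinarizedTracks(200, ["m1"], {"chr1": mat})
        seg = decode_segmentation(model, tracks)
        runs = seg.runs["chr1"]
        assert runs[0][1] == 0 and runs[-1][2] == 100 * 200
        for (_, s1, e1), (_, s2, e2) in zip(runs, runs[1:]):
            assert e1 == s2

    def test_single_bin_chromosome_one_run(self):
        model = default_state_model()
        tracks = BinarizedTracks(200, list(model.marks),
                                 {"chr1": np.zeros((1, 6), dtype=np.uint8)})
        seg = decode_segmentation(model, tracks)
        assert len(seg.runs["chr1"]) == 1

    def test_mark_mismatch_rejected(self, rng):
        truth, tracks, _ = two_state_tracks(rng, n_bins=500)
        truth.marks = ["other"]
        with pytest.raises(ValueError, match="mark"):
            posterior_marginals(truth, tracks)


class TestLikelihoodOracle:
    def test_matches_categorical_hmm_encoding(self, rng):
        """Independent oracle: encode the six marks as 2^6 categories and score
        with hmmlearn's CategoricalHMM using product-derived emission rows."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        model = default_state_model()
        asm = GenomeAssembly([("chr1", 60_000)])
        tracks, _ = simulate_state_tracks(model, asm, seed=5)
        ours = sequence_log_likelihood(model, tracks)

        n_marks = len(model.marks)
        codes = np.array([[int(b) for b in format(c, f"0{n_marks}b")]
                          for c in range(2**n_marks)])
        emis = np.prod(model.emission[:, None, :] ** codes[None] *
                       (1 - model.emission[:, None, :]) ** (1 - codes[None]), axis=2)
        ref = hmm.CategoricalHMM(n_components=model.n_states)
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.emissionprob_ = emis
        X = tracks.data["chr1"]
        seq = (X * (2 ** np.arange(n_marks - 1, -1, -1))).sum(axis=1).reshape(-1, 1)
        theirs = ref.score(seq)
        assert ours == pytest.approx(theirs, rel=1e-9)


class TestPooling:
    def test_adjacent_pooled_runs_merge(self):
        seg = Segmentation({"chr1": [("EnhG1", 0, 400), ("EnhG2", 400, 800)]},
                           vocabulary=list(STATES_18))
        pooled = pool_states(seg)
        assert pooled.runs["chr1"] == [("EnhG", 0, 800)]

    def test_identity_map_unchanged(self):
        runs = {"chr1": [("TSSA", 0, 200), ("Tx", 200, 600)]}
        seg = Segmentation(runs, vocabulary=["TSSA", "Tx"])
        same = seg.relabel({"TSSA": "TSSA", "Tx": "Tx"})
        assert same.runs == runs

    def test_pooled_run_count_never_grows(self, rng):
        labels = rng.choice(list(STATES_18), size=300)
        seg = Segmentation.from_label_vector({"chr1": labels}, 200,
                                             vocabulary=list(STATES_18))
        pooled = pool_states(seg)
        assert pooled.n_runs() <= seg.n_runs()

    def test_unmapped_label_rejected(self):
        seg = Segmentation({"chr1": [("Mystery", 0, 200)]})
        with pytest.raises(ValueError, match="Mystery"):
            pool_states(seg)

    def test_default_map_covers_18_to_13(self):
        assert set(DEFAULT_POOLING_MAP) == set(STATES_18)
        assert set(DEFAULT_POOLING_MAP.values()) == set(STATES_13)


class TestCategories:
    @pytest.mark.parametrize("label,category", [
        ("Tx", "active"), ("TSSA", "active"), ("EnhG", "active"), ("EnhA", "active"),
        ("TSSFlnk", "weak"), ("TxWk", "weak"), ("EnhW", "weak"),
        ("ZNF/Rpts", "heterochromatin"), ("Het", "heterochromatin"),
        ("TssBiv", "bivalent"), ("EnhBiv", "bivalent"),
        ("ReprPC", "polycomb"), ("Quies", "quiescent"),
    ])
    def test_methods_mapping(self, label, category):
        assert categorize_state(label) == category

    def test_mapping_is_total_partition(self):
        cats = {s: categorize_state(s) for s in STATES_13}
        assert len(cats) == 13
        assert set(cats.values()) == {"active", "weak", "heterochromatin",
                                      "bivalent", "polycomb", "quiescent"}

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            categorize_state("NotAState")
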