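import numpy as np
import pytest

from eventreact.context_bow import (
    apply_context_exclusions,
    build_bow,
    context_modulation_interaction,
    context_modulation_main_effect,
    jsd_similarity,
    stopword_hash,
    time_bias_diagnostics,
)

from test_reactivation import make_sim


class TestBuildBow:
    def test_hand_counts(self):
        model = build_bow(["the cat sat", "a cat ran"], stopwords={"the", "a"})
        assert model.vocabulary == ("cat", "ran", "sat")
        assert model.counts.tolist() == [[1, 0, 1], [1, 1, 0]]
        assert np.allclose(model.probs.sum(axis=1), 1.0)

    def test_repeated_word_counted(self):
        text = "A vector is a vector of words; the vector wins."
        model = build_bow([text, "other words"], stopwords={"a", "is", "of", "the"})
        assert model.counts[0, model.vocabulary.index("vector")] == 3

    def test_stopword_only_scene_flagged(self):
        with pytest.warns(RuntimeWarning, match="no retained words"):
            model = build_bow(["the a of", "cat", "dog"], stopwords={"the", "a", "of"})
        assert model.empty_scenes == {1}
        assert model.usable().tolist() == [False, True, True]

    def test_case_folding_and_punctuation(self):
        model = build_bow(["Cat! cat? CAT.", "dog"], stopwords=set())
        assert model.counts[0, model.vocabulary.index("cat")] == 3

    def test_stopword_hash_is_stable(self):
        assert stopword_hash({"a", "b"}) == stopword_hash({"b", "a"})


class TestJsd:
    def test_identical_and_disjoint(self):
        model = build_bow(["cat cat dog", "cat cat dog", "fish bird"], stopwords=set())
        sim = jsd_similarity(model)
        assert sim[0, 1] == pytest.approx(1.0)
        assert sim[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim, sim.T, equal_nan=True)

    def test_matches_direct_formula(self):
        # p = (1/2, 1/2, 0), q = (0, 1/2, 1/2) via two-word scenes
        model = build_bow(["aa bb", "bb cc"], stopwords=set())
        sim = jsd_similarity(model)
        p = np.array([0.5, 0.5, 0.0])
        q = np.array([0.0, 0.5, 0.5])
        m = (p + q) / 2

        def kl(a, b):
            sel = a > 0
            return float(np.sum(a[sel] * np.log2(a[sel] / b[sel])))

        want = 1.0 - np.sqrt(0.5 * kl(p, m) + 0.5 * kl(q, m))
        assert sim[0, 1] == pytest.approx(want, abs=1e-12)

    def test_range(self, rng):
        texts = [
            " ".join(rng.choice(["qa", "qb", "qc", "qd"], size=30)) for _ in range(6)
        ]
        sim = jsd_similarity(build_bow(texts, stopwords=set()))
        assert (sim >= 0).all() and (sim <= 1 + 1e-12).all()


class TestTimeBias:
    @staticmethod
    def model_with_sim(sim_matrix):
        n = sim_matrix.shape[0]
        model = build_bow([f"qword{i} qcommon" for i in range(n)], stopwords=set())
        model.context_sim = sim_matrix
        return model

    def test_constant_matrix_zero_diagnostics(self):
        out = time_bias_diagnostics(self.model_with_sim(np.ones((10, 10))), {1, 2})
        assert out["r_time"] == 0.0
        assert out["t_groups"] == 0.0

    def test_df_is_pairs_minus_two(self):
        out = time_bias_diagnostics(
            self.model_with_sim(np.ones((43, 43))), group_a=range(1, 16)
        )
        assert out["df"] == 43 * 42 // 2 - 2 == 901

    def test_depressed_early_scenes_give_negative_t(self, rng):
        n = 20
        sim = np.full((n, n), 0.6) + rng.normal(0, 0.01, (n, n))
        sim = (sim + sim.T) / 2
        sim[:5, :] -= 0.3
        sim[:, :5] -= 0.3
        out = time_bias_diagnostics(self.model_with_sim(sim), group_a=range(1, 6))
        assert out["t_groups"] < 0
        assert out["r_time"] > 0  # similarity rises with pair position

    def test_exclusion_attenuates_time_bias(self, rng):
        n = 30
        sim = np.full((n, n), 0.6) + rng.normal(0, 0.005, (n, n))
        sim = (sim + sim.T) / 2
        sim[:10, :] -= 0.3
        sim[:, :10] -= 0.3
        model = self.model_with_sim(sim)
        before = time_bias_diagnostics(model, group_a=range(1, 11))
        reduced = apply_context_exclusions(model, exclude=range(1, 11))
        after = time_bias_diagnostics(reduced, group_a=range(12, 15))
        assert abs(after["r_time"]) < abs(before["r_time"])

    def test_degenerate_group_is_error(self):
        model = self.model_with_sim(np.ones((5, 5)))
        with pytest.raises(ValueError):
            time_bias_diagnostics(model, group_a=set())
        with pytest.raises(ValueError):
            time_bias_diagnostics(model, group_a=range(1, 6))


class TestExclusions:
    def test_empty_exclusion_is_identity(self):
        model = build_bow(["qa qb", "qb qc", "qc qd"], stopwords=set())
        out = apply_context_exclusions(model, exclude=())
        assert out.excluded_scenes == frozenset()
        assert out.usable().all()

    def test_over_exclusion_is_error(self):
        model = build_bow(["qa", "qb", "qc", "qd"], stopwords=set())
        with pytest.raises(ValueError):
            apply_context_exclusions(model, exclude={1, 2})

    def test_permutation_equivariance(self, rng):
        texts = [" ".join(rng.choice(["qa", "qb", "qc", "qd", "qe"], 40)) for _ in range(8)]
        model = build_bow(texts)
        sim = jsd_similarity(model)
        perm = rng.permutation(8)
        permuted = build_bow([texts[p] for p in perm])
        sim_p = jsd_similarity(permuted)
        assert np.allclose(sim_p, sim[np.ix_(perm, perm)], atol=1e-12)
        assert np.allclose(
            permuted.minwords, model.minwords[np.ix_(perm, perm)]
        )


def context_fixture(rng, n=8):
    """Context model with varied similarities plus matching neural sims."""
    words = [f"q{c}" for c in "abcdefghij"]
    texts = [" ".join(rng.choice(words, size=rng.integers(20, 60))) for _ in range(n)]
    model = build_bow(texts, stopwords=set())
    jsd_similarity(model)
    return model


def residual_oracle(y, x, cov):
    """Partial correlation by explicit residual regression."""
    X = np.column_stack([np.ones_like(cov), cov])
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    return np.corrcoef(ry, rx)[0, 1]


class TestModulation:
    def test_symmetric_neural_gives_zero_main_effect(self, rng):
        model = context_fixture(rng)
        a = rng.standard_normal((8, 8))
        sim = make_sim((a + a.T) / 2)
        out = context_modulation_main_effect(sim, model, partial_minwords=False)
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_planted_past_coupling_matches_residual_oracle(self, rng):
        model = context_fixture(rng)
        ctx = model.context_sim
        n = 8
        idx = np.arange(1, n + 1)
        off = idx[:, None] - idx[None, :]
        z = rng.standard_normal((n, n)) * 0.05
        z[off > 0] += 2.0 * ctx[off > 0]  # affine coupling in the past part
        sim = make_sim(z)
        got = context_modulation_main_effect(sim, model, partial_minwords=True)
        assert got > 0
        # independent oracle over the same cells
        mw = model.minwords.astype(float)
        parts = {}
        for name, sel in (("past", off > 0), ("future", off < 0)):
            cells = sel & ~sim.removal_mask
            parts[name] = residual_oracle(z[cells], ctx[cells], mw[cells])
        want = np.arctanh(parts["past"]) - np.arctanh(parts["future"])
        assert got == pytest.approx(want, abs=1e-10)

    def test_interaction_matches_class_enumeration(self, rng):
        model = context_fixture(rng)
        ctx = model.context_sim
        n = 8
        labels = np.array([("A", "B")[k % 2] for k in range(n)])
        z = rng.standard_normal((n, n))
        sim = make_sim(z, labels=labels)
        got = context_modulation_interaction(sim, model)
        idx = np.arange(1, n + 1)
        off = idx[:, None] - idx[None, :]
        cong = labels[:, None] == labels[None, :]
        rs = {}
        for part, sel in (("past", off > 0), ("future", off < 0)):
            for c in (True, False):
                cells = sel & ~sim.removal_mask & (cong if c else ~cong)
                rs[(part, c)] = np.corrcoef(z[cells], ctx[cells])[0, 1]
        want = (np.arctanh(rs[("past", True)]) - np.arctanh(rs[("past", False)])) - (
            np.arctanh(rs[("future", True)]) - np.arctanh(rs[("future", False)])
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_planted_past_congruent_coupling_is_positive(self, rng):
        model = context_fixture(rng)
        ctx = model.context_sim
        n = 8
        labels = np.array([("A", "B")[k % 2] for k in range(n)])
        idx = np.arange(1, n + 1)
        off = idx[:, None] - idx[None, :]
        cong = labels[:, None] == labels[None, :]
        z = rng.standard_normal((n, n)) * 0.05
        z[(off > 0) & cong] += 3.0 * ctx[(off > 0) & cong]
        out = context_modulation_interaction(make_sim(z, labels=labels), model)
        assert out > 0.5

    def test_excluded_scenes_drop_out_of_cells(self, rng):
        model = context_fixture(rng)
        reduced = apply_context_exclusions(model, exclude={1, 2})
        z = rng.standard_normal((8, 8))
        sim = make_sim(z)
        full = context_modulation_main_effect(sim, model, partial_minwords=False)
        part = context_modulation_main_effect(sim, reduced, partial_minwords=False)
        assert full != pytest.approx(part)
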