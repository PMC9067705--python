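"""Loss terms vs brute-force oracles, optima, gradients, compositions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonarcount.losses import (
    ABLATIONS,
    LossParts,
    assign_class,
    assign_classes,
    au_count_loss,
    au_count_loss_grad,
    count_loss,
    count_loss_grad,
    ieb_loss,
    ieb_loss_grad,
    ieb_sample_weights,
    ranking_loss,
    ranking_loss_grad,
    total_loss,
)

# ---------------------------------------------------------------- oracles


def oracle_count_loss(c, chat):
    total = 0.0
    for ck, chk in zip(c, chat):
        total += abs(ck - chk)
    return total


def oracle_au_loss(c, chat, s):
    total = 0.0
    for ck, chk, sk in zip(c, chat, s):
        total += abs(ck - chk) * np.exp(-sk) + sk
    return total


def oracle_ranking(scores, eps):
    total = 0.0
    for p, pp in scores:
        total += max(0.0, pp - p + eps)
    return total


def oracle_ieb(c, chat, classes):
    K = len(c)
    total = 0.0
    for k in range(K):
        k_class = sum(1 for cl in classes if cl == classes[k])
        total += -np.log(k_class / K) * abs(c[k] - chat[k])
    return total


# ---------------------------------------------------------------- Lc


class TestCountLoss:
    def test_perfect_prediction(self):
        assert count_loss([3, 4], [3, 4]) == 0.0

    def test_worked_example(self):
        assert count_loss([10, 20], [12, 15]) == pytest.approx(7.0)

    def test_matches_oracle_on_random_batches(self, rng):
        for _ in range(50):
            c = rng.uniform(0, 450, size=100)
            chat = rng.normal(c, 20)
            assert count_loss(c, chat) == pytest.approx(
                oracle_count_loss(c, chat), rel=1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            count_loss([1, 2], [1])


# ---------------------------------------------------------------- Lcau


class TestAuLoss:
    def test_zero_s_reduces_to_count_loss(self, rng):
        c = rng.uniform(0, 450, size=64)
        chat = rng.normal(c, 10)
        s = np.zeros(64)
        assert au_count_loss(c, chat, s) == count_loss(c, chat)

    def test_worked_example(self):
        # |e| = 4, s = ln 4: 4/4 + ln 4
        assert au_count_loss([10.0], [6.0], [np.log(4)]) == pytest.approx(
            1 + np.log(4), abs=1e-12
        )

    def test_matches_oracle(self, rng):
        for _ in range(50):
            c = rng.uniform(0, 450, size=32)
            chat = rng.normal(c, 20)
            s = rng.normal(0, 2, size=32)
            assert au_count_loss(c, chat, s) == pytest.approx(
                oracle_au_loss(c, chat, s), rel=1e-12
            )

    @pytest.mark.parametrize("err", [0.5, 1.0, 4.0, 100.0])
    def test_minimizer_is_log_error(self, err):
        """Grid search confirms argmin_s of e*exp(-s) + s at s = ln e."""
        grid = np.linspace(-6, 8, 20_001)
        values = err * np.exp(-grid) + grid
        s_star = grid[values.argmin()]
        assert s_star == pytest.approx(np.log(err), abs=2 * (grid[1] - grid[0]))


# ---------------------------------------------------------------- Lr


class TestRankingLoss:
    def test_correctly_ordered_pair(self):
        assert ranking_loss([(1.0, 0.5)]) == 0.0

    def test_violation_magnitude(self):
        assert ranking_loss([(0.5, 1.0)]) == pytest.approx(0.5)

    def test_matches_oracle(self, rng):
        scores = list(zip(rng.normal(0, 1, 50), rng.normal(0, 1, 50)))
        for eps in (0.0, 0.1):
            assert ranking_loss(scores, eps) == pytest.approx(
                oracle_ranking(scores, eps), rel=1e-12
            )

    def test_translation_equivariance(self, rng):
        scores = list(zip(rng.normal(0, 1, 30), rng.normal(0, 1, 30)))
        shifted = [(p + 5.0, pp + 5.0) for p, pp in scores]
        assert ranking_loss(shifted) == pytest.approx(ranking_loss(scores), rel=1e-9)

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            ranking_loss([(1, 0)], epsilon=-0.1)


# ---------------------------------------------------------------- classes / Lieb


class TestAbundanceClasses:
    @pytest.mark.parametrize("c,expected", [(0, 1), (49, 1), (50, 2), (149, 2), (150, 3), (438, 3)])
    def test_boundaries(self, c, expected):
        assert assign_class(c) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_class(-1)


class TestIebLoss:
    def test_homogeneous_batch_is_zero(self, rng):
        c = rng.uniform(0, 49, size=10)
        chat = rng.normal(c, 5)
        classes = np.ones(10, dtype=int)
        assert ieb_loss(c, chat, classes) == 0.0

    def test_split_7_2_1_weights(self):
        classes = np.array([1] * 7 + [2] * 2 + [3] * 1)
        w = ieb_sample_weights(classes, 10)
        assert w[0] == pytest.approx(-np.log(0.7), abs=1e-12)
        assert w[7] == pytest.approx(-np.log(0.2), abs=1e-12)
        assert w[9] == pytest.approx(-np.log(0.1), abs=1e-12)

    def test_rarer_class_larger_weight(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 400, size=10)
            classes = assign_classes(counts)
            w = ieb_sample_weights(classes)
            freq = {cl: (classes == cl).sum() for cl in set(classes.tolist())}
            for i in range(10):
                for j in range(10):
                    if freq[classes[i]] < freq[classes[j]]:
                        assert w[i] > w[j]

    def test_matches_oracle(self, rng):
        for _ in range(50):
            c = rng.uniform(0, 400, size=10)
            chat = rng.normal(c, 30)
            classes = assign_classes(c)
            assert ieb_loss(c, chat, classes) == pytest.approx(
                oracle_ieb(c, chat, classes), rel=1e-10
            )

    def test_nonnegative(self, rng):
        c = rng.uniform(0, 400, size=10)
        chat = rng.normal(c, 30)
        assert ieb_loss(c, chat, assign_classes(c)) >= 0.0


# ---------------------------------------------------------------- composition


class TestTotalLoss:
    EXPECTED = {
        # ablation id -> (uses AU term, adds Lr, adds lambda*Lieb)
        "i": (False, False, False),
        "ii": (False, False, True),
        "iii": (True, False, False),
        "iv": (True, False, True),
        "v": (False, False, False),
        "vi": (False, True, False),
        "vii": (False, True, True),
        "viii": (True, True, False),
        "ix": (True, True, True),
    }

    @pytest.mark.parametrize("abl_id", list(EXPECTED))
    def test_all_nine_compositions(self, abl_id):
        au, rank, ieb = self.EXPECTED[abl_id]
        parts = LossParts(Lc=7.0, Lcau=5.0, Lr=2.0, Lieb=3.0)
        total = total_loss(parts, ABLATIONS[abl_id], lam=0.1)
        expected = (5.0 if au else 7.0) + (2.0 if rank else 0.0) + (0.3 if ieb else 0.0)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_lambda_weighted_example(self):
        parts = LossParts(Lc=7.0, Lieb=3.0)
        assert total_loss(parts, ABLATIONS["ii"], lam=0.1) == pytest.approx(7.3)

    def test_missing_term_rejected(self):
        with pytest.raises(ValueError, match="Lr"):
            total_loss(LossParts(Lc=1.0), ABLATIONS["vi"])
        with pytest.raises(ValueError, match="Lcau"):
            total_loss(LossParts(Lc=1.0), ABLATIONS["iii"])


# ---------------------------------------------------------------- gradients


def numeric_grad(f, x, eps=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp.flat[i] += eps
        xm.flat[i] -= eps
        g.flat[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


class TestGradients:
    def test_count_loss_grad(self, rng):
        c = rng.uniform(0, 100, size=12)
        chat = rng.normal(c, 10)
        g = count_loss_grad(c, chat)
        gn = numeric_grad(lambda x: count_loss(c, x), chat)
        np.testing.assert_allclose(g, gn, rtol=1e-4, atol=1e-6)

    def test_au_loss_grads(self, rng):
        c = rng.uniform(0, 100, size=12)
        chat = rng.normal(c, 10)
        s = rng.normal(0, 1, size=12)
        dchat, ds = au_count_loss_grad(c, chat, s)
        np.testing.assert_allclose(
            dchat, numeric_grad(lambda x: au_count_loss(c, x, s), chat), rtol=1e-4, atol=1e-6
        )
        np.testing.assert_allclose(
            ds, numeric_grad(lambda x: au_count_loss(c, chat, x), s), rtol=1e-4, atol=1e-6
        )

    def test_ranking_grad(self, rng):
        p = rng.normal(0, 1, 10)
        pp = rng.normal(0, 1, 10)
        grads = ranking_loss_grad(list(zip(p, pp)))
        gp = numeric_grad(lambda x: ranking_loss(list(zip(x, pp))), p)
        gpp = numeric_grad(lambda x: ranking_loss(list(zip(p, x))), pp)
        np.testing.assert_allclose([g[0] for g in grads], gp, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose([g[1] for g in grads], gpp, rtol=1e-4, atol=1e-6)

    def test_ieb_grad(self, rng):
        c = rng.uniform(0, 400, size=10)
        chat = rng.normal(c, 30)
        classes = assign_classes(c)
        g = ieb_loss_grad(c, chat, classes)
        gn = numeric_grad(lambda x: ieb_loss(c, x, classes), chat)
        np.testing.assert_allclose(g, gn, rtol=1e-4, atol=1e-6)


# ---------------------------------------------------------------- properties


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(0, 450),
            st.floats(-100, 500),
            st.floats(-5, 5),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_loss_oracle_equivalence_property(batch):
    c = np.array([b[0] for b in batch])
    chat = np.array([b[1] for b in batch])
    s = np.array([b[2] for b in batch])
    assert count_loss(c, chat) == pytest.approx(oracle_count_loss(c, chat), rel=1e-10, abs=1e-10)
    assert au_count_loss(c, chat, s) == pytest.approx(oracle_au_loss(c, chat, s), rel=1e-10, abs=1e-10)
    assert count_loss(c, chat) >= 0.0
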