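"""SVM / twin SVM / least-squares twin SVM: oracles, geometry, invariants."""

import numpy as np
import pytest
from scipy import optimize as sopt

import eegtwin as et
from conftest import separable_blobs

LINEAR = et.KernelSpec("linear")


def svm_dual_oracle(X, y, lam):
    """Independent QP solve of the SVM dual (SLSQP with tight tolerances)."""
    n = len(y)
    Z = y[:, None] * X
    Q = Z @ Z.T

    def neg(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def jac(a):
        return -(np.ones(n) - Q @ a)

    res = sopt.minimize(
        neg, np.full(n, lam / 2), jac=jac, bounds=[(0.0, lam)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14})
    return -res.fun


class TestSVM:
    def test_symmetric_pair(self):
        """Two mirrored 1-D points: w = 1, b = 0, margin boundary at +/-1."""
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        m = et.train_svm(X, y, lam=1e6, kernel=LINEAR)
        assert abs(m.w[0] - 1.0) < 1e-6
        assert abs(m.b) < 1e-6

    def test_dual_objective_matches_qp_oracle(self, rng):
        """Objective agrees with an SLSQP QP oracle to 1e-6 on separable data."""
        X, y = separable_blobs(rng, n_per_class=10)
        for lam in (0.5, 10.0):
            m = et.train_svm(X, y, lam, LINEAR)
            assert abs(m.dual_objective() - svm_dual_oracle(X, y, lam)) < 1e-6

    def test_separable_margin_identity(self, rng):
        """Separable solution: geometric margin equals 2 / ||w||."""
        X, y = separable_blobs(rng, n_per_class=10, sep=8.0)
        m = et.train_svm(X, y, lam=1e6, kernel=LINEAR)
        f = m.decision_function(X)
        geometric = (y * f / np.linalg.norm(m.w)).min() * 2.0
        assert abs(geometric - 2.0 / np.linalg.norm(m.w)) < 1e-6
        assert np.all(y * f >= 1.0 - 1e-6)  # zero training error, unit margins

    def test_xor_linear_vs_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        lin = et.train_svm(X, y, lam=10.0, kernel=LINEAR)
        assert np.mean(et.predict(lin, X) == y) == 0.5
        rbf = et.train_svm(X, y, lam=10.0, kernel=et.KernelSpec("rbf", gamma=1.0))
        assert np.mean(et.predict(rbf, X) == y) == 1.0

    def test_label_flip_symmetry(self, rng):
        X, y = separable_blobs(rng, n_per_class=8)
        m = et.train_svm(X, y, 1.0, LINEAR)
        mf = et.train_svm(X, -y, 1.0, LINEAR)
        np.testing.assert_allclose(mf.w, -m.w, atol=1e-6)
        assert abs(mf.b + m.b) < 1e-6

    def test_total_slack_monotone_in_penalty(self, rng):
        """More penalty never increases the optimal total slack sum(xi).

        (The 0/1 training error itself is not guaranteed monotone in the
        penalty; the hinge total at the optimum is.)  On separable data a
        large penalty drives the slack to zero.
        """
        X = np.vstack([rng.standard_normal((30, 2)) + 0.8,
                       rng.standard_normal((30, 2)) - 0.8])
        y = np.r_[np.ones(30), -np.ones(30)]
        # grid ends at 10: far larger penalties on non-separable data push
        # the SMO solver into its iteration cap before full convergence
        slacks = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            m = et.train_svm(X, y, lam, LINEAR)
            slacks.append(m.xi.sum())
        assert all(a >= b - 1e-6 for a, b in zip(slacks, slacks[1:]))
        Xs, ys = separable_blobs(rng, n_per_class=20, sep=8.0)
        assert et.train_svm(Xs, ys, 1e6, LINEAR).xi.sum() < 1e-6

    def test_invalid_inputs_rejected(self, rng):
        X, y = separable_blobs(rng, n_per_class=5)
        with pytest.raises(ValueError):
            et.train_svm(X, y, lam=0.0)
        with pytest.raises(ValueError):
            et.train_svm(X, np.ones(len(y)), lam=1.0)  # single class
        with pytest.raises(ValueError):
            et.train_svm(X, np.where(y > 0, 1.0, 0.0), lam=1.0)  # not {+1,-1}


def _parallel_clouds(rng, n=40):
    A = np.column_stack([rng.uniform(-2, 2, n), 0.05 * rng.standard_normal(n)])
    B = np.column_stack([rng.uniform(-2, 2, n), 2 + 0.05 * rng.standard_normal(n)])
    return np.vstack([A, B]), np.r_[np.ones(n), -np.ones(n)]


def _plane_angle_offset(w, b):
    """Angle (deg) to the horizontal line and its y-offset."""
    w = np.asarray(w, dtype=float)
    angle = np.degrees(np.arccos(abs(w[1]) / np.linalg.norm(w)))
    return angle, -b / w[1]


class TestTwinSVM:
    @pytest.mark.parametrize("trainer", [et.train_twsvm, et.train_lstwsvm])
    def test_parallel_clouds_recovered(self, rng, trainer):
        X, y = _parallel_clouds(rng)
        m = trainer(X, y, 1.0, 1.0, LINEAR)
        a1, o1 = _plane_angle_offset(m.w1, m.b1)
        a2, o2 = _plane_angle_offset(m.w2, m.b2)
        assert a1 < 5 and abs(o1 - 0.0) < 0.1
        assert a2 < 5 and abs(o2 - 2.0) < 0.1

    def test_twsvm_lstwsvm_agree_on_benign_geometry(self, rng):
        X, y = _parallel_clouds(rng)
        m1 = et.train_twsvm(X, y, 1.0, 1.0, LINEAR)
        m2 = et.train_lstwsvm(X, y, 1.0, 1.0, LINEAR)
        for w_a, w_b in ((m1.w1, m2.w1), (m1.w2, m2.w2)):
            cos = abs(w_a @ w_b) / (np.linalg.norm(w_a) * np.linalg.norm(w_b))
            assert np.degrees(np.arccos(min(cos, 1.0))) < 2.0

    def test_one_sample_per_class_exact_fit(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([1.0, -1.0])
        m = et.train_twsvm(X, y, 1.0, 1.0, LINEAR)
        d1, d2 = m.plane_distances(X)
        assert d1[0] < 1e-8 and d2[1] < 1e-8

    def test_cross_data_beats_plain_svm(self, rng):
        """Two elongated orthogonal clouds crossing at the origin.

        The arms are sampled asymmetrically about the crossing point: with a
        perfectly symmetric cross each class straddles the other's plane and
        the one-sided hinge makes the twin problem degenerate (w -> 0), which
        no plane-fitting method can recover from.  With asymmetric arms the
        twin planes lock onto the cloud axes while a single linear separator
        cannot avoid one arm's overlap.
        """
        n = 100
        tA = rng.uniform(-4, 6, n)
        tB = rng.uniform(-4, 6, n)
        A = np.column_stack([tA, 0.05 * rng.standard_normal(n)])
        B = np.column_stack([0.05 * rng.standard_normal(n), tB])
        X = np.vstack([A, B])
        y = np.r_[np.ones(n), -np.ones(n)]
        twin = et.train_twsvm(X, y, 0.01, 0.01, LINEAR)
        svm = et.train_svm(X, y, 1.0, LINEAR)
        acc_twin = np.mean(et.predict(twin, X) == y)
        acc_svm = np.mean(et.predict(svm, X) == y)
        assert acc_twin >= 0.95
        assert acc_svm <= 0.8

    def test_lstwsvm_matches_normal_equations_oracle(self, rng):
        """Each plane equals the least-squares oracle to 1e-8 (100 instances)."""
        for _ in range(100):
            n1 = int(rng.integers(3, 30))
            n2 = int(rng.integers(3, 30))
            d = int(rng.integers(1, 9))
            A = rng.standard_normal((n1, d))
            B = rng.standard_normal((n2, d))
            X = np.vstack([A, B])
            y = np.r_[np.ones(n1), -np.ones(n2)]
            c1, c2 = rng.uniform(0.1, 10.0, 2)
            m = et.train_lstwsvm(X, y, c1, c2, LINEAR, ridge=1e-8)
            H = np.hstack([A, np.ones((n1, 1))])
            G = np.hstack([B, np.ones((n2, 1))])
            # oracle: stacked ridge least-squares problem solved by lstsq
            D1 = np.vstack([G, H / np.sqrt(c1), np.sqrt(1e-8) * np.eye(d + 1)])
            r1 = np.r_[-np.ones(n2), np.zeros(n1 + d + 1)]
            u1 = np.linalg.lstsq(D1, r1, rcond=None)[0]
            np.testing.assert_allclose(np.r_[m.w1, m.b1], u1, atol=1e-8)
            D2 = np.vstack([H, G / np.sqrt(c2), np.sqrt(1e-8) * np.eye(d + 1)])
            r2 = np.r_[np.ones(n1), np.zeros(n2 + d + 1)]
            u2 = np.linalg.lstsq(D2, r2, rcond=None)[0]
            np.testing.assert_allclose(np.r_[m.w2, m.b2], u2, atol=1e-8)

    def test_label_flip_swaps_planes(self, rng):
        X, y = _parallel_clouds(rng)
        m = et.train_lstwsvm(X, y, 1.0, 1.0, LINEAR)
        mf = et.train_lstwsvm(X, -y, 1.0, 1.0, LINEAR)
        np.testing.assert_allclose(m.w1, -mf.w2, atol=1e-8)
        np.testing.assert_allclose(m.w2, -mf.w1, atol=1e-8)

    def test_linear_kernel_expansion_matches_primal(self, rng):
        """Degree-1 polynomial kernel (dual expansion) = linear primal route."""
        X, y = separable_blobs(rng, n_per_class=15, sep=3.0)
        Xt = rng.standard_normal((50, 2))
        primal = et.train_lstwsvm(X, y, 1.0, 1.0, LINEAR)
        dual = et.train_lstwsvm(X, y, 1.0, 1.0,
                                et.KernelSpec("polynomial", degree=1, coef0=0.0))
        np.testing.assert_array_equal(et.predict(primal, Xt),
                                      et.predict(dual, Xt))

    def test_lstwsvm_runtime_smoke(self, rng):
        import time
        X = rng.standard_normal((500, 10))
        y = np.r_[np.ones(250), -np.ones(250)]
        t0 = time.time()
        et.train_lstwsvm(X, y, 1.0, 1.0, LINEAR)
        assert time.time() - t0 < 1.0


class TestPredict:
    def test_on_plane_sample_gets_its_class(self):
        m = et.TwinSVMModel(kernel=LINEAR, costs=(1.0, 1.0),
                            w1=np.array([0.0, 1.0]), b1=0.0,
                            w2=np.array([0.0, 1.0]), b2=-2.0,
                            n_features=2)
        assert et.predict(m, np.array([[0.3, 0.0]]))[0] == 1
        assert et.predict(m, np.array([[0.3, 2.0]]))[0] == -1

    def test_equidistant_tie_goes_to_plus_one(self):
        m = et.TwinSVMModel(kernel=LINEAR, costs=(1.0, 1.0),
                            w1=np.array([0.0, 1.0]), b1=0.0,
                            w2=np.array([0.0, 1.0]), b2=-2.0,
                            n_features=2)
        assert et.predict(m, np.array([[0.0, 1.0]]))[0] == 1

    def test_heldout_blobs_accuracy(self, rng):
        X, y = separable_blobs(rng, n_per_class=60, sep=6.0)
        Xt, yt = separable_blobs(rng, n_per_class=60, sep=6.0)
        m = et.train_lstwsvm(X, y, 1.0, 1.0, LINEAR)
        assert np.mean(et.predict(m, Xt) == yt) >= 0.98

    def test_dimension_mismatch_rejected(self, rng):
        X, y = separable_blobs(rng, n_per_class=5)
        m = et.train_lstwsvm(X, y, 1.0, 1.0, LINEAR)
        with pytest.raises(ValueError, match="dimension"):
            et.predict(m, np.zeros((1, 5)))


class TestMulticlass:
    def test_two_classes_reduces_to_binary(self, rng):
        X, y = separable_blobs(rng, n_per_class=20)
        mc = et.train_multiclass(X, y, base="lstwsvm")
        bi = et.train_lstwsvm(X, y, 1.0, 1.0, LINEAR)
        np.testing.assert_array_equal(mc.predict(X), et.predict(bi, X))
        assert len(mc.pairwise_models) == 1

    def test_pair_count(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.arange(40) % 4
        mc = et.train_multiclass(X, y, base="lstwsvm")
        assert len(mc.pairwise_models) == 6  # 4*3/2

    def test_three_blobs_heldout(self, rng):
        centers = np.array([[0.0, 6.0], [-6.0, -3.0], [6.0, -3.0]])
        def draw(n):
            X = np.vstack([c + rng.standard_normal((n, 2)) for c in centers])
            return X, np.repeat(np.arange(3), n)
        X, y = draw(40)
        Xt, yt = draw(40)
        mc = et.train_multiclass(X, y, base="lstwsvm")
        assert np.mean(mc.predict(Xt) == yt) >= 0.95


class TestSerialization:
    @pytest.mark.parametrize("kernel", [LINEAR, et.KernelSpec("rbf", gamma=0.7)])
    def test_twin_roundtrip(self, rng, kernel):
        X, y = separable_blobs(rng, n_per_class=12)
        m = et.train_lstwsvm(X, y, 2.0, 0.5, kernel)
        m2 = et.model_from_json(et.model_to_json(m))
        Xt = rng.standard_normal((30, 2))
        np.testing.assert_array_equal(et.predict(m, Xt), et.predict(m2, Xt))
        np.testing.assert_allclose(m2.w1, m.w1)

    def test_svm_roundtrip(self, rng):
        X, y = separable_blobs(rng, n_per_class=12)
        m = et.train_svm(X, y, 3.0, et.KernelSpec("rbf", gamma=0.3))
        m2 = et.model_from_json(et.model_to_json(m))
        Xt = rng.standard_normal((30, 2))
        np.testing.assert_allclose(m2.decision_function(Xt),
                                   m.decision_function(Xt), atol=1e-12)
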