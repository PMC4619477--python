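"""Fuzzy scoring, LM training of the 3-10-1 network, grading, SNP calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sangerhet import snpnet
from sangerhet.simulate import TraceSimSpec, simulate_trace


def oracle_fuzzy(features, grid_step=0.005):
    """Independent brute-force Mamdani evaluator on a fine output grid.

    Plain loops and trapezoidal integration; shares only the published
    membership/rule definitions with the implementation.
    """

    def tri(x, a, b, c):
        if x < a or x > c:
            return 0.0
        if x == b:
            return 1.0
        if x < b:
            return (x - a) / (b - a) if b > a else 1.0
        return (c - x) / (c - b) if c > b else 1.0

    def feat_mu(x):
        return (tri(x, -1, 0, 0.5), tri(x, 0, 0.5, 1), tri(x, 0.5, 1, 2))

    classes = [(87.5, 75, 100), (67.5, 60, 75), (40, 20, 60), (10, 1, 19)]
    act = [0.0] * 4
    mus = [feat_mu(x) for x in features]
    for q1 in range(3):
        for q2 in range(3):
            for q3 in range(3):
                s = q1 + q2 + q3
                cls = 0 if s == 0 else 1 if s <= 2 else 2 if s <= 4 else 3
                fire = min(mus[0][q1], mus[1][q2], mus[2][q3])
                act[cls] = max(act[cls], fire)
    ys = np.arange(1.0, 100.0 + grid_step, grid_step)
    agg = np.zeros_like(ys)
    for (b, a, c), alpha in zip(classes, act):
        mem = np.array([min(alpha, tri(y, a, b, c)) for y in ys])
        agg = np.maximum(agg, mem)
    num = np.trapezoid(ys * agg, ys)
    den = np.trapezoid(agg, ys)
    return num / den


class TestFuzzy:
    def test_all_good_hits_true_centroid(self):
        assert snpnet.fuzzy_score([0, 0, 0]) == pytest.approx(87.5, abs=0.01)

    def test_all_poor_hits_strongly_false_centroid(self):
        assert snpnet.fuzzy_score([1, 1, 1]) == pytest.approx(10.0, abs=0.01)

    @pytest.mark.parametrize(
        "features",
        [
            (0.0, 0.5, 0.5),
            (0.2, 0.3, 0.7),
            (0.9, 0.1, 0.4),
            (0.5, 0.5, 0.5),
            (0.05, 0.95, 0.5),
        ],
    )
    def test_matches_grid_integration_oracle(self, features):
        assert snpnet.fuzzy_score(features) == pytest.approx(
            oracle_fuzzy(features), abs=0.1
        )

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            snpnet.fuzzy_score([0.5, 1.2, 0.0])

    def test_monotone_on_quality_grid(self):
        """On the crisp quality grid (each feature fully good/fair/poor),
        degrading any one feature never increases the score."""
        grid = (0.0, 0.5, 1.0)
        for a in grid:
            for b in grid:
                for c in grid:
                    base = snpnet.fuzzy_score([a, b, c])
                    for k, v in enumerate((a, b, c)):
                        if v == 1.0:
                            continue
                        worse = [a, b, c]
                        worse[k] = grid[grid.index(v) + 1]
                        assert snpnet.fuzzy_score(worse) <= base + 1e-9


class TestTrainingSet:
    def test_default_sizes_and_range(self):
        tr, va = snpnet.generate_training_set(seed=0)
        assert len(tr) == 443 and len(va) == 147
        for s in tr + va:
            assert 1.0 <= s.target_score <= 100.0
            assert np.all(s.features >= 0) and np.all(s.features <= 1)

    def test_seed_reproducibility(self):
        a = snpnet.generate_training_set(20, 10, seed=5)
        b = snpnet.generate_training_set(20, 10, seed=5)
        for sa, sb in zip(a[0] + a[1], b[0] + b[1]):
            np.testing.assert_array_equal(sa.features, sb.features)
            assert sa.target_score == sb.target_score

    def test_single_sample_target_is_fuzzy_score(self):
        tr, _ = snpnet.generate_training_set(1, 1, seed=9)
        assert tr[0].target_score == pytest.approx(
            snpnet.fuzzy_score(tr[0].features)
        )


def naive_forward(model, x):
    """Matrix-free loop re-implementation of the network equations."""
    hidden = []
    for j in range(10):
        z = model.b1[j]
        for i in range(3):
            z += model.w1[i, j] * x[i]
        hidden.append(1.0 / (1.0 + np.exp(-z)))
    y = model.b2
    for j in range(10):
        y += model.w2[j] * hidden[j]
    return y, hidden


class TestForward:
    def test_constant_network(self):
        m = snpnet.NetworkModel(np.zeros((3, 10)), np.zeros(10), np.zeros(10), 0.5)
        score, _ = snpnet.forward(m, [0.3, 0.9, 0.1])
        assert score == 50.0

    def test_single_sigmoid_unit(self):
        w2 = np.zeros(10)
        w2[0] = 1.0
        m = snpnet.NetworkModel(np.zeros((3, 10)), np.zeros(10), w2, 0.0)
        y, _ = snpnet._forward_raw(m, np.zeros((1, 3)))
        assert y[0] == pytest.approx(0.5)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        m = snpnet.NetworkModel.unpack(rng.normal(0, 1, 51))
        x = rng.uniform(0, 1, 3)
        y_naive, _ = naive_forward(m, x)
        y_vec, _ = snpnet._forward_raw(m, x.reshape(1, 3))
        assert y_vec[0] == pytest.approx(y_naive, abs=1e-12)


class TestLMStep:
    def test_scalar_identity_jacobian_mu_zero(self):
        delta = snpnet.lm_update(np.array([[1.0]]), np.array([2.0]), 0.0)
        assert delta[0] == pytest.approx(-2.0)

    def test_scalar_identity_jacobian_mu_three(self):
        delta = snpnet.lm_update(np.array([[1.0]]), np.array([2.0]), 3.0)
        assert delta[0] == pytest.approx(-0.5)

    def test_singular_at_mu_zero_raises(self):
        J = np.zeros((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="raise mu"):
            snpnet.lm_update(J, np.array([1.0, 1.0]), 0.0)

    def test_analytic_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        params = rng.normal(0, 1, 51)
        model = snpnet.NetworkModel.unpack(params)
        X = rng.uniform(0, 1, (10, 3))
        d = rng.uniform(0, 1, 10)
        _, J = snpnet._residuals_jacobian(model, X, d)
        h = 1e-6
        for p in range(51):
            up, dn = params.copy(), params.copy()
            up[p] += h
            dn[p] -= h
            yu, _ = snpnet._forward_raw(snpnet.NetworkModel.unpack(up), X)
            yd, _ = snpnet._forward_raw(snpnet.NetworkModel.unpack(dn), X)
            fd = ((d - yu) - (d - yd)) / (2 * h)
            scale = np.maximum(np.abs(fd), 1e-3)
            assert np.max(np.abs(J[:, p] - fd) / scale) < 1e-5


def teacher_samples(seed=1, n=250):
    rng = np.random.default_rng(seed)
    teacher = snpnet.NetworkModel.unpack(rng.uniform(0, 1, 51))
    X = rng.uniform(0, 1, (n, 3))
    y, _ = snpnet._forward_raw(teacher, X)
    d = np.clip(1 + 99 * (y - y.min()) / (y.max() - y.min()), 1.0, 100.0)
    return [snpnet.TrainingSample(x, t) for x, t in zip(X, d)]


class TestTrain:
    def test_teacher_student_function_recovery(self):
        """A noise-free dataset from a same-architecture teacher is fit to
        tiny training error within the iteration budget."""
        samples = teacher_samples(seed=1)
        model, hist = snpnet.train(
            samples[:200], samples[200:], snpnet.LMConfig(seed=1)
        )
        assert len(hist.records) <= 110
        assert hist.v_train[-1] / 200 < 1e-4

    def test_accepted_v_sequence_non_increasing(self):
        tr, va = snpnet.generate_training_set(100, 30, seed=2)
        _, hist = snpnet.train(tr, va, snpnet.LMConfig(seed=2, max_iterations=40))
        vs = [r["V_train"] for r in hist.records if r["accepted"]]
        assert all(b <= a for a, b in zip(vs, vs[1:]))

    def test_epsilon_already_satisfied_stops_immediately(self):
        # stopping rule fires before any update when V(w0) < epsilon
        s = snpnet.TrainingSample(np.array([0.5, 0.5, 0.5]), 50.0)
        _, hist = snpnet.train([s], [s], snpnet.LMConfig(seed=4, epsilon=100.0))
        assert hist.records == []
        assert hist.converged

    def test_fixed_seed_training_bit_identical(self):
        tr, va = snpnet.generate_training_set(60, 20, seed=3)
        cfg = snpnet.LMConfig(seed=3, max_iterations=30)
        m1, _ = snpnet.train(tr, va, cfg)
        m2, _ = snpnet.train(tr, va, cfg)
        np.testing.assert_array_equal(m1.pack(), m2.pack())


class TestGrades:
    @pytest.mark.parametrize(
        "score,noisy,grade",
        [
            (80, 5, 1),
            (75, 9, 1),
            (65, 0, 2),
            (65, 1, 2),
            (65, 2, 3),
            (65, 3, 4),
            (60, 0, 2),
            (59.999, 0, 5),
            (20, 0, 5),
            (19.999, 0, 6),
            (1, 100, 6),
            (100, 0, 1),
        ],
    )
    def test_printed_band_boundaries(self, score, noisy, grade):
        assert snpnet.assign_grade(score, noisy) == grade

    def test_total_function_partitions_domain(self):
        """Every (score, noisy) cell maps to exactly one grade and bands tile
        [1, 100] with the printed cuts."""
        scores = np.arange(1.0, 100.0005, 0.001)
        for noisy in (0, 1, 2, 3, 7):
            grades = np.array([snpnet.assign_grade(s, noisy) for s in scores[::37]])
            assert set(grades) <= {1, 2, 3, 4, 5, 6}
        # boundary sweep at fine resolution around the cuts
        for cut, below, above in ((75, 2, 1), (60, 5, 2), (20, 6, 5)):
            for eps in (0.001, 0.0005):
                assert snpnet.assign_grade(cut, 0) == above
                assert snpnet.assign_grade(cut - eps, 0) == below


class TestCallSnps:
    def test_planted_snps_called_exactly(self, model):
        spec = TraceSimSpec(
            n_bases=120,
            het_snps=[(30, "A", 0.8), (60, "C", 0.8), (90, "G", 0.8)],
            noise_uniform_max=10.0,
            seed=21,
        )
        trace, truth = simulate_trace(spec)
        calls = snpnet.call_snps(trace, model, max_grade=2)
        assert [c.base_index for c in calls] == [t[0] for t in truth.snp_truth]

    def test_homozygous_trace_empty_at_snp_grades(self, model, null_trace):
        # grades 1-4 are the SNP-reporting bands; a clean homozygous trace
        # must produce none (residual double-peak candidates land in the
        # false-SNP bands 5-6 by design)
        trace, _ = null_trace
        assert snpnet.call_snps(trace, model, max_grade=4) == []

    def test_grade_threshold_monotonicity(self, model, snp_trace):
        trace, _ = snp_trace
        strict = {c.base_index for c in snpnet.call_snps(trace, model, 2)}
        relaxed = {c.base_index for c in snpnet.call_snps(trace, model, 6)}
        assert strict <= relaxed

    def test_calls_sorted_unique(self, model, snp_trace):
        trace, _ = snp_trace
        calls = snpnet.call_snps(trace, model, 6)
        idx = [c.base_index for c in calls]
        assert idx == sorted(set(idx))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, model):
        p = tmp_path / "m.json"
        snpnet.save_model(model, p)
        again = snpnet.load_model(p)
        np.testing.assert_array_equal(model.pack(), again.pack())
        assert again.fuzzy_rule_version == model.fuzzy_rule_version

    def test_default_model_regenerates_bit_identically(self, tmp_path):
        from importlib import resources

        model, _ = snpnet.train_default_model()
        p = tmp_path / "regen.json"
        snpnet.save_model(model, p)
        shipped = (
            resources.files("sangerhet.data")
            .joinpath("default_model.json")
            .read_bytes()
        )
        assert p.read_bytes() == shipped
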