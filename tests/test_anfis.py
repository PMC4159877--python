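"""Takagi-Sugeno neuro-fuzzy model: architecture, inference and training."""

import numpy as np
import pandas as pd
import pytest

from anthoqsar.anfis import (
    AllRulesInactiveError,
    ANFISModel,
    DegenerateRangeError,
    Rule,
    TrainingConfig,
    TriangularMF,
    _gradients,
    fit_anfis,
    init_grid,
    memberships,
    predict,
    train,
)


def random_table(n=30, d=4, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(-2, 3, size=(n, d)),
                        columns=[f"x{j}" for j in range(d)])


class TestTriangularMF:
    def test_peak_and_vertices(self):
        mf = TriangularMF(0.0, 1.0, 3.0)
        assert mf.degree(1.0) == 1.0
        assert mf.degree(0.0) == 0.0
        assert mf.degree(3.0) == 0.0

    def test_linear_interpolation(self):
        mf = TriangularMF(0.0, 1.0, 3.0)
        assert mf.degree(2.0) == pytest.approx(0.5)   # (3-2)/(3-1)
        assert mf.degree(0.5) == pytest.approx(0.5)

    def test_zero_outside_support(self):
        mf = TriangularMF(0.0, 1.0, 3.0)
        assert mf.degree(-1.0) == 0.0 and mf.degree(4.0) == 0.0

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            TriangularMF(2.0, 1.0, 3.0)
        with pytest.raises(ValueError):
            TriangularMF(1.0, 1.0, 1.0)


class TestInitGrid:
    @pytest.mark.parametrize("d, m, n_rules", [(4, 2, 16), (2, 2, 4), (1, 3, 3)])
    def test_rule_count_is_product_of_mf_counts(self, d, m, n_rules):
        model = init_grid(random_table(d=d), mfs_per_input=m)
        assert len(model.rules) == n_rules
        assert len({r.antecedent for r in model.rules}) == n_rules  # all distinct
        for rule in model.rules:
            assert rule.consequent.shape == (d + 1,)
            assert np.all(rule.consequent == 0.0)

    def test_two_mf_placement_spans_range(self):
        X = pd.DataFrame({"a": [2.0, 6.0, 4.0]})
        model = init_grid(X, mfs_per_input=2, standardize=False)
        lo, hi = 2.0, 6.0
        delta = hi - lo
        m0, m1 = model.mfs[0]
        assert (m0.left, m0.peak, m0.right) == (lo - delta, lo, hi)
        assert (m1.left, m1.peak, m1.right) == (lo, hi, hi + delta)
        # the pair sums to full membership everywhere on the observed range
        for x in np.linspace(lo, hi, 11):
            assert m0.degree(x) + m1.degree(x) == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(DegenerateRangeError, match="flat"):
            init_grid(X)


class TestInference:
    def test_membership_degree_one_at_peak(self):
        X = random_table(d=2, seed=1)
        model = init_grid(X, standardize=False)
        x = np.array([model.mfs[0][0].peak, model.mfs[1][1].peak])
        degs = memberships(model, x)
        assert degs[0][0] == 1.0 and degs[1][1] == 1.0

    def test_constant_consequents_predict_the_constant(self):
        X = random_table(d=3, seed=2)
        model = init_grid(X)
        for rule in model.rules:
            rule.consequent = np.array([7.5, 0.0, 0.0, 0.0])
        # normalization makes the output exactly the shared constant
        pred = predict(model, X)
        assert pred == pytest.approx(np.full(len(X), 7.5))

    def test_single_rule_model(self):
        model = ANFISModel(
            input_names=["x"],
            mfs=[[TriangularMF(0.0, 4.0, 8.0)]],
            rules=[Rule((0,), np.array([2.0, 3.0]))],
            input_ranges=[(0.0, 8.0)],
            standardize=False,
        )
        assert predict(model, [[4.0]]) == pytest.approx([14.0])  # 2 + 3*4

    def test_hand_enumerated_two_rule_forward_pass(self):
        """One input, two MFs: output recomputed by enumerating both rules
        by hand at x = 0.25."""
        model = ANFISModel(
            input_names=["x"],
            mfs=[[TriangularMF(-1.0, 0.0, 1.0), TriangularMF(0.0, 1.0, 2.0)]],
            rules=[
                Rule((0,), np.array([1.0, 2.0])),   # g0 = 1 + 2x
                Rule((1,), np.array([3.0, -1.0])),  # g1 = 3 - x
            ],
            input_ranges=[(0.0, 1.0)],
            standardize=False,
        )
        # mu0(0.25) = 0.75, mu1(0.25) = 0.25; g0 = 1.5, g1 = 2.75
        # f = 0.75*1.5 + 0.25*2.75 = 1.8125
        assert predict(model, [[0.25]]) == pytest.approx([1.8125])

    def test_normalized_firing_sums_to_one(self):
        from anthoqsar.anfis import _firing
        X = random_table(n=50, d=3, seed=3)
        model = init_grid(X)
        w = _firing(model, model.transform(X.to_numpy()))
        s = w.sum(axis=1)
        assert np.all(s > 0)
        assert (w / s[:, None]).sum(axis=1) == pytest.approx(np.ones(50))

    def test_rule_order_permutation_invariance(self):
        X = random_table(n=20, d=2, seed=4)
        rng = np.random.default_rng(5)
        model = init_grid(X)
        for rule in model.rules:
            rule.consequent = rng.normal(size=3)
        base = predict(model, X)
        perm = rng.permutation(len(model.rules))
        shuffled = ANFISModel(
            input_names=model.input_names,
            mfs=model.mfs,
            rules=[model.rules[i] for i in perm],
            input_ranges=model.input_ranges,
            standardize=model.standardize,
        )
        assert predict(shuffled, X) == pytest.approx(base, rel=1e-12)

    def test_all_rules_inactive_names_inputs(self):
        X = random_table(d=2, seed=6)
        model = init_grid(X)
        with pytest.raises(AllRulesInactiveError, match="x0"):
            predict(model, [[1e6, 1e6]])


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Backpropagated vertex gradients agree with central differences
        away from the non-differentiable vertices."""
        rng = np.random.default_rng(7)
        X = random_table(n=40, d=2, seed=7)
        y = rng.normal(size=40)
        model = init_grid(X)
        for rule in model.rules:
            rule.consequent = rng.normal(size=3)
        # jitter vertices so no data point sits exactly on one (the analytic
        # subgradient there is 0 by convention, which central differences
        # cannot reproduce)
        for k in range(2):
            model.mfs[k] = [
                TriangularMF(-1.05, 0.013, 0.97),
                TriangularMF(0.021, 1.017, 2.1),
            ]
        Xt = model.transform(X.to_numpy())

        def mse():
            from anthoqsar.anfis import _forward
            _, _, _, f = _forward(model, Xt, X.to_numpy())
            return float(np.mean((f - y) ** 2))

        premise, cons = _gradients(model, Xt, y)
        h = 1e-6
        for k in range(2):
            for m_idx in range(2):
                for vi, attr in enumerate(("left", "peak", "right")):
                    mf = model.mfs[k][m_idx]
                    orig = getattr(mf, attr)
                    setattr(mf, attr, orig + h)
                    up = mse()
                    setattr(mf, attr, orig - h)
                    down = mse()
                    setattr(mf, attr, orig)
                    fd = (up - down) / (2 * h)
                    assert premise[k][m_idx, vi] == pytest.approx(fd, rel=1e-4, abs=1e-7)
        # consequent gradient of one coefficient
        rule = model.rules[3]
        orig = rule.consequent[1]
        rule.consequent[1] = orig + h
        up = mse()
        rule.consequent[1] = orig - h
        down = mse()
        rule.consequent[1] = orig
        assert cons[3, 1] == pytest.approx((up - down) / (2 * h), rel=1e-5)


class TestTraining:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainingConfig(epochs=0)

    def test_recovers_a_representable_model(self):
        """Data generated exactly by a TS model on the same grid is fitted
        to a residual far below the signal variance."""
        rng = np.random.default_rng(8)
        X = random_table(n=100, d=2, seed=8)
        planted = init_grid(X)
        for rule in planted.rules:
            rule.consequent = rng.normal(size=3)
        y = predict(planted, X)
        model, trace = fit_anfis(X, y, cfg=TrainingConfig(epochs=5))
        assert trace[-1] < 1e-3 * np.var(y)

    def test_frozen_premises_error_non_increasing_exactly(self):
        rng = np.random.default_rng(9)
        X = random_table(n=25, d=2, seed=9)
        y = rng.normal(size=25)
        model = init_grid(X)
        _, trace = train(model, X, y, TrainingConfig(epochs=10, learning_rate=0.0))
        assert np.all(np.diff(trace) <= 1e-12)

    def test_study_scale_run_trace(self):
        """21 compounds, 4 inputs, 100 epochs: full-length trace, error
        non-increasing within a small tolerance."""
        from anthoqsar.synthetic_data import SyntheticSpec, generate
        X, y, _ = generate(SyntheticSpec(n_compounds=21, seed=10))
        model, trace = fit_anfis(X, y, cfg=TrainingConfig(epochs=100))
        assert trace.shape == (100,)
        assert np.all(np.diff(trace) <= max(1e-9, 1e-3 * trace[0]))
        assert len(model.rules) == 16

    def test_pure_gradient_mode_reduces_error(self):
        rng = np.random.default_rng(11)
        X = random_table(n=60, d=2, seed=11)
        y = (X["x0"] + 0.5 * X["x1"]).to_numpy() + 0.05 * rng.normal(size=60)
        cfg = TrainingConfig(epochs=200, learning_rate=0.05,
                             consequent_solver="gradient")
        _, trace = fit_anfis(X, y, cfg=cfg)
        assert trace[-1] < 0.25 * trace[0]

    def test_planted_model_noise_floor(self):
        """With a planted smooth surface plus noise sigma, held-out RMSE
        approaches sigma at large n (seeded)."""
        sigma = 0.5
        rng = np.random.default_rng(12)
        Xtr = pd.DataFrame(rng.uniform(0, 4, size=(500, 2)), columns=["a", "b"])
        Xte = pd.DataFrame(rng.uniform(0.2, 3.8, size=(500, 2)), columns=["a", "b"])

        def surface(df):
            return np.sin(df["a"]) + 0.5 * df["b"]

        ytr = surface(Xtr).to_numpy() + sigma * rng.normal(size=500)
        yte = surface(Xte).to_numpy() + sigma * rng.normal(size=500)
        model, _ = fit_anfis(Xtr, ytr, cfg=TrainingConfig(epochs=30), mfs_per_input=3)
        rmse = float(np.sqrt(np.mean((model.predict(Xte) - yte) ** 2)))
        assert 0.85 * sigma <= rmse <= 1.25 * sigma


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(13)
        X = random_table(n=30, d=3, seed=13)
        y = rng.normal(size=30)
        model, _ = fit_anfis(X, y, cfg=TrainingConfig(epochs=3))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = ANFISModel.load(path)
        assert loaded.to_dict() == model.to_dict()
        # bit-identical predictions after the round trip
        assert np.array_equal(predict(loaded, X), predict(model, X))

    def test_unsupported_version_rejected(self, tmp_path):
        X = random_table(d=2)
        model = init_grid(X)
        d = model.to_dict()
        d["format_version"] = 999
        with pytest.raises(ValueError, match="version"):
            ANFISModel.from_dict(d)
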