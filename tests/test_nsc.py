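import json

import numpy as np
import pandas as pd
import pytest

from immunophen import nsc


def _dataset(rng, n_per=(15, 15, 15), genes=20, sep=3.0):
    """Three Gaussian classes with the first few genes informative."""
    classes = ["desert", "excluded", "infiltrated"]
    cols, labels, blocks = [], [], []
    for ci, (cls, n) in enumerate(zip(classes, n_per)):
        x = rng.normal(0, 1, (genes, n))
        x[ci * 3 : ci * 3 + 3, :] += sep
        blocks.append(x)
        cols += [f"{cls[:3]}{i}" for i in range(n)]
        labels += [cls] * n
    expr = pd.DataFrame(
        np.hstack(blocks), index=[f"g{i}" for i in range(genes)], columns=cols
    )
    return expr, pd.Series(labels, index=cols)


def _oracle_nearest_centroid(expr, labels, X_new, priors=None):
    """Independent brute-force standardized nearest-centroid scorer."""
    X = expr.to_numpy(dtype=float)
    y = labels.to_numpy()
    classes = sorted(set(y))
    n, K = X.shape[1], len(classes)
    cents = np.column_stack([X[:, y == c].mean(axis=1) for c in classes])
    ssw = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        ssw += ((X[:, y == c] - cents[:, j : j + 1]) ** 2).sum(axis=1)
    s = np.sqrt(ssw / (n - K))
    s0 = np.median(s)
    if priors is None:
        priors = np.array([(y == c).mean() for c in classes])
    scores = np.empty((X_new.shape[1], K))
    for j in range(K):
        d = X_new - cents[:, j : j + 1]
        scores[:, j] = (d**2 / (s + s0)[:, None] ** 2).sum(axis=0) - 2 * np.log(priors[j])
    logp = -scores / 2
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True), classes


class TestDeltaZeroOracle:
    def test_equivalence_on_random_datasets(self):
        rng = np.random.default_rng(0)
        for rep in range(50):
            expr, labels = _dataset(rng, n_per=(8, 8, 8), genes=10,
                                    sep=rng.uniform(0, 3))
            model = nsc._build_model(expr, labels, delta=0.0, m_variant="minus")
            X_new = rng.normal(0, 2, (10, 6))
            new = pd.DataFrame(X_new, index=expr.index,
                               columns=[f"n{i}" for i in range(6)])
            _, post = nsc.predict_nsc(model, new)
            p_oracle, classes = _oracle_nearest_centroid(expr, labels, X_new)
            assert list(post.columns) == classes
            np.testing.assert_allclose(post.to_numpy(), p_oracle, atol=1e-9)


class TestShrinkage:
    def test_total_shrinkage_prior_argmax(self, rng):
        expr, labels = _dataset(rng, n_per=(20, 10, 10))
        model = nsc._build_model(expr, labels, delta=0.0, m_variant="minus")
        model.delta = float(np.abs(model.standardized_offsets).max()) + 1.0
        cents = model.shrunken_centroids()
        np.testing.assert_allclose(
            cents - model.overall_centroid[:, None], 0.0, atol=1e-12
        )
        _, post = nsc.predict_nsc(model, expr)
        assert (post.idxmax(axis=1) == "desert").all()  # largest class

    def test_equal_priors_total_shrinkage_uniform_posterior(self, rng):
        expr, labels = _dataset(rng, n_per=(10, 10, 10))
        model = nsc._build_model(expr, labels, delta=0.0, m_variant="minus")
        model.delta = float(np.abs(model.standardized_offsets).max()) + 1.0
        _, post = nsc.predict_nsc(model, expr.iloc[:, :3])
        np.testing.assert_allclose(post.to_numpy(), 1 / 3, atol=1e-12)

    def test_monotone_gene_survival(self, rng):
        expr, labels = _dataset(rng)
        model = nsc._build_model(expr, labels, delta=0.0, m_variant="minus")
        deltas = np.linspace(0, np.abs(model.standardized_offsets).max(), 15)
        counts = [model.n_active_genes(d) for d in deltas]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == len(model.gene_ids)
        assert counts[-1] <= 1

    def test_sample_at_shrunken_centroid(self, rng):
        expr, labels = _dataset(rng, sep=6.0)
        model = nsc._build_model(expr, labels, delta=0.5, m_variant="minus")
        cents = model.shrunken_centroids()
        j = model.classes.index("excluded")
        sample = pd.Series(cents[:, j], index=model.gene_ids)
        _, post = nsc.predict_nsc(model, sample)
        assert post.iloc[0].idxmax() == "excluded"


class TestHandComputedToy:
    def test_two_gene_two_class_posteriors(self):
        # class A centroids (+1, +1), class B (-1, -1), pooled sd exactly 1
        a = np.sqrt(0.75)  # 4 samples/class, ssw = 8a^2, sd^2 = 8a^2/6 = 1
        A = np.array([[1 + a, 1 - a, 1 + a, 1 - a],
                      [1 + a, 1 - a, 1 + a, 1 - a]])
        B = -A
        expr = pd.DataFrame(np.hstack([A, B]), index=["g0", "g1"],
                            columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=expr.columns)
        model = nsc._build_model(expr, labels, delta=0.5, m_variant="minus")
        assert model.s0 == pytest.approx(1.0)
        np.testing.assert_allclose(model.pooled_sd, 1.0)
        # spreadsheet-style evaluation at x = (0.5, 0.5):
        m = np.sqrt(1 / 4 - 1 / 8)
        d_A = 1.0 / (m * 2.0)  # (centroid - overall)/(m*(s+s0))
        d_A_shrunk = d_A - 0.5
        cent_A = 0.0 + m * 2.0 * d_A_shrunk          # per gene, class A
        cent_B = -cent_A
        x = 0.5
        delta_A = 2 * ((x - cent_A) ** 2) / 4.0 - 2 * np.log(0.5)
        delta_B = 2 * ((x - cent_B) ** 2) / 4.0 - 2 * np.log(0.5)
        pA = np.exp(-delta_A / 2) / (np.exp(-delta_A / 2) + np.exp(-delta_B / 2))
        sample = pd.Series([x, x], index=["g0", "g1"])
        _, post = nsc.predict_nsc(model, sample)
        assert post.iloc[0]["A"] == pytest.approx(pA, abs=1e-9)
        assert post.iloc[0]["B"] == pytest.approx(1 - pA, abs=1e-9)


class TestConfidenceGate:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.80, 0.15, 0.05), "c0"),
            ((0.60, 0.30, 0.10), nsc.UNCLASSIFIED),  # max <= 0.7
            ((0.71, 0.29, 0.00), "c0"),
            ((0.70, 0.20, 0.10), nsc.UNCLASSIFIED),  # strict > hi
            ((0.72, 0.28, 0.00), "c0"),
            ((0.50, 0.50, 0.00), nsc.UNCLASSIFIED),
        ],
    )
    def test_gate_rules(self, p, expected):
        assert nsc.confidence_gate(p, ["c0", "c1", "c2"]) == expected

    def test_other_class_at_lo_blocks(self):
        # 0.50 is not strictly below lo
        assert nsc.confidence_gate((0.5, 0.5), ["a", "b"]) == nsc.UNCLASSIFIED

    def test_invalid_posteriors(self):
        with pytest.raises(ValueError, match="probability"):
            nsc.confidence_gate((0.8, 0.4), ["a", "b"])

    def test_vacuous_gate(self):
        assert nsc.confidence_gate((0.4, 0.35, 0.25), ["a", "b", "c"], hi=0.0, lo=1.0) == "a"

    def test_gate_invariant(self, rng):
        for _ in range(200):
            p = rng.dirichlet([1, 1, 1])
            label = nsc.confidence_gate(p, ["a", "b", "c"])
            top = np.argmax(p)
            others = np.delete(p, top)
            expected_classified = p[top] > 0.7 and (others < 0.5).all()
            assert (label != nsc.UNCLASSIFIED) == expected_classified


class TestCrossValidate:
    def test_separable_zero_error_at_delta0(self, rng):
        expr, labels = _dataset(rng, sep=8.0)
        curve, _ = nsc.cross_validate(expr, labels, np.array([0.0]), folds=5, seed=1)
        assert curve["cv_error"].iloc[0] == 0.0

    def test_permuted_labels_null_error(self):
        # at total shrinkage the prediction is the training-fold prior
        # argmax, so permuted labels give error = 1 - max prior
        errs = []
        for seed in range(20):
            gen = np.random.default_rng(seed)
            expr, labels = _dataset(gen, n_per=(20, 10, 10), sep=5.0)
            permuted = pd.Series(
                gen.permutation(labels.to_numpy()), index=labels.index
            )
            curve, _ = nsc.cross_validate(
                expr, permuted, np.array([1e6]), folds=4, seed=seed
            )
            errs.append(curve["cv_error"].iloc[0])
        null = 1 - 0.5  # max prior = 20/40
        se = np.std(errs) / np.sqrt(len(errs))
        assert abs(np.mean(errs) - null) <= 3 * se + 0.02

    def test_determinism(self, rng):
        expr, labels = _dataset(rng)
        grid = np.linspace(0, 3, 5)
        c1, _ = nsc.cross_validate(expr, labels, grid, folds=5, seed=3)
        c2, _ = nsc.cross_validate(expr, labels, grid, folds=5, seed=3)
        pd.testing.assert_frame_equal(c1, c2)


class TestTrain:
    def test_curve_shape_well_separated(self, rng):
        expr, labels = _dataset(rng, n_per=(20, 14, 14), sep=6.0)
        model = nsc.train_nsc(expr, labels, cv_folds=7, seed=2)
        curve = model.cv_error_curve
        assert curve["cv_error"].iloc[0] <= 0.05
        assert curve["cv_error"].iloc[-1] == pytest.approx(
            1 - 20 / 48, abs=0.15
        )
        assert model.delta >= 0

    def test_tie_break_directions(self, rng):
        expr, labels = _dataset(rng, sep=10.0)
        model = nsc.train_nsc(expr, labels, cv_folds=5, seed=4)
        err = model.cv_error_curve["cv_error"].to_numpy()
        tied = model.cv_error_curve["delta"][err == err.min()]
        assert model.delta == pytest.approx(tied.min())
        parsimonious = nsc.train_nsc(expr, labels, cv_folds=5, seed=4,
                                     tie_break="largest")
        assert parsimonious.delta == pytest.approx(tied.max())
        with pytest.raises(ValueError, match="tie_break"):
            nsc.train_nsc(expr, labels, cv_folds=5, seed=4, tie_break="median")

    def test_small_class_error(self, rng):
        expr, labels = _dataset(rng, n_per=(15, 15, 4))
        with pytest.raises(ValueError, match="cv_folds"):
            nsc.train_nsc(expr, labels, cv_folds=10)

    def test_label_permutation_equivariance(self, rng):
        expr, labels = _dataset(rng)
        model = nsc._build_model(expr, labels, delta=0.3, m_variant="minus")
        renamed = labels.map({"desert": "zzz", "excluded": "excluded",
                              "infiltrated": "infiltrated"})
        model2 = nsc._build_model(expr, renamed, delta=0.3, m_variant="minus")
        _, p1 = nsc.predict_nsc(model, expr)
        _, p2 = nsc.predict_nsc(model2, expr)
        np.testing.assert_allclose(
            p1["desert"].to_numpy(), p2["zzz"].to_numpy(), atol=1e-12
        )

    def test_serialization_round_trip(self, rng, tmp_path):
        expr, labels = _dataset(rng)
        model = nsc.train_nsc(expr, labels, cv_folds=5, seed=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = nsc.NSCModel.from_json(path)
        _, p1 = nsc.predict_nsc(model, expr)
        _, p2 = nsc.predict_nsc(loaded, expr)
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())
        json.loads(path.read_text())  # valid JSON

    def test_missing_gene_error(self, rng):
        expr, labels = _dataset(rng)
        model = nsc._build_model(expr, labels, delta=0.0, m_variant="minus")
        with pytest.raises(ValueError, match="missing model genes"):
            nsc.predict_nsc(model, expr.drop(index="g0"))

    def test_posteriors_sum_to_one(self, rng):
        expr, labels = _dataset(rng)
        model = nsc._build_model(expr, labels, delta=0.7, m_variant="minus")
        _, post = nsc.predict_nsc(model, expr)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_m_variant_plus(self, rng):
        expr, labels = _dataset(rng)
        m1 = nsc._build_model(expr, labels, delta=0.0, m_variant="minus")
        m2 = nsc._build_model(expr, labels, delta=0.0, m_variant="plus")
        assert (m2.m_k > m1.m_k).all()
        with pytest.raises(ValueError, match="m_variant"):
            nsc._build_model(expr, labels, delta=0.0, m_variant="bogus")
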