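import numpy as np
import pandas as pd
import pytest

import lymphomap as lm
from lymphomap.matrix import ExpressionMatrix
from lymphomap.som import (
    assign_genes,
    load_model,
    mean_portrait,
    portrait,
    render_portrait,
    save_model,
    train_som,
)


def online_kmeans(X, centroids, orders, lrs):
    """Independent oracle: plain online k-means with a given presentation
    order and learning-rate sequence (what a radius-0 SOM must reduce to)."""
    c = centroids.copy()
    step = 0
    for order in orders:
        for gi in order:
            x = X[gi]
            d2 = ((c - x) ** 2).sum(axis=1)
            b = int(np.argmin(d2))
            c[b] += lrs[step] * (x - c[b])
            step += 1
    return c


def two_cluster_matrix(rng, n=60, m=8, sep=6.0):
    X = rng.normal(0, 0.3, size=(n, m))
    X[: n // 2] += sep
    genes = [f"g{i}" for i in range(n)]
    samples = [f"s{j}" for j in range(m)]
    return ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))


class TestTrainSom:
    def test_radius_zero_reduces_to_online_kmeans(self, rng):
        """1x2 grid with the neighborhood annealed to 0 reproduces the
        online k-means trajectory from the same initialization to 1e-6."""
        m = two_cluster_matrix(rng)
        X = m.values
        epochs = 8
        model = train_som(m, rows=1, cols=2, seed=3, epochs=epochs,
                          learning_rate=(0.05, 0.01), radius=(0.0, 0.0))
        # replay the same seeded presentation order
        replay = np.random.default_rng(np.random.SeedSequence([3, 7]))
        orders = [replay.permutation(X.shape[0]) for _ in range(epochs)]
        total = epochs * X.shape[0]
        fracs = np.arange(total) / (total - 1)
        lrs = 0.05 * (0.01 / 0.05) ** fracs  # the trainer's decay schedule
        from lymphomap.som import _linear_init

        oracle = online_kmeans(X, _linear_init(X, 1, 2), orders, lrs)
        np.testing.assert_allclose(model.codebook, oracle, atol=1e-6)
        # and the final codebook approximates the two cluster centroids
        centroids = np.vstack([X[:30].mean(axis=0), X[30:].mean(axis=0)])
        d = np.abs(model.codebook[np.argsort(model.codebook[:, 0])]
                   - centroids[np.argsort(centroids[:, 0])])
        assert d.max() < 0.2

    def test_identical_profiles_single_unit(self):
        X = np.tile([1.0, -1.0, 0.5, 0.5], (20, 1))
        m = ExpressionMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                         columns=list("abcd"))
        )
        model = train_som(m, rows=2, cols=2, seed=0, epochs=5)
        assert model.gene_assignment.nunique() == 1
        unit = model.gene_assignment.iloc[0]
        np.testing.assert_allclose(model.codebook[unit], X[0], atol=1e-6)

    def test_same_seed_reproducible(self, rng):
        m = two_cluster_matrix(rng)
        a = train_som(m, rows=3, cols=3, seed=11, epochs=5)
        b = train_som(m, rows=3, cols=3, seed=11, epochs=5)
        np.testing.assert_array_equal(a.codebook, b.codebook)
        assert (a.gene_assignment == b.gene_assignment).all()

    def test_assignment_is_argmin_post_hoc(self, small_model):
        pre, model, portraits, groups = small_model
        units = assign_genes(model.codebook, pre.values)
        assert (units == model.gene_assignment.to_numpy()).all()

    def test_topology_planted_modules(self, small_model, small_cohort):
        """Genes of one module sit closer together on the grid than genes
        of different modules."""
        _, _, truth = small_cohort
        pre, model, _, _ = small_model
        coords = {
            g: model.unit_coord(int(u)) for g, u in model.gene_assignment.items()
        }
        within, between = [], []
        labels = list(truth.module_gene_map)
        for i, la in enumerate(labels):
            ga = truth.module_gene_map[la]
            ca = np.array([coords[g] for g in ga], dtype=float)
            within.append(np.linalg.norm(ca - ca.mean(axis=0), axis=1).mean())
            for lb in labels[i + 1:]:
                cb = np.array([coords[g] for g in truth.module_gene_map[lb]],
                              dtype=float)
                between.append(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0)))
        assert np.mean(within) < np.mean(between)


class TestPortraits:
    def test_unit_value_is_mean_of_assigned_genes(self, small_model):
        pre, model, portraits, _ = small_model
        s = pre.sample_ids[0]
        p = portraits[s]
        unit_genes = model.unit_gene_lists
        for unit, genes in list(unit_genes.items())[:25]:
            assert p.values[unit] == pytest.approx(
                pre.data.loc[genes, s].mean()
            )

    def test_empty_units_interpolated_from_codebook(self, small_model):
        pre, model, portraits, _ = small_model
        empty = np.flatnonzero(model.empty_units)
        s = pre.sample_ids[3]
        j = model.sample_ids.index(s)
        p = portraits[s]
        for u in empty:
            assert p.values[u] == pytest.approx(model.codebook[u, j])
            assert p.interpolated[u]

    def test_unknown_sample_errors(self, small_model):
        pre, model, _, _ = small_model
        with pytest.raises(KeyError):
            portrait(model, pre, "nope")

    def test_mean_portrait_brute_force(self, rng):
        from tests.conftest import random_portrait

        ps = [random_portrait(rng, pid=f"p{i}") for i in range(3)]
        mp = mean_portrait(ps, "grp")
        np.testing.assert_allclose(
            mp.values, np.vstack([p.values for p in ps]).mean(axis=0)
        )
        assert mp.kind == "group-mean"

    def test_mean_portrait_symmetry_and_singleton(self, rng):
        from tests.conftest import random_portrait

        p = random_portrait(rng)
        neg = lm.Portrait("n", -p.values, p.grid_rows, p.grid_cols)
        np.testing.assert_allclose(mean_portrait([p, neg], "z").values, 0.0,
                                   atol=1e-12)
        np.testing.assert_allclose(mean_portrait([p], "one").values, p.values)
        with pytest.raises(ValueError):
            mean_portrait([], "empty")


class TestPersistenceAndRender:
    def test_model_round_trip(self, small_model, tmp_path):
        pre, model, _, _ = small_model
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_allclose(back.codebook, model.codebook, atol=1e-9)
        assert (back.gene_assignment == model.gene_assignment).all()
        assert (back.grid_rows, back.grid_cols) == (model.grid_rows,
                                                    model.grid_cols)

    def test_render_and_csv_round_trip(self, rng, tmp_path):
        from tests.conftest import random_portrait

        p = random_portrait(rng)
        png = tmp_path / "p.png"
        csv = tmp_path / "p.csv"
        render_portrait(p, png, csv_path=csv)
        assert png.stat().st_size > 0
        np.testing.assert_allclose(np.loadtxt(csv, delimiter=","), p.grid,
                                   atol=1e-9)

    def test_constant_portrait_renders(self, tmp_path):
        p = lm.Portrait("const", np.ones(16), 4, 4)
        render_portrait(p, tmp_path / "c.png")
        assert (tmp_path / "c.png").exists()
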