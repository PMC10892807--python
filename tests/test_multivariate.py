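"""PCA and PLS path modelling against independent oracles."""

import numpy as np
import pandas as pd
import pytest

import ornaval as ov
from ornaval.multivariate import (
    BlockSpec,
    PathModel,
    block_scores,
    bootstrap_paths,
    default_path_model,
    fit_pls_sem,
    pca,
    standardize,
)


def make_df(arr, prefix="x"):
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestStandardize:
    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        x = make_df(rng.normal(size=(50, 3)))
        assert np.allclose(standardize(x), standardize(x + 100.0))

    def test_unit_example(self):
        z = standardize(make_df(np.array([[1.0], [2.0], [3.0]])))
        assert np.allclose(z.to_numpy().ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = make_df(rng.gamma(2, 3, size=(40, 4)))
        z = standardize(x)
        assert np.allclose(standardize(z), z)

    def test_zero_variance_column_named(self):
        x = make_df(np.ones((10, 2)))
        x["x1"] = np.arange(10.0)
        with pytest.raises(ValueError, match="x0"):
            standardize(x)


class TestPca:
    def test_collinear_data_pc1_explains_all(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca(df)
        assert res.variance_fraction[0] == pytest.approx(100.0, abs=1e-8)

    def test_two_indicator_closed_form(self):
        # PC1 share of a 2x2 correlation matrix is (1 + |rho|) / 2
        rng = np.random.default_rng(2)
        z = rng.normal(size=(4000, 2))
        rho = 0.6
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        df = pd.DataFrame({"a": z[:, 0], "b": y})
        observed_rho = abs(df.corr().iloc[0, 1])
        res = pca(df)
        assert res.variance_fraction[0] == pytest.approx(
            100 * (1 + observed_rho) / 2, abs=1e-8
        )

    def test_matches_svd_oracle_and_reconstructs(self):
        rng = np.random.default_rng(3)
        df = make_df(rng.normal(size=(50, 14)))
        res = pca(df)
        z = standardize(df).to_numpy()
        # oracle: SVD of the standardized data
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig_oracle = s**2 / (len(z) - 1)
        assert res.eigenvalues == pytest.approx(eig_oracle, abs=1e-8)
        for j in range(14):
            v = vt[j]
            assert min(
                np.abs(res.loadings.iloc[:, j].to_numpy() - v).max(),
                np.abs(res.loadings.iloc[:, j].to_numpy() + v).max(),
            ) < 1e-8
        # full-rank reconstruction of the standardized data
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, z, atol=1e-8)

    def test_variance_fractions_sum_to_100_and_scores_uncorrelated(self):
        rng = np.random.default_rng(4)
        df = make_df(rng.gamma(3, 2, size=(80, 6)))
        res = pca(df)
        assert res.variance_fraction.sum() == pytest.approx(100.0, abs=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        c = np.corrcoef(res.scores.to_numpy(), rowvar=False)
        off = c - np.diag(np.diag(c))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        df = make_df(rng.normal(size=(30, 4)))
        res = pca(df)
        for j in range(4):
            col = res.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pca(make_df(np.ones((1, 3))))


class TestBlockScores:
    def test_single_indicator_block_is_standardized_indicator(self):
        rng = np.random.default_rng(6)
        df = make_df(rng.normal(size=(40, 1)))
        scores, signs = block_scores(df, [BlockSpec("b", ("x0",))])
        assert np.allclose(scores["b"], standardize(df).to_numpy().ravel())
        assert signs["b"]["x0"] == pytest.approx(1.0)

    def test_perfectly_correlated_pair(self):
        x = np.arange(30.0)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        scores, signs = block_scores(df, [BlockSpec("b", ("a", "b"))])
        assert abs(signs["b"]["a"]) == pytest.approx(1.0, abs=1e-10)
        assert abs(signs["b"]["b"]) == pytest.approx(1.0, abs=1e-10)

    def test_copula_block_signs_match_direct_correlation(self):
        names = ["pedicel_length", "corolla_tube_length"]
        R = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]], index=names, columns=names)
        t = ov.generate_traits(
            ov.default_params(plot_sd_fraction=0.0, correlation=R), seed=7
        )
        df = t.df[names].dropna()
        scores, signs = block_scores(df, [BlockSpec("floral", tuple(names))])
        z = standardize(df)
        for c in names:
            direct = float(np.corrcoef(z[c], scores["floral"])[0, 1])
            assert signs["floral"][c] == pytest.approx(direct, abs=1e-10)


def simulate_chain(beta: float, n: int, seed: int) -> pd.DataFrame:
    """warming -> block -> score with structural coefficient beta."""
    rng = np.random.default_rng(seed)
    warming = np.repeat([0.0, 1.0], n // 2)
    block = beta * standardize(pd.DataFrame({"w": warming}))["w"].to_numpy()
    block = block + np.sqrt(max(1 - beta**2, 0.01)) * rng.standard_normal(n)
    score = beta * (block - block.mean()) / block.std(ddof=1)
    score = score + np.sqrt(max(1 - beta**2, 0.01)) * rng.standard_normal(n)
    return pd.DataFrame({"warming": warming, "block": block, "score": score})


def chain_model() -> PathModel:
    return PathModel(
        blocks={"warming": ("warming",), "block": ("block",), "score": ("score",)},
        edges=[("warming", "block"), ("block", "score")],
    )


class TestPlsSem:
    def test_single_indicator_reduces_to_ols_path_analysis(self):
        rng = np.random.default_rng(8)
        n = 300
        df = pd.DataFrame({
            "w": np.repeat([0.0, 1.0], n // 2),
            "m": rng.normal(size=n),
            "f": rng.normal(size=n),
            "s": rng.normal(size=n),
        })
        df["m"] += 0.5 * df["w"]
        df["f"] -= 0.7 * df["w"]
        df["s"] += 0.6 * df["f"] - 0.2 * df["m"]
        model = PathModel(
            blocks={"w": ("w",), "m": ("m",), "f": ("f",), "s": ("s",)},
            edges=[("w", "m"), ("w", "f"), ("m", "s"), ("f", "s")],
        )
        fit = fit_pls_sem(df, model)
        z = standardize(df)
        # oracle: standardized least squares per endogenous variable
        for target, preds in (("m", ["w"]), ("f", ["w"]), ("s", ["m", "f"])):
            X = z[preds].to_numpy()
            beta, *_ = np.linalg.lstsq(X, z[target].to_numpy(), rcond=None)
            for p_, b in zip(preds, beta):
                assert fit.path_coefficients[(p_, target)] == pytest.approx(b, abs=1e-8)
            resid = z[target].to_numpy() - X @ beta
            r2_oracle = 1 - resid @ resid / (z[target] @ z[target])
            assert fit.r_squared[target] == pytest.approx(r2_oracle, abs=1e-8)

    def test_r2_equals_squared_multiple_correlation(self):
        df = simulate_chain(0.6, 400, seed=9)
        fit = fit_pls_sem(df, chain_model())
        y = fit.latent_scores
        r = np.corrcoef(y["block"], y["score"])[0, 1]
        assert fit.r_squared["score"] == pytest.approx(r**2, abs=1e-10)

    def test_structural_coefficient_recovery(self):
        df = simulate_chain(0.5, 5000, seed=10)
        fit = fit_pls_sem(df, chain_model())
        assert fit.path_coefficients[("block", "score")] == pytest.approx(0.5, abs=0.05)
        assert fit.path_coefficients[("warming", "block")] == pytest.approx(0.5, abs=0.05)

    def test_null_effect_coefficients_near_zero(self):
        coefs = []
        for rep in range(30):
            df = simulate_chain(0.0, 400, seed=100 + rep)
            fit = fit_pls_sem(df, chain_model())
            coefs.append(fit.path_coefficients[("warming", "block")])
        se = 1 / np.sqrt(400)
        assert abs(np.mean(coefs)) < 3 * se / np.sqrt(30)

    def test_multi_indicator_blocks_converge_and_align(self):
        rng = np.random.default_rng(11)
        n = 500
        latent = rng.standard_normal(n)
        df = pd.DataFrame({
            "w": np.repeat([0.0, 1.0], n // 2),
            "s": 0.6 * latent + 0.8 * rng.standard_normal(n),
        })
        for k in range(3):
            df[f"b{k}"] = latent + 0.6 * rng.standard_normal(n)
        model = PathModel(
            blocks={"w": ("w",), "B": ("b0", "b1", "b2"), "s": ("s",)},
            edges=[("w", "B"), ("B", "s")],
        )
        fit = fit_pls_sem(df, model)
        assert fit.iterations < 300
        # latent proxy must track the generating latent closely
        r = np.corrcoef(fit.latent_scores["B"], latent)[0, 1]
        assert abs(r) > 0.9
        assert fit.path_coefficients[("B", "s")] > 0.3

    def test_cyclic_model_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModel(
                blocks={"a": ("x",), "b": ("y",)},
                edges=[("a", "b"), ("b", "a")],
            )

    def test_singular_predecessors_rejected(self):
        n = 100
        x = np.random.default_rng(12).normal(size=n)
        df = pd.DataFrame({"a": x, "b": x, "s": x + 0.1})
        model = PathModel(
            blocks={"a": ("a",), "b": ("b",), "s": ("s",)},
            edges=[("a", "s"), ("b", "s")],
        )
        with pytest.raises(ValueError, match="singular|cap"):
            fit_pls_sem(df, model)


class TestBootstrap:
    def test_same_seed_identical(self):
        df = simulate_chain(0.5, 200, seed=13)
        a = bootstrap_paths(df, chain_model(), replicates=100, seed=5)
        b = bootstrap_paths(df, chain_model(), replicates=100, seed=5)
        assert a.equals(b)

    def test_strong_effect_flagged_significant(self):
        df = simulate_chain(0.7, 500, seed=14)
        boot = bootstrap_paths(df, chain_model(), replicates=500, seed=6)
        row = boot[(boot["source"] == "block") & (boot["target"] == "score")]
        assert bool(row["significant"].iloc[0])

    def test_replicate_floor(self):
        df = simulate_chain(0.5, 100, seed=15)
        with pytest.raises(ValueError):
            bootstrap_paths(df, chain_model(), replicates=10, seed=1)


class TestDefaultModel:
    def test_variants_are_acyclic_and_complete(self):
        for variant in ("two-flowering-blocks", "one-flowering-block"):
            m = default_path_model(variant)
            assert m.topological_order()[0] == "warming"
            assert not m.predecessors("warming")
            assert "ornamental_score" in m.endogenous()
        with pytest.raises(ValueError):
            default_path_model("unknown")
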