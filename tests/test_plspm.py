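"""PLS path modeling: reliability, oracles, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

from cryoextender.plspm import (
    BlockSpec,
    PLSPathModel,
    default_blocks,
    default_path_matrix,
    dg_rho,
    endogenous_summary,
    fit_plspm,
)


class TestDGRho:
    def test_duplicated_indicators_give_one(self, rng):
        v = rng.normal(size=200)
        assert dg_rho(np.column_stack([v, v])) == pytest.approx(1.0)

    def test_single_indicator_is_one_by_convention(self, rng):
        assert dg_rho(rng.normal(size=100)) == 1.0

    def test_weakly_correlated_pair_below_threshold(self, rng):
        """Two indicators with equicorrelation r have
        rho = (2 + 2r) / (3 + r), which tends to 2/3 as r -> 0 and stays
        below the 0.70 unidimensionality threshold for small r."""
        z = rng.normal(size=5000)
        X = 0.23 * z[:, None] + rng.normal(size=(5000, 2))  # r ~ 0.05
        r = float(np.corrcoef(X[:, 0], X[:, 1])[0, 1])
        rho = dg_rho(X)
        assert rho == pytest.approx((2 + 2 * r) / (3 + r), abs=0.01)
        assert rho < 0.70

    def test_highly_correlated_pair_above_threshold(self, rng):
        z = rng.normal(size=500)
        X = z[:, None] + 0.2 * rng.normal(size=(500, 2))
        assert dg_rho(X) > 0.90

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        with pytest.raises(ValueError, match="constant"):
            dg_rho(X)


def _single_indicator_model(rng, n=400):
    x1 = rng.normal(size=n)
    x2 = 0.5 * x1 + 0.8 * rng.normal(size=n)
    y = 0.6 * x1 - 0.4 * x2 + 0.5 * rng.normal(size=n)
    tbl = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
    blocks = [BlockSpec("bx1", ("x1",)), BlockSpec("bx2", ("x2",)), BlockSpec("by", ("y",))]
    P = pd.DataFrame(0, index=["bx1", "bx2", "by"], columns=["bx1", "bx2", "by"])
    P.loc["bx2", "bx1"] = 1
    P.loc["by", ["bx1", "bx2"]] = 1
    return tbl, blocks, P


class TestSingleIndicatorOracle:
    def test_paths_equal_standardized_ols(self, rng):
        tbl, blocks, P = _single_indicator_model(rng)
        m = PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)
        Z = (tbl - tbl.mean()) / tbl.std(ddof=1)
        beta, *_ = np.linalg.lstsq(
            Z[["x1", "x2"]].to_numpy(), Z["y"].to_numpy(), rcond=None
        )
        np.testing.assert_allclose(
            m.path_coefficients_.loc["by", ["bx1", "bx2"]].to_numpy(), beta, atol=1e-8
        )
        fitted = Z[["x1", "x2"]].to_numpy() @ beta
        r2_oracle = 1 - ((Z["y"].to_numpy() - fitted) ** 2).sum() / (Z["y"] ** 2).sum()
        assert m.r2_["by"] == pytest.approx(r2_oracle, abs=1e-8)

    def test_two_block_closed_form(self, rng):
        """X -> Y with single indicators of correlation r: path = r,
        R^2 = r^2 and GoF = |r| (single-indicator communalities excluded)."""
        n = 300
        x = rng.normal(size=n)
        y = 0.7 * x + 0.6 * rng.normal(size=n)
        tbl = pd.DataFrame({"x": x, "y": y})
        blocks = [BlockSpec("bx", ("x",)), BlockSpec("by", ("y",))]
        P = pd.DataFrame(0, index=["bx", "by"], columns=["bx", "by"])
        P.loc["by", "bx"] = 1
        m = PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)
        r = float(np.corrcoef(x, y)[0, 1])
        assert m.path_coefficients_.loc["by", "bx"] == pytest.approx(r, abs=1e-8)
        assert m.r2_["by"] == pytest.approx(r**2, abs=1e-8)
        assert m.gof_ == pytest.approx(abs(r), abs=1e-8)


def _five_block_generator(rng, n=400, loading=0.97):
    """Latent structural model mirroring the extender blocks; manifests
    are latent * loading + noise."""
    bc = rng.normal(size=n)
    ep = rng.normal(size=n)
    paths = {
        ("cpa", "bc"): 0.5,
        ("cpa", "ep"): 0.3,
        ("ao", "ep"): 0.2,
        ("ao", "cpa"): 0.4,
        ("mot", "bc"): 0.2,
        ("mot", "ep"): -0.15,
        ("mot", "cpa"): 0.6,
        ("mot", "ao"): -0.2,
    }
    def noise(s): return s * rng.normal(size=n)
    cpa = paths[("cpa", "bc")] * bc + paths[("cpa", "ep")] * ep + noise(0.6)
    ao = paths[("ao", "ep")] * ep + paths[("ao", "cpa")] * cpa + noise(0.7)
    mot = (paths[("mot", "bc")] * bc + paths[("mot", "ep")] * ep
           + paths[("mot", "cpa")] * cpa + paths[("mot", "ao")] * ao + noise(0.4))
    latents = {"bc": bc, "ep": ep, "cpa": cpa, "ao": ao, "mot": mot}
    data = {}
    for name, z in latents.items():
        z = (z - z.mean()) / z.std(ddof=1)
        for i in (1, 2):
            e = np.sqrt(1 - loading**2)
            data[f"{name}{i}"] = loading * z + e * rng.normal(size=n)
    tbl = pd.DataFrame(data)
    blocks = [BlockSpec(nm, (f"{nm}1", f"{nm}2")) for nm in latents]
    names = list(latents)
    P = pd.DataFrame(0, index=names, columns=names)
    for (t, s) in paths:
        P.loc[t, s] = 1
    # standardized true paths: rescale by latent sds
    sds = {k: v.std(ddof=1) for k, v in latents.items()}
    std_paths = {(t, s): b * sds[s] / sds[t] for (t, s), b in paths.items()}
    return tbl, blocks, P, std_paths


class TestFiveBlockRecovery:
    def test_path_coefficients_recovered(self):
        """With highly reliable indicators the inner path coefficients are
        recovered within +-0.05 on average over seeds at n = 400."""
        errors = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            tbl, blocks, P, std_paths = _five_block_generator(rng)
            m = PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)
            for (t, s), b in std_paths.items():
                errors.append(m.path_coefficients_.loc[t, s] - b)
        assert np.mean(np.abs(errors)) < 0.05

    def test_endogenous_ordering_with_strong_cpa_to_motility(self):
        rng = np.random.default_rng(55)
        tbl, blocks, P, _ = _five_block_generator(rng)
        m = PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)
        summary = endogenous_summary(m)
        assert summary["block"].iloc[0] == "mot"
        assert summary["r2"].is_monotonic_decreasing


class TestModelStructure:
    def test_latent_scores_unit_variance(self, rng):
        tbl, blocks, P = _single_indicator_model(rng)
        m = PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)
        np.testing.assert_allclose(
            m.latent_scores_.var(ddof=1).to_numpy(), 1.0, atol=1e-8
        )

    def test_loading_sign_convention(self, rng):
        tbl, blocks, P, _ = _five_block_generator(rng)
        m = PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)
        for lam in m.loadings_.values():
            assert sum(lam.values()) > 0

    def test_gof_invariant_to_block_and_row_order(self, rng):
        tbl, blocks, P, _ = _five_block_generator(rng)
        m1 = PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)
        rev = list(reversed(blocks))
        P2 = P.loc[[b.name for b in rev], [b.name for b in rev]]
        m2 = PLSPathModel(blocks=rev, path_matrix=P2).fit(tbl)
        shuffled = tbl.sample(frac=1.0, random_state=1)
        m3 = PLSPathModel(blocks=blocks, path_matrix=P).fit(shuffled)
        assert m2.gof_ == pytest.approx(m1.gof_, abs=1e-8)
        assert m3.gof_ == pytest.approx(m1.gof_, abs=1e-8)

    def test_cyclic_path_matrix_rejected(self, rng):
        tbl, blocks, P = _single_indicator_model(rng)
        P.loc["bx1", "by"] = 1  # creates a cycle
        with pytest.raises(ValueError, match="cyclic"):
            PLSPathModel(blocks=blocks, path_matrix=P).fit(tbl)

    def test_default_blocks_run_on_study_table(self, default_table):
        m = fit_plspm(default_table)
        assert set(m.dg_rho_) == {b.name for b in default_blocks()}
        assert 0.0 <= m.gof_ <= 1.0
        assert m.dg_rho_["motility"] > 0.70  # tm and pm co-move
        # motility is endogenous and strongly explained by the components
        assert m.r2_["motility"] > 0.2

    def test_factorial_and_path_schemes_run(self, rng):
        tbl, blocks, P = _single_indicator_model(rng)
        for scheme in ("factorial", "path"):
            m = PLSPathModel(blocks=blocks, path_matrix=P, scheme=scheme).fit(tbl)
            assert np.isfinite(m.gof_)

    def test_default_path_matrix_is_acyclic(self):
        blocks = default_blocks()
        P = default_path_matrix(blocks)
        assert (P.to_numpy() * P.to_numpy().T).sum() == 0
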