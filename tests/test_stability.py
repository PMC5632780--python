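"""Bootstrap CIs, centrality difference test, CS-coefficient, diagnostics."""

import numpy as np
import pytest
from scipy.stats import norm, t as t_dist

import symptomnet as sn
from symptomnet.stability import BootstrapError, cs_from_correlations


def ggm_truth(precision, kind="symmetric"):
    p = precision.shape[0]
    cuts = {"symmetric": norm.ppf([0.25, 0.5, 0.75]),
            "skewed": norm.ppf([0.7, 0.85, 0.95])}[kind]
    return sn.GroundTruthGGM(precision, [cuts.copy() for _ in range(p)])


class TestCsDefinition:
    GRID = (0.1, 0.25, 0.4, 0.55, 0.7, 0.75)

    def test_perfect_correlations_give_max_of_grid(self):
        corrs = {d: np.ones(50) for d in self.GRID}
        assert cs_from_correlations(corrs) == 0.75

    def test_zero_correlations_give_zero(self):
        corrs = {d: np.zeros(50) for d in self.GRID}
        assert cs_from_correlations(corrs) == 0.0

    def test_threshold_exceeded_only_at_low_drops(self):
        corrs = {d: np.full(50, 0.9 if d <= 0.4 else 0.3) for d in self.GRID}
        assert cs_from_correlations(corrs) == 0.4

    def test_raising_threshold_never_raises_cs(self):
        rng = np.random.default_rng(0)
        corrs = {d: rng.uniform(0.3, 1.0, 40) for d in self.GRID}
        values = [cs_from_correlations(corrs, threshold=thr)
                  for thr in (0.5, 0.7, 0.9)]
        assert values == sorted(values, reverse=True)

    def test_95_percent_rule_is_strict(self):
        # exactly 94% above threshold fails, 95% passes
        fail = {0.25: np.array([1.0] * 94 + [0.0] * 6)}
        ok = {0.25: np.array([1.0] * 95 + [0.0] * 5)}
        assert cs_from_correlations(fail) == 0.0
        assert cs_from_correlations(ok) == 0.25


class TestBootstrapEdges:
    def test_degenerate_identical_rows_rejected(self):
        vals = np.tile([1.0, 2.0, 0.0], (30, 1))
        ds = sn.SymptomDataset(vals, ["a", "b", "c"])
        with pytest.raises(BootstrapError):
            sn.bootstrap_edges(ds, B=10, seed=0)

    def test_strong_edge_ci_excludes_zero(self, fast_glasso):
        P = np.eye(4)
        P[0, 1] = P[1, 0] = -0.4  # true partial correlation +0.4
        ds = sn.sample_ordinal(ggm_truth(P), 1000, seed=1)
        ci = sn.bootstrap_edges(ds, fast_glasso, B=500, seed=2)
        row = ci[(ci.node_a == ds.node_labels[0]) & (ci.node_b == ds.node_labels[1])]
        assert row.iloc[0]["lower"] > 0
        assert bool(row.iloc[0]["nonzero"])

    def test_null_model_cis_cover_zero(self, fast_glasso):
        ds = sn.sample_ordinal(ggm_truth(np.eye(4)), 1000, seed=3)
        ci = sn.bootstrap_edges(ds, fast_glasso, B=500, seed=4)
        covered = ((ci["lower"] <= 0) & (ci["upper"] >= 0)).mean()
        assert covered >= 0.9

    def test_ci_brackets_point_estimate_for_reliable_edges(self, fast_glasso):
        P = np.eye(3)
        P[0, 1] = P[1, 0] = -0.45
        ds = sn.sample_ordinal(ggm_truth(P), 800, seed=5)
        ci = sn.bootstrap_edges(ds, fast_glasso, B=200, seed=6)
        strong = ci[ci["nonzero"]]
        assert ((strong["lower"] <= strong["estimate"] + 1e-9)
                & (strong["estimate"] <= strong["upper"] + 1e-9)).all()


class TestDifferenceTest:
    def test_duplicated_columns_never_differ(self, fast_glasso):
        P = np.eye(3)
        P[0, 1] = P[1, 0] = -0.3
        base = sn.sample_ordinal(ggm_truth(P), 400, seed=7)
        vals = np.column_stack([base.values, base.values[:, 2]])
        ds = sn.SymptomDataset(vals, ["a", "b", "c", "c2"])
        out = sn.centrality_difference_test(ds, fast_glasso, B=100, seed=8)
        for m, mat in out.items():
            assert not mat.loc["c", "c2"]
            # structural contract: symmetric and hollow
            assert (mat.to_numpy() == mat.to_numpy().T).all()
            assert not np.diag(mat.to_numpy()).any()

    def test_hub_strength_exceeds_leaf(self, fast_glasso):
        p = 5
        P = np.eye(p)
        P[0, 1:] = P[1:, 0] = -0.22  # star: hub 0 with 4 leaves
        ds = sn.sample_ordinal(ggm_truth(P), 2000, seed=9)
        out = sn.centrality_difference_test(ds, fast_glasso, B=200, seed=10,
                                            metrics=("strength",))
        hub = ds.node_labels[0]
        leaves = ds.node_labels[1:]
        assert sum(out["strength"].loc[hub, l] for l in leaves) >= 3


class TestCsCoefficient:
    def test_strong_structure_is_stable(self):
        t = sn.random_ggm(8, 0.35, weight_range=(0.3, 0.4), seed=21)
        ds = sn.sample_ordinal(t, 1000, seed=22)
        cs = sn.cs_coefficient(ds, sn.GlassoConfig(n_lambda=20),
                               metrics=("strength",), B_per_drop=30, seed=1)
        assert cs["strength"] >= 0.5

    def test_invalid_grid_rejected(self):
        ds, _ = sn.csa_ptsd_preset(seed=1, n=60)
        with pytest.raises(ValueError):
            sn.cs_coefficient(ds, drop_grid=[0.0, 0.5], B_per_drop=30)
        with pytest.raises(ValueError):
            sn.cs_coefficient(ds, B_per_drop=5)


class TestVarianceDiagnostics:
    def test_perfect_linear_relation(self, csa_dataset):
        ds, _ = csa_dataset
        desc = sn.describe(ds)
        cent = sn.node_centrality(sn.fit_network(ds, sn.GlassoConfig(n_lambda=20)))
        # overwrite strength with 2*SD: r must be exactly 1
        cent.table["strength"] = 2 * desc.sd.to_numpy()
        out = sn.variance_diagnostics(desc, cent)
        r, p = out["sd_vs_strength"]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-6

    def test_orthogonalized_strength_gives_zero_r(self, csa_dataset):
        ds, _ = csa_dataset
        desc = sn.describe(ds)
        cent = sn.node_centrality(sn.fit_network(ds, sn.GlassoConfig(n_lambda=20)))
        sd = desc.sd.to_numpy()
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(sd))
        sd_c = sd - sd.mean()
        y = y - y.mean()
        y = y - (y @ sd_c) / (sd_c @ sd_c) * sd_c
        cent.table["strength"] = y + 5  # keep strengths positive-ish
        r, _ = sn.variance_diagnostics(desc, cent)["sd_vs_strength"]
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_t_formula_oracle(self):
        rng = np.random.default_rng(4)
        sd = rng.uniform(0.5, 1.5, 17)
        skew = rng.uniform(-0.5, 2.0, 17)
        strength = rng.uniform(0.2, 2.0, 17)
        import pandas as pd
        desc = sn.DescriptiveTable(pd.DataFrame(
            {"mean": np.zeros(17), "sd": sd, "skewness": skew,
             "degenerate": False}, index=[f"v{i}" for i in range(17)]))
        cent_tab = pd.DataFrame({"strength": strength},
                                index=[f"v{i}" for i in range(17)])

        class Stub:
            def __getitem__(self, m):
                return cent_tab[m]

        out = sn.variance_diagnostics(desc, Stub())
        for key, x in (("sd_vs_strength", sd), ("skewness_vs_strength", skew)):
            r, p = out[key]
            r_direct = np.corrcoef(x, strength)[0, 1]
            tval = r_direct * np.sqrt(15 / (1 - r_direct**2))
            p_direct = 2 * t_dist.sf(abs(tval), 15)
            assert r == pytest.approx(r_direct, abs=1e-12)
            assert p == pytest.approx(p_direct, rel=1e-9)
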