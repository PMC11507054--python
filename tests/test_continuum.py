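import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serrapath import (
    continuum_pca,
    fit_principal_curve,
    gene_trends,
    hurdle_de,
    normalize,
    one_vs_rest_markers,
    order_samples,
    select_continuum_genes,
)
from serrapath.continuum import log2fc_matrix


def brute_spearman(x, y):
    """Independent oracle: rank correlation from first principles."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_pca(x):
    """Independent oracle: dense eigendecomposition of the covariance."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    coords = xc @ v[:, :2]
    return coords, v[:, :2]


class TestHurdleDE:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, size=(40, 30)).astype(float)
        x = np.log1p(x)
        res = hurdle_de(x, x.copy())
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res.loc[res["tested"], "p_value"] > 0.9).all()

    def test_log2fc_pseudocount_arithmetic(self):
        # de-logged target mean 3, reference mean 1 -> log2(4/2) = 1
        target = np.full((20, 3), np.log1p(3.0))
        ref = np.full((20, 3), np.log1p(1.0))
        res = hurdle_de(target, ref)
        np.testing.assert_allclose(res["log2fc"], 1.0, atol=1e-12)

    def test_small_group_returns_none(self):
        x = np.log1p(np.ones((3, 5)))
        assert hurdle_de(x, np.log1p(np.ones((50, 5)))) is None

    def test_rare_genes_untested(self):
        rng = np.random.default_rng(1)
        t = np.log1p(rng.poisson(1.0, (50, 2)).astype(float))
        r = np.log1p(rng.poisson(1.0, (50, 2)).astype(float))
        t[:, 1] = 0.0
        r[:, 1] = 0.0
        r[0, 1] = np.log1p(1.0)  # detected in 2% of one group only
        res = hurdle_de(t, r, min_pct=0.05)
        assert not res["tested"].iloc[1]
        assert np.isnan(res["p_value"].iloc[1])


class TestProfileAndSelection:
    def test_profile_covers_all_samples(self, continuum_profile):
        profile, ds, truth = continuum_profile
        assert profile["sample_id"].nunique() == 12  # reference samples anchor too
        assert (profile["p_adj"].dropna() >= profile["p_value"].dropna().min()).all()

    def test_selection_rule_exhaustive_recheck(self, continuum_profile):
        profile, ds, truth = continuum_profile
        selected = select_continuum_genes(profile, alpha=0.05, min_samples=2)
        counts = (
            profile[profile["p_adj"] < 0.05].groupby("gene")["sample_id"].nunique()
        )
        for gene in selected:
            assert counts.get(gene, 0) >= 2
        excluded = set(profile["gene"]) - set(selected)
        for gene in excluded:
            assert counts.get(gene, 0) < 2

    def test_single_sample_gene_excluded_two_included(self):
        rows = []
        for sid, padj_a, padj_b in (("s1", 0.01, 0.01), ("s2", 0.5, 0.01), ("s3", 0.9, 0.9)):
            rows.append({"sample_id": sid, "gene": "A", "log2fc": 1.0, "p_value": padj_a,
                         "p_adj": padj_a})
            rows.append({"sample_id": sid, "gene": "B", "log2fc": 1.0, "p_value": padj_b,
                         "p_adj": padj_b})
        profile = pd.DataFrame(rows)
        assert select_continuum_genes(profile) == ["B"]

    def test_alpha_one_selects_everything(self, continuum_profile):
        # a vacuous threshold keeps every gene tested in >= 2 samples
        profile, ds, truth = continuum_profile
        selected = select_continuum_genes(profile, alpha=1.0000001, min_samples=2)
        tested_counts = (
            profile[profile["p_adj"].notna()].groupby("gene")["sample_id"].nunique()
        )
        assert set(selected) == set(tested_counts.index[tested_counts >= 2])

    def test_empty_selection_advises(self):
        profile = pd.DataFrame(
            [{"sample_id": "s1", "gene": "A", "log2fc": 0.0, "p_value": 0.9, "p_adj": 0.9}]
        )
        with pytest.raises(ValueError, match="alpha"):
            select_continuum_genes(profile)

    def test_de_power_on_strong_continuum_genes(self, continuum_profile):
        # |beta| >= 2 genes should be significant in the two most progressed
        # samples with high power at 150 cells/sample
        profile, ds, truth = continuum_profile
        top2 = sorted(truth.s_true, key=truth.s_true.get)[-2:]
        strong = [g for g, b in truth.beta.items() if abs(b) >= 2]
        sub = profile[profile["gene"].isin(strong) & profile["sample_id"].isin(top2)]
        assert (sub["p_adj"] < 0.05).mean() >= 0.7


class TestPCA:
    def test_collinear_samples_have_zero_pc2_variance(self):
        t = np.linspace(0, 1, 6)
        rows = []
        for i, ti in enumerate(t):
            for j in range(4):
                rows.append({"sample_id": f"s{i}", "gene": f"g{j}",
                             "log2fc": ti * (j + 1), "p_value": 0.01, "p_adj": 0.01})
        pc, evr, _ = continuum_pca(pd.DataFrame(rows), [f"g{j}" for j in range(4)])
        assert evr[1] == pytest.approx(0.0, abs=1e-12)

    def test_gene_column_permutation_invariance(self, continuum_profile):
        profile, ds, truth = continuum_profile
        genes = select_continuum_genes(profile)
        pc1, _, _ = continuum_pca(profile, genes)
        pc2, _, _ = continuum_pca(profile, genes[::-1])
        np.testing.assert_allclose(pc1.to_numpy(), pc2.to_numpy(), atol=1e-8)

    def test_matches_dense_eigen_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 3))
        rows = [
            {"sample_id": f"s{i}", "gene": f"g{j}", "log2fc": x[i, j],
             "p_value": 0.01, "p_adj": 0.01}
            for i in range(4)
            for j in range(3)
        ]
        pc, evr, _ = continuum_pca(pd.DataFrame(rows), [f"g{j}" for j in range(3)])
        oracle, loadings = brute_pca(x)
        for j in range(2):
            got = pc.to_numpy()[:, j]
            want = oracle[:, j]
            # orientation-free comparison; signs fixed by convention
            assert min(np.abs(got - want).max(), np.abs(got + want).max()) < 1e-10

    def test_identical_profiles_rejected_rank_one_allowed(self):
        rows = [
            {"sample_id": f"s{i}", "gene": f"g{j}", "log2fc": 1.0,
             "p_value": 0.01, "p_adj": 0.01}
            for i in range(4)
            for j in range(3)
        ]
        with pytest.raises(ValueError, match="identical"):
            continuum_pca(pd.DataFrame(rows), [f"g{j}" for j in range(3)])
        rank1 = [
            {"sample_id": f"s{i}", "gene": f"g{j}", "log2fc": float(i),
             "p_value": 0.01, "p_adj": 0.01}
            for i in range(4)
            for j in range(3)
        ]
        pc, evr, _ = continuum_pca(pd.DataFrame(rank1), [f"g{j}" for j in range(3)])
        np.testing.assert_allclose(pc["PC2"], 0.0, atol=1e-12)

    def test_missing_entries_imputed_as_zero(self):
        rows = [
            {"sample_id": f"s{i}", "gene": f"g{j}", "log2fc": 1.0,
             "p_value": 0.01, "p_adj": 0.01}
            for i in range(3)
            for j in range(3)
            if not (i == 0 and j == 0)
        ]
        wide, n_imputed = log2fc_matrix(pd.DataFrame(rows), [f"g{j}" for j in range(3)])
        assert n_imputed == 1
        assert wide.loc["s0", "g0"] == 0.0


class TestPrincipalCurve:
    @staticmethod
    def line_coords(n=8, seed=0):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 1, n))
        pts = np.column_stack([0.5 + 2.0 * t, 1.0 - 0.7 * t])
        stages = ["normal", "normal"] + ["SSL"] * (n - 4) + ["tumor", "tumor"]
        pc = pd.DataFrame(pts, columns=["PC1", "PC2"],
                          index=[f"s{i}" for i in range(n)])
        return pc, pd.Series(stages, index=pc.index), t

    def test_collinear_points_give_exact_line_projections(self):
        pc, stages, t = self.line_coords()
        curve, pos, converged, _ = fit_principal_curve(pc, stages)
        expect = (t - t.min()) / (t.max() - t.min())
        got = np.array([pos[f"s{i}"] for i in range(len(t))])
        np.testing.assert_allclose(got, expect, atol=1e-12)
        assert converged

    def test_positions_span_unit_interval(self, continuum_profile):
        profile, ds, truth = continuum_profile
        stages = ds.cells.drop_duplicates("sample_id").set_index("sample_id")["stage"]
        res = order_samples(profile, stages)
        vals = np.array(list(res.position.values()))
        assert vals.min() == 0.0 and vals.max() == 1.0

    def test_input_order_invariance(self):
        pc, stages, t = self.line_coords(seed=4)
        _, pos_fwd, _, _ = fit_principal_curve(pc, stages)
        perm = pc.iloc[::-1]
        _, pos_rev, _, _ = fit_principal_curve(perm, stages.iloc[::-1])
        for s in pc.index:
            assert pos_fwd[s] == pytest.approx(pos_rev[s], abs=1e-9)

    def test_orientation_normal_before_tumor(self, continuum_profile):
        profile, ds, truth = continuum_profile
        stages = ds.cells.drop_duplicates("sample_id").set_index("sample_id")["stage"]
        res = order_samples(profile, stages)
        normal_pos = [res.position[s] for s in res.position if stages[s] == "normal"]
        tumor_pos = [res.position[s] for s in res.position if stages[s] == "tumor"]
        assert np.mean(normal_pos) < np.mean(tumor_pos)

    def test_too_few_samples_rejected(self):
        pc = pd.DataFrame({"PC1": [0.0, 1, 2], "PC2": [0.0, 0, 0]},
                          index=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 4"):
            fit_principal_curve(pc, pd.Series(["normal", "SSL", "tumor"],
                                              index=pc.index))


class TestGeneTrends:
    @staticmethod
    def profile_of(vectors, axis):
        rows = []
        for gene, vec in vectors.items():
            for i, v in enumerate(vec):
                rows.append({"sample_id": f"s{i}", "gene": gene, "log2fc": v,
                             "p_value": 0.01, "p_adj": 0.01})
        ax = pd.Series(axis, index=[f"s{i}" for i in range(len(axis))])
        return pd.DataFrame(rows), ax

    def test_monotone_gene_has_rho_one(self):
        profile, ax = self.profile_of({"up": [0, 1, 2, 3, 4, 5]}, np.arange(6))
        out = gene_trends(profile, ax)
        assert out["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_rank_oracle(self):
        rng = np.random.default_rng(5)
        vecs = {f"g{j}": rng.normal(size=6) for j in range(8)}
        ax = rng.normal(size=6)
        profile, axis = self.profile_of(vecs, ax)
        out = gene_trends(profile, axis).set_index("gene")
        for g, v in vecs.items():
            assert out.loc[g, "spearman_rho"] == pytest.approx(
                brute_spearman(ax, np.asarray(v)), abs=1e-12
            )

    def test_constant_vector_flagged_not_crashing(self):
        profile, ax = self.profile_of(
            {"flat": [1.0] * 6, "up": [0, 1, 2, 3, 4, 5]}, np.arange(6)
        )
        out = gene_trends(profile, ax).set_index("gene")
        assert out.loc["flat", "constant"]
        assert np.isnan(out.loc["flat", "spearman_rho"])
        assert not out.loc["up", "constant"]

    def test_planted_slopes_recover_signs(self, continuum_profile):
        profile, ds, truth = continuum_profile
        stages = ds.cells.drop_duplicates("sample_id").set_index("sample_id")["stage"]
        res = order_samples(profile, stages)
        trends = gene_trends(
            profile, pd.Series(res.position), genes=res.selected_genes
        ).set_index("gene")
        strong = {g: b for g, b in truth.beta.items() if abs(b) >= 2}
        checked = agree = 0
        for g, b in strong.items():
            if g in trends.index and not trends.loc[g, "constant"]:
                checked += 1
                agree += np.sign(trends.loc[g, "spearman_rho"]) == np.sign(b)
        assert checked > 20
        assert agree / checked >= 0.95


class TestMarkers:
    def test_type_specific_program_gene_ranked_first(self):
        from serrapath import ProgramDef, SimConfig, generate_dataset

        cfg = SimConfig(
            n_samples_per_stage={"normal": 2},
            n_cells_per_sample=200,
            n_genes=400,
            n_continuum_genes=0,
            slope_range=(0.0, 0.0),
            cell_type_fractions={"A": 0.5, "B": 0.5},
            program_defs={"sig": ProgramDef(5, 2.0, 1.0, cell_types=["A"])},
            seed=41,
        )
        ds, truth = generate_dataset(cfg)
        norm = normalize(ds)
        markers = one_vs_rest_markers(norm, top_n=5)
        top_a = markers[markers["cell_type"] == "A"]["gene"].tolist()
        sig = set(truth.program_membership["sig"]["genes"])
        assert top_a[0] in sig  # the planted program leads the ranking
        assert len(sig & set(top_a)) >= 3

    def test_identical_types_yield_no_markers_beyond_control(self, null_dataset):
        ds, _ = null_dataset
        norm = normalize(ds)
        rng = np.random.default_rng(6)
        norm = normalize(ds)
        norm.cells = norm.cells.copy()
        norm.cells["cell_type"] = rng.permutation(
            np.repeat(["X", "Y"], norm.n_cells // 2)
        )
        markers = one_vs_rest_markers(norm, top_n=50)
        assert len(markers) <= 0.01 * norm.n_genes * 2 + 2

    def test_top_n_zero_empty(self, null_dataset):
        ds, _ = null_dataset
        norm = normalize(ds)
        norm.cells = norm.cells.copy()
        norm.cells["cell_type"] = ["X", "Y"] * (norm.n_cells // 2)
        assert len(one_vs_rest_markers(norm, top_n=0)) == 0
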