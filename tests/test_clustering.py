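"""Feature preprocessing, k selection, phenotype naming, composition calls."""

import numpy as np
import pandas as pd
import pytest

import pdacpheno as pp
from pdacpheno.clustering import (FeatureMatrix, PhenotypeModelSpec,
                                  compose_tumors, fit_phenotypes,
                                  mean_silhouette, name_clusters,
                                  preprocess_features, select_k)
from pdacpheno.config import (ALL_MARKERS, AnalysisConfig, SUBTYPE_MARKERS,
                              UNASSIGNED)
from oracles import silhouette_direct


def table_from_logged(Y: np.ndarray, eps: float) -> pd.DataFrame:
    """Invert the log2(p + eps) transform so PCA sees exactly Y."""
    props = np.exp2(Y) - eps
    assert (props > 0).all() and (props < 1).all()
    df = pd.DataFrame(props, columns=list(SUBTYPE_MARKERS))
    df.insert(0, "tile_id", [f"t{i}" for i in range(len(df))])
    df["tumor_id"] = "tumor0"
    df["PANCK"] = 0.8
    return df


class TestPreprocess:
    def test_component_retention_matches_eigen_oracle(self):
        # construct logged data with an exact singular spectrum so the
        # explained-variance ratios are (0.50, 0.30, 0.15, 0.04, ...)
        rng = np.random.default_rng(0)
        n = 400
        evr = np.array([0.50, 0.30, 0.15, 0.04, 0.006, 0.003, 0.001])
        G = rng.standard_normal((n, 7))
        G -= G.mean(axis=0)
        Q, _ = np.linalg.qr(G)
        V, _ = np.linalg.qr(rng.standard_normal((7, 7)))
        Y = Q @ np.diag(np.sqrt(evr)) @ V.T
        Y = Y * 0.5 - 3.0  # place log2-proportions in a valid range
        cfg = AnalysisConfig()
        table = table_from_logged(Y, cfg.log_epsilon)
        fm = preprocess_features(table, cfg)
        # oracle: eigen-decomposition of the covariance of the logged data
        logged = np.log2(table[list(SUBTYPE_MARKERS)].to_numpy() + cfg.log_epsilon)
        cov = np.cov(logged - logged.mean(axis=0), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        oracle_evr = eig / eig.sum()
        assert np.allclose(oracle_evr[:4], [0.50, 0.30, 0.15, 0.04], atol=1e-9)
        assert fm.n_components == 3
        assert np.allclose(fm.explained_variance_ratio, oracle_evr[:3],
                           atol=1e-9)

    def test_duplicated_rows_raise(self, cfg):
        table, _ = pp.generate_tile_table(n_per_phenotype=5, seed=0)
        table[list(ALL_MARKERS)] = 0.3
        with pytest.raises(ValueError):
            preprocess_features(table, cfg)

    def test_deterministic(self, cfg, small_table):
        table, _ = small_table
        a = preprocess_features(table, cfg)
        b = preprocess_features(table, cfg)
        assert a.scores.equals(b.scores)

    def test_panck_excluded_from_features(self, cfg, small_table):
        table = small_table[0].copy()
        fm1 = preprocess_features(table, cfg)
        table["PANCK"] = 0.99
        fm2 = preprocess_features(table, cfg)
        assert np.allclose(fm1.scores.to_numpy(), fm2.scores.to_numpy())

    def test_empty_table_raises(self, cfg):
        with pytest.raises(ValueError):
            preprocess_features(pd.DataFrame(), cfg)


class TestSilhouetteAndK:
    def test_silhouette_matches_direct_formula(self, cfg):
        rng = np.random.default_rng(1)
        for n, k in ((20, 2), (45, 3), (50, 4)):
            X = rng.standard_normal((n, 3))
            labels = rng.integers(0, k, n)
            if len(np.unique(labels)) < 2:
                continue
            ours = mean_silhouette(X, labels, cfg)
            assert ours == pytest.approx(silhouette_direct(X, labels),
                                         abs=1e-12)
            assert -1.0 <= ours <= 1.0

    def test_two_blobs_select_two(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (60, 2)),
                       rng.normal(5, 0.3, (60, 2))])
        fm = FeatureMatrix(
            scores=pd.DataFrame(X, columns=["PC1", "PC2"]),
            explained_variance_ratio=np.array([0.6, 0.4]),
            components=pd.DataFrame(), log_epsilon=1e-3,
            mean_=np.zeros(2))
        cfg = AnalysisConfig(k_range=(2, 3, 4, 5))
        assert select_k(fm, cfg) == 2

    def test_single_candidate_returned(self, cfg, small_table):
        table, _ = small_table
        fm = preprocess_features(table, cfg.replace(k_range=(2,)))
        assert select_k(fm, cfg.replace(k_range=(2,))) == 2

    def test_planted_four_profiles_select_four(self, cfg, small_table):
        table, _ = small_table
        fm = preprocess_features(table, cfg)
        assert select_k(fm, cfg) == 4

    def test_infeasible_k_range_raises(self, cfg):
        table, _ = pp.generate_tile_table(n_per_phenotype=2, seed=0)
        fm = preprocess_features(table, cfg)
        with pytest.raises(ValueError):
            select_k(fm, cfg)  # k_range up to 8 > n-1 = 7


class TestNamingAndFit:
    def test_noise_free_labels_exact(self, cfg):
        profiles = [pp.PhenotypeProfile(p.name, p.mean_proportion, np.inf)
                    for p in pp.DEFAULT_PROFILES]
        table, gt = pp.generate_tile_table(profiles, n_per_phenotype=50,
                                           seed=3)
        fm = preprocess_features(table, cfg)
        spec, labels = fit_phenotypes(table, fm, 4, cfg)
        assert (labels == gt.tile_labels.reindex(labels.index)).all()
        assert set(spec.names.values()) == set(pp.PHENOTYPES)

    def test_default_noise_agreement(self, recovery_fit):
        table, gt, res = recovery_fit
        agreement = (res.labels == gt.tile_labels.reindex(res.labels.index)).mean()
        assert agreement >= 0.95

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_merged_clusters_stay_nameable(self, cfg, small_table, k):
        table, _ = small_table
        fm = preprocess_features(table, cfg)
        spec, _ = fit_phenotypes(table, fm, k, cfg)
        n_unassigned = sum(1 for v in spec.names.values() if v == UNASSIGNED)
        assert n_unassigned <= 4 - k
        named = [v for v in spec.names.values() if v != UNASSIGNED]
        assert len(named) == len(set(named))  # names unique

    def test_label_invariance_to_tile_order(self, cfg, small_table):
        table, _ = small_table
        fm = preprocess_features(table, cfg)
        _, labels = fit_phenotypes(table, fm, 4, cfg)
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fm2 = preprocess_features(shuffled, cfg)
        _, labels2 = fit_phenotypes(shuffled, fm2, 4, cfg)
        joined = labels.rename("a").to_frame().join(labels2.rename("b"))
        assert (joined["a"] == joined["b"]).mean() > 0.999

    def test_noise_degrades_agreement_monotonically(self, cfg):
        agreements = []
        for conc in (np.inf, 50.0, 3.0):
            profiles = [pp.PhenotypeProfile(p.name, p.mean_proportion, conc)
                        for p in pp.DEFAULT_PROFILES]
            table, gt = pp.generate_tile_table(profiles, n_per_phenotype=300,
                                               seed=11)
            fm = preprocess_features(table, cfg)
            _, labels = fit_phenotypes(table, fm, 4, cfg)
            agreements.append(
                (labels == gt.tile_labels.reindex(labels.index)).mean())
        assert agreements[0] == 1.0
        assert agreements[0] >= agreements[1] >= agreements[2]

    def test_k_exceeding_distinct_points_raises(self, cfg):
        # 24 tiles but only two distinct feature points
        table, _ = pp.generate_tile_table(n_per_phenotype=6, seed=0)
        table[list(SUBTYPE_MARKERS)] = 0.3
        table["GATA6"] = [0.1, 0.2] * 12
        fm = preprocess_features(table, cfg)
        with pytest.raises(ValueError):
            fit_phenotypes(table, fm, 10, cfg)

    def test_dominance_rule_blocks_weak_basal(self, cfg):
        # MUC16 maximal but not dominant → no Basal.MUC16 name
        centroids = pd.DataFrame(
            [[0.02, 0.02, 0.02, 0.20, 0.18, 0.19, 0.02],
             [0.40, 0.45, 0.35, 0.02, 0.02, 0.02, 0.02]],
            columns=list(SUBTYPE_MARKERS))
        names = name_clusters(centroids, cfg)
        assert "Basal.MUC16" not in names.values()
        assert names[1] == "Classical"

    def test_model_json_round_trip(self, tmp_path, recovery_fit):
        _, _, res = recovery_fit
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = PhenotypeModelSpec.from_json(path)
        assert loaded.k == res.spec.k
        assert loaded.names == {int(k): v for k, v in res.spec.names.items()}
        assert np.allclose(loaded.centroids_raw.to_numpy(),
                           res.spec.centroids_raw.to_numpy())


class TestCompose:
    def make_composition(self, cfg, labels_per_tumor):
        rows, labels, ids = [], [], []
        i = 0
        for tumor, labs in labels_per_tumor.items():
            for lab in labs:
                ids.append(f"t{i}")
                rows.append({"tile_id": f"t{i}", "tumor_id": tumor})
                labels.append(lab)
                i += 1
        table = pd.DataFrame(rows)
        return compose_tumors(pd.Series(labels, index=ids), table, cfg)

    def test_presence_boundary_is_strict(self, cfg):
        comp = self.make_composition(cfg, {
            "A": ["Classical"] * 989 + ["Basal.MUC16"] * 11,   # 1.1% basal
            "B": ["Classical"] * 990 + ["Basal.MUC16"] * 10,   # exactly 1%
        })
        comp = comp.set_index("tumor_id")
        assert bool(comp.loc["A", "basal_present"])
        assert not bool(comp.loc["B", "basal_present"])

    def test_single_phenotype_tumor(self, cfg):
        comp = self.make_composition(cfg, {"A": ["Intermediate"] * 10})
        row = comp.iloc[0]
        assert row["prop_Intermediate"] == 1.0
        assert row["predominant"] == "Intermediate"
        assert bool(row["predominance_strict"])

    def test_tie_break_order(self, cfg):
        comp = self.make_composition(cfg, {
            "A": ["Basal.MUC16"] * 5 + ["Intermediate"] * 5})
        assert comp.iloc[0]["predominant"] == "Intermediate"
        assert not bool(comp.iloc[0]["predominance_strict"])

    def test_proportions_sum_to_one(self, cfg, recovery_fit):
        table, _, res = recovery_fit
        comp = res.compose()
        prop_cols = [c for c in comp.columns if c.startswith("prop_")]
        assert np.allclose(comp[prop_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_pooled_equals_weighted_tumor_mean(self, cfg, recovery_fit):
        table, _, res = recovery_fit
        comp = res.compose()
        pooled = res.pooled()
        for p in pp.PHENOTYPES:
            weighted = (comp[f"prop_{p}"] * comp["n_tiles"]).sum() / comp["n_tiles"].sum()
            assert pooled[p] == pytest.approx(weighted, abs=1e-12)

    def test_unknown_tile_raises(self, cfg):
        table = pd.DataFrame({"tile_id": ["t0"], "tumor_id": ["A"]})
        labels = pd.Series(["Classical"], index=["t1"])
        with pytest.raises(ValueError):
            compose_tumors(labels, table, cfg)


class TestModelResultsSurface:
    def test_summary_mentions_key_quantities(self, recovery_fit):
        _, _, res = recovery_fit
        text = res.summary()
        assert "k: 4" in text
        assert "Classical" in text and "Basal.MUC16" in text
        assert "silhouette" in text

    def test_fixed_k_skips_selection(self, cfg, small_table):
        table, _ = small_table
        res = pp.TilePhenotypeModel(table, cfg).fit(k=3)
        assert res.k == 3 and res.silhouette_by_k is None
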