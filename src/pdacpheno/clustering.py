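"""Tile-phenotype discovery: log/PCA features, silhouette-selected k-means,
rule-based cluster naming, per-tumor composition calls.

The modelling surface follows the statsmodels convention: build a
:class:`TilePhenotypeModel` from a tile table, call :meth:`fit`, and work
with the returned :class:`TilePhenotypeResults` (centroids, phenotype
names, labels, diagnostics, ``summary()``). The underlying operations
(:func:`preprocess_features`, :func:`select_k`, :func:`fit_phenotypes`,
:func:`compose_tumors`) are also usable directly.

Features are PCA scores of log2(proportion + ε) over the seven subtype
markers (PanCK is a gate, not a phenotype axis), keeping components whose
explained variance ratio exceeds 5%. The cluster count is chosen by mean
silhouette over a candidate range; clusters are then named from their raw
marker centroids: a MUC16-dominant cluster is Basal.MUC16, an
S100A2-dominant cluster is Basal.S100A2, the cluster with the highest mean
classical expression (CLDN18/GATA6/TFF1) is Classical, and a remaining
KRT17-topped, classical-low cluster is Intermediate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .config import (AnalysisConfig, BASAL_PHENOTYPES, CLASSICAL_MARKERS,
                     PHENOTYPE_ORDER, PHENOTYPES, SUBTYPE_MARKERS, UNASSIGNED)

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Retained PCA scores of log-transformed marker proportions."""

    scores: pd.DataFrame                 # tiles × components, index = tile_id
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame             # loadings, components × markers
    log_epsilon: float
    mean_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def log_transform(table: pd.DataFrame, cfg: AnalysisConfig,
                  markers: Sequence[str] = SUBTYPE_MARKERS) -> pd.DataFrame:
    x = table[list(markers)].astype(float)
    if (x.values < 0).any() or (x.values > 1).any():
        raise ValueError("marker proportions must lie in [0, 1]")
    return np.log2(x + cfg.log_epsilon)


def preprocess_features(table: pd.DataFrame, cfg: AnalysisConfig
                        ) -> FeatureMatrix:
    """log2(p + ε) over the seven subtype markers, then PCA; keep components
    with explained variance ratio > cfg.pca_var_min.

    Component signs follow a fixed convention (the loading of largest
    magnitude is positive) so the output is deterministic.
    """
    if table.empty:
        raise ValueError("tile table is empty")
    logged = log_transform(table, cfg)
    X = logged.to_numpy()
    if cfg.scale_pca:
        sd = X.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValueError("zero-variance marker under scaling")
        X = (X - X.mean(axis=0)) / sd
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance input: no principal component retained")

    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    keep = evr > cfg.pca_var_min
    if not keep.any():
        raise ValueError("no component exceeds the variance threshold")
    scores = scores[:, keep]
    comps = pca.components_[keep]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(comps.shape[0]):
        i = np.argmax(np.abs(comps[j]))
        if comps[j, i] < 0:
            comps[j] *= -1
            scores[:, j] *= -1
    idx = table["tile_id"] if "tile_id" in table.columns else table.index
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    fm = FeatureMatrix(
        scores=pd.DataFrame(scores, index=pd.Index(idx, name="tile_id"),
                            columns=cols),
        explained_variance_ratio=evr[keep].copy(),
        components=pd.DataFrame(comps, index=cols, columns=list(SUBTYPE_MARKERS)),
        log_epsilon=cfg.log_epsilon,
        mean_=pca.mean_.copy(),
    )
    logger.info("retained %d/%d components (EVR %s)", fm.n_components, n_comp,
                np.round(fm.explained_variance_ratio, 3).tolist())
    return fm


def _kmeans(X: np.ndarray, k: int, cfg: AnalysisConfig) -> KMeans:
    km = KMeans(n_clusters=k, n_init=cfg.kmeans_restarts, init="k-means++",
                random_state=cfg.seed)
    km.fit(X)
    return km


def mean_silhouette(X: np.ndarray, labels: np.ndarray,
                    cfg: AnalysisConfig) -> float:
    """Mean silhouette, subsampled (seeded) above cfg.silhouette_max_n."""
    n = X.shape[0]
    if n > cfg.silhouette_max_n:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(n, cfg.silhouette_max_n, replace=False)
        X, labels = X[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            return -1.0
    return float(silhouette_score(X, labels))


def select_k(features: FeatureMatrix, cfg: AnalysisConfig,
             return_scores: bool = False):
    """Cluster count maximizing mean silhouette of a seeded k-means fit,
    ties broken toward smaller k."""
    X = features.scores.to_numpy()
    n = X.shape[0]
    ks = [k for k in cfg.k_range]
    if any(k > n - 1 for k in ks):
        raise ValueError(f"k_range {ks} infeasible for n={n}")
    scores: dict[int, float] = {}
    for k in ks:
        labels = _kmeans(X, k, cfg).labels_
        scores[k] = mean_silhouette(X, labels, cfg)
        logger.info("silhouette(k=%d) = %.4f", k, scores[k])
    best = ks[0]
    for k in ks[1:]:
        if scores[k] > scores[best]:
            best = k
    if return_scores:
        return best, scores
    return best


@dataclass
class PhenotypeModelSpec:
    """Fitted cluster centroids with assigned phenotype names."""

    k: int
    centroids_pca: pd.DataFrame      # k × components
    centroids_raw: pd.DataFrame      # k × markers, mean raw proportions
    names: dict[int, str]
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "k": self.k,
            "centroids_pca": self.centroids_pca.to_dict(orient="index"),
            "centroids_raw": self.centroids_raw.to_dict(orient="index"),
            "names": {str(i): n for i, n in self.names.items()},
            "seed": self.seed,
            "config": _jsonable(self.config),
        }
        s = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeModelSpec":
        doc = json.loads(Path(path).read_text())
        cp = pd.DataFrame.from_dict(doc["centroids_pca"], orient="index")
        cp.index = cp.index.astype(int)
        cp = cp[sorted(cp.columns, key=lambda c: int(str(c).lstrip("PC")))]
        cr = pd.DataFrame.from_dict(doc["centroids_raw"], orient="index")
        cr.index = cr.index.astype(int)
        cr = cr.reindex(columns=[m for m in SUBTYPE_MARKERS if m in cr.columns])
        return cls(int(doc["k"]), cp.sort_index(), cr.sort_index(),
                   {int(i): n for i, n in doc["names"].items()},
                   int(doc["seed"]), doc.get("config", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def name_clusters(centroids_raw: pd.DataFrame, cfg: AnalysisConfig
                  ) -> dict[int, str]:
    """Assign phenotype names to clusters from their raw marker centroids.

    Rules, applied in order over remaining clusters:
      1. the cluster with maximal MUC16 mean, if MUC16 dominates that
         cluster (≥ cfg.dominance_ratio × every other marker) → Basal.MUC16;
      2. likewise for S100A2 → Basal.S100A2;
      3. the cluster maximizing mean(CLDN18, GATA6, TFF1) → Classical;
      4. any remaining cluster with KRT17 as its top marker and a low
         classical mean → Intermediate (highest KRT17 first).
    Clusters matching no rule are Unassigned.
    """
    C = centroids_raw[list(SUBTYPE_MARKERS)]
    remaining = list(C.index)
    names: dict[int, str] = {}

    def dominant(i: int, marker: str) -> bool:
        row = C.loc[i]
        others = row.drop(marker)
        return bool((row[marker] >= cfg.dominance_ratio * others).all())

    for marker, pheno in (("MUC16", "Basal.MUC16"), ("S100A2", "Basal.S100A2")):
        if not remaining:
            break
        i = C.loc[remaining, marker].idxmax()
        if dominant(i, marker):
            names[i] = pheno
            remaining.remove(i)

    if remaining:
        classical_mean = C.loc[remaining, list(CLASSICAL_MARKERS)].mean(axis=1)
        i = classical_mean.idxmax()
        names[i] = "Classical"
        remaining.remove(i)

    cand = []
    for i in remaining:
        row = C.loc[i]
        if (row.idxmax() == "KRT17"
                and row[list(CLASSICAL_MARKERS)].mean()
                < cfg.intermediate_classical_max):
            cand.append(i)
    if cand:
        i = C.loc[cand, "KRT17"].idxmax()
        names[i] = "Intermediate"
        remaining.remove(i)

    for i in remaining:
        names[i] = UNASSIGNED
    return names


def fit_phenotypes(table: pd.DataFrame, features: FeatureMatrix, k: int,
                   cfg: AnalysisConfig
                   ) -> tuple[PhenotypeModelSpec, pd.Series]:
    """Seeded multi-restart k-means at k clusters, followed by rule-based
    phenotype naming. Returns the model and a tile_id → phenotype series."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = features.scores.to_numpy()
    if k > len(np.unique(X, axis=0)):
        raise ValueError("k exceeds the number of distinct points")
    km = _kmeans(X, k, cfg)
    idx = features.scores.index
    raw = table.set_index(idx if "tile_id" not in table.columns
                          else table["tile_id"])[list(SUBTYPE_MARKERS)]
    centroids_raw = raw.groupby(km.labels_).mean()
    centroids_raw = centroids_raw.reindex(range(k)).fillna(0.0)
    centroids_pca = pd.DataFrame(km.cluster_centers_, index=range(k),
                                 columns=features.scores.columns)
    names = name_clusters(centroids_raw, cfg)
    labels = pd.Series([names[i] for i in km.labels_], index=idx,
                       name="phenotype")
    spec = PhenotypeModelSpec(k, centroids_pca, centroids_raw, names,
                              cfg.seed, cfg.to_dict())
    return spec, labels


def compose_tumors(labels: pd.Series, table: pd.DataFrame,
                   cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-tumor phenotype proportions with presence / predominance calls.

    `present_*` uses the strict >1% rule; `basal_present` applies it to the
    summed basal proportion; `predominant` is the argmax phenotype with
    ties broken in the fixed order Classical, Intermediate, Basal.MUC16,
    Basal.S100A2; `predominance_strict` flags a majority (>50%) cluster.
    """
    if "tile_id" in table.columns:
        tumor = table.set_index("tile_id")["tumor_id"]
    else:
        tumor = table["tumor_id"]
    df = pd.DataFrame({"phenotype": labels, "tumor_id": tumor.reindex(labels.index)})
    if df["tumor_id"].isna().any():
        raise ValueError("every labeled tile must have a tumor_id")
    phenos = [p for p in PHENOTYPE_ORDER]
    counts = (df.groupby("tumor_id")["phenotype"].value_counts()
                .unstack(fill_value=0).reindex(columns=phenos, fill_value=0))
    n_tiles = counts.sum(axis=1)
    props = counts.div(n_tiles, axis=0)

    out = props.copy()
    out.columns = [f"prop_{p}" for p in phenos]
    out["n_tiles"] = n_tiles
    for p in phenos:
        out[f"present_{p}"] = props[p] > cfg.presence_min
    basal = props[list(BASAL_PHENOTYPES)].sum(axis=1)
    out["basal_proportion"] = basal
    out["basal_present"] = basal > cfg.presence_min
    # argmax with deterministic tie-break = first max in PHENOTYPE_ORDER
    out["predominant"] = props[phenos].idxmax(axis=1)
    out["predominance_strict"] = props[phenos].max(axis=1) > cfg.predominance_min
    return out.reset_index()


def pooled_composition(labels: pd.Series) -> pd.Series:
    """Phenotype proportions pooled over all tiles."""
    return labels.value_counts(normalize=True).reindex(
        list(PHENOTYPE_ORDER), fill_value=0.0)


class TilePhenotypeModel:
    """Tile-phenotype clustering model over a filtered tile table.

    Parameters
    ----------
    tile_table : DataFrame in TileTable layout (tile_id, tumor_id, geometry
        columns, and one proportion column per panel marker).
    config : AnalysisConfig, optional.

    Examples
    --------
    >>> model = TilePhenotypeModel.from_dataframe(tiles)   # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(self, tile_table: pd.DataFrame,
                 config: AnalysisConfig | None = None):
        if tile_table.empty:
            raise ValueError("tile table is empty")
        self.table = tile_table.reset_index(drop=True)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TilePhenotypeModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, config: AnalysisConfig | None = None
                 ) -> "TilePhenotypeModel":
        from .io import read_tile_table
        return cls(read_tile_table(path), config)

    def fit(self, k: int | None = None) -> "TilePhenotypeResults":
        """Preprocess, select k by silhouette (unless given), cluster, name."""
        cfg = self.config
        features = preprocess_features(self.table, cfg)
        if k is None:
            k, sil = select_k(features, cfg, return_scores=True)
        else:
            sil = None
        spec, labels = fit_phenotypes(self.table, features, k, cfg)
        return TilePhenotypeResults(self, features, spec, labels, sil)


class TilePhenotypeResults:
    """Fitted tile-phenotype model: centroids, names, labels, diagnostics."""

    def __init__(self, model: TilePhenotypeModel, features: FeatureMatrix,
                 spec: PhenotypeModelSpec, labels: pd.Series,
                 silhouette_by_k: Mapping[int, float] | None = None):
        self.model = model
        self.features = features
        self.spec = spec
        self.labels = labels
        self.silhouette_by_k = dict(silhouette_by_k) if silhouette_by_k else None

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def names(self) -> dict[int, str]:
        return self.spec.names

    def compose(self, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
        return compose_tumors(self.labels, self.model.table,
                              cfg or self.model.config)

    def pooled(self) -> pd.Series:
        return pooled_composition(self.labels)

    def summary(self) -> str:
        lines = ["Tile phenotype clustering", "=" * 45]
        lines.append(f"tiles: {len(self.labels)}    k: {self.k}    "
                     f"components: {self.features.n_components}")
        evr = ", ".join(f"{v:.1%}" for v in self.features.explained_variance_ratio)
        lines.append(f"explained variance (retained): {evr}")
        if self.silhouette_by_k:
            s = ", ".join(f"k={k}: {v:.3f}"
                          for k, v in sorted(self.silhouette_by_k.items()))
            lines.append(f"mean silhouette: {s}")
        lines.append("")
        lines.append("cluster centroids (raw marker proportions):")
        tab = self.spec.centroids_raw.round(3).copy()
        tab.insert(0, "phenotype", [self.names[i] for i in tab.index])
        lines.append(tab.to_string())
        lines.append("")
        pooled = self.pooled()
        lines.append("pooled tile composition:")
        for p, v in pooled.items():
            if v > 0:
                lines.append(f"  {p:<14s} {v:6.1%}")
        return "\n".join(lines)

    def plot_centroids(self, ax=None):
        """Bar plot of raw marker centroids per named cluster."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        tab = self.spec.centroids_raw.copy()
        tab.index = [self.names[i] for i in tab.index]
        tab.T.plot.bar(ax=ax)
        ax.set_ylabel("mean positive-pixel proportion")
        ax.set_xlabel("marker")
        return ax

    def to_json(self, path=None) -> str:
        return self.spec.to_json(path)
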