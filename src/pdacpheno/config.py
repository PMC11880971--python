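"""Analysis configuration and marker-panel constants.

The panel comprises PanCK (the epithelial gate) plus seven subtype markers:
three classical (GATA6, CLDN18, TFF1) and four basal-like (MUC16, S100A2,
KRT17, PanBS — a KRT5/KRT14/p63 cocktail stained as one channel). The five
serial slides carry the channels in duplex/singleplex combinations, which is
why channels are grouped by slide for registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

PANCK = "PANCK"
CLASSICAL_MARKERS = ("CLDN18", "GATA6", "TFF1")
BASAL_MARKERS = ("MUC16", "S100A2", "KRT17", "PanBS")
SUBTYPE_MARKERS = ("GATA6", "CLDN18", "TFF1", "MUC16", "S100A2", "KRT17", "PanBS")
ALL_MARKERS = (PANCK,) + SUBTYPE_MARKERS

#: Serial-slide layout: one singleplex PanCK slide, one singleplex MUC16
#: slide, and three duplex slides.
DEFAULT_CHANNEL_SLIDE = {
    "PANCK": "slide_panck",
    "GATA6": "slide_gata6_s100a2",
    "S100A2": "slide_gata6_s100a2",
    "PanBS": "slide_panbs_tff1",
    "TFF1": "slide_panbs_tff1",
    "KRT17": "slide_krt17_cldn18",
    "CLDN18": "slide_krt17_cldn18",
    "MUC16": "slide_muc16",
}

PHENOTYPES = ("Classical", "Intermediate", "Basal.MUC16", "Basal.S100A2")
BASAL_PHENOTYPES = ("Basal.MUC16", "Basal.S100A2")
UNASSIGNED = "Unassigned"

#: Deterministic tie-break order for predominance calls.
PHENOTYPE_ORDER = PHENOTYPES + (UNASSIGNED,)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and knobs of the tile-phenotyping pipeline.

    Defaults follow the published analysis where it states a value: 200-μm
    tiles, tumor tiles gated at >10% PanCK, presence >1%, predominance >50%,
    PCA components retained above 5% explained variance, two-sided alpha
    0.05. Quantities the analysis leaves unstated (scanner resolution,
    log pseudo-count, k-means restarts, silhouette subsample) are exposed
    here with documented defaults.
    """

    tile_size_um: float = 200.0
    #: Scanner resolution in μm per pixel. Not reported for the original
    #: cohort; 2.0 keeps synthetic canvases at desk scale (100-px tiles).
    mpp: float = 2.0
    panck_min: float = 0.10
    #: A tile is "nontruncated" when its inside-annotation fraction reaches
    #: this value; 1.0 = fully inside.
    truncation_min_inside: float = 1.0
    presence_min: float = 0.01
    predominance_min: float = 0.50
    pca_var_min: float = 0.05
    log_epsilon: float = 1e-3
    alpha: float = 0.05
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    seed: int = 0
    #: Columns are always centered before PCA; variance scaling is off by
    #: default because the log transform already stabilizes scale.
    scale_pca: bool = False
    kmeans_restarts: int = 25
    silhouette_max_n: int = 10_000
    #: "Dominant" marker in cluster naming: its centroid mean must be at
    #: least this multiple of every other marker mean in the cluster.
    dominance_ratio: float = 1.5
    #: Upper bound on mean classical-marker expression for the Intermediate
    #: naming rule ("negative for all markers except KRT17").
    intermediate_classical_max: float = 0.25

    def __post_init__(self) -> None:
        if self.tile_size_um <= 0:
            raise ValueError("tile_size_um must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        for name in ("panck_min", "truncation_min_inside", "presence_min",
                     "predominance_min", "pca_var_min", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")
        if not self.k_range or any(k < 2 for k in self.k_range):
            raise ValueError("k_range must contain integers >= 2")

    @property
    def tile_size_px(self) -> int:
        return int(round(self.tile_size_um / self.mpp))

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(int(k) for k in d["k_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("analysis", doc))


def validate_markers(columns: Sequence[str]) -> None:
    """Raise if any panel marker column is missing."""
    missing = [m for m in ALL_MARKERS if m not in columns]
    if missing:
        raise ValueError(f"missing marker column(s): {', '.join(missing)}")
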