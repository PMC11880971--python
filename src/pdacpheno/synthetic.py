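"""Synthetic-data generators with planted ground truth.

The real cohorts behind the tile-phenotyping analysis are not public, so
every downstream stage is exercised on generated data whose answers are
known by construction:

* **tile tables** — per-tile marker proportions drawn from a catalog of
  phenotype profiles (Beta noise around profile means), with planted labels;
* **slide stacks** — co-registered binary positive-pixel masks on a shared
  canvas (Bernoulli pixels inside phenotype regions), with planted rigid
  misalignments between serial slides;
* **cohorts** — per-tumor phenotype compositions plus survival records with
  a planted hazard effect of basal presence;
* **H-score TMA tables** — intensity-class records with subtype labels for
  the marker-triage rules.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
import shapely

from .config import (ALL_MARKERS, BASAL_PHENOTYPES, DEFAULT_CHANNEL_SLIDE,
                     PHENOTYPES, SUBTYPE_MARKERS, PANCK)
from .registration import IDENTITY, RigidTransform, apply_transform_mask

TILE_META_COLUMNS = ("tile_id", "tumor_id", "slide_id", "row", "col",
                     "x0", "y0", "x1", "y1", "inside_fraction", "truncated")


@dataclass(frozen=True)
class PhenotypeProfile:
    """Expected positive-pixel fraction per marker for one tile phenotype.

    `concentration` controls Beta dispersion around the means: the per-tile
    proportion of marker m is Beta(mean*c, (1-mean)*c). ``c = inf`` is the
    noise-free mode in which every tile equals its profile means.
    """

    name: str
    mean_proportion: Mapping[str, float]
    concentration: float = 50.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        missing = [m for m in ALL_MARKERS if m not in self.mean_proportion]
        if missing:
            raise ValueError(f"profile {self.name!r} missing markers {missing}")
        for m, v in self.mean_proportion.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mean for {m} outside [0, 1]: {v}")
        if self.mean_proportion[PANCK] <= 0.10:
            raise ValueError("tumor phenotypes must have PANCK mean > 0.10")

    def means(self, markers: Sequence[str] = ALL_MARKERS) -> np.ndarray:
        return np.array([self.mean_proportion[m] for m in markers])


def _profile(name, panck, **kw) -> PhenotypeProfile:
    means = {m: kw.get(m, 0.02) for m in SUBTYPE_MARKERS}
    means[PANCK] = panck
    return PhenotypeProfile(name, means)


#: Default catalog. The published analysis reports no per-cluster marker
#: means; these values are chosen to match its qualitative description:
#: Classical mixes CLDN18/GATA6/TFF1; Intermediate is KRT17-high with
#: low-moderate GATA6 and little else; Basal.MUC16 is MUC16-dominant with
#: moderate KRT17; Basal.S100A2 is S100A2-dominant with moderate PanBS.
DEFAULT_PROFILES: tuple[PhenotypeProfile, ...] = (
    _profile("Classical", 0.85, CLDN18=0.50, GATA6=0.45, TFF1=0.40,
             KRT17=0.03),
    _profile("Intermediate", 0.80, KRT17=0.35, GATA6=0.12, CLDN18=0.05,
             TFF1=0.04),
    _profile("Basal.MUC16", 0.80, MUC16=0.45, KRT17=0.12, PanBS=0.05,
             S100A2=0.03),
    _profile("Basal.S100A2", 0.80, S100A2=0.50, PanBS=0.20, KRT17=0.10,
             MUC16=0.03),
)


@dataclass
class GroundTruth:
    """Planted answers accompanying a generated artifact."""

    tile_labels: pd.Series | None = None            # tile_id -> phenotype
    transforms: dict[str, RigidTransform] | None = None  # slide -> planted
    tumor_compositions: pd.DataFrame | None = None  # tumor x phenotype
    region_phenotypes: dict[str, str] | None = None
    profiles: tuple[PhenotypeProfile, ...] | None = None


@dataclass
class SlideStack:
    """Co-registered per-channel binary masks over annotated tumor tissue.

    `channels` maps marker name to a boolean positive-pixel mask on the
    shared canvas; `channel_slide` records which physical slide each channel
    was stained on; `tissue` holds one whole-tissue footprint mask per slide
    (what a registration stage actually aligns). Synthetic stacks carry
    their :class:`GroundTruth`.
    """

    channels: dict[str, np.ndarray]
    channel_slide: dict[str, str]
    tissue: dict[str, np.ndarray]
    annotation: BaseGeometry
    mpp: float
    ground_truth: GroundTruth | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def with_masks(self, channels, tissue) -> "SlideStack":
        return SlideStack(channels, dict(self.channel_slide), tissue,
                          self.annotation, self.mpp, self.ground_truth)

    def validate(self) -> None:
        shp = self.shape
        for name, m in self.channels.items():
            if m.shape != shp:
                raise ValueError(f"channel {name!r} shape {m.shape} != {shp}")


def _draw_proportions(rng: np.random.Generator, profile: PhenotypeProfile,
                      n: int, markers: Sequence[str]) -> np.ndarray:
    means = profile.means(markers)
    if np.isinf(profile.concentration):
        return np.tile(means, (n, 1))
    c = profile.concentration
    out = np.empty((n, len(markers)))
    for j, mu in enumerate(means):
        if mu <= 0.0:
            out[:, j] = 0.0
        elif mu >= 1.0:
            out[:, j] = 1.0
        else:
            out[:, j] = rng.beta(mu * c, (1.0 - mu) * c, size=n)
    return np.clip(out, 0.0, 1.0)


def generate_tile_table(
    profiles: Sequence[PhenotypeProfile] = DEFAULT_PROFILES,
    n_per_phenotype: Mapping[str, int] | int = 500,
    seed: int = 0,
    n_tumors: int = 20,
    tile_px: int = 100,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a tile table with planted phenotype labels.

    Marker proportions are Beta draws around each profile's means; tiles are
    laid out on a synthetic grid and assigned to `n_tumors` tumors at
    random. Deterministic for a given (arguments, seed).
    """
    profiles = tuple(profiles)
    if not profiles:
        raise ValueError("profile list must be non-empty")
    if isinstance(n_per_phenotype, int):
        n_per_phenotype = {p.name: n_per_phenotype for p in profiles}
    by_name = {p.name: p for p in profiles}
    unknown = set(n_per_phenotype) - set(by_name)
    if unknown:
        raise ValueError(f"counts given for unknown profiles: {sorted(unknown)}")
    for name, n in n_per_phenotype.items():
        if n < 1:
            raise ValueError(f"count for {name!r} must be >= 1, got {n}")

    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for name in sorted(n_per_phenotype):
        n = int(n_per_phenotype[name])
        blocks.append(_draw_proportions(rng, by_name[name], n, ALL_MARKERS))
        labels.extend([name] * n)
    props = np.vstack(blocks)
    n_total = props.shape[0]

    # shuffle so tumors are phenotype mixtures, preserving label pairing
    perm = rng.permutation(n_total)
    props = props[perm]
    labels = [labels[i] for i in perm]

    ids = [f"t{i:06d}" for i in range(n_total)]
    grid_w = max(1, int(np.ceil(np.sqrt(n_total))))
    rows = np.arange(n_total) // grid_w
    cols = np.arange(n_total) % grid_w
    table = pd.DataFrame({
        "tile_id": ids,
        "tumor_id": [f"tumor{k:03d}" for k in rng.integers(0, n_tumors, n_total)],
        "slide_id": "synthetic",
        "row": rows,
        "col": cols,
        "x0": cols * tile_px,
        "y0": rows * tile_px,
        "x1": (cols + 1) * tile_px,
        "y1": (rows + 1) * tile_px,
        "inside_fraction": 1.0,
        "truncated": False,
    })
    for j, m in enumerate(ALL_MARKERS):
        table[m] = props[:, j]
    gt = GroundTruth(tile_labels=pd.Series(labels, index=ids, name="phenotype"),
                     profiles=profiles)
    return table, gt


def _as_geometry(region) -> BaseGeometry:
    if isinstance(region, BaseGeometry):
        return region
    x0, y0, x1, y1 = region
    return shapely_box(x0, y0, x1, y1)


def rasterize(geom: BaseGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside `geom`."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return shapely.contains_xy(geom, xs.ravel() + 0.5, ys.ravel() + 0.5).reshape(h, w)


def generate_slide_stack(
    profiles: Sequence[PhenotypeProfile] = DEFAULT_PROFILES,
    layout: Mapping[str, tuple] | None = None,
    mpp: float = 2.0,
    planted_transforms: Mapping[str, RigidTransform] | None = None,
    seed: int = 0,
    canvas_shape: tuple[int, int] | None = None,
    margin: int = 60,
    channel_slide: Mapping[str, str] = DEFAULT_CHANNEL_SLIDE,
) -> tuple[SlideStack, GroundTruth]:
    """Generate co-registered per-channel masks with planted misalignments.

    `layout` maps region name → (geometry, phenotype name); geometry is a
    shapely polygon or an (x0, y0, x1, y1) box in pixel coordinates of the
    reference frame. Within each region, every channel mask is an
    independent Bernoulli field at the region phenotype's marker mean, so
    observed positive fractions converge to the profile means as regions
    grow. Each slide's masks are then warped by its planted rigid transform
    (identity by default); registration should recover the inverse.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    if not layout:
        raise ValueError("layout must assign at least one region")
    by_name = {p.name: p for p in profiles}
    regions: dict[str, tuple[BaseGeometry, str]] = {}
    for rname, (geom, pheno) in layout.items():
        if pheno not in by_name:
            raise ValueError(f"region {rname!r} uses unknown phenotype {pheno!r}")
        regions[rname] = (_as_geometry(geom), pheno)

    union = unary_union([g for g, _ in regions.values()])
    if canvas_shape is None:
        _, _, x1, y1 = union.bounds
        canvas_shape = (int(np.ceil(y1)) + margin, int(np.ceil(x1)) + margin)
    h, w = canvas_shape
    x0b, y0b, x1b, y1b = union.bounds
    if x0b < 0 or y0b < 0 or x1b > w or y1b > h:
        raise ValueError("layout regions fall outside the canvas")

    rng = np.random.default_rng(seed)
    region_masks = {r: rasterize(g, (h, w)) for r, (g, _) in regions.items()}
    tissue_ref = np.zeros((h, w), bool)
    for m in region_masks.values():
        tissue_ref |= m

    channels: dict[str, np.ndarray] = {}
    for marker in ALL_MARKERS:
        mask = np.zeros((h, w), bool)
        for rname, (_, pheno) in sorted(regions.items()):
            p = by_name[pheno].mean_proportion[marker]
            rm = region_masks[rname]
            npx = int(rm.sum())
            if npx and p > 0:
                mask[rm] |= rng.random(npx) < p
        channels[marker] = mask

    planted = {s: IDENTITY for s in set(channel_slide.values())}
    if planted_transforms:
        planted.update(planted_transforms)
    tissue = {}
    for s in sorted(planted):
        t = planted[s]
        tissue[s] = tissue_ref if t.is_identity else apply_transform_mask(tissue_ref, t)
    for marker in channels:
        t = planted[channel_slide[marker]]
        if not t.is_identity:
            channels[marker] = apply_transform_mask(channels[marker], t)

    gt = GroundTruth(transforms=dict(planted),
                     region_phenotypes={r: p for r, (_, p) in regions.items()},
                     profiles=tuple(profiles))
    stack = SlideStack(channels, dict(channel_slide), tissue, union, mpp, gt)
    return stack, gt


DEFAULT_COVARIATE_PREVALENCE = {
    "age_gt_65": 0.50,
    "positive_margins": 0.20,
    "vascular_emboli": 0.35,
    "lymph_node_invasion": 0.65,
    "vascular_invasion": 0.40,
    "perineural_invasion": 0.80,
}

COVARIATES = tuple(DEFAULT_COVARIATE_PREVALENCE)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic resected-PDAC cohort.

    Defaults emulate a 95-patient surgical cohort: prevalences give roughly
    two thirds of tumors a detectable (>1%) basal component, the baseline
    hazard puts median survival near four years, and basal presence carries
    a planted hazard ratio of 1.9.
    """

    n_tumors: int = 95
    phenotype_prevalence: Mapping[str, float] = field(default_factory=lambda: {
        "Classical": 0.29, "Intermediate": 0.43,
        "Basal.MUC16": 0.14, "Basal.S100A2": 0.14})
    dirichlet_concentration: float = 1.2
    basal_hazard_ratio: float = 1.9
    baseline_hazard: float = 0.015      # events per month
    censoring_rate: float = 0.3
    presence_min: float = 0.01
    weibull_shape: float = 1.0          # 1.0 = exponential survival times
    covariate_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        prev = self.phenotype_prevalence
        if set(prev) != set(PHENOTYPES):
            raise ValueError(f"prevalence must cover exactly {PHENOTYPES}")
        if any(v < 0 for v in prev.values()) or abs(sum(prev.values()) - 1) > 1e-9:
            raise ValueError("prevalence must be non-negative and sum to 1")
        for name in ("dirichlet_concentration", "basal_hazard_ratio",
                     "baseline_hazard", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")


def generate_cohort(config: CohortConfig = CohortConfig()
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate per-tumor compositions and survival records.

    Compositions are Dirichlet draws around the configured prevalence.
    Event times are Weibull (exponential when shape = 1) with hazard scaled
    by `basal_hazard_ratio` whenever the summed basal proportion exceeds
    `presence_min`. Censoring is an independent exponential whose rate is
    set so the expected censored fraction matches `censoring_rate`.
    Covariates are independent binaries that do not enter the hazard, so
    the planted basal effect is the only signal a Cox model should find.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    alpha = np.array([cfg.phenotype_prevalence[p] for p in PHENOTYPES])
    alpha = alpha * cfg.dirichlet_concentration
    comp = rng.dirichlet(alpha, size=cfg.n_tumors)
    tumor_ids = [f"tumor{k:03d}" for k in range(cfg.n_tumors)]
    comp_df = pd.DataFrame(comp, index=pd.Index(tumor_ids, name="tumor_id"),
                           columns=list(PHENOTYPES))
    basal_share = comp_df[list(BASAL_PHENOTYPES)].sum(axis=1)
    basal_present = basal_share > cfg.presence_min

    hazard = np.where(basal_present, cfg.baseline_hazard * cfg.basal_hazard_ratio,
                      cfg.baseline_hazard)
    u = rng.random(cfg.n_tumors)
    # Weibull with scale such that h(t) = hazard * k * t^(k-1) / ... reduces
    # to exponential(hazard) at shape 1.
    k = cfg.weibull_shape
    event_time = (-np.log(u)) ** (1.0 / k) / hazard

    if cfg.censoring_rate <= 0.0:
        observed, event = event_time, np.ones(cfg.n_tumors, bool)
    elif cfg.censoring_rate >= 1.0:
        observed, event = event_time, np.zeros(cfg.n_tumors, bool)
    else:
        cr = cfg.censoring_rate
        cens_rate = cfg.baseline_hazard * cr / (1.0 - cr)
        cens_time = rng.exponential(1.0 / cens_rate, size=cfg.n_tumors)
        event = event_time <= cens_time
        observed = np.minimum(event_time, cens_time)
    observed = np.maximum(observed, 1e-6)

    surv = pd.DataFrame({
        "patient_id": tumor_ids,
        "time_months": observed,
        "event": event,
        "basal_present": basal_present.to_numpy(),
    })
    for cov, p in cfg.covariate_prevalence.items():
        surv[cov] = rng.random(cfg.n_tumors) < p

    gt = GroundTruth(tumor_compositions=comp_df.copy())
    return comp_df, surv, gt


def generate_tma_table(
    n_classical: int = 13,
    n_basal: int = 8,
    markers: Sequence[str] = SUBTYPE_MARKERS,
    seed: int = 0,
) -> pd.DataFrame:
    """H-score TMA records with subtype labels for marker triage.

    Emulates a specificity TMA of clear-classical and clear-basal cases:
    classical markers score moderate/strong in classical cases and null/weak
    in basal cases, and vice versa; no stromal expression by default.
    Columns: marker, case_id, subtype, intensity, stromal_expression,
    pct_positive, hscore.
    """
    rng = np.random.default_rng(seed)
    from .config import CLASSICAL_MARKERS
    rows = []
    for marker in markers:
        is_classical_marker = marker in CLASSICAL_MARKERS
        for subtype, n in (("classical", n_classical), ("basal", n_basal)):
            concordant = (subtype == "classical") == is_classical_marker
            for i in range(n):
                if concordant:
                    intensity = int(rng.choice([1, 2, 3], p=[0.2, 0.4, 0.4]))
                else:
                    intensity = int(rng.choice([0, 1], p=[0.8, 0.2]))
                pct = int(rng.integers(40, 101)) if intensity else 0
                rows.append({
                    "marker": marker,
                    "case_id": f"{subtype[:1]}{i:02d}",
                    "subtype": subtype,
                    "intensity": intensity,
                    "stromal_expression": False,
                    "pct_positive": pct,
                    "hscore": intensity * pct,
                })
    return pd.DataFrame(rows)
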