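"""Tile cutting, per-tile marker quantification, tile filtering, H-scores.

Annotated tumor regions are cut into fixed-size square tiles (200 μm by
default) on an axis-aligned grid anchored at the annotation bounding box.
Each tile records the fraction of its area inside the annotation; tiles not
fully inside are flagged truncated. Per tile and channel, the proportion of
positive pixels is computed over the tile∩annotation area, so boundary
tiles are unbiased if retained under a relaxed truncation threshold.

The tumor-tile filter is the published two-step rule: drop truncated tiles,
then keep tiles with strictly more than 10% PanCK-positive pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry

from .config import ALL_MARKERS, AnalysisConfig, PANCK, validate_markers
from .synthetic import SlideStack, rasterize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Tile:
    """One grid tile; bbox is 0-based half-open [x0,x1)×[y0,y1) in pixels."""

    tumor_id: str
    slide_id: str
    row: int
    col: int
    x0: int
    y0: int
    x1: int
    y1: int
    inside_fraction: float
    truncated: bool

    @property
    def tile_id(self) -> str:
        return f"{self.tumor_id}_{self.slide_id}_r{self.row}_c{self.col}"

    @property
    def side(self) -> int:
        return self.x1 - self.x0

    def geometry(self) -> BaseGeometry:
        return shapely_box(self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True)
class HScore:
    """IHC H-score: intensity class (0–3) × percent positive cells (0–100)."""

    intensity: int
    pct_positive: float

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity must be in {{0,1,2,3}}, got {self.intensity}")
        if not 0.0 <= self.pct_positive <= 100.0:
            raise ValueError(f"pct_positive must lie in [0, 100], got {self.pct_positive}")

    @property
    def value(self) -> float:
        return self.intensity * self.pct_positive


def compute_hscore(intensity: int, pct_positive: float) -> HScore:
    """H-score of one stain: intensity (0 null, 1 weak, 2 moderate,
    3 strong) times percent positive tumor cells, giving 0–300."""
    return HScore(intensity, pct_positive)


def cut_tiles(annotation: BaseGeometry, canvas_shape: tuple[int, int],
              cfg: AnalysisConfig, tumor_id: str = "tumor",
              slide_id: str = "stack") -> list[Tile]:
    """Cut the annotation into an axis-aligned grid of square tiles.

    The grid is anchored at the annotation bounding-box origin (floored to
    integer pixels); tile side = round(tile_size_um / mpp). Every tile with
    non-zero intersection is emitted, carrying its inside-annotation area
    fraction; tiles below `cfg.truncation_min_inside` are flagged truncated.
    """
    if annotation is None or annotation.is_empty or annotation.area == 0:
        raise ValueError("annotation is empty")
    side = cfg.tile_size_px
    if side < 1:
        raise ValueError("tile size below one pixel at this resolution")
    h, w = canvas_shape
    bx0, by0, bx1, by1 = annotation.bounds
    if bx0 < 0 or by0 < 0 or bx1 > w or by1 > h:
        raise ValueError("annotation extends outside the canvas")
    ox, oy = int(np.floor(bx0)), int(np.floor(by0))
    n_cols = int(np.ceil((bx1 - ox) / side))
    n_rows = int(np.ceil((by1 - oy) / side))
    area = float(side * side)
    tiles: list[Tile] = []
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = ox + c * side, oy + r * side
            tile_geom = shapely_box(x0, y0, x0 + side, y0 + side)
            inter = annotation.intersection(tile_geom).area
            if inter <= 0:
                continue
            frac = min(inter / area, 1.0)
            tiles.append(Tile(tumor_id, slide_id, r, c, x0, y0,
                              x0 + side, y0 + side, frac,
                              frac < cfg.truncation_min_inside - 1e-9))
    logger.info("cut %d tiles (%d truncated) from annotation",
                len(tiles), sum(t.truncated for t in tiles))
    return tiles


def quantify_tiles(tiles: Sequence[Tile], stack: SlideStack,
                   markers: Sequence[str] = ALL_MARKERS) -> pd.DataFrame:
    """Positive-pixel proportion per tile and channel.

    The denominator is the pixel count of tile∩annotation (pixel centers
    inside the annotation); the numerator is the positive pixels of the
    channel mask within that same region.
    """
    if not tiles:
        raise ValueError("no tiles to quantify")
    missing = [m for m in markers if m not in stack.channels]
    if missing:
        raise ValueError(f"stack is missing channel(s): {', '.join(missing)}")
    stack.validate()
    h, w = stack.shape
    ann_mask = rasterize(stack.annotation, (h, w))

    records = []
    for t in tiles:
        if t.x0 < 0 or t.y0 < 0 or t.x1 > w or t.y1 > h:
            raise ValueError(f"tile {t.tile_id} outside canvas")
        sub_ann = ann_mask[t.y0:t.y1, t.x0:t.x1]
        denom = int(sub_ann.sum())
        rec = {"tile_id": t.tile_id, **asdict(t)}
        for m in markers:
            sub = stack.channels[m][t.y0:t.y1, t.x0:t.x1]
            rec[m] = float((sub & sub_ann).sum() / denom) if denom else 0.0
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    return table


def filter_tiles(table: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Two-step tumor-tile filter: keep nontruncated tiles, then tiles with
    strictly more than `cfg.panck_min` PanCK-positive proportion."""
    validate_markers(table.columns)
    n0 = len(table)
    step1 = table[~table["truncated"].astype(bool)]
    step2 = step1[step1[PANCK] > cfg.panck_min]
    logger.info("tile filter: %d total -> %d nontruncated -> %d tumor tiles "
                "(PanCK > %.0f%%)", n0, len(step1), len(step2),
                100 * cfg.panck_min)
    return step2.copy()


def tiles_to_frame(tiles: Sequence[Tile]) -> pd.DataFrame:
    rows = [{"tile_id": t.tile_id, **asdict(t)} for t in tiles]
    return pd.DataFrame(rows)
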