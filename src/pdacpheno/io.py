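"""Readers/writers for the formats the pipeline touches.

CSV is the canonical tabular interchange, JSON carries models/manifests/
transforms, single-channel 8-bit TIFF or PNG carries masks, and annotations
travel as QuPath-style GeoJSON (FeatureCollection of Polygon/MultiPolygon
in pixel coordinates, holes honored).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.validation import make_valid

from .config import ALL_MARKERS
from .registration import RigidTransform
from .synthetic import GroundTruth, SlideStack, TILE_META_COLUMNS

TILE_TABLE_COLUMNS = list(TILE_META_COLUMNS) + list(ALL_MARKERS)


# ---------------------------------------------------------------- annotations

def read_annotation(path: str | Path, strict: bool = True) -> BaseGeometry:
    """Read a GeoJSON FeatureCollection of polygons into one geometry.

    Polygon and MultiPolygon features (optionally wrapped in QuPath-style
    Feature objects) are unioned; holes are honored. Invalid rings raise
    under `strict`, otherwise they are repaired with make_valid.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed GeoJSON in {path}: {e}") from e
    if doc.get("type") == "FeatureCollection":
        feats = doc.get("features", [])
        geoms_json = [f.get("geometry") for f in feats]
    elif doc.get("type") == "Feature":
        geoms_json = [doc.get("geometry")]
    else:
        geoms_json = [doc]
    geoms = []
    for g in geoms_json:
        if g is None:
            continue
        if g.get("type") not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"non-polygon geometry of type {g.get('type')!r}")
        geom = shape(g)
        if not geom.is_valid:
            if strict:
                raise ValueError("invalid polygon ring (re-read with "
                                 "strict=False to repair)")
            geom = make_valid(geom)
        geoms.append(geom)
    if not geoms:
        raise ValueError(f"no polygon annotations in {path}")
    return unary_union(geoms)


def write_annotation(geom: BaseGeometry, path: str | Path) -> None:
    doc = {"type": "FeatureCollection",
           "features": [{"type": "Feature", "properties": {},
                         "geometry": mapping(geom)}]}
    Path(path).write_text(json.dumps(doc) + "\n")


# ---------------------------------------------------------------- tile tables

def write_tile_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a TileTable CSV (proportions at 12 significant digits)."""
    missing = [c for c in TILE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"tile table missing column(s): {', '.join(missing)}")
    table[TILE_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_tile_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TILE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"tile table missing column(s): {', '.join(missing)}")
    if table["tile_id"].duplicated().any():
        dup = table.loc[table["tile_id"].duplicated(), "tile_id"].iloc[0]
        raise ValueError(f"duplicate tile id {dup!r}")
    table["truncated"] = table["truncated"].astype(bool)
    return table


# --------------------------------------------------------------------- masks

def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Binary mask as single-channel 8-bit TIFF or PNG (0 / 255)."""
    path = Path(path)
    arr = (np.asarray(mask, bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        Image.fromarray(arr, mode="L").save(path)
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")
    if arr.ndim != 2:
        raise ValueError("mask must be single-channel")
    return arr > 127


# ------------------------------------------------------------------ transforms

def write_transforms(transforms: dict[str, RigidTransform],
                     path: str | Path) -> None:
    doc = {s: {"dx": t.dx, "dy": t.dy, "theta": t.theta}
           for s, t in sorted(transforms.items())}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_transforms(path: str | Path) -> dict[str, RigidTransform]:
    doc = json.loads(Path(path).read_text())
    return {s: RigidTransform(d["dx"], d["dy"], d.get("theta", 0.0))
            for s, d in doc.items()}


# ----------------------------------------------------------------- slide stacks

def write_slide_stack(stack: SlideStack, outdir: str | Path,
                      fmt: str = "tif") -> None:
    """Persist a SlideStack as a directory: one TIFF/PNG per channel and
    per-slide tissue mask, annotation GeoJSON, JSON metadata, and — for
    synthetic stacks — a ground-truth sidecar."""
    out = Path(outdir)
    (out / "channels").mkdir(parents=True, exist_ok=True)
    (out / "tissue").mkdir(exist_ok=True)
    for name, mask in stack.channels.items():
        write_mask(mask, out / "channels" / f"{name}.{fmt}")
    for s, mask in stack.tissue.items():
        write_mask(mask, out / "tissue" / f"{s}.{fmt}")
    write_annotation(stack.annotation, out / "annotation.geojson")
    meta = {"mpp": stack.mpp, "channel_slide": stack.channel_slide,
            "format": fmt}
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    gt = stack.ground_truth
    if gt is not None and gt.transforms is not None:
        sidecar = {
            "transforms": {s: {"dx": t.dx, "dy": t.dy, "theta": t.theta}
                           for s, t in sorted(gt.transforms.items())},
            "region_phenotypes": gt.region_phenotypes,
        }
        (out / "ground_truth.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_slide_stack(indir: str | Path) -> SlideStack:
    out = Path(indir)
    meta = json.loads((out / "meta.json").read_text())
    fmt = meta.get("format", "tif")
    channel_slide = meta["channel_slide"]
    channels = {name: read_mask(out / "channels" / f"{name}.{fmt}")
                for name in channel_slide}
    tissue = {s: read_mask(out / "tissue" / f"{s}.{fmt}")
              for s in sorted(set(channel_slide.values()))}
    annotation = read_annotation(out / "annotation.geojson")
    gt = None
    gt_path = out / "ground_truth.json"
    if gt_path.exists():
        doc = json.loads(gt_path.read_text())
        gt = GroundTruth(
            transforms={s: RigidTransform(d["dx"], d["dy"], d.get("theta", 0.0))
                        for s, d in doc.get("transforms", {}).items()},
            region_phenotypes=doc.get("region_phenotypes"),
        )
    return SlideStack(channels, channel_slide, tissue, annotation,
                      float(meta["mpp"]), gt)


# ------------------------------------------------------------------- manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    stage: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, stage: str, seed: int, config: dict,
               input_paths: list[str | Path] = ()) -> "RunManifest":
        from . import __version__
        inputs = {}
        for p in input_paths:
            p = Path(p)
            if p.is_file():
                inputs[str(p)] = _sha256(p)
            elif p.is_dir():
                for f in sorted(p.rglob("*")):
                    if f.is_file():
                        inputs[str(f)] = _sha256(f)
        return cls(stage=stage, seed=seed, config=config, inputs=inputs,
                   version=__version__,
                   timestamp=datetime.now(timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        doc = {"stage": self.stage, "seed": self.seed, "config": self.config,
               "inputs": self.inputs, "version": self.version,
               "timestamp": self.timestamp}
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                         default=str) + "\n")
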