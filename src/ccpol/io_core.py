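"""Shared I/O: TIFF/CSV readers and writers, run configuration, provenance.

All physical quantities carry explicit units in column names
(distance_um, force_pN, work_fJ, ...).  Coordinates are image-frame
micrometers: origin top-left, y increasing downward.  Every analysis
output directory gets a JSON snapshot of the configuration and package
version used, so a run is reproducible from its outputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ccpol")

__all__ = ["RunConfig", "read_image", "write_results", "read_centroid_table",
           "read_edge_polyline"]


@dataclass
class RunConfig:
    """Stage parameters, paths and unit metadata for one analysis run."""

    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    bin_width_um: float = 50.0
    merge_window_frames: int = 3
    coloc_denominator: str = "query"
    cadherin_threshold_pN: float = 150.0
    follower_rows: tuple[int, int] = (2, 5)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["follower_rows"] = list(d["follower_rows"])
        return d

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["follower_rows"] = tuple(d.get("follower_rows", (2, 5)))
        return cls(**d)


def read_image(path, channel_map: dict | None = None,
               pixel_size_um: float | None = None):
    """Read a TIFF; returns (channels, pixel_size_um).

    ``channel_map`` names planes of a multi-channel stack by role, e.g.
    {1: 'nucleus', 2: 'golgi'} (1-based plane indices); without it a single
    2D array is returned under the role 'image'.  Pixel size comes from
    TIFF resolution metadata unless overridden; if neither is available an
    error names the config key to set.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta_px = None
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and res.value[0] > 0:
            num, den = res.value
            px_per_unit = num / den
            unit_um = {2: 25400.0, 3: 10000.0}.get(
                getattr(unit.value, "value", unit.value) if unit else 2)
            if unit_um and px_per_unit > 0:
                meta_px = unit_um / px_per_unit
    if pixel_size_um is not None:
        if meta_px is not None and not np.isclose(meta_px, pixel_size_um, rtol=0.05):
            logger.info("pixel size override %.4g um/px (metadata said %.4g)",
                        pixel_size_um, meta_px)
        px = pixel_size_um
    elif meta_px is not None:
        px = meta_px
    else:
        raise ValueError("pixel size unknown: set RunConfig.pixel_size_um")

    if channel_map:
        if arr.ndim != 3:
            raise ValueError("channel_map given but image is not a stack")
        channels = {role: arr[int(idx) - 1] for idx, role in channel_map.items()}
    else:
        channels = {"image": arr}
    return channels, float(px)


def read_centroid_table(path) -> pd.DataFrame:
    """Read a cells CSV with columns cell_id, nx_um, ny_um, gx_um, gy_um."""
    df = pd.read_csv(path)
    required = {"cell_id", "nx_um", "ny_um"}
    if not required <= set(df.columns):
        raise ValueError(f"centroid table must have columns {sorted(required)}")
    return df


def read_edge_polyline(path) -> np.ndarray:
    """Read an edge polyline CSV with columns x_um, y_um."""
    df = pd.read_csv(path)
    return df[["x_um", "y_um"]].to_numpy(float)


def write_results(tables: dict[str, pd.DataFrame], summary: dict, out_dir,
                  config: RunConfig | None = None, prefix: str = "") -> list[Path]:
    """Write CSV tables + JSON summary + config snapshot; returns the paths.

    File names are namespaced by ``prefix`` so two stages can share one
    directory without clobbering.  Column order is preserved as given, so
    reruns with the same config are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tag = f"{prefix}_" if prefix else ""
    for name, df in tables.items():
        p = out / f"{tag}{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    from . import __version__
    payload = {"summary": summary, "package_version": __version__}
    if config is not None:
        payload["config"] = config.to_dict()
    p = out / f"{tag}summary.json"
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
    written.append(p)
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
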