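"""Readers, writers and run configuration.

Rasters travel as single-band ESRI ASCII grids of integer codes (a plain-text
header of ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value followed by
the rows); all tables are UTF-8 CSV with a header row and '.' decimals.  The
run configuration is a flat YAML mapping validated before any computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .landscape import LandscapeGrid, Legend

log = logging.getLogger(__name__)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class InputError(ValueError):
    """Invalid input file or configuration (exit code 1 territory)."""


def read_ascii_grid(path, legend: Legend | None = None,
                    ecoregion_id=None) -> LandscapeGrid:
    """Read an ESRI ASCII grid of integer land-cover codes.

    The cell size comes from the header (cells are square by format).  When a
    legend is given, every non-nodata code is validated against it and
    offending codes are reported.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raise InputError(
            "GeoTIFF input is not supported in this build; convert the raster "
            "to an ESRI ASCII grid (.asc)"
        )
    header: dict[str, float] = {}
    nodata = -9999
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                key = parts[0].lower()
                if key == "nodata_value":
                    nodata = int(float(parts[1]))
                else:
                    header[key] = float(parts[1])
            else:
                fh.seek(pos)
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise InputError(f"{path}: missing header keys {missing}")
        data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise InputError(
            f"{path}: data shape {data.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    grid = LandscapeGrid(
        data, cell_size=header["cellsize"],
        ecoregion_id=ecoregion_id if ecoregion_id is not None else path.stem,
        nodata_code=nodata,
    )
    if legend is not None:
        grid.validate_against(legend)
    return grid


def write_ascii_grid(grid: LandscapeGrid, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {grid.cell_size:g}\n")
        fh.write(f"NODATA_value {grid.nodata_code}\n")
        for row in grid.codes:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def write_cf_table(frame: pd.DataFrame, path) -> None:
    """Schema-stable CF CSV, sorted by the full record key."""
    keys = [k for k in ("ecoregion", "country", "group", "land_use", "intensity",
                        "approach", "extent", "kind") if k in frame.columns]
    frame.sort_values(keys).to_csv(path, index=False, float_format="%.12g")


VARIANT_CHOICES = ("default", "no_intensity", "no_fragmentation", "rr_lo", "rr_hi")


@dataclass
class RunConfig:
    """Validated run configuration for the pipeline commands."""

    landscape_dir: Path
    legend: Path
    rr: Path
    z: Path
    dispersal: Path
    gep: Path
    regen: Path
    ecoregion_biome: Path
    output_dir: Path
    suitability: Path | None = None
    s_total: Path | None = None
    overlaps: Path | None = None
    centroids: Path | None = None
    variant: str = "default"
    groups: list[str] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        kwargs = {}
        for name, value in raw.items():
            if name not in cls.__dataclass_fields__:
                raise InputError(f"unknown config key {name!r}")
            f = cls.__dataclass_fields__[name]
            if "Path" in str(f.type) and value is not None:
                value = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
            kwargs[name] = value
        try:
            cfg = cls(**kwargs)
        except TypeError as err:
            raise InputError(f"config incomplete: {err}") from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.variant not in VARIANT_CHOICES:
            raise InputError(
                f"variant {self.variant!r} not one of {VARIANT_CHOICES}"
            )
        for name in ("landscape_dir", "legend", "rr", "z", "dispersal", "gep",
                     "regen", "ecoregion_biome"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise InputError(f"required input {name} missing: {p}")
        for name in ("suitability", "s_total", "overlaps", "centroids"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InputError(f"configured input {name} does not exist: {p}")


def load_bundle(cfg: RunConfig):
    """Load all inputs of a run; validation happens before any computation."""
    from .params import ParamSet
    from .synth import VERTEBRATE_GROUPS

    legend = Legend.read_csv(cfg.legend)
    grids = {}
    for asc in sorted(Path(cfg.landscape_dir).glob("*.asc")):
        g = read_ascii_grid(asc, legend)
        grids[g.ecoregion_id] = g
    if not grids:
        raise InputError(f"no .asc rasters found in {cfg.landscape_dir}")
    rr = pd.read_csv(cfg.rr)
    params = ParamSet(
        rr=rr,
        z=pd.read_csv(cfg.z),
        dispersal=pd.read_csv(cfg.dispersal),
        gep=pd.read_csv(cfg.gep),
        regen=pd.read_csv(cfg.regen),
        ecoregion_biome=pd.read_csv(cfg.ecoregion_biome),
        suitability=pd.read_csv(cfg.suitability) if cfg.suitability else None,
        s_total=pd.read_csv(cfg.s_total) if cfg.s_total else None,
        vertebrate_groups=tuple(
            g for g in rr["group"].unique() if g in VERTEBRATE_GROUPS
        ),
    )
    return grids, legend, params


def write_world(world, out_dir) -> Path:
    """Emit a synthetic world as a self-contained input bundle + config."""
    out = Path(out_dir)
    (out / "landscapes").mkdir(parents=True, exist_ok=True)
    for eco, grid in world.grids.items():
        write_ascii_grid(grid, out / "landscapes" / f"{eco}.asc")
    world.legend.table.to_csv(out / "legend.csv", index=False)
    p = world.params
    p.rr.to_csv(out / "rr.csv", index=False)
    p.z.to_csv(out / "z.csv", index=False)
    p.dispersal.to_csv(out / "dispersal.csv", index=False)
    p.gep.to_csv(out / "gep.csv", index=False)
    p.regen.to_csv(out / "regen.csv", index=False)
    p.ecoregion_biome.to_csv(out / "ecoregion_biome.csv", index=False)
    cfg = {
        "landscape_dir": "landscapes", "legend": "legend.csv", "rr": "rr.csv",
        "z": "z.csv", "dispersal": "dispersal.csv", "gep": "gep.csv",
        "regen": "regen.csv", "ecoregion_biome": "ecoregion_biome.csv",
        "output_dir": "out", "seed": world.spec.seed,
    }
    if p.suitability is not None:
        p.suitability.to_csv(out / "suitability.csv", index=False)
        p.s_total.to_csv(out / "s_total.csv", index=False)
        cfg["suitability"] = "suitability.csv"
        cfg["s_total"] = "s_total.csv"
    world.overlaps.to_csv(out / "overlaps.csv", index=False)
    world.centroids.to_csv(out / "centroids.csv", index=False)
    cfg["overlaps"] = "overlaps.csv"
    cfg["centroids"] = "centroids.csv"
    world.ecoregion_areas().to_csv(out / "ecoregion_areas.csv", index=False)
    world.landuse_areas().to_csv(out / "landuse_areas.csv", index=False)
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
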