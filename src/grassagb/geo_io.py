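"""Raster and tabular I/O for the biomass-mapping pipeline.

Rasters travel as :class:`Raster` (single- or multi-band numpy array plus
:class:`RasterMeta`).  On disk, pixel data go to TIFF via :mod:`tifffile`
and the georeferencing (geotransform, CRS tag, nodata, band names,
wavelengths, units) to a JSON sidecar ``<path>.aux.json``.  Hyperspectral
cubes may alternatively be stored ENVI-style: a raw band-sequential
float32 file next to a plain-text ``.hdr`` carrying the wavelength list.

Coordinate convention, fixed repo-wide: pixel-centre coordinates, 0-based
indices, x increasing east with column, y increasing north (so y decreases
with row index).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "RasterMeta",
    "Raster",
    "PlotSample",
    "read_raster",
    "write_raster",
    "read_cube",
    "write_cube",
    "read_plots",
    "write_plots",
    "make_provenance",
]

log = logging.getLogger("grassagb")

TOOL_VERSION = "0.1.0"

VALID_UNITS = ("reflectance", "m2/m2", "g/m2", "label")


def make_provenance(config=None, seed=None) -> dict:
    """Provenance record embedded by every writer: tool version, a stable
    hash of the generating configuration, and the seed used."""
    blob = json.dumps(config, sort_keys=True, default=str) if config is not None else ""
    return {
        "tool": "grassagb",
        "version": TOOL_VERSION,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": seed,
    }


@dataclass
class RasterMeta:
    """Georeferencing and semantics of a raster.

    ``origin_x``/``origin_y`` locate the *centre* of pixel (row 0, col 0);
    ``pixel_x``/``pixel_y`` are positive pixel sizes in map units, x east,
    y north (row index increases southwards).
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_x: float = 1.0
    pixel_y: float = 1.0
    crs: str = "local"
    nodata: float = float("nan")
    band_names: tuple = ()
    wavelengths_nm: tuple = ()
    units: str = "reflectance"

    def __post_init__(self):
        if self.pixel_x == 0 or self.pixel_y == 0:
            raise ValueError("pixel sizes must be nonzero")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        names = tuple(self.band_names)
        if len(names) != len(set(names)):
            raise ValueError("band names must be unique")
        object.__setattr__(self, "band_names", names)
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))

    def colrow_to_xy(self, col, row):
        return (self.origin_x + np.asarray(col) * self.pixel_x,
                self.origin_y - np.asarray(row) * self.pixel_y)

    def xy_to_colrow(self, x, y):
        """Continuous (fractional) pixel coordinates of map points."""
        return ((np.asarray(x) - self.origin_x) / self.pixel_x,
                (self.origin_y - np.asarray(y)) / self.pixel_y)

    def coarsened(self, factor: int) -> "RasterMeta":
        """Metadata of the block-aggregated raster: the coarse (0,0) centre
        sits at the centroid of the first factor×factor fine block."""
        half = (factor - 1) / 2.0
        return RasterMeta(
            origin_x=self.origin_x + half * self.pixel_x,
            origin_y=self.origin_y - half * self.pixel_y,
            pixel_x=self.pixel_x * factor,
            pixel_y=self.pixel_y * factor,
            crs=self.crs,
            nodata=self.nodata,
            band_names=self.band_names,
            wavelengths_nm=self.wavelengths_nm,
            units=self.units,
        )


@dataclass
class Raster:
    """In-memory raster: ``data`` is (rows, cols) or (bands, rows, cols)."""

    data: np.ndarray
    meta: RasterMeta = field(default_factory=RasterMeta)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D or 3-D")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_bands(self):
        return 1 if self.data.ndim == 2 else self.data.shape[0]


@dataclass(frozen=True)
class PlotSample:
    """Elemental sampling unit: a square ground plot with harvested AGB and
    optically measured LAI (map coordinates of the plot centre)."""

    plot_id: str
    x: float
    y: float
    agb_g_m2: float
    lai: float
    esu_m: float = 1.0

    def __post_init__(self):
        if self.agb_g_m2 < 0:
            raise ValueError(f"plot {self.plot_id}: AGB must be >= 0")
        if self.lai < 0:
            raise ValueError(f"plot {self.plot_id}: LAI must be >= 0")


# ---------------------------------------------------------------------------
# raster read/write (TIFF + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path) -> Path:
    return Path(str(path) + ".aux.json")


def write_raster(path, raster: Raster, provenance: dict | None = None) -> None:
    path = Path(path)
    kw = {"photometric": "minisblack"} if raster.data.ndim == 3 else {}
    tifffile.imwrite(path, np.ascontiguousarray(raster.data), **kw)
    meta = asdict(raster.meta)
    meta["nodata"] = None if np.isnan(raster.meta.nodata) else raster.meta.nodata
    payload = {"meta": meta, "provenance": provenance or raster.provenance or make_provenance()}
    _sidecar(path).write_text(json.dumps(payload, indent=1))


def read_raster(path) -> Raster:
    path = Path(path)
    data = tifffile.imread(path)
    side = _sidecar(path)
    provenance: dict = {}
    if side.exists():
        payload = json.loads(side.read_text())
        m = payload.get("meta", {})
        if m.get("nodata") is None:
            m["nodata"] = float("nan")
        m["band_names"] = tuple(m.get("band_names", ()))
        m["wavelengths_nm"] = tuple(m.get("wavelengths_nm", ()))
        meta = RasterMeta(**m)
        provenance = payload.get("provenance", {})
    else:
        meta = RasterMeta()
        log.warning("raster %s has no sidecar; default metadata and nodata=NaN substituted", path)
    return Raster(np.asarray(data), meta, provenance)


# ---------------------------------------------------------------------------
# hyperspectral cube read/write
# ---------------------------------------------------------------------------

def write_cube(path, cube: Raster, provenance: dict | None = None) -> None:
    """Write a reflectance cube.  ``.tif`` → multiband TIFF + sidecar;
    anything else → ENVI-style raw BSQ float32 with a text ``.hdr``."""
    if cube.data.ndim != 3:
        raise ValueError("cube must be 3-D (bands, rows, cols)")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        write_raster(path, cube, provenance)
        return
    nb, nr, nc = cube.data.shape
    np.ascontiguousarray(cube.data, dtype=np.float32).tofile(path)
    m = cube.meta
    prov = provenance or cube.provenance or make_provenance()
    wl = ", ".join(f"{w:.3f}" for w in m.wavelengths_nm)
    hdr = "\n".join([
        "ENVI",
        "; written by grassagb " + TOOL_VERSION,
        f"; provenance = {json.dumps(prov)}",
        f"samples = {nc}",
        f"lines = {nr}",
        f"bands = {nb}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        f"map info = {{local, 1.0, 1.0, {m.origin_x}, {m.origin_y}, {m.pixel_x}, {m.pixel_y}, {m.crs}}}",
        f"data ignore value = {m.nodata}",
        f"wavelength units = Nanometers",
        "wavelength = { " + wl + " }",
        "",
    ])
    Path(str(path) + ".hdr").write_text(hdr)


def _parse_envi_header(text: str) -> dict:
    out: dict = {}
    body = text
    # collapse { ... } blocks onto one line
    pos = 0
    while (i := body.find("{", pos)) != -1:
        j = body.find("}", i)
        if j == -1:
            break
        body = body[:i] + body[i:j + 1].replace("\n", " ") + body[j + 1:]
        pos = j + 1
    for line in body.splitlines():
        line = line.strip()
        if line.startswith(";") and "provenance =" in line:
            out["provenance"] = json.loads(line.split("provenance =", 1)[1])
            continue
        if "=" not in line or line.startswith(";"):
            continue
        key, val = (s.strip() for s in line.split("=", 1))
        out[key.lower()] = val.strip("{} ")
    return out


def read_cube(path) -> Raster:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        cube = read_raster(path)
        if cube.data.ndim != 3:
            raise ValueError(f"{path} is not a multiband cube")
        if not cube.meta.wavelengths_nm:
            raise ValueError(f"{path}: hyperspectral cube lacks wavelength metadata")
        return cube
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    h = _parse_envi_header(hdr_path.read_text())
    nb, nr, nc = int(h["bands"]), int(h["lines"]), int(h["samples"])
    if "wavelength" not in h:
        raise ValueError(f"{path}: hyperspectral cube lacks wavelength metadata")
    wl = tuple(float(w) for w in h["wavelength"].split(","))
    data = np.fromfile(path, dtype=np.float32).reshape(nb, nr, nc)
    mi = [s.strip() for s in h.get("map info", "").split(",")]
    if len(mi) >= 7:
        origin_x, origin_y, px, py = float(mi[3]), float(mi[4]), float(mi[5]), float(mi[6])
        crs = mi[7] if len(mi) > 7 else "local"
    else:
        origin_x = origin_y = 0.0
        px = py = 1.0
        crs = "local"
    if "data ignore value" in h:
        nodata = float(h["data ignore value"])
    else:
        nodata = float("nan")
        log.warning("cube %s lacks a nodata value; NaN substituted", path)
    meta = RasterMeta(origin_x, origin_y, px, py, crs=crs, nodata=nodata,
                      wavelengths_nm=wl, units="reflectance")
    return Raster(data, meta, h.get("provenance", {}))


# ---------------------------------------------------------------------------
# plot tables
# ---------------------------------------------------------------------------

PLOT_COLUMNS = ("plot_id", "x", "y", "agb_g_m2", "lai")


def read_plots(path) -> list[PlotSample]:
    """Read a CSV plot table (columns plot_id, x, y, agb_g_m2, lai and an
    optional esu_m), validating each row."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        for required in PLOT_COLUMNS:
            if required not in cols:
                raise ValueError(f"plot table {path} is missing column {required!r}")
        plots: list[PlotSample] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            pid = row["plot_id"].strip()
            if pid in seen:
                raise ValueError(f"{path} row {i}: duplicate plot_id {pid!r}")
            seen.add(pid)
            try:
                plots.append(PlotSample(
                    plot_id=pid,
                    x=float(row["x"]), y=float(row["y"]),
                    agb_g_m2=float(row["agb_g_m2"]), lai=float(row["lai"]),
                    esu_m=float(row.get("esu_m") or 1.0),
                ))
            except ValueError as exc:
                raise ValueError(f"{path} row {i}: {exc}") from exc
    return plots


def write_plots(path, plots, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLOT_COLUMNS + ("esu_m",))
        for p in plots:
            writer.writerow([p.plot_id, p.x, p.y, p.agb_g_m2, p.lai, p.esu_m])
    if provenance is not None:
        _sidecar(path).write_text(json.dumps({"provenance": provenance}, indent=1))
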