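"""File formats: single-band GeoTIFF rasters and the NetCDF LAI-cube stack.

GeoTIFFs are written through :mod:`tifffile` with explicit GeoTIFF tags
(ModelPixelScale, ModelTiepoint, a minimal GeoKeyDirectory carrying the EPSG
code) plus the GDAL nodata tag, so the files are georeferenced and readable
by standard GIS stacks. The LAI cube is stored as a single NetCDF (classic
format, written via xarray's scipy backend) with the grid parameters as
global attributes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from .core import CropMask, GridSpec, LaiCube

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113


def _geotiff_extratags(grid: GridSpec, nodata) -> list[tuple]:
    # GeoKeyDirectory: version 1.1.0; ModelTypeProjected, RasterPixelIsArea,
    # and the projected CRS EPSG code.
    keys = (
        1, 1, 0, 3,
        1024, 0, 1, 1,
        1025, 0, 1, 1,
        3072, 0, 1, int(grid.epsg),
    )
    tags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(grid.pixel_size), float(grid.pixel_size), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.x_origin), float(grid.y_origin), 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(keys), keys),
    ]
    if nodata is not None:
        nod = str(int(nodata)) if float(nodata).is_integer() else str(float(nodata))
        tags.append((_GDAL_NODATA, "s", 0, nod))
    return tags


def write_geotiff(path, array: np.ndarray, grid: GridSpec, nodata=None) -> Path:
    """Write a single-band georeferenced GeoTIFF."""
    path = Path(path)
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, array, extratags=_geotiff_extratags(grid, nodata))
    return path


def read_geotiff(path) -> tuple[np.ndarray, GridSpec, float | None]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`.

    Returns (array, grid, nodata); nodata is None when the tag is absent.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        array = page.asarray()
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_MODEL_TIEPOINT].value
        geokeys = tags[_GEO_KEY_DIRECTORY].value
        nodata_tag = tags.get(_GDAL_NODATA)
    epsg = 0
    keys = np.asarray(geokeys).reshape(-1, 4)
    for key_id, _, _, value in keys[1:]:
        if key_id == 3072:
            epsg = int(value)
    grid = GridSpec(
        n_rows=array.shape[0],
        n_cols=array.shape[1],
        x_origin=float(tiepoint[3]),
        y_origin=float(tiepoint[4]),
        pixel_size=float(scale[0]),
        epsg=epsg,
    )
    nodata = float(nodata_tag.value) if nodata_tag is not None else None
    return array, grid, nodata


# ---------------------------------------------------------------------------
# LAI cube stack
# ---------------------------------------------------------------------------


def cube_to_dataset(cube: LaiCube) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "lai": (("year", "composite", "y", "x"), cube.values.astype(np.float64)),
            "valid": (("year", "composite", "y", "x"), cube.valid.astype(np.int8)),
        },
        coords={
            "year": np.asarray(cube.years, dtype=np.int32),
            "composite": np.asarray(cube.composite_doys, dtype=np.int32),
        },
        attrs={
            "x_origin": float(cube.grid.x_origin),
            "y_origin": float(cube.grid.y_origin),
            "pixel_size": float(cube.grid.pixel_size),
            "epsg": np.int32(cube.grid.epsg),
        },
    )
    return ds


def write_cube(path, cube: LaiCube) -> Path:
    """Write the LAI cube as a classic-format NetCDF stack."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cube_to_dataset(cube).to_netcdf(path, engine="scipy")
    return path


def read_cube(path) -> LaiCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
        values = ds["lai"].values.astype(float)
        valid = ds["valid"].values.astype(bool)
        years = tuple(int(y) for y in ds["year"].values)
        doys = ds["composite"].values.astype(int)
        grid = GridSpec(
            n_rows=values.shape[2],
            n_cols=values.shape[3],
            x_origin=float(ds.attrs["x_origin"]),
            y_origin=float(ds.attrs["y_origin"]),
            pixel_size=float(ds.attrs["pixel_size"]),
            epsg=int(ds.attrs["epsg"]),
        )
    return LaiCube(values=values, valid=valid, years=years, composite_doys=doys, grid=grid)


# ---------------------------------------------------------------------------
# crop / region masks
# ---------------------------------------------------------------------------


def write_masks(out_dir, masks: CropMask) -> dict[str, Path]:
    """Write each crop mask and the region raster as GeoTIFFs.

    Returns the mapping of logical name -> path. The region raster carries
    0 (outside) as nodata; a sidecar CSV maps integer labels to region ids.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for crop, mask in masks.masks.items():
        paths[f"mask_{crop}"] = write_geotiff(
            out_dir / f"crop_mask_{crop}.tif", mask.astype(np.uint8), masks.grid, nodata=0
        )
    paths["regions"] = write_geotiff(
        out_dir / "regions.tif", masks.region_ids.astype(np.int16), masks.grid, nodata=0
    )
    import pandas as pd

    labels = pd.DataFrame(
        sorted(masks.region_names.items()), columns=["label", "region_id"]
    )
    label_path = out_dir / "region_labels.csv"
    labels.to_csv(label_path, index=False)
    paths["region_labels"] = label_path
    return paths


def read_masks(out_dir) -> CropMask:
    import pandas as pd

    out_dir = Path(out_dir)
    labels = pd.read_csv(out_dir / "region_labels.csv")
    region_array, grid, _ = read_geotiff(out_dir / "regions.tif")
    masks: dict[str, np.ndarray] = {}
    for path in sorted(out_dir.glob("crop_mask_*.tif")):
        crop = path.stem.replace("crop_mask_", "")
        arr, g, _ = read_geotiff(path)
        if not g.same_footprint(grid):
            raise ValueError(f"mask {path.name} grid differs from region raster")
        masks[crop] = arr.astype(bool)
    return CropMask(
        masks=masks,
        region_ids=region_array.astype(np.int16),
        region_names={int(r.label): str(r.region_id) for r in labels.itertuples()},
        grid=grid,
    )
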