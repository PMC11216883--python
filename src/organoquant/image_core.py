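"""Calibrated image I/O, projection, background and pixel-statistics primitives.

Every quantification assay in this package is composed from the operations
here: reading multi-channel confocal stacks, collapsing them to maximum
intensity projections, estimating a per-staining-set background as the mean
of per-image minima, rasterizing manually traced polygons, thresholding to
binary masks, connected-component labeling with area filtering, and masked
mean / integrated intensities.

Conventions
-----------
- Pixel coordinates are 0-based ``(y, x)`` raster order; polygon vertices are
  ``(x, y)`` in pixel units.  A pixel belongs to a polygon mask when its
  center lies inside or on the polygon boundary.
- Thresholding uses ``pixel >= threshold`` (ties in the foreground).
- Connected components use 8-connectivity, matching ImageJ particle analysis
  of contiguous structures.
- Background subtraction clips at zero; intensities are never negative.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon
from skimage import measure
from skimage.filters import threshold_otsu

from . import _imagej_roi

logger = logging.getLogger("organoquant")

PROVENANCE_ORDER = ("raw", "max_projection", "background_subtracted")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageStack:
    """A calibrated multi-channel (optionally z-resolved) pixel array.

    ``pixels`` is indexed ``(channel, z, y, x)``; a single-plane acquisition
    has a singleton z axis.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    image_id: str
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError("ImageStack pixels must be (channel, z, y, x)")
        if np.min(self.pixels) < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        names = tuple(self.channel_names)
        if len(names) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {self.pixels.shape[0]} channels"
            )
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        object.__setattr__(self, "channel_names", names)

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; stack has {self.channel_names}"
            ) from None


@dataclass(frozen=True)
class ImagePlane:
    """A single 2-D channel plane with its processing provenance."""

    pixels: np.ndarray
    channel_name: str
    pixel_size_um: float
    image_id: str
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("ImagePlane pixels must be 2-D")
        if self.provenance not in PROVENANCE_ORDER:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if np.min(self.pixels) < 0:
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class RegionOfInterest:
    """A simple closed polygon traced over an image, in pixel coordinates."""

    vertices: tuple[tuple[float, float], ...]
    label: str = "field"
    image_id: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)
        poly = self.polygon
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("ROI polygon is self-intersecting")
        if poly.area <= 0:
            raise ValueError("ROI polygon has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def area_px2(self) -> float:
        """Shoelace area in px^2."""
        return float(self.polygon.area)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean mask congruent with its source plane."""

    pixels: np.ndarray
    pixel_size_um: float
    origin: str = "threshold"
    meta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.dtype != bool:
            raise ValueError("BinaryMask pixels must be a 2-D boolean array")

    @property
    def area_um2(self) -> float:
        return float(np.count_nonzero(self.pixels)) * self.pixel_size_um**2

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels & other.pixels, self.pixel_size_um, "composition")

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.pixels, self.pixel_size_um, "composition")


@dataclass(frozen=True)
class LabeledRegions:
    """Connected components of a mask with a per-region area table."""

    label_image: np.ndarray
    regions: pd.DataFrame  # columns: label, area_px, area_um2, bbox..., centroid...
    pixel_size_um: float

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class BackgroundModel:
    """Per staining-set, per-channel background intensity.

    The background is the mean over all images of a set of each image's
    minimum pixel intensity; all conditions of a set were stained and
    imaged together, so one value serves the whole set.
    """

    set_id: str
    channel_name: str
    background_value: float

    def __post_init__(self) -> None:
        if self.background_value < 0:
            raise ValueError("background_value must be >= 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_channel_map(channel_map) -> tuple[str, ...]:
    if isinstance(channel_map, str):
        sep = ";" if ";" in channel_map else ","
        return tuple(s.strip() for s in channel_map.split(sep) if s.strip())
    return tuple(channel_map)


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        size = image["Pixels"].get("PhysicalSizeX")
        return float(size) if size is not None else None
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(path: str | Path, manifest_row: Mapping) -> ImageStack:
    """Read a multi-page/OME TIFF into a calibrated ``ImageStack``.

    The manifest row supplies the channel order (``channel_map``) and a
    fallback ``pixel_size_um``; a physical pixel size embedded in OME
    metadata takes precedence over the manifest value.
    """
    path = Path(path)
    channels = _parse_channel_map(manifest_row["channel_map"])
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_px = _ome_pixel_size(tif)

    # normalize to (C, Z, Y, X)
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if data.ndim == 2:
        data, axes = data[None, None], "CZYX"
    elif data.ndim == 3 and "C" in axes:
        data = np.moveaxis(data, axes.index("C"), 0)[:, None]
        axes = "CZYX"
    elif data.ndim == 3:
        data, axes = data[None], "CZYX"
    elif data.ndim == 4:
        order = [axes.index(a) for a in "CZYX"]
        data = np.transpose(data, order)
        axes = "CZYX"
    else:
        raise ValueError(f"cannot interpret TIFF axes {axes!r} in {path}")

    if data.shape[0] != len(channels):
        raise ValueError(
            f"{path}: manifest declares {len(channels)} channels but file has "
            f"{data.shape[0]}"
        )

    pixel_size = meta_px
    if pixel_size is None:
        raw = manifest_row.get("pixel_size_um")
        pixel_size = float(raw) if raw is not None and not pd.isna(raw) else None
    if pixel_size is None:
        raise ValueError(f"{path}: pixel size absent from both metadata and manifest")

    z_step = manifest_row.get("z_step_um")
    z_step = float(z_step) if z_step is not None and not pd.isna(z_step) else None
    return ImageStack(
        pixels=np.asarray(data),
        channel_names=channels,
        pixel_size_um=float(pixel_size),
        z_step_um=z_step,
        image_id=str(manifest_row.get("image_id", path.stem)),
    )


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an ``ImageStack`` as an OME-TIFF with its pixel size embedded."""
    # tifffile's OME writer rejects singleton axes; single-plane stacks are CYX
    pixels = stack.pixels
    axes = "CZYX"
    if pixels.shape[1] == 1:
        pixels, axes = pixels[:, 0], "CYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.z_step_um is not None:
        metadata["PhysicalSizeZ"] = stack.z_step_um
        metadata["PhysicalSizeZUnit"] = "µm"
    # explicit photometric stops tiny trailing axes being read as RGB samples
    tifffile.imwrite(path, pixels, ome=True, photometric="minisblack", metadata=metadata)


def _roi_from_vertices(vertices, label, day=None, image_id="") -> RegionOfInterest:
    return RegionOfInterest(
        vertices=tuple(vertices), label=label or "field", day=day, image_id=image_id
    )


def read_roi(path: str | Path) -> list[RegionOfInterest]:
    """Read polygon ROIs from an ImageJ ``.roi``/``.zip`` or a GeoJSON file.

    Non-polygon ROI types (lines, points) and self-intersecting polygons are
    rejected with ``ValueError``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".roi":
        name, verts = _imagej_roi.decode_roi_bytes(path.read_bytes())
        return [_roi_from_vertices(verts, name or path.stem)]
    if suffix == ".zip":
        rois = []
        with zipfile.ZipFile(path) as zf:
            for entry in sorted(zf.namelist()):
                if not entry.lower().endswith(".roi"):
                    continue
                name, verts = _imagej_roi.decode_roi_bytes(zf.read(entry))
                rois.append(_roi_from_vertices(verts, name or Path(entry).stem))
        return rois
    if suffix in {".json", ".geojson"}:
        collection = json.loads(path.read_text())
        if collection.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
        rois = []
        for feat in collection["features"]:
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Polygon":
                raise ValueError(
                    f"{path}: unsupported geometry {geom.get('type')!r}; "
                    "only Polygon features are accepted"
                )
            ring = geom["coordinates"][0]
            if len(ring) > 1 and tuple(ring[0]) == tuple(ring[-1]):
                ring = ring[:-1]
            props = feat.get("properties") or {}
            rois.append(
                _roi_from_vertices(
                    [tuple(p) for p in ring],
                    props.get("label") or props.get("name"),
                    day=props.get("day"),
                    image_id=props.get("image_id", ""),
                )
            )
        return rois
    raise ValueError(f"unsupported ROI file type: {path}")


def write_roi_geojson(path: str | Path, rois: Iterable[RegionOfInterest]) -> None:
    features = []
    for roi in rois:
        ring = [list(v) for v in roi.vertices] + [list(roi.vertices[0])]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "label": roi.label,
                    "day": roi.day,
                    "image_id": roi.image_id,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


# ---------------------------------------------------------------------------
# projection, background, masking
# ---------------------------------------------------------------------------


def max_project(stack: ImageStack, channel: str) -> ImagePlane:
    """Collapse one channel's z-stack to its maximum intensity projection."""
    idx = stack.channel_index(channel)
    return ImagePlane(
        pixels=np.max(stack.pixels[idx], axis=0),
        channel_name=channel,
        pixel_size_um=stack.pixel_size_um,
        image_id=stack.image_id,
        provenance="max_projection",
    )


def compute_set_background(
    planes: Sequence[ImagePlane], set_id: str
) -> BackgroundModel:
    """Background for a staining set: mean over images of each image's minimum."""
    if not planes:
        raise ValueError("cannot compute a background from an empty set")
    channels = {p.channel_name for p in planes}
    if len(channels) != 1:
        raise ValueError(f"mixed channels in background set: {sorted(channels)}")
    minima = [float(np.min(p.pixels)) for p in planes]
    return BackgroundModel(
        set_id=set_id,
        channel_name=planes[0].channel_name,
        background_value=float(np.mean(minima)),
    )


def subtract_background(plane: ImagePlane, bg: BackgroundModel) -> ImagePlane:
    """Subtract the set background, clipping negatives to zero."""
    if plane.channel_name != bg.channel_name:
        raise ValueError(
            f"channel mismatch: plane {plane.channel_name!r} vs background "
            f"{bg.channel_name!r}"
        )
    return replace(
        plane,
        pixels=np.clip(plane.pixels - bg.background_value, 0, None),
        provenance="background_subtracted",
    )


def polygon_mask(
    roi: RegionOfInterest, shape: tuple[int, int], pixel_size_um: float
) -> BinaryMask:
    """Rasterize a traced polygon: pixels whose centers fall inside or on it.

    A polygon lying entirely outside the image yields an empty mask with a
    logged warning (mis-registered traces should not abort a batch run);
    downstream empty-mask preconditions then fail per image.
    """
    poly = roi.polygon
    if poly.area <= 0:
        raise ValueError("degenerate (zero-area) polygon")
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    y0, y1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    if x0 > x1 or y0 > y1:
        logger.warning(
            "ROI %r on image %r lies entirely outside the image; empty mask",
            roi.label,
            roi.image_id,
        )
        return BinaryMask(mask, pixel_size_um, origin="polygon")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = shapely.points(xs.ravel(), ys.ravel())
    shapely.prepare(poly)
    inside = shapely.covers(poly, pts).reshape(xs.shape)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return BinaryMask(mask, pixel_size_um, origin="polygon")


def threshold_mask(
    plane: ImagePlane, threshold: float | str = "auto"
) -> BinaryMask:
    """Binarize a plane at ``pixel >= threshold``.

    ``threshold="auto"`` computes an Otsu threshold on the plane and records
    the chosen value in the mask's ``meta`` (a reproducible stand-in for the
    per-replicate threshold an operator would pick by eye).
    """
    if isinstance(threshold, str):
        if threshold not in {"auto", "otsu"}:
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if np.ptp(plane.pixels) == 0:
            raise ValueError("auto threshold is undefined on a constant plane")
        value = float(threshold_otsu(plane.pixels))
        logger.info(
            "auto threshold %.4g chosen for %s/%s",
            value,
            plane.image_id,
            plane.channel_name,
        )
    else:
        value = float(threshold)
    return BinaryMask(
        plane.pixels >= value,
        plane.pixel_size_um,
        origin="threshold",
        meta={"threshold": value},
    )


def connected_components(mask: BinaryMask) -> LabeledRegions:
    """8-connectivity labeling with per-region areas in μm²."""
    label_image = measure.label(mask.pixels, connectivity=2)
    props = measure.regionprops(label_image)
    px_area = mask.pixel_size_um**2
    table = pd.DataFrame(
        {
            "label": [p.label for p in props],
            "area_px": [p.area for p in props],
            "area_um2": [p.area * px_area for p in props],
            "bbox_min_row": [p.bbox[0] for p in props],
            "bbox_min_col": [p.bbox[1] for p in props],
            "bbox_max_row": [p.bbox[2] for p in props],
            "bbox_max_col": [p.bbox[3] for p in props],
            "centroid_row": [p.centroid[0] for p in props],
            "centroid_col": [p.centroid[1] for p in props],
        }
    )
    return LabeledRegions(label_image, table, mask.pixel_size_um)


def filter_components_by_area(
    regions: LabeledRegions, min_area_um2: float
) -> BinaryMask:
    """Drop components smaller than ``min_area_um2``; exact ties are kept.

    Mirrors the spurious-noise rule: network areas *less than* the cutoff
    are excluded, areas equal to it are retained.
    """
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    keep = regions.regions.loc[
        regions.regions["area_um2"] >= min_area_um2, "label"
    ].to_numpy()
    mask = np.isin(regions.label_image, keep) & (regions.label_image > 0)
    return BinaryMask(mask, regions.pixel_size_um, origin="composition")


# ---------------------------------------------------------------------------
# pixel statistics
# ---------------------------------------------------------------------------


def _check_congruent(plane: ImagePlane, mask: BinaryMask) -> None:
    if plane.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"plane shape {plane.pixels.shape} != mask shape {mask.pixels.shape}"
        )


def mean_intensity(plane: ImagePlane, mask: BinaryMask) -> float:
    """Arithmetic mean of plane pixels under the mask."""
    _check_congruent(plane, mask)
    if not mask.pixels.any():
        raise ValueError("mean intensity over an empty mask is undefined")
    return float(np.mean(plane.pixels[mask.pixels]))


def integrated_intensity(plane: ImagePlane, mask: BinaryMask) -> float:
    """Sum of plane pixels under the mask (0 for an empty mask)."""
    _check_congruent(plane, mask)
    return float(np.sum(plane.pixels[mask.pixels]))
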