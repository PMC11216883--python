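"""Synthetic multi-channel microscopy fields with exported ground truth.

No public accession holds the raw organoid microscopy, so every pipeline
stage is exercised against rendered stand-ins that emulate the statistical
structure the assays rely on:

* an elliptical organoid body containing LTL+ tubule tubes and PODXL+
  podocyte tufts;
* a curvilinear branching CD31+ vessel network grown to a target coverage
  fraction and split between the organoid interior and the surrounding
  stroma;
* DAPI nuclei scattered with a minimum separation;
* a target channel (APOL1 by default) rendered at ``base x condition
  multiplier`` inside cellular masks — the IFN-γ preset multiplier of 1.5
  mirrors the ~50% induction the assays are meant to resolve;
* uniform additive background plus a camera-like noise model (Poisson shot
  noise at a configurable gain, additive Gaussian read noise) applied per
  z-slice.

Ground-truth masks, noiseless intensity fields and the realized multipliers
accompany every rendered field, so recovery can be scored exactly.  All
randomness flows from a single seed through named, order-stable substreams;
identical (config, seed, condition) yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import find_boundaries, watershed

from . import image_core as ic
from .assays import TimecourseSeries

# condition label for the interferon-gamma arm used throughout
IFNG = "IFNg"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganoidConfig:
    semi_axes_um: tuple[float, float] = (90.0, 70.0)
    tubule_count: int = 4
    tubule_width_um: float = 8.0
    tuft_count: int = 4
    tuft_radius_um: float = 15.0


@dataclass(frozen=True)
class VesselConfig:
    width_um: float = 6.0
    coverage_fraction: float = 0.12  # of the whole field
    interior_fraction: float = 0.35  # walks seeded inside the organoid
    retention_factor: float = 1.0  # multiplies coverage (degradation arms)
    branch_probability: float = 0.02
    step_px: float = 2.0


@dataclass(frozen=True)
class NucleiConfig:
    count: int = 150
    radius_um: float = 4.0
    min_separation_um: float = 12.0


@dataclass(frozen=True)
class ChannelConfig:
    base: Mapping[str, float] = field(
        default_factory=lambda: {
            "DAPI": 150.0,
            "PODXL": 120.0,
            "LTL": 120.0,
            "APOL1": 100.0,
            "GSDMD": 100.0,
            "CD31": 110.0,
            # a live PODXL-GFP reporter is far brighter than immunostains:
            # the integrated in-trace signal must dominate residual projected
            # background for per-organoid normalization to be meaningful
            "GFP": 800.0,
            "brightfield": 80.0,
        }
    )
    condition_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {IFNG: {"APOL1": 1.5, "GSDMD": 1.5}}
    )
    background: float = 20.0
    # monolayer CD31 rendering: bright junctions, dim intracellular fill
    junctional_cd31: float = 200.0
    intracellular_cd31: float = 40.0


@dataclass(frozen=True)
class NoiseConfig:
    gaussian_sigma: float = 2.0
    poisson_gain: float = 0.5  # photons-per-ADU; 0 disables shot noise

    @property
    def enabled(self) -> bool:
        return self.gaussian_sigma > 0 or self.poisson_gain > 0


@dataclass(frozen=True)
class TimecourseConfig:
    gfp_decay: float = 0.7  # per imaging session
    area_shrinkage: float = 1.0
    vessel_retention: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    field_size_px: tuple[int, int] = (384, 384)
    pixel_size_um: float = 1.0
    z_slices: int = 10
    z_step_um: float = 10.0
    organoid: OrganoidConfig = field(default_factory=OrganoidConfig)
    vessels: VesselConfig = field(default_factory=VesselConfig)
    nuclei: NucleiConfig = field(default_factory=NucleiConfig)
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    timecourse: TimecourseConfig = field(default_factory=TimecourseConfig)
    target_channel: str = "APOL1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_slices < 1:
            raise ValueError("invalid geometry")
        cov = self.vessels.coverage_fraction * self.vessels.retention_factor
        if not 0 < cov < 1:
            raise ValueError("vessel coverage fraction must lie in (0, 1)")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """What a synthetic field was rendered from."""

    masks: Mapping[str, np.ndarray]  # body, tubules, tufts, vessels, nuclei
    vessel_labels: np.ndarray
    vessel_regions: pd.DataFrame  # label, area_um2, compartment
    nuclei_centers: np.ndarray  # (n, 2) as (y, x)
    clean_channels: Mapping[str, np.ndarray]
    multipliers: Mapping[str, float]
    body_vertices: tuple[tuple[float, float], ...]

    @property
    def vessel_coverage(self) -> float:
        return float(np.count_nonzero(self.masks["vessels"])) / self.masks["vessels"].size


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("body", "tubules", "tufts", "vessels", "nuclei", "noise")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.Generator(np.random.Philox(s)) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# geometric rendering helpers
# ---------------------------------------------------------------------------


def _ellipse_mask(shape, center, semi_axes, angle) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_polygon(center, semi_axes, angle, n=48):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    a, b = semi_axes
    u, v = a * np.cos(t), b * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    x = center[1] + c * u - s * v
    y = center[0] + s * u + c * v
    return tuple((float(xi), float(yi)) for xi, yi in zip(x, y))


def _disk_offsets(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    r = max(1, radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= r**2
    return dy[keep], dx[keep]


def _stamp(canvas: np.ndarray, y: int, x: int, dy: np.ndarray, dx: np.ndarray) -> None:
    h, w = canvas.shape
    yy, xx = y + dy, x + dx
    ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    canvas[yy[ok], xx[ok]] = True


def _grow_vessels(shape, body, cfg: VesselConfig, pixel_size_um, rng) -> np.ndarray:
    """Random-walk branching tubes grown until the coverage target is met."""
    target = cfg.coverage_fraction * cfg.retention_factor
    canvas = np.zeros(shape, dtype=bool)
    total = shape[0] * shape[1]
    dy, dx = _disk_offsets(int(round(cfg.width_um / (2 * pixel_size_um))))
    body_idx = np.argwhere(body)
    budget = 40 * int(target * total)  # hard stop against pathological configs

    pending: list[tuple[float, float, float]] = []
    steps = 0
    while canvas.sum() < target * total and steps < budget:
        if not pending:
            if len(body_idx) and rng.random() < cfg.interior_fraction:
                y0, x0 = body_idx[rng.integers(len(body_idx))]
            else:
                y0, x0 = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
            pending.append((float(y0), float(x0), rng.uniform(0, 2 * np.pi)))
        y, x, theta = pending.pop()
        walk_len = int(rng.integers(30, 120))
        for _ in range(walk_len):
            _stamp(canvas, int(round(y)), int(round(x)), dy, dx)
            steps += 1
            theta += rng.normal(0, 0.35)
            y += cfg.step_px * np.sin(theta)
            x += cfg.step_px * np.cos(theta)
            if not (0 <= y < shape[0] and 0 <= x < shape[1]):
                break
            if rng.random() < cfg.branch_probability:
                pending.append((y, x, theta + rng.choice([-1, 1]) * np.pi / 3))
            if canvas.sum() >= target * total:
                break
    return canvas


def _place_nuclei(shape, cfg: NucleiConfig, pixel_size_um, rng) -> np.ndarray:
    min_sep = cfg.min_separation_um / pixel_size_um
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < cfg.count:
        attempts += 1
        if attempts > 200 * cfg.count:
            raise ValueError(
                f"cannot place {cfg.count} nuclei at {cfg.min_separation_um} μm "
                "separation in this field"
            )
        y, x = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        if centers:
            arr = np.asarray(centers)
            if np.min((arr[:, 0] - y) ** 2 + (arr[:, 1] - x) ** 2) < min_sep**2:
                continue
        centers.append((y, x))
    return np.asarray(centers)


def _nuclei_mask(shape, centers, radius_px) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    dy, dx = _disk_offsets(int(round(radius_px)))
    for y, x in centers:
        _stamp(mask, int(round(y)), int(round(x)), dy, dx)
    return mask


def _random_tube(shape, inside, width_px, rng) -> np.ndarray:
    """One curved tube constrained to the ``inside`` mask."""
    canvas = np.zeros(shape, dtype=bool)
    dy, dx = _disk_offsets(int(round(width_px / 2)))
    idx = np.argwhere(inside)
    if not len(idx):
        raise ValueError("tubules requested but the organoid body is empty")
    y, x = idx[rng.integers(len(idx))].astype(float)
    theta = rng.uniform(0, 2 * np.pi)
    for _ in range(int(rng.integers(40, 90))):
        _stamp(canvas, int(round(y)), int(round(x)), dy, dx)
        theta += rng.normal(0, 0.4)
        ny, nx = y + 1.5 * np.sin(theta), x + 1.5 * np.cos(theta)
        if 0 <= ny < shape[0] and 0 <= nx < shape[1] and inside[int(ny), int(nx)]:
            y, x = ny, nx
        else:
            theta += np.pi / 2  # bounce off the body wall
    return canvas & inside


def _z_weights(z_slices: int) -> np.ndarray:
    """Depth profile of a projected object; peaks at exactly 1 mid-stack."""
    z = np.arange(z_slices, dtype=float)
    w = np.exp(-(((z - (z_slices - 1) / 2) / max(1.0, z_slices / 3)) ** 2))
    return w / w.max()


def _apply_noise(slices: np.ndarray, noise: NoiseConfig, rng) -> np.ndarray:
    if not noise.enabled:
        return slices
    out = slices.astype(np.float64)
    if noise.poisson_gain > 0:
        g = noise.poisson_gain
        out = rng.poisson(np.clip(out, 0, None) / g) * g
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0, noise.gaussian_sigma, size=out.shape)
    return np.clip(out, 0, None)


def _assemble_stack(
    clean: Mapping[str, np.ndarray],
    config: GeneratorConfig,
    rng,
    image_id: str,
    flat_channels: frozenset[str] = frozenset({"brightfield"}),
) -> ic.ImageStack:
    """Distribute 2-D noiseless fields over z and apply per-slice noise.

    Fluorescent signal follows a peaked depth profile whose maximum weight is
    exactly 1, so the noiseless maximum projection returns the 2-D field;
    background is uniform across depth.
    """
    names = tuple(clean)
    w = _z_weights(config.z_slices)
    h, wd = config.field_size_px
    stack = np.empty((len(names), config.z_slices, h, wd), dtype=np.float64)
    bg = config.channels.background
    for ci, name in enumerate(names):
        for zi in range(config.z_slices):
            scale = 1.0 if name in flat_channels else w[zi]
            plane = clean[name] * scale + (0.0 if name in flat_channels else bg)
            stack[ci, zi] = _apply_noise(plane[None], config.noise, rng)[0]
    return ic.ImageStack(
        pixels=stack.astype(np.float32),
        channel_names=names,
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        image_id=image_id,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _multipliers_for(config: GeneratorConfig, condition: str) -> dict[str, float]:
    table = config.channels.condition_multipliers.get(condition, {})
    return {ch: float(table.get(ch, 1.0)) for ch in config.channels.base}


def generate_organoid_field(
    config: GeneratorConfig,
    condition: str = "control",
    image_id: str | None = None,
    channels: Sequence[str] = ("DAPI", "PODXL", "LTL", "APOL1", "CD31"),
) -> tuple[ic.ImageStack, GroundTruth]:
    """Render one organoid-plus-vessel-network field for a condition."""
    rngs = _streams(config.seed)
    shape = config.field_size_px
    px = config.pixel_size_um
    oc = config.organoid

    a, b = (ax / px for ax in oc.semi_axes_um)
    if 2 * max(a, b) > min(shape):
        raise ValueError("organoid does not fit in the field")
    center = (
        shape[0] / 2 + rngs["body"].uniform(-10, 10),
        shape[1] / 2 + rngs["body"].uniform(-10, 10),
    )
    angle = rngs["body"].uniform(0, np.pi)
    body = _ellipse_mask(shape, center, (a, b), angle)
    body_vertices = _ellipse_polygon(center, (a, b), angle)

    interior = _ellipse_mask(shape, center, (0.85 * a, 0.85 * b), angle)
    tubules = np.zeros(shape, dtype=bool)
    for _ in range(oc.tubule_count):
        tubules |= _random_tube(shape, interior, oc.tubule_width_um / px, rngs["tubules"])

    tufts = np.zeros(shape, dtype=bool)
    r_tuft = oc.tuft_radius_um / px
    if 2 * r_tuft > min(a, b):
        raise ValueError("podocyte tufts do not fit inside the organoid body")
    pocket = _ellipse_mask(shape, center, (a - r_tuft, b - r_tuft), angle)
    pocket_idx = np.argwhere(pocket)
    dy, dx = _disk_offsets(int(round(r_tuft)))
    for _ in range(oc.tuft_count):
        y, x = pocket_idx[rngs["tufts"].integers(len(pocket_idx))]
        _stamp(tufts, y, x, dy, dx)

    vessels = _grow_vessels(shape, body, config.vessels, px, rngs["vessels"])
    labels, _ = ndimage.label(vessels, structure=np.ones((3, 3), dtype=int))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    comp_interior = ndimage.labeled_comprehension(
        body, labels, ids, np.mean, float, 0.0
    ) if len(ids) else np.array([])
    vessel_regions = pd.DataFrame(
        {
            "label": ids,
            "area_um2": counts * px**2,
            "compartment": np.where(comp_interior > 0.5, "interior", "stromal")
            if len(ids)
            else [],
        }
    )

    nuclei_centers = _place_nuclei(shape, config.nuclei, px, rngs["nuclei"])
    nuclei = _nuclei_mask(shape, nuclei_centers, config.nuclei.radius_um / px)

    mult = _multipliers_for(config, condition)
    base = config.channels.base
    target = config.target_channel
    cellular = body | vessels
    renderers = {
        "DAPI": lambda: base["DAPI"] * mult["DAPI"] * nuclei,
        "PODXL": lambda: base["PODXL"] * mult["PODXL"] * tufts,
        "LTL": lambda: base["LTL"] * mult["LTL"] * tubules,
        "CD31": lambda: base["CD31"] * mult["CD31"] * vessels,
        "GFP": lambda: base["GFP"] * mult["GFP"] * tufts,
        "brightfield": lambda: base["brightfield"] * (1.0 - 0.25 * body),
        target: lambda: base[target] * mult[target] * cellular,
    }
    clean = {ch: renderers[ch]().astype(np.float64) for ch in channels}

    gt = GroundTruth(
        masks={
            "body": body,
            "tubules": tubules,
            "tufts": tufts,
            "vessels": vessels,
            "nuclei": nuclei,
        },
        vessel_labels=labels,
        vessel_regions=vessel_regions,
        nuclei_centers=nuclei_centers,
        clean_channels=clean,
        multipliers=mult,
        body_vertices=body_vertices,
    )
    stack = _assemble_stack(
        clean, config, rngs["noise"], image_id or f"field_s{config.seed}_{condition}"
    )
    return stack, gt


def generate_timecourse(
    config: GeneratorConfig,
    days: Sequence[int] = (0, 3, 7),
    condition: str = "control",
    organoid_id: str | None = None,
) -> tuple[TimecourseSeries, list[GroundTruth]]:
    """Sequentially imaged live organoid: GFP decays, the body may shrink.

    The GFP field of the k-th imaging session is scaled by ``gfp_decay**k``
    and the body ellipse by ``sqrt(area_shrinkage)**k``; the per-day
    bright-field trace polygon is exported alongside each stack.
    """
    days = tuple(int(d) for d in days)
    if not days or days[0] != 0:
        raise ValueError("timecourse must include day 0")
    tc = config.timecourse
    organoid_id = organoid_id or f"organoid_s{config.seed}_{condition}"

    rois, stacks, truths = [], [], []
    for k, day in enumerate(days):
        shrink = tc.area_shrinkage**k
        oc = config.organoid
        day_cfg = config.replace(
            organoid=dataclasses.replace(
                oc,
                semi_axes_um=tuple(ax * np.sqrt(shrink) for ax in oc.semi_axes_um),
            ),
            channels=dataclasses.replace(
                config.channels,
                base={**config.channels.base, "GFP": config.channels.base["GFP"] * tc.gfp_decay**k},
            ),
            vessels=dataclasses.replace(
                config.vessels,
                retention_factor=config.vessels.retention_factor * tc.vessel_retention**k,
            ),
        )
        stack, gt = generate_organoid_field(
            day_cfg,
            condition=condition,
            image_id=f"{organoid_id}_d{day}",
            channels=("brightfield", "GFP", "PODXL"),
        )
        rois.append(
            ic.RegionOfInterest(
                vertices=gt.body_vertices,
                label="organoid_body",
                image_id=stack.image_id,
                day=day,
            )
        )
        stacks.append(stack)
        truths.append(gt)
    series = TimecourseSeries(
        organoid_id=organoid_id,
        days=days,
        rois=tuple(rois),
        stacks=tuple(stacks),
        condition=condition,
    )
    return series, truths


def generate_monolayer(
    config: GeneratorConfig,
    condition: str = "control",
    image_id: str | None = None,
) -> tuple[dict[str, ic.ImagePlane], GroundTruth]:
    """Endothelial monolayer field: DAPI nuclei, APOL1 cytoplasm, CD31 junctions.

    CD31 renders bright cell-boundary junctions over a dim intracellular
    fill, so a single global threshold between the two levels isolates the
    junctional compartment.
    """
    rngs = _streams(config.seed)
    shape = config.field_size_px
    px = config.pixel_size_um
    image_id = image_id or f"monolayer_s{config.seed}_{condition}"

    centers = _place_nuclei(shape, config.nuclei, px, rngs["nuclei"])
    r_px = config.nuclei.radius_um / px
    nuclei = _nuclei_mask(shape, centers, r_px)
    nuc_labels, _ = ndimage.label(nuclei, structure=np.ones((3, 3), dtype=int))

    # voronoi-like cells from nucleus centers; junctions on the boundaries
    markers = np.zeros(shape, dtype=int)
    for i, (y, x) in enumerate(centers, start=1):
        markers[int(y), int(x)] = i
    seed_dist = ndimage.distance_transform_edt(markers == 0)
    cells = watershed(seed_dist, markers)
    junction = find_boundaries(cells, mode="thick")
    junction = ndimage.binary_dilation(junction, iterations=1)

    mult = _multipliers_for(config, condition)
    base = config.channels.base
    cyto = ndimage.binary_dilation(
        nuclei, iterations=max(1, int(round(2 * r_px)))
    )
    clean = {
        "DAPI": base["DAPI"] * mult["DAPI"] * nuclei,
        "APOL1": base["APOL1"] * mult["APOL1"] * cyto,
        "CD31": np.where(
            junction,
            config.channels.junctional_cd31,
            config.channels.intracellular_cd31,
        ).astype(np.float64),
    }

    bg = config.channels.background
    planes = {}
    for name, img in clean.items():
        noisy = _apply_noise(img + bg, config.noise, rngs["noise"])
        planes[name] = ic.ImagePlane(
            pixels=noisy.astype(np.float32),
            channel_name=name,
            pixel_size_um=px,
            image_id=image_id,
            provenance="raw",
        )

    gt = GroundTruth(
        masks={"nuclei": nuclei, "junction": junction, "cytoplasm": cyto},
        vessel_labels=np.zeros(shape, dtype=int),
        vessel_regions=pd.DataFrame(columns=["label", "area_um2", "compartment"]),
        nuclei_centers=centers,
        clean_channels=clean,
        multipliers=mult,
        body_vertices=(),
    )
    return planes, gt


# ---------------------------------------------------------------------------
# fixture export (same formats the pipeline reads)
# ---------------------------------------------------------------------------


def ground_truth_summary(gt: GroundTruth, pixel_size_um: float) -> dict:
    return {
        "vessel_coverage": gt.vessel_coverage if "vessels" in gt.masks else None,
        "vessel_component_areas_um2": gt.vessel_regions["area_um2"].tolist(),
        "vessel_compartments": gt.vessel_regions.get(
            "compartment", pd.Series(dtype=str)
        ).tolist(),
        "n_nuclei": int(len(gt.nuclei_centers)),
        "nuclei_centers": [[float(y), float(x)] for y, x in gt.nuclei_centers],
        "multipliers": dict(gt.multipliers),
        "mask_areas_um2": {
            k: float(np.count_nonzero(v)) * pixel_size_um**2
            for k, v in gt.masks.items()
        },
    }


def write_field_fixture(
    outdir: str | Path,
    stack: ic.ImageStack,
    gt: GroundTruth,
    rois: Sequence[ic.RegionOfInterest],
    manifest_rows: list[dict],
    *,
    set_id: str,
    condition: str,
    assay: str,
    replicate: str = "r1",
    day: int | None = None,
) -> None:
    """Write TIFF + GeoJSON ROI + ground-truth JSON and append a manifest row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiff = outdir / f"{stack.image_id}.ome.tif"
    roi_path = outdir / f"{stack.image_id}.rois.geojson"
    gt_path = outdir / f"{stack.image_id}.groundtruth.json"
    ic.write_stack(tiff, stack)
    ic.write_roi_geojson(roi_path, rois)
    gt_path.write_text(
        json.dumps(ground_truth_summary(gt, stack.pixel_size_um), indent=1)
    )
    manifest_rows.append(
        {
            "image_path": tiff.name,
            "image_id": stack.image_id,
            "set_id": set_id,
            "condition": condition,
            "day": day,
            "replicate": replicate,
            "assay": assay,
            "roi_path": roi_path.name,
            "channel_map": ";".join(stack.channel_names),
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
        }
    )
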