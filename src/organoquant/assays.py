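"""The four quantification assays, composed from :mod:`organoquant.image_core`.

Each assay emits :class:`AssayRecord` rows — one per image and metric — that
downstream normalization, well-summary and statistics layers consume:

* ``organoid_intensity``: mean background-subtracted target intensity (APOL1,
  GSDMD, ...) of the max projection inside a manually traced organoid body.
* ``network``: CD31+ vessel-network area fractions for the whole region of
  interest and for the stroma (outside the organoid trace), plus stromal
  vessel APOL1 with the 2,000 μm² spurious-component exclusion.
* ``timecourse``: per-day organoid area and integrated PODXL-GFP signal,
  normalized to the same organoid's day-0 values.
* ``monolayer``: nuclear density via DAPI particle counting, per-cell APOL1
  inside dilated nuclear masks, and junctional CD31 area fraction.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

from . import image_core as ic

logger = logging.getLogger("organoquant")

ASSAY_METRICS: dict[str, set[str]] = {
    "organoid_intensity": {"mean_APOL1", "mean_GSDMD", "mean_target"},
    "network": {
        "network_density_total",
        "network_density_stromal",
        "network_area_total_um2",
        "network_area_stromal_um2",
        "stromal_vessel_APOL1",
    },
    "timecourse": {"organoid_area_um2", "integrated_GFP"},
    "monolayer": {"nuclei_per_mm2", "per_cell_APOL1", "junctional_CD31_fraction"},
}


@dataclass(frozen=True)
class AssayRecord:
    """One measurement: an image, a metric, its raw and normalized values."""

    assay: str
    image_id: str
    metric: str
    raw_value: float
    condition: str = ""
    day: int | None = None
    replicate: str | None = None
    well: str | None = None
    normalized_value: float | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.raw_value):
            raise ValueError(f"raw_value must be finite, got {self.raw_value}")
        if self.normalized_value is not None and self.normalized_value < 0:
            raise ValueError("normalized_value must be >= 0")
        known = ASSAY_METRICS.get(self.assay)
        if known is not None and self.metric not in known and not self.metric.startswith("mean_"):
            raise ValueError(f"metric {self.metric!r} not in {self.assay!r} vocabulary")


def records_to_frame(records: Iterable[AssayRecord]) -> pd.DataFrame:
    rows = [vars(r) for r in records]
    return pd.DataFrame(
        rows,
        columns=[
            "assay",
            "image_id",
            "metric",
            "raw_value",
            "condition",
            "day",
            "replicate",
            "well",
            "normalized_value",
            "excluded",
        ],
    )


@dataclass(frozen=True)
class TimecourseSeries:
    """One organoid tracked across days: a trace and a stack per day."""

    organoid_id: str
    days: tuple[int, ...]
    rois: tuple[ic.RegionOfInterest, ...]
    stacks: tuple[ic.ImageStack, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        if not days or days[0] != 0:
            raise ValueError("timecourse series must start at day 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if not (len(days) == len(self.rois) == len(self.stacks)):
            raise ValueError("one trace and one stack required per day")
        object.__setattr__(self, "days", days)


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------


def organoid_body_intensity(
    stack: ic.ImageStack,
    roi: ic.RegionOfInterest,
    channel: str,
    bg: ic.BackgroundModel,
    condition: str = "",
    replicate: str | None = None,
    well: str | None = None,
) -> AssayRecord:
    """Mean background-subtracted target intensity within the organoid trace.

    The trace (drawn on LTL/PODXL staining) defines the organoid perimeter;
    quantification happens on the background-subtracted maximum intensity
    projection of the requested channel.
    """
    if roi.label != "organoid_body":
        raise ValueError(f"expected an organoid_body ROI, got {roi.label!r}")
    plane = ic.subtract_background(ic.max_project(stack, channel), bg)
    mask = ic.polygon_mask(roi, plane.pixels.shape, plane.pixel_size_um)
    return AssayRecord(
        assay="organoid_intensity",
        image_id=stack.image_id,
        metric=f"mean_{channel}",
        raw_value=ic.mean_intensity(plane, mask),
        condition=condition,
        replicate=replicate,
        well=well,
    )


def normalize_to_control(
    records: Sequence[AssayRecord],
    control_condition: str,
    group_keys: tuple[str, ...] = ("assay", "metric", "replicate"),
    on_missing_control: str = "raise",
) -> list[AssayRecord]:
    """Divide each raw value by the mean control raw value of its group.

    Within every normalization group the mean of the control records'
    normalized values is exactly 1.  Excluded records pass through
    unnormalized.  ``on_missing_control="skip"`` leaves a group without
    usable control records unnormalized (with a warning) instead of
    aborting — batch runs can lose every control of a group to the
    stromal-area exclusion.
    """
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        if rec.excluded:
            continue
        groups[tuple(getattr(rec, k) for k in group_keys)].append(i)

    out = list(records)
    for key, idxs in groups.items():
        control = [records[i].raw_value for i in idxs if records[i].condition == control_condition]
        if not control or float(np.mean(control)) == 0:
            reason = "no" if not control else "zero-mean"
            if on_missing_control == "skip":
                logger.warning(
                    "%s %r control records in group %s; left unnormalized",
                    reason, control_condition, key,
                )
                continue
            raise ValueError(
                f"{reason} {control_condition!r} records in group {key}"
            )
        denom = float(np.mean(control))
        for i in idxs:
            out[i] = replace(records[i], normalized_value=records[i].raw_value / denom)
    return out


def network_assay(
    stack: ic.ImageStack,
    organoid_roi: ic.RegionOfInterest,
    cd31_channel: str,
    apol1_channel: str,
    threshold: float | str,
    bg: ic.BackgroundModel,
    min_area_um2: float = 2000.0,
    condition: str = "",
    replicate: str | None = None,
    well: str | None = None,
) -> list[AssayRecord]:
    """Vessel-network density and stromal-vessel APOL1 for one field.

    The acquired region of interest contains a single organoid; the manual
    organoid trace splits the CD31+ binary into interior and stromal
    compartments.  Densities are area fractions: total CD31+ area over the
    field area, and stromal CD31+ area over the stromal (field minus
    organoid) area, both from the unfiltered binary.  Stromal APOL1 is
    measured on the background-subtracted APOL1 projection within the
    stromal CD31+ mask after removing components smaller than
    ``min_area_um2``; organoids whose retained stromal network area does not
    exceed ``min_area_um2`` are flagged excluded rather than measured.
    """
    cd31 = ic.max_project(stack, cd31_channel)
    cd31_mask = ic.threshold_mask(cd31, threshold)
    px2 = stack.pixel_size_um**2
    h, w = cd31.pixels.shape
    field_area = h * w * px2

    body = ic.polygon_mask(organoid_roi, (h, w), stack.pixel_size_um)
    stromal_mask = ic.BinaryMask(
        cd31_mask.pixels & ~body.pixels, stack.pixel_size_um, "composition"
    )
    stromal_area_denom = field_area - body.area_um2

    common = dict(
        assay="network",
        image_id=stack.image_id,
        condition=condition,
        replicate=replicate,
        well=well,
    )
    records = [
        AssayRecord(metric="network_density_total", raw_value=cd31_mask.area_um2 / field_area, **common),
        AssayRecord(metric="network_area_total_um2", raw_value=cd31_mask.area_um2, **common),
        AssayRecord(
            metric="network_density_stromal",
            raw_value=(stromal_mask.area_um2 / stromal_area_denom) if stromal_area_denom > 0 else 0.0,
            **common,
        ),
        AssayRecord(metric="network_area_stromal_um2", raw_value=stromal_mask.area_um2, **common),
    ]

    retained = ic.filter_components_by_area(
        ic.connected_components(stromal_mask), min_area_um2
    )
    if retained.area_um2 > min_area_um2:
        apol1 = ic.subtract_background(ic.max_project(stack, apol1_channel), bg)
        records.append(
            AssayRecord(
                metric="stromal_vessel_APOL1",
                raw_value=ic.mean_intensity(apol1, retained),
                **common,
            )
        )
    else:
        logger.info(
            "image %s: stromal network area %.0f μm² <= %.0f μm²; "
            "stromal APOL1 excluded",
            stack.image_id,
            retained.area_um2,
            min_area_um2,
        )
        records.append(
            AssayRecord(metric="stromal_vessel_APOL1", raw_value=0.0, excluded=True, **common)
        )
    return records


def timecourse_assay(
    series: TimecourseSeries, gfp_channel: str = "GFP", bg: ic.BackgroundModel | None = None
) -> list[AssayRecord]:
    """Per-day organoid area and integrated GFP, normalized to day 0.

    The bright-field trace of each day defines that day's perimeter; the
    integrated GFP signal and trace area are each divided by the organoid's
    own day-0 value, so every series starts at 1.
    """
    raw: dict[str, list[float]] = {"organoid_area_um2": [], "integrated_GFP": []}
    for roi, stack in zip(series.rois, series.stacks):
        plane = ic.max_project(stack, gfp_channel)
        if bg is not None:
            plane = ic.subtract_background(plane, bg)
        mask = ic.polygon_mask(roi, plane.pixels.shape, plane.pixel_size_um)
        raw["organoid_area_um2"].append(mask.area_um2)
        raw["integrated_GFP"].append(ic.integrated_intensity(plane, mask))

    records = []
    for metric, values in raw.items():
        day0 = values[0]
        if day0 <= 0:
            raise ValueError(f"day-0 {metric} must be positive, got {day0}")
        for day, value, stack in zip(series.days, values, series.stacks):
            records.append(
                AssayRecord(
                    assay="timecourse",
                    image_id=stack.image_id,
                    metric=metric,
                    raw_value=value,
                    normalized_value=value / day0,
                    condition=series.condition,
                    day=day,
                    well=series.organoid_id,
                )
            )
    return records


def monolayer_assay(
    planes: Mapping[str, ic.ImagePlane],
    thresholds: Mapping[str, float | str],
    bg: Mapping[str, ic.BackgroundModel],
    dilation_radius_um: float = 5.0,
    particle_area_bounds_um2: tuple[float, float] = (20.0, 500.0),
    condition: str = "",
    replicate: str | None = None,
    well: str | None = None,
) -> list[AssayRecord]:
    """Nuclear density, per-cell APOL1 and junctional CD31 for one field.

    Nuclei are DAPI connected components with areas inside
    ``particle_area_bounds_um2`` (particle counting; touching nuclei stay
    merged — no declumping).  Cell bodies are approximated by dilating each
    retained nuclear mask by ``dilation_radius_um``; per-cell APOL1 is the
    mean background-subtracted APOL1 intensity within the dilated union.
    Junctional CD31 is the area fraction above one uniform global threshold
    chosen high enough to exclude the dimmer intracellular staining.
    """
    if "DAPI" not in planes:
        raise ValueError("monolayer assay requires a DAPI plane")
    if dilation_radius_um <= 0:
        raise ValueError("dilation_radius_um must be positive")
    dapi = planes["DAPI"]
    px = dapi.pixel_size_um
    px2 = px**2
    lo, hi = particle_area_bounds_um2

    dapi_mask = ic.threshold_mask(dapi, thresholds.get("DAPI", "auto"))
    regions = ic.connected_components(dapi_mask)
    in_bounds = regions.regions[
        (regions.regions["area_um2"] >= lo) & (regions.regions["area_um2"] <= hi)
    ]
    n_nuclei = len(in_bounds)
    field_area_mm2 = dapi.pixels.size * px2 / 1e6

    common = dict(
        assay="monolayer",
        image_id=dapi.image_id,
        condition=condition,
        replicate=replicate,
        well=well,
    )
    records = [
        AssayRecord(metric="nuclei_per_mm2", raw_value=n_nuclei / field_area_mm2, **common)
    ]

    if "APOL1" in planes:
        if n_nuclei == 0:
            raise ValueError("per-cell APOL1 requested but no nuclei detected")
        nuclear = np.isin(regions.label_image, in_bounds["label"].to_numpy())
        cell_body = dilation(nuclear, disk(max(1, round(dilation_radius_um / px))))
        apol1 = ic.subtract_background(planes["APOL1"], bg["APOL1"])
        records.append(
            AssayRecord(
                metric="per_cell_APOL1",
                raw_value=ic.mean_intensity(
                    apol1, ic.BinaryMask(cell_body, px, "dilation")
                ),
                **common,
            )
        )

    if "CD31" in planes:
        threshold = thresholds.get("CD31")
        if threshold is None:
            raise ValueError("junctional CD31 needs an explicit global threshold")
        cd31_mask = ic.threshold_mask(planes["CD31"], float(threshold))
        records.append(
            AssayRecord(
                metric="junctional_CD31_fraction",
                raw_value=float(np.count_nonzero(cd31_mask.pixels)) / cd31_mask.pixels.size,
                **common,
            )
        )
    return records


def well_summary(
    records: Sequence[AssayRecord],
    group_keys: tuple[str, ...] = ("assay", "metric", "condition", "well"),
) -> list[AssayRecord]:
    """Average the regions of interest of a well into one record per metric.

    The reported per-well metric is the mean over the (typically 4) fields
    imaged in that culture well; normalized values are averaged when every
    member carries one.
    """
    groups: dict[tuple, list[AssayRecord]] = defaultdict(list)
    for rec in records:
        if rec.excluded:
            continue
        groups[tuple(getattr(rec, k) for k in group_keys)].append(rec)
    if not groups:
        raise ValueError("no records to summarize")

    out = []
    for members in groups.values():
        first = members[0]
        norm = [m.normalized_value for m in members]
        out.append(
            replace(
                first,
                image_id=f"well:{first.well}" if first.well else first.image_id,
                raw_value=float(np.mean([m.raw_value for m in members])),
                normalized_value=float(np.mean(norm)) if all(v is not None for v in norm) else None,
            )
        )
    return out
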