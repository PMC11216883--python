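"""Seeded recovery experiments: the package measured against its own ground truth.

Each function renders synthetic fields under controlled conditions, runs the
corresponding assay exactly as the pipeline would, and reports how well the
configured quantity was recovered.  They are the computational core of the
numbered analysis drivers and of the acceptance script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import assays, image_core as ic, synthetic_data as sd

CD31_THRESHOLD = 75.0  # stands in for the per-replicate operator threshold


def _body_roi(gt: sd.GroundTruth) -> ic.RegionOfInterest:
    return ic.RegionOfInterest(gt.body_vertices, label="organoid_body")


def effect_ratio_recovery(
    multipliers: tuple[float, ...] = (1.25, 1.5, 2.0),
    n_per_arm: int = 20,
    seed: int = 0,
    base_config: sd.GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Treated/control ratio of group-mean organoid-body target intensity.

    Renders ``n_per_arm`` fields per arm at default noise (one shared
    control arm), computes each field's mean background-subtracted target
    intensity inside the traced body, and compares the recovered
    treated/control ratio of group means with the configured multiplier.
    The background is estimated from the arm's own projections, as in a
    real staining set.
    """
    cfg0 = base_config or sd.GeneratorConfig()

    def _arm(condition: str, multiplier: float, arm_seed: int) -> list[float]:
        mult_table = {"treated": {cfg0.target_channel: multiplier}}
        fields = []
        for i in range(n_per_arm):
            cfg = cfg0.replace(
                seed=arm_seed + i,
                channels=dataclasses.replace(
                    cfg0.channels, condition_multipliers=mult_table
                ),
            )
            fields.append(
                sd.generate_organoid_field(
                    cfg, condition, channels=(cfg0.target_channel,)
                )
            )
        planes = [ic.max_project(s, cfg0.target_channel) for s, _ in fields]
        bg = ic.compute_set_background(planes, f"arm_{condition}_{multiplier}")
        return [
            assays.organoid_body_intensity(
                s, _body_roi(gt), cfg0.target_channel, bg, condition=condition
            ).raw_value
            for s, gt in fields
        ]

    control = _arm("control", 1.0, seed)
    rows = []
    for j, r in enumerate(multipliers):
        treated = _arm("treated", r, seed + 1000 * (j + 1))
        rows.append(
            {
                "multiplier": r,
                "recovered_ratio": float(np.mean(treated) / np.mean(control)),
                "n_control": n_per_arm,
                "n_treated": n_per_arm,
            }
        )
    return pd.DataFrame(rows)


def network_density_recovery(
    coverages: tuple[float, ...] = (0.05, 0.12, 0.25),
    n_per_arm: int = 3,
    seed: int = 0,
    base_config: sd.GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Recover rendered vessel coverage fractions through the network assay."""
    cfg0 = base_config or sd.GeneratorConfig()
    rows = []
    for j, cov in enumerate(coverages):
        densities, truths = [], []
        for i in range(n_per_arm):
            cfg = cfg0.replace(
                seed=seed + 100 * j + i,
                vessels=dataclasses.replace(cfg0.vessels, coverage_fraction=cov),
            )
            stack, gt = sd.generate_organoid_field(
                cfg, "control", channels=("CD31", cfg0.target_channel)
            )
            recs = assays.network_assay(
                stack, _body_roi(gt), "CD31", cfg0.target_channel,
                threshold=CD31_THRESHOLD,
                bg=ic.BackgroundModel("r", cfg0.target_channel, cfg0.channels.background),
            )
            densities.append(
                next(r.raw_value for r in recs if r.metric == "network_density_total")
            )
            truths.append(gt.vessel_coverage)
        rows.append(
            {
                "coverage_target": cov,
                "coverage_rendered": float(np.mean(truths)),
                "density_recovered": float(np.mean(densities)),
                "abs_error": float(abs(np.mean(densities) - cov)),
                "n": n_per_arm,
            }
        )
    return pd.DataFrame(rows)


def stromal_retention_ordering(
    retentions: tuple[float, ...] = (1.0, 0.7, 0.4),
    n_per_arm: int = 3,
    seed: int = 0,
    base_config: sd.GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Stromal network density across vessel-retention arms (degradation)."""
    cfg0 = base_config or sd.GeneratorConfig()
    rows = []
    for j, retention in enumerate(retentions):
        stromal = []
        for i in range(n_per_arm):
            cfg = cfg0.replace(
                seed=seed + 100 * j + i,
                vessels=dataclasses.replace(
                    cfg0.vessels, retention_factor=retention
                ),
            )
            stack, gt = sd.generate_organoid_field(
                cfg, "control", channels=("CD31", cfg0.target_channel)
            )
            recs = assays.network_assay(
                stack, _body_roi(gt), "CD31", cfg0.target_channel,
                threshold=CD31_THRESHOLD,
                bg=ic.BackgroundModel("r", cfg0.target_channel, cfg0.channels.background),
            )
            stromal.append(
                next(
                    r.raw_value
                    for r in recs
                    if r.metric == "network_density_stromal"
                )
            )
        rows.append(
            {
                "retention_factor": retention,
                "stromal_density": float(np.mean(stromal)),
                "n": n_per_arm,
            }
        )
    return pd.DataFrame(rows)


def monolayer_count_agreement(
    counts: tuple[int, ...] = (50, 150, 300),
    seed: int = 0,
    base_config: sd.GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Nuclear-density particle counts against the generator's truth."""
    cfg0 = base_config or sd.GeneratorConfig()
    rows = []
    for j, count in enumerate(counts):
        cfg = cfg0.replace(
            seed=seed + j, nuclei=dataclasses.replace(cfg0.nuclei, count=count)
        )
        planes, gt = sd.generate_monolayer(cfg, "control")
        recs = assays.monolayer_assay(
            planes,
            thresholds={"DAPI": "auto", "CD31": 100.0},
            bg={
                cfg0.target_channel: ic.BackgroundModel(
                    "m", cfg0.target_channel, cfg0.channels.background
                )
            },
        )
        per_mm2 = next(r.raw_value for r in recs if r.metric == "nuclei_per_mm2")
        field_mm2 = (
            cfg.field_size_px[0] * cfg.field_size_px[1] * cfg.pixel_size_um**2 / 1e6
        )
        estimated = per_mm2 * field_mm2
        rows.append(
            {
                "true_count": count,
                "estimated_count": float(estimated),
                "agreement_pct": float(100 * (1 - abs(estimated - count) / count)),
            }
        )
    return pd.DataFrame(rows)


def gfp_decay_recovery(
    decay: float = 0.7,
    days: tuple[int, ...] = (0, 3, 7),
    n_series: int = 3,
    seed: int = 0,
    base_config: sd.GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Normalized integrated-GFP trajectories against the configured decay."""
    cfg0 = base_config or sd.GeneratorConfig()
    trajectories = []
    for i in range(n_series):
        cfg = cfg0.replace(
            seed=seed + i,
            timecourse=dataclasses.replace(cfg0.timecourse, gfp_decay=decay),
        )
        series, _ = sd.generate_timecourse(cfg, days, "control")
        bg = ic.compute_set_background(
            [ic.max_project(s, "GFP") for s in series.stacks], "tc"
        )
        recs = assays.timecourse_assay(series, bg=bg)
        trajectories.append(
            {r.day: r.normalized_value for r in recs if r.metric == "integrated_GFP"}
        )
    rows = []
    for k, day in enumerate(days):
        vals = [t[day] for t in trajectories]
        rows.append(
            {
                "day": day,
                "expected": decay**k,
                "recovered": float(np.mean(vals)),
                "n": n_series,
            }
        )
    return pd.DataFrame(rows)
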