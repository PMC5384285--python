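"""Seeded generators emulating the screen's wet-lab inputs, with ground
truth attached.

Three generators mirror the three kinds of raw data the pipeline consumes:

* replicate plate absorbances with multiplicative compound effects and a
  fixed coefficient of variation (the colorimetric viability tier);
* qPCR Ct values with additive cycle noise around a programmed true fold
  (the expression tiers);
* two-channel axon/myelin confocal stacks with a programmable myelinated
  fraction (the imaging tier).

Every generator is reproducible bit-for-bit given (params, seed), and emits
a :class:`SyntheticTruth` record of the parameters that generated the data
so recovery can be tested against ground truth. Default effect and noise
sizes mirror the magnitudes of the original screen's positive controls
(ER around 1.3-1.5 with a few-percent CV, detectable in triplicate).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .assay_io import Condition, CtMeasurement, GeneRole, PlateWell, WellRole
from .errors import ValidationError
from .remyelination_imaging import ImageStack

__all__ = [
    "PlateSimParams",
    "CtSimParams",
    "StackSimParams",
    "SyntheticTruth",
    "simulate_plate_experiment",
    "simulate_ct_experiment",
    "simulate_confocal_stack",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters emitted atomically with a simulated dataset."""

    kind: str
    values: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class PlateSimParams:
    n_compounds: int = 96
    frac_active: float = 0.1
    true_er_active: float = 1.5
    true_er_inactive: float = 1.0
    vehicle_mean: float = 0.5
    cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    # fixed active set (compound indices), e.g. to share truth across
    # replicate experiments; None -> drawn at random from frac_active
    active_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_replicates < 1:
            raise ValidationError("n_compounds and n_replicates must be >= 1")
        if not 0 <= self.frac_active <= 1:
            raise ValidationError("frac_active must be in [0, 1]")
        if self.cv < 0 or self.vehicle_mean <= 0:
            raise ValidationError("cv must be >= 0 and vehicle_mean > 0")
        if self.active_indices is not None and any(
            i < 0 or i >= self.n_compounds for i in self.active_indices
        ):
            raise ValidationError("active_indices out of range")


@dataclass(frozen=True)
class CtSimParams:
    true_fold: float = 4.0
    ct_sd: float = 0.2
    reference_ct: float = 15.0
    control_delta_ct: float = 5.0
    n_experiments: int = 3
    gene_name: str = "MBP"
    reference_gene: str = "GAPDH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fold <= 0:
            raise ValidationError("true_fold must be > 0")
        if self.ct_sd < 0 or self.n_experiments < 1:
            raise ValidationError("ct_sd must be >= 0 and n_experiments >= 1")


@dataclass(frozen=True)
class StackSimParams:
    layers: int = 5
    height: int = 256
    width: int = 256
    n_axons: int = 12
    axon_width: int = 3
    myelin_fraction: float = 0.4
    background_noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.myelin_fraction <= 1:
            raise ValidationError("myelin_fraction must be in [0, 1]")
        if min(self.layers, self.height, self.width, self.n_axons, self.axon_width) < 1:
            raise ValidationError("stack dimensions and axon parameters must be >= 1")
        if self.background_noise_sd < 0:
            raise ValidationError("background_noise_sd must be >= 0")


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    # physical absorbances are non-negative
    return np.clip(rng.normal(mean, sd, size=size), 0.0, None)


def simulate_plate_experiment(
    params: PlateSimParams,
) -> tuple[list[PlateWell], SyntheticTruth]:
    """Simulate one plate experiment run in replicates.

    Drug-well absorbance ~ Normal(vehicle_mean * true_er, cv * mean),
    truncated at zero; vehicle wells analogous with true_er = 1. A random
    ``frac_active`` subset of compounds carries the active effect size.
    """
    rng = np.random.default_rng(params.seed)
    if params.active_indices is not None:
        active_idx = set(params.active_indices)
    else:
        n_active = round(params.frac_active * params.n_compounds)
        active_idx = set(rng.choice(params.n_compounds, size=n_active, replace=False).tolist())

    plate_id = f"plate-{params.seed}"
    wells: list[PlateWell] = []
    true_er: dict[str, float] = {}

    vehicle_abs = _truncated_normal(
        rng, params.vehicle_mean, params.cv * params.vehicle_mean, params.n_replicates
    )
    for r, a in enumerate(vehicle_abs, start=1):
        wells.append(
            PlateWell(
                plate_id=plate_id,
                well=f"VEH{r:02d}",
                role=WellRole.VEHICLE,
                absorbance=float(a),
                replicate=r,
            )
        )

    for i in range(params.n_compounds):
        cid = f"C{i + 1:04d}"
        er = params.true_er_active if i in active_idx else params.true_er_inactive
        true_er[cid] = er
        mean = params.vehicle_mean * er
        drug_abs = _truncated_normal(rng, mean, params.cv * mean, params.n_replicates)
        for r, a in enumerate(drug_abs, start=1):
            wells.append(
                PlateWell(
                    plate_id=plate_id,
                    well=f"{cid}-{r}",
                    role=WellRole.DRUG,
                    compound_id=cid,
                    absorbance=float(a),
                    concentration_um=10.0,
                    replicate=r,
                )
            )

    truth = SyntheticTruth(
        kind="plate",
        values={
            "true_er": true_er,
            "active_ids": sorted(f"C{i + 1:04d}" for i in active_idx),
            "params": params,
        },
    )
    return wells, truth


def simulate_ct_experiment(
    params: CtSimParams,
) -> tuple[list[CtMeasurement], SyntheticTruth]:
    """Simulate paired treated/control Ct measurements over independent
    experiments.

    The treated target Ct sits ``log2(true_fold)`` cycles below the control
    target Ct; independent Normal(0, ct_sd) noise is added to every
    measurement.
    """
    rng = np.random.default_rng(params.seed)
    measurements: list[CtMeasurement] = []
    control_target_ct = params.reference_ct + params.control_delta_ct
    treated_target_ct = control_target_ct - math.log2(params.true_fold)

    for e in range(1, params.n_experiments + 1):
        exp = f"E{e}"
        noise = rng.normal(0.0, params.ct_sd, size=4)
        spec = [
            (f"{exp}-trt", Condition.TREATED, GeneRole.TARGET, params.gene_name, treated_target_ct + noise[0]),
            (f"{exp}-trt", Condition.TREATED, GeneRole.REFERENCE, params.reference_gene, params.reference_ct + noise[1]),
            (f"{exp}-ctl", Condition.CONTROL, GeneRole.TARGET, params.gene_name, control_target_ct + noise[2]),
            (f"{exp}-ctl", Condition.CONTROL, GeneRole.REFERENCE, params.reference_gene, params.reference_ct + noise[3]),
        ]
        for sample_id, condition, role, gene, ct in spec:
            measurements.append(
                CtMeasurement(
                    sample_id=sample_id,
                    condition=condition,
                    gene_role=role,
                    gene_name=gene,
                    ct=float(ct),
                    experiment_id=exp,
                )
            )

    truth = SyntheticTruth(kind="ct", values={"true_fold": params.true_fold, "params": params})
    return measurements, truth


def _axon_mask(rng: np.random.Generator, params: StackSimParams) -> np.ndarray:
    """Random smooth curves dilated to the axon width."""
    h, w = params.height, params.width
    mask = np.zeros((h, w), dtype=bool)
    n_steps = 2 * (h + w)
    for _ in range(params.n_axons):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            yi, xi = int(y), int(x)
            if 0 <= yi < h and 0 <= xi < w:
                mask[yi, xi] = True
            else:
                break
            angle += rng.normal(0.0, 0.15)
            y += math.sin(angle)
            x += math.cos(angle)
    radius = params.axon_width // 2
    if radius > 0:
        yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
        structure = yy**2 + xx**2 <= radius**2
        mask = ndimage.binary_dilation(mask, structure=structure)
    return mask


def simulate_confocal_stack(
    params: StackSimParams,
) -> tuple[ImageStack, SyntheticTruth]:
    """Simulate a two-channel (red = axons, green = myelin) uint8 z-stack.

    The red channel carries the axon curves at high intensity in every
    layer; in each layer an exactly ``round(f * n_axon_pixels)``-sized random
    subset of axon pixels carries the green signal, so the green mask is a
    subset of the red mask by construction. Background noise stays below the
    default fixed thresholds.
    """
    rng = np.random.default_rng(params.seed)
    axons = _axon_mask(rng, params)
    axon_idx = np.flatnonzero(axons)
    n_axon = axon_idx.size
    n_green = round(params.myelin_fraction * n_axon)

    shape = (params.layers, params.height, params.width)
    # background strictly below the default threshold of 100
    background = np.clip(
        np.abs(rng.normal(0.0, params.background_noise_sd, size=shape + (2,))), 0, 80
    )
    voxels = background.astype(np.float64)

    green_counts = []
    for layer in range(params.layers):
        red_intensity = np.clip(rng.normal(180, 15, size=n_axon), 130, 255)
        voxels[layer, ..., 0].flat[axon_idx] = red_intensity
        chosen = rng.choice(n_axon, size=n_green, replace=False) if n_green else np.array([], int)
        if chosen.size:
            green_intensity = np.clip(rng.normal(180, 15, size=chosen.size), 130, 255)
            voxels[layer, ..., 1].flat[axon_idx[chosen]] = green_intensity
        green_counts.append(int(chosen.size))

    stack = ImageStack(
        voxels=voxels.astype(np.uint8),
        channels={"red": 0, "green": 1},
        z_spacing_um=1.0,
    )
    truth = SyntheticTruth(
        kind="stack",
        values={
            "myelin_fraction": params.myelin_fraction,
            "axon_pixels": int(n_axon),
            "green_pixels_per_layer": green_counts,
            "params": params,
        },
    )
    return stack, truth
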