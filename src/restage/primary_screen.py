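"""Tier 1 of the screen: MTT efficacy ratios, assay quality, threshold
selection and retest confirmation.

The primary readout is the Efficacy Ratio (ER), the mean drug-well absorbance
divided by the mean vehicle-well absorbance of the same experiment. Compounds
whose ER clears a fixed threshold (default 1.3, chosen from the positive
controls' effect size) progress; primary positives are retested in 3-5
independent experiments and kept when their mean ER still clears it.

Threshold comparisons are made after rounding the ratio to the threshold's
printed precision (one decimal, half away from zero) so that a ratio printed
as 1.29 counts as 1.3; pass ``rounding_decimals=None`` for a strict
comparison.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .assay_io import PlateWell, WellRole
from .errors import ComputationError, ValidationError

__all__ = [
    "EfficacyRatio",
    "ScreenQuality",
    "ConfirmedHit",
    "efficacy_ratios",
    "z_factor",
    "z_factor_from_stats",
    "select_primary_hits",
    "confirm_hits",
    "confirm_hits_from_means",
    "round_half_away",
]


@dataclass(frozen=True)
class EfficacyRatio:
    compound_id: str
    er: float
    n_drug_wells: int
    n_vehicle_wells: int
    experiment_id: str


@dataclass(frozen=True)
class ScreenQuality:
    """Screening-window coefficient (Z-factor) and its ingredients."""

    z_factor: float
    mu_pos: float
    mu_neg: float
    sigma_pos: float
    sigma_neg: float


@dataclass(frozen=True)
class ConfirmedHit:
    compound_id: str
    mean_er: float
    n_experiments: int
    per_experiment_er: tuple[float, ...]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def efficacy_ratios(
    wells: Sequence[PlateWell], *, subtract_blank: bool = False
) -> list[EfficacyRatio]:
    """Compute one ER per (compound, experiment).

    Each plate is treated as one experiment; the denominator is the mean of
    that plate's vehicle wells (no cross-plate pooling). With
    ``subtract_blank`` the mean blank-well absorbance of the plate is
    subtracted from every absorbance first.
    """
    by_plate: dict[str, list[PlateWell]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)

    out: list[EfficacyRatio] = []
    for plate_id in sorted(by_plate):
        plate = by_plate[plate_id]
        blank = 0.0
        if subtract_blank:
            blanks = [w.absorbance for w in plate if w.role is WellRole.BLANK]
            blank = float(np.mean(blanks)) if blanks else 0.0
        vehicle = [w.absorbance - blank for w in plate if w.role is WellRole.VEHICLE]
        if not vehicle:
            raise ComputationError(f"plate {plate_id}: no vehicle wells")
        vehicle_mean = float(np.mean(vehicle))
        if vehicle_mean == 0:
            raise ComputationError(f"plate {plate_id}: vehicle mean is zero")

        by_compound: dict[str, list[float]] = {}
        for w in plate:
            if w.role is WellRole.DRUG:
                by_compound.setdefault(w.compound_id, []).append(w.absorbance - blank)
        for cid in sorted(by_compound):
            drug = by_compound[cid]
            out.append(
                EfficacyRatio(
                    compound_id=cid,
                    er=float(np.mean(drug)) / vehicle_mean,
                    n_drug_wells=len(drug),
                    n_vehicle_wells=len(vehicle),
                    experiment_id=plate_id,
                )
            )
    return out


def z_factor_from_stats(
    mu_pos: float, sigma_pos: float, mu_neg: float, sigma_neg: float
) -> ScreenQuality:
    """Z-factor from summary statistics: ``1 - 3(s+ + s-)/|m+ - m-|``."""
    if mu_pos == mu_neg:
        raise ComputationError("Z-factor undefined: control means are equal")
    z = 1.0 - 3.0 * (sigma_pos + sigma_neg) / abs(mu_pos - mu_neg)
    return ScreenQuality(z, mu_pos, mu_neg, sigma_pos, sigma_neg)


def z_factor(pos: Sequence[float], neg: Sequence[float]) -> ScreenQuality:
    """Z-factor from raw positive/negative control absorbances (sample sd)."""
    if len(pos) < 2 or len(neg) < 2:
        raise ComputationError("Z-factor needs at least 2 values per control group")
    pos_arr, neg_arr = np.asarray(pos, float), np.asarray(neg, float)
    return z_factor_from_stats(
        float(pos_arr.mean()),
        float(pos_arr.std(ddof=1)),
        float(neg_arr.mean()),
        float(neg_arr.std(ddof=1)),
    )


def _passes(er: float, threshold: float, rounding_decimals: Optional[int]) -> bool:
    if rounding_decimals is None:
        return er >= threshold
    return round_half_away(er, rounding_decimals) >= threshold


def select_primary_hits(
    ers: Iterable[EfficacyRatio],
    threshold: float = 1.3,
    *,
    rounding_decimals: Optional[int] = 1,
) -> list[str]:
    """Compound ids whose ER clears ``threshold``, in descending-ER order
    (ties broken by id)."""
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    passing = [e for e in ers if _passes(e.er, threshold, rounding_decimals)]
    passing.sort(key=lambda e: (-e.er, e.compound_id))
    return [e.compound_id for e in passing]


def confirm_hits(
    replicates: Mapping[str, Sequence[EfficacyRatio]],
    threshold: float = 1.3,
    min_experiments: int = 3,
    *,
    rounding_decimals: Optional[int] = 1,
) -> list[ConfirmedHit]:
    """Retest confirmation: keep compounds whose mean ER over independent
    experiments clears the threshold.

    Compounds with fewer than ``min_experiments`` replicate experiments are
    excluded with a warning rather than silently judged on thin data.
    """
    confirmed: list[ConfirmedHit] = []
    for cid in sorted(replicates):
        ers = tuple(e.er for e in replicates[cid])
        if len(ers) < min_experiments:
            warnings.warn(
                f"compound {cid}: only {len(ers)} experiments (< {min_experiments}); excluded",
                stacklevel=2,
            )
            continue
        mean_er = float(np.mean(ers))
        if _passes(mean_er, threshold, rounding_decimals):
            confirmed.append(ConfirmedHit(cid, mean_er, len(ers), ers))
    confirmed.sort(key=lambda h: (-h.mean_er, h.compound_id))
    return confirmed


def confirm_hits_from_means(
    mean_er_by_compound: Mapping[str, float],
    threshold: float = 1.3,
    *,
    rounding_decimals: Optional[int] = 1,
) -> list[str]:
    """Apply the confirmation rule to already-averaged ERs (e.g. a published
    summary table); returns passing compound names sorted by descending mean."""
    passing = [
        (name, er)
        for name, er in mean_er_by_compound.items()
        if _passes(er, threshold, rounding_decimals)
    ]
    passing.sort(key=lambda t: (-t[1], t[0]))
    return [name for name, _ in passing]
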