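"""Weighted multi-assay scoring and ranking (tier 2 of the screen).

Each confirmed compound carries three raw fold values measured in purified
OPC cultures: thymidine-incorporation proliferation, and 2^-ddCt expression
folds for the early (CGT) and late (MBP) differentiation markers. Each raw
value is multiplied by its assay weight and the three contributions are
summed:

    total = 10 * prolif + 3 * cgt + 5 * mbp

Differentiation is rewarded over proliferation (remyelination typically
fails at the late stages of precursor development), and the late marker over
the early one. The MTT weight (1) exists in the weight vector but the
viability assay acts only as the tier-1 pass/fail gate: it contributes no
term to the total. Compounds whose total exceeds the selection threshold
(strictly greater than 100 by default) progress to the next tier.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assay_io import PaperFixture, load_paper_fixture
from .errors import ComputationError, ValidationError

__all__ = [
    "ScoreWeights",
    "AssayRaws",
    "ScoredCompound",
    "score_contribution",
    "total_score",
    "rank_and_select",
    "raws_from_table2",
]

DEFAULT_SELECTION_THRESHOLD = 100.0


@dataclass(frozen=True)
class ScoreWeights:
    """Per-assay score multipliers."""

    w_mtt: float = 1.0
    w_prolif: float = 10.0
    w_cgt: float = 3.0
    w_mbp: float = 5.0

    def __post_init__(self) -> None:
        if min(self.w_mtt, self.w_prolif, self.w_cgt, self.w_mbp) < 0:
            raise ValidationError("score weights must be >= 0")


@dataclass(frozen=True)
class AssayRaws:
    """Raw per-assay fold values for one compound."""

    compound_id: str
    prolif_raw: float
    cgt_raw: float
    mbp_raw: float
    prolif_se: Optional[float] = None
    cgt_se: Optional[float] = None
    mbp_se: Optional[float] = None

    def __post_init__(self) -> None:
        for label, v in (
            ("prolif_raw", self.prolif_raw),
            ("cgt_raw", self.cgt_raw),
            ("mbp_raw", self.mbp_raw),
        ):
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{self.compound_id}: {label} must be finite and >= 0, got {v}"
                )


@dataclass(frozen=True)
class ScoredCompound:
    compound_id: str
    prolif_total: float
    cgt_total: float
    mbp_total: float
    total_score: float


def score_contribution(raw: float, weight: float) -> float:
    """One assay's contribution to the total: raw fold times assay weight."""
    if raw < 0 or weight < 0:
        raise ValidationError("raw value and weight must be >= 0")
    return raw * weight


def total_score(raws: AssayRaws, weights: ScoreWeights = ScoreWeights()) -> ScoredCompound:
    """Weighted total over the three scored assays (MTT excluded by design)."""
    prolif = score_contribution(raws.prolif_raw, weights.w_prolif)
    cgt = score_contribution(raws.cgt_raw, weights.w_cgt)
    mbp = score_contribution(raws.mbp_raw, weights.w_mbp)
    return ScoredCompound(
        compound_id=raws.compound_id,
        prolif_total=prolif,
        cgt_total=cgt,
        mbp_total=mbp,
        total_score=prolif + cgt + mbp,
    )


def rank_and_select(
    scored: Sequence[ScoredCompound],
    selection_threshold: float = DEFAULT_SELECTION_THRESHOLD,
    *,
    strict: bool = True,
) -> tuple[list[ScoredCompound], list[ScoredCompound]]:
    """Rank by descending total (ties alphabetical by id) and select the
    compounds above the threshold (strict ``>`` by default)."""
    if not scored:
        raise ComputationError("cannot rank an empty list")
    ranked = sorted(scored, key=lambda s: (-s.total_score, s.compound_id))
    if strict:
        selected = [s for s in ranked if s.total_score > selection_threshold]
    else:
        selected = [s for s in ranked if s.total_score >= selection_threshold]
    return ranked, selected


def raws_from_table2(fixture: PaperFixture | pd.DataFrame | None = None) -> list[AssayRaws]:
    """Build :class:`AssayRaws` from the packaged raw score table (compound
    rows only; positive-control rows are not scored)."""
    if fixture is None:
        fixture = load_paper_fixture("table2")
    df = fixture.rows if isinstance(fixture, PaperFixture) else fixture
    out: list[AssayRaws] = []
    for _, row in df[df["role"] == "compound"].iterrows():
        out.append(
            AssayRaws(
                compound_id=row["compound"],
                prolif_raw=float(row["prolif_raw"]),
                cgt_raw=float(row["cgt_raw"]),
                mbp_raw=float(row["mbp_raw"]),
                prolif_se=None if pd.isna(row["prolif_se"]) else float(row["prolif_se"]),
                cgt_se=None if pd.isna(row["cgt_se"]) else float(row["cgt_se"]),
                mbp_se=None if pd.isna(row["mbp_se"]) else float(row["mbp_se"]),
            )
        )
    return out
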