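"""Orchestration of the staged screen.

Five tiers run in sequence, each consuming only the previous tier's
survivors:

1. ``mtt`` — viability/metabolic screen; efficacy-ratio threshold with
   retest confirmation.
2. ``opc_score`` — weighted multi-assay scoring in purified OPC cultures;
   total score above the selection threshold.
3. ``mixed_glia`` — significance gate requiring both differentiation
   markers (MBP and CGT) up-regulated at the chosen alpha.
4. ``slice_myelination`` — developing-slice gate on MBP alone.
5. ``slice_remyelination`` — demyelinated-slice gate on MBP alone, with the
   confocal co-localization index reported for the final survivors.

Two significance profiles are first-class: ``strict`` (alpha = 0.05) and
``reproduction`` (alpha = 0.055, matching the published table's flagging of
p = 0.051 and p = 0.0532 as significant). No multiple-testing correction is
applied at any tier.

The pipeline runs either on the packaged fixture tables (tiers 1-3; the
later tiers' per-experiment data were never published) or fully on
synthetic data with known ground truth.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import synthetic_data as sd
from .assay_io import load_paper_fixture, fixture_checksum, normalize_compound_name
from .errors import ComputationError, ValidationError
from .expression_quant import fold_change_ddct, one_sample_fold_test
from .primary_screen import EfficacyRatio, confirm_hits, confirm_hits_from_means, efficacy_ratios
from .remyelination_imaging import ColocParams, condition_index, stack_index
from .tier_scoring import AssayRaws, ScoreWeights, rank_and_select, raws_from_table2, total_score

__all__ = [
    "Tier",
    "GeneGateResult",
    "TierResult",
    "PipelineConfig",
    "PipelineReport",
    "tier_gate",
    "run_pipeline",
    "write_report",
    "read_report_survivors",
]


class Tier(str, Enum):
    MTT = "mtt"
    OPC_SCORE = "opc_score"
    MIXED_GLIA = "mixed_glia"
    SLICE_MYELINATION = "slice_myelination"
    SLICE_REMYELINATION = "slice_remyelination"


@dataclass(frozen=True)
class GeneGateResult:
    """Per-compound p-values for the genes a significance tier inspects."""

    compound_id: str
    p_values: Mapping[str, float]


@dataclass
class TierResult:
    tier: Tier
    n_in: int
    survivors: list[str]
    details: dict = field(default_factory=dict)
    skipped: bool = False
    notice: str = ""


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    ``profile`` selects the significance rule: ``strict`` gates at
    alpha = 0.05, ``reproduction`` at 0.055. ``mode`` selects fixture-backed
    (published tables, tiers 1-3) or fully synthetic inputs.
    """

    mode: str = "synthetic"  # "synthetic" | "fixture"
    profile: str = "strict"  # "strict" | "reproduction"
    seed: int = 0
    er_threshold: float = 1.3
    rounding_decimals: Optional[int] = 1
    score_threshold: float = 100.0
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    # synthetic-mode sizes
    n_compounds: int = 40
    frac_active: float = 0.1
    n_confirm_experiments: int = 3
    n_gate_experiments: int = 4
    ct_sd: float = 0.15
    cv: float = 0.05
    # synthetic true effect sizes for active compounds, per tier
    true_er_active: float = 1.5
    true_prolif_fold: float = 3.0
    true_cgt_fold: float = 8.0
    true_mbp_fold: float = 30.0
    gate_mbp_fold: float = 3.5
    gate_cgt_fold: float = 2.5
    slice_mbp_fold: float = 3.0
    remyelin_fraction_active: float = 0.45
    remyelin_fraction_control: float = 0.15
    imaging_size: int = 64
    n_stacks_per_condition: int = 3

    @property
    def alpha(self) -> float:
        if self.profile == "strict":
            return 0.05
        if self.profile == "reproduction":
            return 0.055
        raise ValidationError(f"unknown profile {self.profile!r}")


@dataclass
class PipelineReport:
    parameters: dict
    tiers: list[TierResult]
    provenance: dict

    def survivor_chain(self) -> list[list[str]]:
        return [t.survivors for t in self.tiers if not t.skipped]

    def as_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "tiers": [
                {
                    "tier": t.tier.value,
                    "n_in": t.n_in,
                    "n_survivors": len(t.survivors),
                    "survivors": t.survivors,
                    "details": t.details,
                    "skipped": t.skipped,
                    "notice": t.notice,
                }
                for t in self.tiers
            ],
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, indent=2)


def tier_gate(
    results: Sequence[GeneGateResult],
    alpha: float = 0.05,
    require_both_genes: bool = True,
    genes: Sequence[str] = ("MBP", "CGT"),
) -> list[str]:
    """Survivors of a significance tier.

    A compound survives when p <= alpha for *both* listed genes
    (``require_both_genes=True``, the mixed-glia rule) or for the first
    listed gene alone (the slice-tier rule, MBP only). A compound missing a
    required p-value is discarded with a warning.
    """
    required = list(genes) if require_both_genes else [genes[0]]
    survivors = []
    for r in results:
        missing = [g for g in required if g not in r.p_values]
        if missing:
            warnings.warn(
                f"compound {r.compound_id}: missing p-value for {missing}; discarded",
                stacklevel=2,
            )
            continue
        if all(r.p_values[g] <= alpha for g in required):
            survivors.append(r.compound_id)
    return sorted(survivors)


# ---------------------------------------------------------------------------
# fixture-backed run (tiers 1-3; later tiers were never published per-experiment)


def _fixture_tiers(config: PipelineConfig) -> list[TierResult]:
    t1 = load_paper_fixture("table1")
    t2 = load_paper_fixture("table2")
    t3 = load_paper_fixture("table3")

    # Tier 1: confirmation rule on the published mean ERs. The internal
    # control (lovastatin, mean ER 1.23) fails the rule but is carried
    # forward by design as the screen's internal control.
    means = {
        normalize_compound_name(row["compound"]): float(row["average_er"])
        for _, row in t1.rows.iterrows()
    }
    internal_control = "LOVASTATIN"
    confirmed = confirm_hits_from_means(
        {k: v for k, v in means.items() if k != internal_control},
        threshold=config.er_threshold,
        rounding_decimals=config.rounding_decimals,
    )
    tier1 = TierResult(
        tier=Tier.MTT,
        n_in=len(means),
        survivors=sorted(confirmed) + [internal_control],
        details={"n_confirmed": len(confirmed), "internal_control": internal_control},
    )

    # Tier 2: weighted scoring of the raw assay table.
    raws = raws_from_table2(t2)
    scored = [total_score(r, config.weights) for r in raws]
    ranked, selected = rank_and_select(scored, config.score_threshold)
    tier2 = TierResult(
        tier=Tier.OPC_SCORE,
        n_in=len(scored),
        survivors=sorted(normalize_compound_name(s.compound_id) for s in selected),
        details={
            "top_ranked": ranked[0].compound_id,
            "scores": {s.compound_id: round(s.total_score, 2) for s in ranked},
        },
    )

    # Tier 3: dual-gene significance gate on the published p-values.
    gate_inputs = [
        GeneGateResult(
            compound_id=normalize_compound_name(row["compound"]),
            p_values={"MBP": float(row["mbp_p"]), "CGT": float(row["cgt_p"])},
        )
        for _, row in t3.rows.iterrows()
        if row["role"] == "compound"
    ]
    tier3 = TierResult(
        tier=Tier.MIXED_GLIA,
        n_in=len(gate_inputs),
        survivors=tier_gate(gate_inputs, alpha=config.alpha, require_both_genes=True),
        details={"alpha": config.alpha},
    )

    skipped = [
        TierResult(
            tier=t,
            n_in=0,
            survivors=[],
            skipped=True,
            notice="per-experiment inputs not published; tier skipped",
        )
        for t in (Tier.SLICE_MYELINATION, Tier.SLICE_REMYELINATION)
    ]
    return [tier1, tier2, tier3, *skipped]


# ---------------------------------------------------------------------------
# synthetic run (all five tiers, ground truth known)


def _child_seed(base: int, k: int) -> int:
    return (base * 1_000 + k) % (2**31 - 1)


def _simulate_gate_pvalues(
    config: PipelineConfig,
    compounds: Sequence[str],
    active: set[str],
    genes_folds: Mapping[str, tuple[float, float]],
    seed: int,
) -> list[GeneGateResult]:
    """Per-compound p-values from simulated ddCt experiments.

    ``genes_folds`` maps gene -> (active_fold, inactive_fold).
    """
    results = []
    for i, cid in enumerate(compounds):
        p_values = {}
        for j, (gene, (fold_a, fold_i)) in enumerate(sorted(genes_folds.items())):
            params = sd.CtSimParams(
                true_fold=fold_a if cid in active else fold_i,
                ct_sd=config.ct_sd,
                n_experiments=config.n_gate_experiments,
                gene_name=gene,
                seed=_child_seed(seed, i * 10 + j),
            )
            measurements, _ = sd.simulate_ct_experiment(params)
            folds = [
                fold_change_ddct(measurements, f"E{e}-trt", f"E{e}-ctl", f"E{e}").fold
                for e in range(1, params.n_experiments + 1)
            ]
            p_values[gene] = one_sample_fold_test(folds).p_value
        results.append(GeneGateResult(cid, p_values))
    return results


def _synthetic_tiers(config: PipelineConfig) -> list[TierResult]:
    base = config.seed
    rng = np.random.default_rng(_child_seed(base, 1))
    n_active = round(config.frac_active * config.n_compounds)
    active_indices = tuple(
        sorted(rng.choice(config.n_compounds, size=n_active, replace=False).tolist())
    )
    active_ids = {f"C{i + 1:04d}" for i in active_indices}

    # Tier 1: replicate plate experiments with a shared active set.
    per_compound: dict[str, list[EfficacyRatio]] = {}
    for e in range(config.n_confirm_experiments):
        params = sd.PlateSimParams(
            n_compounds=config.n_compounds,
            frac_active=config.frac_active,
            true_er_active=config.true_er_active,
            cv=config.cv,
            seed=_child_seed(base, 100 + e),
            active_indices=active_indices,
        )
        wells, _ = sd.simulate_plate_experiment(params)
        for er in efficacy_ratios(wells):
            per_compound.setdefault(er.compound_id, []).append(er)
    confirmed = confirm_hits(
        per_compound,
        threshold=config.er_threshold,
        min_experiments=config.n_confirm_experiments,
        rounding_decimals=config.rounding_decimals,
    )
    tier1 = TierResult(
        tier=Tier.MTT,
        n_in=config.n_compounds,
        survivors=sorted(h.compound_id for h in confirmed),
        details={"true_actives": sorted(active_ids)},
    )

    # Tier 2: weighted scoring from simulated assay folds.
    scored = []
    for i, cid in enumerate(tier1.survivors):
        is_active = cid in active_ids
        folds = {}
        for j, (gene, fold_a) in enumerate(
            (("CGT", config.true_cgt_fold), ("MBP", config.true_mbp_fold))
        ):
            params = sd.CtSimParams(
                true_fold=fold_a if is_active else 1.0,
                ct_sd=config.ct_sd,
                n_experiments=config.n_gate_experiments,
                gene_name=gene,
                seed=_child_seed(base, 200 + i * 10 + j),
            )
            measurements, _ = sd.simulate_ct_experiment(params)
            per_exp = [
                fold_change_ddct(measurements, f"E{e}-trt", f"E{e}-ctl", f"E{e}").fold
                for e in range(1, params.n_experiments + 1)
            ]
            folds[gene] = float(np.mean(per_exp))
        prolif_true = config.true_prolif_fold if is_active else 1.0
        prolif_rng = np.random.default_rng(_child_seed(base, 250 + i))
        prolif = max(0.0, float(prolif_rng.normal(prolif_true, config.ct_sd * prolif_true)))
        scored.append(
            total_score(
                AssayRaws(cid, prolif_raw=prolif, cgt_raw=folds["CGT"], mbp_raw=folds["MBP"]),
                config.weights,
            )
        )
    if scored:
        ranked, selected = rank_and_select(scored, config.score_threshold)
        tier2_survivors = sorted(s.compound_id for s in selected)
        tier2_details = {"scores": {s.compound_id: round(s.total_score, 3) for s in ranked}}
    else:
        tier2_survivors, tier2_details = [], {}
    tier2 = TierResult(
        tier=Tier.OPC_SCORE, n_in=len(tier1.survivors), survivors=tier2_survivors,
        details=tier2_details,
    )

    # Tier 3: mixed glia, both genes must clear alpha.
    gate3 = _simulate_gate_pvalues(
        config,
        tier2.survivors,
        active_ids,
        {"MBP": (config.gate_mbp_fold, 1.0), "CGT": (config.gate_cgt_fold, 1.0)},
        seed=_child_seed(base, 300),
    )
    tier3 = TierResult(
        tier=Tier.MIXED_GLIA,
        n_in=len(tier2.survivors),
        survivors=tier_gate(gate3, alpha=config.alpha, require_both_genes=True),
        details={"p_values": {g.compound_id: dict(g.p_values) for g in gate3}},
    )

    # Tier 4: developing slices, MBP alone.
    gate4 = _simulate_gate_pvalues(
        config, tier3.survivors, active_ids,
        {"MBP": (config.slice_mbp_fold, 1.0)}, seed=_child_seed(base, 400),
    )
    tier4 = TierResult(
        tier=Tier.SLICE_MYELINATION,
        n_in=len(tier3.survivors),
        survivors=tier_gate(gate4, alpha=config.alpha, require_both_genes=False, genes=("MBP",)),
        details={"p_values": {g.compound_id: dict(g.p_values) for g in gate4}},
    )

    # Tier 5: demyelinated slices, MBP alone, plus the imaging index for
    # the final survivors.
    gate5 = _simulate_gate_pvalues(
        config, tier4.survivors, active_ids,
        {"MBP": (config.slice_mbp_fold, 1.0)}, seed=_child_seed(base, 500),
    )
    tier5_survivors = tier_gate(
        gate5, alpha=config.alpha, require_both_genes=False, genes=("MBP",)
    )
    imaging: dict[str, dict] = {}
    coloc = ColocParams()
    control_stacks = [
        stack_index(
            sd.simulate_confocal_stack(
                sd.StackSimParams(
                    height=config.imaging_size,
                    width=config.imaging_size,
                    myelin_fraction=config.remyelin_fraction_control,
                    seed=_child_seed(base, 600 + s),
                )
            )[0],
            coloc,
        )
        for s in range(config.n_stacks_per_condition)
    ]
    control = condition_index("control", control_stacks)
    for i, cid in enumerate(tier5_survivors):
        stacks = [
            stack_index(
                sd.simulate_confocal_stack(
                    sd.StackSimParams(
                        height=config.imaging_size,
                        width=config.imaging_size,
                        myelin_fraction=config.remyelin_fraction_active
                        if cid in active_ids
                        else config.remyelin_fraction_control,
                        seed=_child_seed(base, 700 + i * 10 + s),
                    )
                )[0],
                coloc,
            )
            for s in range(config.n_stacks_per_condition)
        ]
        ci = condition_index(cid, stacks, control=control)
        imaging[cid] = {
            "mean_index": round(ci.mean, 4),
            "sem": round(ci.sem, 4),
            "relative_index": round(ci.relative_index, 4) if ci.relative_index else None,
        }
    tier5 = TierResult(
        tier=Tier.SLICE_REMYELINATION,
        n_in=len(tier4.survivors),
        survivors=tier5_survivors,
        details={
            "p_values": {g.compound_id: dict(g.p_values) for g in gate5},
            "remyelination_index": imaging,
            "control_index": round(control.mean, 4),
        },
    )
    return [tier1, tier2, tier3, tier4, tier5]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the tier cascade and return a structured, deterministic report.

    The survivor lists are nested by construction: each tier only sees the
    previous tier's survivors.
    """
    if config.mode == "fixture":
        tiers = _fixture_tiers(config)
        provenance = {
            "seed": config.seed,
            "fixture_checksums": {n: fixture_checksum(n) for n in ("table1", "table2", "table3")},
        }
    elif config.mode == "synthetic":
        tiers = _synthetic_tiers(config)
        provenance = {"seed": config.seed}
    else:
        raise ValidationError(f"unknown pipeline mode {config.mode!r}")
    if not tiers:
        raise ComputationError("pipeline produced no tiers")

    params = asdict(config)
    params["alpha"] = config.alpha
    return PipelineReport(parameters=params, tiers=tiers, provenance=provenance)


_MACHINE_MARKER = "## machine-readable (JSON)"


def write_report(report: PipelineReport, path) -> None:
    """Write a human-readable summary followed by a machine-readable JSON
    section; byte-identical across runs with identical inputs and seed."""
    lines = ["# staged screen report", ""]
    for t in report.tiers:
        if t.skipped:
            lines.append(f"tier {t.tier.value}: SKIPPED ({t.notice})")
        else:
            lines.append(
                f"tier {t.tier.value}: {t.n_in} in -> {len(t.survivors)} survivors"
            )
    lines += ["", _MACHINE_MARKER, report.to_json(), ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_report_survivors(path) -> list[list[str]]:
    """Recover the per-tier survivor lists from a written report."""
    text = Path(path).read_text(encoding="utf-8")
    payload = json.loads(text.split(_MACHINE_MARKER, 1)[1])
    return [t["survivors"] for t in payload["tiers"] if not t["skipped"]]


def report_checksum(report: PipelineReport) -> str:
    return hashlib.sha256(report.to_json().encode()).hexdigest()
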