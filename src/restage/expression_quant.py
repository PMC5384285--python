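"""Relative expression quantification (2^-ddCt) and the paired-test
machinery used by every significance-gated tier.

The fold change of a target transcript in a treated sample relative to a
control sample, both normalized to a reference gene (GAPDH in the original
screen), is

    dCt   = Ct_target - Ct_reference          (per sample)
    ddCt  = dCt_treated - dCt_control
    fold  = 2 ** (-ddCt)

Amplification efficiency is fixed at exact doubling; replicate Ct values
within a sample are averaged before dCt.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .assay_io import Condition, CtMeasurement, GeneRole
from .errors import ComputationError, DegenerateVarianceError, PairingError

__all__ = [
    "FoldChange",
    "PairedTestResult",
    "FoldSummary",
    "fold_change_ddct",
    "paired_t_test",
    "one_sample_fold_test",
    "summarize_folds",
]


@dataclass(frozen=True)
class FoldChange:
    sample_id: str
    gene_name: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    fold: float
    experiment_id: str = "E1"


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    df: int
    p_value: float
    n_pairs: int
    mean_diff: float


@dataclass(frozen=True)
class FoldSummary:
    mean_fold: float
    sem: float
    n: int
    single_observation: bool = False


def _mean_ct(
    measurements: Sequence[CtMeasurement],
    sample_id: str,
    condition: Condition,
    gene_role: GeneRole,
) -> tuple[float, str]:
    """Average replicate Ct values for one (sample, condition, role) cell."""
    vals = [
        m.ct
        for m in measurements
        if m.sample_id == sample_id and m.condition is condition and m.gene_role is gene_role
    ]
    genes = {
        m.gene_name
        for m in measurements
        if m.sample_id == sample_id and m.condition is condition and m.gene_role is gene_role
    }
    if not vals:
        raise PairingError(
            f"sample '{sample_id}' ({condition.value}) lacks a {gene_role.value} Ct measurement"
        )
    if len(genes) > 1:
        raise PairingError(
            f"sample '{sample_id}' ({condition.value}) has {gene_role.value} Cts for "
            f"multiple genes {sorted(genes)}; split the input per gene"
        )
    return float(np.mean(vals)), genes.pop()


def fold_change_ddct(
    measurements: Sequence[CtMeasurement],
    treated_sample: str,
    control_sample: str,
    experiment_id: str = "E1",
) -> FoldChange:
    """Compute the 2^-ddCt fold change of the target gene, treated vs control."""
    subset = [m for m in measurements if m.experiment_id == experiment_id]
    if not subset:
        subset = list(measurements)
    ct_t_target, gene = _mean_ct(subset, treated_sample, Condition.TREATED, GeneRole.TARGET)
    ct_t_ref, _ = _mean_ct(subset, treated_sample, Condition.TREATED, GeneRole.REFERENCE)
    ct_c_target, _ = _mean_ct(subset, control_sample, Condition.CONTROL, GeneRole.TARGET)
    ct_c_ref, _ = _mean_ct(subset, control_sample, Condition.CONTROL, GeneRole.REFERENCE)

    d_treated = ct_t_target - ct_t_ref
    d_control = ct_c_target - ct_c_ref
    ddct = d_treated - d_control
    return FoldChange(
        sample_id=treated_sample,
        gene_name=gene,
        delta_ct_treated=d_treated,
        delta_ct_control=d_control,
        delta_delta_ct=ddct,
        fold=float(2.0 ** (-ddct)),
        experiment_id=experiment_id,
    )


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Classical two-sided paired Student's t-test on positional pairs.

    Raises :class:`DegenerateVarianceError` when the paired differences have
    zero spread (including the all-identical case), where the statistic is
    undefined, rather than reporting a spurious p-value.
    """
    x_arr = np.asarray(x, float)
    y_arr = np.asarray(y, float)
    if x_arr.shape != y_arr.shape:
        raise ComputationError("paired test requires equal-length inputs")
    n = x_arr.size
    if n < 2:
        raise ComputationError("paired test requires n >= 2 pairs")
    diffs = x_arr - y_arr
    if float(diffs.std(ddof=1)) == 0.0:
        raise DegenerateVarianceError("paired differences have zero spread; t undefined")
    res = stats.ttest_rel(x_arr, y_arr)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        df=n - 1,
        p_value=float(res.pvalue),
        n_pairs=n,
        mean_diff=float(diffs.mean()),
    )


def one_sample_fold_test(folds: Sequence[float], null_fold: float = 1.0) -> PairedTestResult:
    """Test whether replicate fold changes differ from the no-effect value.

    Equivalent to a paired t-test of the treated measurement against its own
    control (each experiment contributes one fold), which is how per-compound
    significance is gated across tiers.
    """
    folds = list(folds)
    return paired_t_test(folds, [null_fold] * len(folds))


def summarize_folds(folds: Sequence[float | FoldChange]) -> FoldSummary:
    """Mean +/- SEM of fold values. With n=1 the SEM is reported as 0 and the
    summary flagged, keeping aggregation total over singleton measurements."""
    values = np.asarray(
        [f.fold if isinstance(f, FoldChange) else float(f) for f in folds], float
    )
    if values.size == 0:
        raise ComputationError("cannot summarize an empty list of folds")
    if values.size == 1:
        warnings.warn("summarizing a single fold: SEM reported as 0", stacklevel=2)
        return FoldSummary(float(values[0]), 0.0, 1, single_observation=True)
    sem = float(values.std(ddof=1) / np.sqrt(values.size))
    return FoldSummary(float(values.mean()), sem, int(values.size))
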