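# Methods

## The staged screen

`restage` models a multi-tiered phenotypic screen for remyelinating drug
candidates as a cascade of five analysis tiers, each consuming only the
survivors of the previous one. The tiers, their readouts and their pass
rules are:

| tier | readout | rule |
|---|---|---|
| `mtt` | efficacy ratio (ER) of metabolic activity | mean ER ≥ 1.3 over ≥ 3 experiments |
| `opc_score` | weighted multi-assay total score | total > 100 (strict) |
| `mixed_glia` | 2^−ΔΔCt folds for MBP *and* CGT | paired t-test, p ≤ α for both genes |
| `slice_myelination` | MBP fold in developing slices | p ≤ α for MBP alone |
| `slice_remyelination` | MBP fold in demyelinated slices | p ≤ α for MBP alone; co-localization index reported |

Survivor lists are nested by construction, and a report (human-readable
text plus a machine-readable JSON section) is emitted deterministically for
a given seed.

## Efficacy ratio and threshold precision

ER is computed per (compound, experiment) against that experiment's own
vehicle mean; there is no cross-plate pooling, so the statistic is invariant
to rescaling all absorbances of an experiment. Optional blank subtraction
(off by default) removes the mean blank-well absorbance first.

Threshold comparisons round the ratio to the threshold's printed precision
— one decimal, half away from zero — before comparing, so a compound whose
mean ER prints as 1.29 is counted as 1.3. This choice reconciles the
published confirmation list (which contains a 1.29 entry) with its stated
count of 42 confirmed compounds; a strict comparison is available by
passing `rounding_decimals=None`. The internal control lovastatin
(mean ER 1.23) fails the rule and is carried forward explicitly as a
control, never through the rule itself.

The Z-factor uses the standard screening-window coefficient
1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with sample standard deviations (ddof = 1) when
computed from raw control wells; a summary-statistics closed form is also
exposed. It is undefined for equal control means and errors rather than
returning a sentinel.

## Relative quantification and significance gating

Fold changes use the exact-doubling 2^−ΔΔCt model (no efficiency
correction; no multi-reference normalization). Replicate Ct values within a
(sample, gene) cell are averaged before ΔCt. Two useful invariants follow
and are tested: adding a constant to all four Ct values leaves the fold
unchanged, and swapping treated/control gives the reciprocal fold.

Per-compound significance is assessed on fold values across experiments: a
paired Student's t-test of the per-experiment folds against the no-effect
value 1 (equivalent to pairing each treated measurement with its own
control). The test is two-sided with df = n − 1; a zero-spread difference
vector raises a degenerate-variance error instead of reporting p = 0.
No multiple-testing correction is applied at any tier — a deliberate
fidelity choice, not a statistical recommendation.

Two significance profiles are first-class: `strict` (α = 0.05) and
`reproduction` (α = 0.055). The published mixed-glia table flags p = 0.051
and p = 0.0532 as significant while stating five dual-gene survivors; the
strict rule would keep only three. The `reproduction` profile encodes the
comparison the published table actually made; `strict` is the default for
new data.

## Weighted scoring

The total score is linear in the raw folds: 10·prolif + 3·CGT + 5·MBP.
Differentiation is weighted above proliferation (remyelination typically
fails at late precursor development), and the late marker (MBP, weight 5)
above the early one (CGT, weight 3); proliferation's weight of 10
compensates its smaller dynamic range. The MTT weight of 1 is carried in
the weight vector for completeness but contributes no term: the viability
assay acts purely as the tier-1 gate, and every published total equals the
sum of the three non-MTT contributions. Selection is strictly greater than
the threshold (100), ties rank alphabetically.

Recomputing totals from the packaged two-decimal raws reproduces the
published totals within ±0.1; the residual discrepancies (e.g. 354.67
recomputed vs 354.65 printed) show the original totals were computed from
unrounded raws, which are not recoverable. Tests and the acceptance script
therefore use the ±0.1 band.

## Remyelination index

A pixel co-localizes when both the green (MBP) and red (NFH) intensities
exceed their thresholds; the per-layer index is |coloc| / |NFH⁺|, which is
bounded in [0, 1] because the co-localization mask is the intersection of
the two channel masks. The published description samples "yellow" on an
RGB overlay via a palette-matching step; the dual-threshold AND mask is
that step's effect on the overlay and is implemented directly.

Choices where the source procedure is silent:

* **Thresholds** — "above a defined intensity" with no value given.
  Default here is per-channel, per-layer Otsu (parameter-free); fixed
  thresholds are available and are used wherever exact reproducibility
  matters. Otsu is unreliable when a channel has no true signal (it will
  split background noise), so zero-signal edge cases use fixed thresholds.
* **Aggregation** — per-layer indices are averaged (unweighted) into a
  stack index, stack indices averaged per condition (three stacks per
  experimental point); neither averaging level was stated.
* **Layers with no NFH signal** are flagged undefined and excluded from
  the stack mean rather than counted as 0, to avoid biasing sparse-axon
  fields downward.

Channel roles always come from metadata or CLI flags, never from pixel
statistics.

## Synthetic data

The generators reproduce the statistical structure each tier assumes, at
the effect and noise magnitudes of the original screen's positive controls,
and emit ground truth with every dataset:

* **Plates** — drug wells ~ Normal(vehicle_mean · ER_true, cv · mean)
  truncated at zero, vehicle wells with ER_true = 1; defaults: triplicate
  wells, vehicle mean 0.5, CV 5%, active ER 1.5. The CV is calibrated so
  control-sized effects (ER 1.3–1.4, as the screen's PDGF and T3+T4
  controls showed) are detectable in triplicate; under these conditions
  ≥ 95% of true actives and ≤ 1% of inactives clear the 1.3 threshold.
* **Ct values** — the treated target Ct sits log2(fold_true) cycles below
  the control target Ct; independent Normal(0, 0.2 cycles) noise on every
  measurement; reference gene fixed at Ct 15.
* **Confocal stacks** — red channel: random smooth curves (random-walk
  paths dilated to a 3-px width) at intensity ≈ 180 in every layer of a
  5 × 256 × 256 stack; green channel: an exactly round(f · |axon pixels|)
  random subset of axon pixels per layer, so the green mask is a subset of
  the red mask and the programmed myelinated fraction f is the index's
  ground truth; background noise is clipped below the default fixed
  threshold. Not modeled: point-spread blur, channel bleed-through,
  z-correlation of the myelin signal, demyelination dynamics.

Because the generators are idealized, passing recovery tests demonstrates
correctness of the quantification arithmetic and gating logic — not
robustness to real acquisition artifacts (uneven illumination, partial
overlap, probe non-specificity).

Every generator is bit-reproducible given (params, seed); the pipeline
derives per-stage child seeds from its master seed, and all seeds stay
below 2³¹.

## Analog shortlisting

Tanimoto similarity |A∩B|/|A∪B| over fixed-length bit sets, with the
both-empty case defined as 0 (warned, not raised). Fingerprints may come
from any external toolkit via CSV (hex-encoded), from RDKit Morgan
fingerprints when RDKit is installed, or from the built-in hashed
SMILES-character-n-gram fallback — a deterministic stand-in that captures
string similarity only and is labeled as such. The original analog search's
fingerprint type, length and cutoff were never stated, so no retrieval
result is treated as reproducible; the module's contract is the similarity
arithmetic (symmetry, identity, and 1 − T being a metric, all tested).

## Problem sizes in the default runs

The packaged-table computations are exact and instantaneous. Synthetic runs
default to 40 compounds × 3 plate experiments, 4 expression experiments
per gate, and 3 stacks of 5 × 64 × 64 px per imaging condition; the imaging
recovery study in the test suite uses the full 256 × 256 default at 20
seeds per fraction. These sizes give stable pass/fail behavior at the
stated effect sizes while keeping a full run to seconds.

## Known limitations

* The raw 2,000-compound primary-screen distribution was never published;
  the single-pass count of 127 positives is therefore not reproducible and
  not attempted.
* Fixture-backed runs stop after the mixed-glia tier: the slice tiers'
  per-experiment data exist only as plots in the source and are simulated
  instead; the report marks those tiers as skipped.
* The plate schema (wells per compound, vehicle placement) is a neutral
  reconstruction; well coordinates are labels with no geometry semantics.
* Whether published per-compound tests were run on folds or on ΔΔCt values
  is unstated; folds are the default here.
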