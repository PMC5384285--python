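# restage

A tested, reusable implementation of a staged phenotypic screening pipeline
for repurposing registered drugs as remyelinating agents. The original
screen worked through a cascade of assays on mouse oligodendrocyte
precursor cells (OPC) and cerebellar slice cultures; `restage` re-implements
its analysis stages so they can be rerun, audited, and applied to new data:

1. **Primary MTT screen** — each compound's metabolic effect is an
   *Efficacy Ratio*, ER = mean drug-well absorbance / mean vehicle-well
   absorbance; compounds with mean ER ≥ 1.3 over replicate experiments are
   confirmed. Assay quality is the screening-window coefficient
   Z = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|.
2. **Weighted multi-assay scoring** — each confirmed compound's raw fold
   effects on OPC proliferation (³H-thymidine), early differentiation (CGT
   transcripts) and late differentiation (MBP transcripts) are combined as
   total = 10·prolif + 3·CGT + 5·MBP; compounds with total > 100 are hits.
3. **Significance-gated tiers** — expression effects are quantified as
   2^−ΔΔCt fold changes (GAPDH reference) and gated by paired Student's
   t-tests: a mixed-glia tier requiring *both* MBP and CGT at p ≤ α, then
   slice myelination/remyelination tiers gating on MBP alone.
4. **Remyelination index** — confocal MBP/NFH stacks are quantified per
   z-layer as (pixels above threshold in both channels) / (NFH⁺ pixels),
   averaged over layers and stacks.
5. **Analog shortlisting** — Tanimoto similarity over 2-D fingerprints.

Wet-lab inputs are replaced by seeded synthetic generators
(`restage.synthetic_data`) that emit ground truth alongside every dataset,
and by packaged transcriptions of the published confirmation, scoring and
significance tables.

## Worked example

```python
from restage.tier_scoring import raws_from_table2, total_score, rank_and_select

scored = [total_score(r) for r in raws_from_table2()]
ranked, selected = rank_and_select(scored, 100.0)
print(ranked[0].compound_id, round(ranked[0].total_score, 2))
print(len(selected), sorted(s.compound_id for s in selected))
```

prints

```
LOVASTATIN 389.23
7 ['5-METHYL-7-METHOXYISOFLAVONE', 'CHLORMADINONE ACETATE', 'EDARAVONE',
   'FENAMISAL', 'LOSARTAN', 'LOVASTATIN', 'VULPINIC ACID']
```

i.e. lovastatin (the screen's internal control) tops the weighted ranking
at a recomputed total of 389.23, and exactly seven compounds exceed the
selection threshold of 100. The same cascade is available end to end:

```bash
restage run --mode fixture --profile reproduction --seed 1 --out report.txt
# tier mtt: 43 -> 43
# tier opc_score: 43 -> 7
# tier mixed_glia: 7 -> 5
```

42 compounds clear the confirmation rule (plus the internal control carried
by design), seven clear the score threshold, and five clear the dual-gene
significance gate. A fully synthetic run with known ground truth:

```bash
restage run --mode synthetic --seed 4 --out report.txt
restage simulate stack --myelin-fraction 0.4 --seed 2 --out s.tif
restage remyelin-index --stack s.tif --threshold 100 --out index.csv
# stack index = 0.4004 over 5 layers
```

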