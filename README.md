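# lrckit

Quantitative analysis of label-retaining cells (LRCs) in H2B-GFP pulse-chase
experiments on epithelial tissue, built around the thymic epithelial cell
(TEC) setting: slowly dividing progenitor candidates retain a nuclear
histone-GFP label through a long chase while the rest of the epithelium
dilutes it away.  The toolkit is for experimentalists and analysts who need
to (i) turn label-decay arithmetic into defensible flow-cytometry gates,
(ii) quantify whether LRCs cluster in tissue sections, (iii) compare
proliferation between subsets after injury, and (iv) screen a two-sample
RPKM table for fold-changes — and who want every step reproducible from a
single seed.

## The models

**Label dilution.** Nuclear H2B-GFP intensity halves at each division and
decays with the protein's half-life `T` (24 days by default):

    I(d, t) = I0 · 2^(−d) · 2^(−t/T)

After a 112-day (16-week) chase a non-divider keeps `2^(−112/24) ≈ 3.9%` of
its pulse intensity.  The GFPhi (LRC) gate is placed at that zero-division
intensity divided by a spread allowance (√2 by default), and always at
least 4× the empirical negative-control boundary — so a cell at the gate
needs three divisions (an eightfold dilution) to become GFP⁻.

**Spatial dispersion.** Sections are partitioned into 40–50 equal-area
quadrats and per-quadrat LRC counts are summarized by the dispersion index
`DI = s²/x̄` (1 under complete spatial randomness, ≫1 for clustering) and a
chi-square goodness-of-fit test against the maximum-likelihood Poisson
model (tail bins merged to ≥5 expected; df = bins − 2; p-values floored at
2.2 × 10⁻¹⁶).  The cortico-medullary region (CMR) is the band within
100 µm of the cortex–medulla junction, computed by a Euclidean distance
transform of the label mask.

**Proliferation.** Per-group BrdU⁺ fractions and the proliferation index
`BrdU⁺(day 7) / BrdU⁺(day 0)`, with a median-fluorescence check that BrdU
signal reflects replication rather than repair.

**Expression screen.** Single-replicate fold-change screen: keep genes with
RPKM > 1 in at least one sample, call |log2FC| > 1 differential, split by
direction, rank by |log2FC| for top-N lists, and compute per-gene Z-score
profiles across subsets.

Seeded generators (`lrckit.synthetic`) emulate flow-event tables, quadrat
counts, clustered tissue maps and RPKM tables with the effect sizes the
analyses assume, so the whole pipeline runs without any raw data.

## Worked example

Quadrat analysis of one simulated section set (178 equal-area sections,
overdispersed counts at the default calibration):

```python
from lrckit.synthetic import QuadratSimConfig, gen_quadrat_counts
from lrckit.spatial import dispersion_report, cluster_summary

counts = gen_quadrat_counts(QuadratSimConfig(seed=1))
rep = dispersion_report(counts)
print(f"sections: {rep.n}, mean count: {rep.mean:.2f}")
print(f"dispersion index: {rep.dispersion_index:.2f}")
print(f"Poisson GOF: chi2 = {rep.gof_statistic:.1f}, df = {rep.gof_df}, p = {rep.gof_p:.3g}")
lrc, sec = cluster_summary(counts, threshold=32)
print(f"cells in >32-count sections: {100*lrc:.1f}% of cells in {100*sec:.1f}% of sections")
```

prints

```
sections: 178, mean count: 16.57
dispersion index: 28.63
Poisson GOF: chi2 = 1523.9, df = 13, p = 2.2e-16
cells in >32-count sections: 53.2% of cells in 14.6% of sections
```

— the counts average ~16 LRCs per section but their variance-to-mean ratio
is ~29 (a single draw scatters around the configured 34.81), the Poisson
null is rejected below the reporting floor, and about half of all cells sit
in the ~15% of sections that form clusters.  The same analyses are
available from the shell (`lrckit simulate-quadrats`, `lrckit quadrat`,
`lrckit gate`, `lrckit regions`, `lrckit prolif`, `lrckit descreen`,
`lrckit run`); `lrckit run --seed 7 --outdir out/` executes every stage and
writes all tables plus one deterministic `report.json`.

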