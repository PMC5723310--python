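# Methods

This note records the models implemented in `lrckit`, the assumptions and
defaults behind them, what the synthetic-data generators do and do not
emulate, and the numerical conventions that would otherwise be invisible in
the API.

## Label-dilution kinetics (`lrckit.kinetics`)

A pulse-chase with a tet-inducible H2B-GFP reporter labels nuclei during
the pulse; during the chase the label halves at each division (histone
partitioning between daughters) and decays exponentially by protein
turnover.  The model is

    I(d, t) = I0 · 2^(−d) · 2^(−t / T),

with `T` the protein half-life (default 24 days), `t` the chase time
(default 112 days = 16 weeks) and `d` the division count.  Assumptions:
symmetric label segregation at division, continuous first-order turnover,
no cell death (dead cells are simply absent from event tables).

Boundary conventions are strict where they matter: a cell whose intensity
is a factor `r` above the GFP⁻/GFPint boundary needs the smallest `d` with
`r·2^(−d) < 1` to become GFP⁻ — strictly below, so a 4× margin implies
three divisions (an eightfold dilution), not two.

The model-derived GFPhi gate is the zero-division end-of-chase intensity
divided by an allowance for measurement spread.  The default allowance is
√2: half a division on the log2 scale, splitting the interval between
zero- and one-division cells symmetrically.  It is configurable; with the
default multiplicative noise (CV 0.20, see below) about 4–5% of true
non-dividers fall below this gate, which is why end-to-end recovery of a
5.5% label-retaining fraction reads ~5.3%.

## GFP gating (`lrckit.gating`)

The negative boundary is the 99.9th percentile of the negative-control
intensity distribution (a `max` rule is also available); how the original
cytometry boundary was drawn is not recoverable, so the quantile rule is
this package's documented choice.  The GFPhi boundary is
`max(model-derived gate, 4 × negative boundary)`, honouring both the
half-life-aware placement and the 4×-margin constraint; the
`GateThresholds` type rejects any pair violating the 4× invariant.
Classification: `intensity ≤ neg` → GFP⁻, `≥ gfphi` → GFPhi, otherwise
GFPint (boundary membership fixed as stated; the instrument convention is
unknowable, so it is simply pinned and tested).

LRC composition combines per-subset LRC frequencies `f₋, f₊` with the
population fraction `p` of UEA1⁻ cells as `f₋p / (f₋p + f₊(1−p))`; with
the observed 5.5% / 1.8% frequencies and `p = 1/3` this gives 60.4% of
LRCs being UEA1⁻.

## Spatial statistics (`lrckit.spatial`)

*Dispersion index*: sample variance (n−1 denominator) over sample mean.
The n−1 choice is the standard definition; at the effect size of interest
(DI ≈ 35 at n = 178) the n vs n−1 distinction is far inside the noise.

*Poisson goodness of fit*: the rate is the maximum-likelihood estimate
(sample mean); the integer count histogram is compared with Poisson
expectations after greedy merging of adjacent cells from the low end, the
final bin absorbing the upper tail, so every bin has expected mass ≥ 5;
statistic referred to chi-square with `bins − 2` degrees of freedom.  The
classical caveat applies (with an MLE from ungrouped data the true null
law lies between chi-square with `bins−2` and `bins−1` df); simulation at
the default geometry puts the type-I error at ~0.06 at α = 0.05, within
the calibration band the test suite enforces ([0.03, 0.07]).  An
index-of-dispersion test — `(n−1)·DI` against chi-square with `n−1` df —
is provided as a selectable alternative; both floor reported p-values at
2.2 × 10⁻¹⁶, the conventional smallest-reportable value.

*Regions*: the CMR is the band within 100 µm (inclusive) of the
cortico-medullary junction.  Distances come from Euclidean distance
transforms on each side of the cortex/medulla interface at mask resolution,
corrected by half a pixel and sampled at point positions by bilinear
interpolation, so a point exactly 100 µm from a straight boundary is
assigned to the CMR.  Coordinates are µm with the origin at the mask's
top-left corner, x rightward, y downward, 0-based pixel indices.

*Quadrats*: the near-square factorization of the target section count is
laid over the mask bounding box as half-open rectangles `[x0,x1)×[y0,y1)`,
so counts always conserve the point total.  The default target is 45
sections (middle of the 40–50 range used for real slices).

*Microscopy LRC rule*: in image-derived intensity tables a cell is an LRC
when strictly above 4× the brightest negative-control cell.

## Synthetic data (`lrckit.synthetic`)

All generators draw from `numpy.random.Generator` streams split from one
integer seed via `SeedSequence(seed, spawn_key=(stream_id, replicate))`
with fixed per-generator stream ids — identical configs reproduce outputs
byte for byte, and replicates are independent.

**Flow events.** Per subset, an event is quiescent (d = 0) with the
subset's label-retaining probability (defaults 0.055 for UEA1⁻, 0.018 for
UEA1⁺), else a divider with `5 + Poisson(3)` divisions — dividers sit past
the detectability horizon, and since nothing constrains the excess over
five divisions, a shifted Poisson is the simplest choice.  Labeling
efficiency (default 0.75) applies to every event; unlabeled cells and all
negative-control events draw from a log-normal autofluorescence
distribution (median 1 a.u., CV 0.5 — no empirical distribution is
available, so log-normal is an assumption).  Labeled intensity is the
kinetic model value times median-unbiased log-normal noise (CV 0.20);
autofluorescence is *not* added to label signal, so noise-free settings
reproduce model values exactly.  The end-to-end gating recovery checks run
with labeling efficiency 1: the recovery statement "percent GFPhi equals
the configured quiescent fraction" is only an identity when every
quiescent cell carries label; with partial labeling the generator's
quiescent fraction is a pre-labeling rate and the GFPhi yield scales down
accordingly.

**Quadrat counts.** Poisson(λ) for the null; negative binomial for
clustered patterns, parameterized by mean `m` and dispersion index `DI`
(size `r = m/(DI−1)`, success probability `1/DI`, giving variance
`DI·m` exactly).  Defaults: 178 sections, mean 16.11236, DI 34.81 — the
observed section statistics.  The negative binomial was chosen for its
closed-form mean/DI mapping; the 2-D cluster process below is reserved
for maps.

**Tissue maps.** The frame is 1000 × 1000 µm at 1 px = 1 µm.  The medulla
occupies the left of the frame up to a sinusoidal boundary (amplitude
40 µm, period 500 µm, random phase) whose mean position realizes a 35%
medullary area fraction — a single smooth interface rather than multiple
medullary islets, which keeps the CMR band geometry exact and cheap.  The
K5⁺K8⁺ double-positive compartment is the band of tissue within a distance
quantile of the CMJ realizing a 26% area fraction; remaining medulla is
K5⁺, remaining cortex K8⁺.  Under these defaults the CMR (±100 µm,
~21% of area) is a strict subset of the K5⁺K8⁺ band — the only geometry
consistent with more points in K5⁺K8⁺ (63%) than in the CMR (53.6%).

Points come from a Thomas (Neyman–Scott) process: parents choose one of
three distance zones — CMR core, the K5⁺K8⁺ fringe beyond it, far tissue —
with probabilities (0.5389, 0.1279, 0.3332), sit uniformly inside the
zone, and receive `n_lrc / 12` offspring on average, scattered with
σ = 20 µm and resampled until inside the tissue.  The zone probabilities
were calibrated once, by a pilot simulation that estimated the 3 × 3
offspring-mixing matrix (offspring blur moves mass between adjacent zones)
and solved it against the target point fractions (0.536, 0.094, 0.370);
they are frozen as defaults, and realized shares average ~53.6% in the CMR
and ~63% in K5⁺K8⁺ across seeds.  `parent_zone_probs=None` gives unbiased
placement; `offspring_sigma_um=0` disables clustering.

**Expression tables.** Gene baselines are log-normal (median 4 RPKM,
log-sd 1.6, leaving a realistic sub-1-RPKM tail for the filter to remove).
Planted effects `|log2FC| = 1 + Exponential(1)` are assigned to 5.2% (up)
and 12.1% (down) of *expressed* genes (baseline ≥ 2 RPKM): fold-changes
are only meaningful for genes the screen can see past its expression
filter, and planting on sub-threshold genes would asymmetrically delete
down-regulated truth (their LRC value drops below the filter while an
up-regulated gene's rises above it).  Per-sample noise is Gaussian on the
log2 scale (sd 0.25).  The default down share of planted effects gives a
detected down-fraction of ~0.69–0.70.

**BrdU records.** Per-group Bernoulli positivity with defaults encoding
the regeneration scenario: at steady state UEA1⁺ NonLRCs proliferate most
(12%); at day 7 after sublethal irradiation UEA1⁻ LRC-derived (GFP⁺) cells
surge to 25% while UEA1⁺ NonLRCs drop to 5% — a more-than-twofold decrease.
The exact group percentages are not published; these values are scenario
choices that preserve the published qualitative orderings, and the tests
assert orderings and recovery, not the placeholder levels.  BrdU
fluorescence is log-normal (median 100 for BrdU⁺ vs 5 background, CV 0.6),
so the BrdU⁺/population median ratio comfortably exceeds the replication-
consistency factor of 7.

### What the generators do not emulate

No spectral spillover/compensation, no instrument saturation, no doublets;
no 3-D tissue, no multiple medullary islets, no section-to-section area
variation; no gene–gene correlation, library-size or length biases in
expression; no cell death or dose–response for irradiation.  Passing tests
therefore show the *statistical machinery* is correct at the stated effect
sizes — not that real cytometry or imaging artifacts are handled.

## Pipeline (`lrckit.pipeline`, `lrckit.cli`)

One YAML-loadable `RunConfig` (single seed, stage selection, per-stage
parameter blocks) drives simulate → gate → spatial → proliferation →
screen.  Configs are validated before any output is written.  Reports
embed provenance (seed, config hash, package version) and contain no
timestamps or timings (those go to logging), so identical configs yield
byte-identical `report.json` files.  `reproduce()` re-derives every
headline quantity at full scale — 200 Poisson replicates, 100,000 gating
events, 500 clustered-count replicates, 100 tissue sections with 1,000
points each — sizes chosen so sampling error sits well inside each
quantity's tolerance while a full run stays under a minute.

## Known limitations

* The detection-limit ratio between pulse intensity and autofluorescence
  is configurable, not modelled: no dynamic-range measurement exists to
  pin it.
* The chi-square GOF test is mildly anticonservative (see above); use the
  dispersion test when exact null calibration matters more than histogram
  shape sensitivity.
* Quadrat partitioning assumes the tissue footprint fills its bounding box
  when equalizing section areas; for strongly non-convex real masks the
  per-section tissue areas should be checked against the equal-area
  tolerance.
* The single-replicate screen has no error model; sensitivity/specificity
  reported on synthetic tables quantify threshold behaviour, not
  statistical significance.
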