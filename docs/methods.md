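# Methods

This note documents the models and numerical choices behind `indigoferm`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and the limits of what passing tests
demonstrate.

## Colorimetry

Dyeing intensity is the Euclidean norm `√(L*² + a*² + b*²)` of the mean
CIELAB colour of a scanned swatch.  Conversions assume an sRGB scanner:
IEC 61966-2-1 piecewise gamma, D65 white, 2° observer (the `skimage.color`
defaults).  Averaging is done **in Lab space** before taking the norm,
because the score is defined on L\*, a\*, b\* values; averaging raw sRGB
first is available (`score_image(average_in="srgb")`) for sensitivity
checks.  Swatch masking is a central crop (default `border_fraction=0.15`)
— no segmentation is attempted, since dyed swatches are assumed to fill the
scan with at most a light undyed margin.  Out-of-gamut Lab colours are
clipped to the sRGB cube and flagged.  8-bit quantisation bounds the
render→score round trip at roughly ΔE(CIE76) ≈ 0.3; the package asserts
< 0.5.

## Composition and diversity

"Others" aggregation keeps a taxon iff its **maximum** relative abundance
over the samples of the analysis window is ≥ the cutoff (default 4.1 %,
boundary inclusive), and is applied separately per window (early days 1–7
vs late days 10–209), mirroring how such figures are windowed.  Alpha
diversity is computed at a fixed rarefaction depth (default 8 825 reads) by
multivariate-hypergeometric subsampling without replacement; samples
shallower than the depth are excluded with a warning.  The default is 10
replicate rarefactions averaged per sample, with per-(sample, replicate)
seeds derived from the master seed — one draw versus an average is a
configuration choice, not a model claim.  Shannon diversity uses log base 2
(bits), the common amplicon-workflow default.  The analytic rarefaction
mean, `E[S] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d))`, is evaluated in log space
(`gammaln`) and serves as the independent oracle for the Monte-Carlo path.

## Redundancy analysis

The community matrix (samples × taxa) is Hellinger-transformed (√p) by
default — the standard pre-transform that makes Euclidean ordination well
behaved for closed relative-abundance data; `none` is available.
Environmental variables are standardised to zero mean, unit variance.
Wheat-bran additions enter as a decaying pulse level
`Σ_events e^{−(t−t_event)/τ}` with τ = 30 d, reflecting that a bran dose is
consumed within about a month.  The RDA itself is the textbook definition:
column-centre Y and X, project (`lstsq`), diagonalise `ŶᵀŶ/(n−1)` for the
constrained axes and the residual for the unconstrained ones.  Scores
follow the scaling-2 (species-focused) convention; each axis's sign is
fixed by making its largest-magnitude species loading positive, so outputs
are reproducible.  Exactly collinear environment columns are dropped
greedily (rank test per column) with a warning.  Permutation significance
tests are out of scope.

## Co-occurrence networks

Edges are Spearman rank correlations between per-taxon relative-abundance
trajectories over a period's sampled days ("trend" is read as the
trajectory itself; a first-differences mode exists behind
`build_network(mode="diff")`).  An edge is kept iff |r_s| > 0.6 **and**
p < 0.05, both strict; the sign of r_s labels the edge positive/negative,
and node weight is the taxon's summed proportion over the period.
Two-sided p-values are exact for n ≤ 8 — full enumeration of rank
permutations, with the null |r| table cached per rank multiset — and a
t-approximation (`t = r_s√((n−2)/(1−r_s²))`, n−2 df) otherwise.
Constant-series pairs are skipped with a warning rather than assigned
r_s = 0.  No multiple-testing correction is applied, matching common
practice for these descriptive networks.

## Predicted metagenome and phenotype attribution

The functional profile is the taxon-by-gene-content decomposition:
`contrib(sample, ko, taxon) = abundance × copy_number`, KO totals summing
over taxa (conservation is asserted to 1e-9).  Hidden-state prediction of
gene content is out of scope — content is imported (PICRUSt2 layouts) or
generated.  Subpathway totals give a KO mapped to k subpathways its full
abundance in each; unmapped KOs pool under `unclassified`.  Ratio screens
keep subpathways strictly above the threshold (default 1.05); zero
denominators are reported separately as undefined.

The KO–phenotype screen correlates **changes**: within each batch, first
differences of dyeing intensity and of each KO's per-sample-normalised
abundance between consecutive sampled days (regardless of gap length),
pooled across batches, Pearson r per KO, hits at r ≥ 0.69 (inclusive).
Pearson is the default because the network analysis names Spearman
explicitly while the KO screen does not; Spearman can be obtained by
ranking upstream.  A `level` mode correlates raw values instead.  KO
columns are normalised to per-sample relative abundance first so sequencing
depth does not masquerade as change.  The oxidoreductase filter keeps hits
whose annotation lists any EC 1.\* number *and* carries the NAD(P)-dependence
flag; unannotated hits are surfaced in a separate bucket, never dropped
silently.

## The synthetic fermentation generator

The generator's job is to produce data with the statistical structure the
analysis assumes — environmental forcing, succession, sequencing noise, and
a *planted, recoverable* gene-to-phenotype link — not to model vat
chemistry.

**Environment.**  Per batch and day: pH starts at the pretreatment pH,
declines by a constant acid-production rate (0.2 pH/d) and is reset to the
ceiling (11.2) whenever it would cross the floor (9.67), flagging a Ca(OH)₂
addition — so the pH sawtooths inside the maintenance band, never dwelling
below the floor.  ORP follows a falling sigmoid (+100 mV → −550 mV,
midpoint day 1.5); no ORP numerals appear in the study's text, so the scale
is a configurable invention.  Substrate pools: labile sukumo nutrients
decay (τ = 5 d); wheat bran jumps by 1 AU on days 5/19/51/85/194 and decays
with τ = 30 d; dead microbial cells rise as a pretreatment die-off hump and
then persist at a sustained level (1.0 AU), reflecting continuous community
turnover feeding the necrophagous guild.

**Succession** is a seeded discrete-time multiplicative (replicator-like)
update.  Daily log-fitness per taxon: baseline + Gaussian pH kernel
(scale 3.0) + signed logistic ORP term (scale 1.5, width 120 mV) +
substrate-affinity terms (scale 5.0) − self-crowding penalty (6.0 × own
share) + N(0, 2.0) daily noise; shares renormalise each day.  The taxon
catalog spans the observed guilds: early aerobes (labile specialists,
prefer high ORP), facultative anaerobes / lactic-acid bacteria and obligate
anaerobes (alkaliphilic, prefer low ORP), with a resource trade-off between
bran adaptation and dead-cell use.  Indigo reducers are the bran-adapted
anaerobes — the guild the bran pulses recruit — and the inoculum is
aerobe-biased (10×), as composting is an aerobic solid fermentation.  Three
choices deserve comment:

* the **self-crowding penalty (6.0)** keeps tens of taxa coexisting;
  without it the multiplicative dynamics collapse to a single winner within
  weeks, which contradicts the diverse communities the analysis assumes;
* the **daily growth noise (σ = 2.0 log-units)** makes taxon trajectories
  strongly idiosyncratic.  This emulates the large between-sampling
  volatility real vat communities show, and it is what makes the planted
  signal *identifiable*: the dye tracks one specific weighting of reducer
  taxa, and only gene columns with essentially that carrier set can
  correlate with it at r ≥ 0.69 — background KOs, carried by random taxon
  subsets, cannot.  With weak noise the community collapses onto a few
  coherent modes and any reducer-skewed background KO becomes a false
  positive;
* **reducer gene dosage** is a per-taxon lognormal factor (σ = 1.2) shared
  across the causal KO set — strong reducers carry proportionally more of
  every causal gene — so all causal KOs track the same dosage-weighted
  signal.

**Reads** are multinomial draws at per-sample depths uniform in
[10⁴, 10⁵].  **Gene content**: background KOs present per taxon with
probability 0.5 at 1 + Poisson(0.3) copies; causal KOs add
5 × dosage extra copies in every reducer, making the reducer mean strictly
higher by construction.  **Dye phenotype**:
`I = baseline + (saturation − baseline)·logistic(slope·s) + N(0, σ)` with
s the community-weighted causal-KO abundance; defaults baseline 20,
saturation 80, slope 0.04, σ = 10 % of the attainable dynamic range
(saturation − baseline)/2 = 30, i.e. σ = 3.  Since logistic(0) = ½, the
zero-signal intensity sits at the mid-range; the slope is chosen so the
realised signal sweeps the upper half of the logistic without saturating.
The emitted L\*a\*b\* lies along a fixed blue-leaning unit direction
(b\* < 0) scaled to the intensity, so the norm identity is exact by
construction.  Annotations mirror the biology of the planted set: causal
KOs are NAD(P)-dependent oxidoreductases (EC 1.\*); background KOs draw
generic annotations, about 10 % of them non-NAD(P) class-1 enzymes.

**Determinism.**  All randomness flows from one master seed through
SHA-256-derived substreams keyed by stage and batch id, so identical
(design, params, seed) give byte-identical datasets and adding a batch or a
stage never perturbs existing ones.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: no indigo/leuco-indigo chemistry or thermodynamic
ORP; no chimeras, primer bias or copy-number variation in the "sequencing";
no taxonomy (taxa are abstract ids); the phenotype link is a clean
monotone function of one gene set, whereas real dyeing capacity integrates
physiology well beyond gene copy number.  Recovery results on synthetic
data bound what the screen can do under its own assumptions; they are not
evidence about any particular real vat.

## Orchestration

`run_pipeline` executes generation (or import) → composition per window →
alpha diversity → RDA per window → per-batch networks per window →
predicted metagenome → subpathway screens (earliest-reducing batch vs the
others on day 3) → KO screen → oxidoreductase filter → contribution day
ratios (day 2→3 and 3→4 for the high-pH batches, top contributing taxon
per hit).  Every artifact is TSV with a provenance log line; the manifest
records the config hash and seed, and identical config + seed reproduces
every numeric output byte for byte.  Analysis windows default to days 1–7
and 10–209.  The problem sizes used by the test suite and the acceptance
script (e.g. 3 batches × 14 sampled days, 40 taxa, 300 KOs, 20 generator
seeds) are chosen to exercise the full chain at desk scale.

## Known limitations

* The discrete-time update can overshoot (period-2 oscillation) for a
  taxon near dominance under a steep crowding penalty; at the default
  catalog sizes shares stay small enough that this is immaterial, but
  two-taxon toy systems should use a gentler penalty.
* Exact Spearman p-values are enumerated only to n = 8 (8! permutations);
  beyond that the t-approximation is used, which is slightly liberal at
  n ≈ 9–12.
* `encode_environment` requires every sample's pH/ORP either in its
  metadata or in a matching environment series; there is no interpolation
  for unsampled days.
* The oxidoreductase filter trusts its annotation table; with real KEGG
  annotations the NAD(P)-dependence flag must be curated by the user.
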