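# Methods

## Data model

The analysis substrate is a binary taxon-by-cell incidence matrix.
Presence is binary: any occurrence record implies presence, duplicates
collapse. Cell identifiers are opaque strings; EEA-style codes
(`10kmE523N201`) are additionally parsed into square polygons when GeoJSON
export is requested. Taxon and cell orderings are lexicographic, so
identical input bytes always yield identical matrices and downstream
numbers. Metric surfaces distinguish *undefined* from zero: CWE at SR = 0,
PD of an empty cell and SES with a degenerate null are encoded as missing
(empty CSV field), never as 0 or a sentinel.

Trees are rooted, with branch lengths required (they are the substance of
PD and PE) and polytomies preserved. Tips absent from the occurrence
matrix are pruned with a warning rather than an error, mirroring the
common situation of subsetting a national phylogeny to a study flora.
Trait tables are long-format categorical records with union semantics: a
taxon may hold several categories of the same trait, and each contributes
once per cell. Trait coverage may be partial; the functional stage runs on
the covered subset and reports it.

## Metrics

For cell *c*, taxa *s* with range size *r_s* (number of occupied cells),
branches *b* with length *L_b* and branch range *R_b* (number of cells
holding at least one descendant tip of *b*):

    SR_c  = |{s present in c}|
    WE_c  = Σ_{s in c} 1 / r_s
    CWE_c = WE_c / SR_c            (undefined at SR_c = 0)
    PD_c  = Σ_{b present in c} L_b
    PE_c  = Σ_{b present in c} L_b / R_b

A branch is *present* in a cell iff any descendant tip is. Both
phylogenetic metrics are computed from one branch × taxon incidence
matrix; branch-cell presence is then a single boolean matrix product, so
PD and PE over all cells cost one pass. Two identities follow directly
and are enforced in the tests at 1e-9: Σ_c WE_c equals the taxon count
(each taxon spreads total weight 1 over its range) and Σ_c PE_c equals
the total tree length.

**Root convention.** PD includes every branch on the paths from a cell's
tips to the root (and a root edge, when the Newick carries one). This
matches the "total branch length of the lineages present" reading, makes
single-taxon cells well-defined, and is the single place where a
convention choice changes numbers: an MRCA-only variant would subtract
the shared root path. On a star tree with unit pendant branches the
convention gives PD_c = SR_c and PE_c = WE_c exactly — the phylogenetic
metrics collapse onto the taxonomic ones, which the tests assert.

## Null models and significance

**CWE.** The significance of per-cell CWE is assessed against a
permutation null with 999 permutations by default. The default
*curveball* algorithm preserves every taxon range and every cell richness
exactly (fixed-fixed margins): a trade picks two taxa and reallocates the
cells unique to each uniformly at random. Because CWE confounds richness
and range size, the fixed-fixed null isolates the *identity* composition
of cells. The chain burns in for 5 × (number of presences) trades and
advances 1 × presences trades between replicates, chained from the last
state; both factors are configurable. Margin preservation can be asserted
on every replicate (`check_margins=True`; the tests do). A richness-only
alternative (*tip_shuffle*: each cell redraws its SR_c taxa uniformly,
ranges recomputed from the redrawn matrix) is provided behind the same
interface; which randomization a given study used is rarely stated, so
neither is claimed canonical.

**p-values.** One tail is p_high = (1 + #{null ≥ obs}) / (1 + n_perm),
p_low analogously; the two-tailed p doubles the smaller tail and is
capped at 1. Ties count toward both tails (conservative, valid under
exchangeability). The one-tailed floor is 1/(n_perm + 1). Cells are
classified significantly high / low at α = 0.05 by tail direction.

**PD_SES.** The default null (*uniform_tip_draw*) draws, independently
per cell, n_perm random sets of SR_c tips uniformly without replacement —
the classic fixed-richness null whose moments SES tools compute
analytically; here they are Monte-Carlo estimates (sd with ddof = 1), so
equivalence is statistical, not exact. A *tip_label_shuffle* alternative
permutes tip labels once per replicate, preserving co-occurrence
structure. SES is reported wherever the null varies (sd > 0), including
richness-1 cells; degenerate cells (e.g. a cell holding every tip) are
reported as undefined, never dropped silently. Classification at ±1.96 is
boundary-inclusive: SES ≥ 1.96 is overdispersed, ≤ −1.96 clustered.

## Hotspots, binning, overlap, crosswalk

L1 hotspots are the cells at or above the empirical `level`-quantile
(default 0.99, linear interpolation) of a surface's defined values; ties
at the threshold are included, so the set may exceed the nominal 1% — a
deliberately conservative choice for conservation screening. Map-style
bins use 5 quantile classes by default (robust to the heavy-tailed
endemism distributions; published class breaks are rarely stated, so any
scheme is a reconstruction and the breaks are logged). Protected-area
overlap is cell-level boolean membership accounting — counts and
identities of inside/outside cells per class or hotspot set, plus the
headline "all medium-or-better cells inside" check. Fractional (area
weighted) membership is out of scope.

The CICES crosswalk maps eight indicator letters (T taxonomic, P
phylogenetic, G growth form, L life form, LV longevity, D dispersal mode,
PL pollination type, C petal color) to 11 ecosystem-service classes
(4 provisioning, 3 regulating/maintenance, 4 cultural). A class is
relevant in a cell iff at least one of its letters is flagged (letters
are alternatives, not conjunctions). The default flag rule — T from
SR/CWE L1 membership, P from PD/PE, trait letters from the most-diverse
band flags — is explicit and overridable, as is the crosswalk table
itself (CSV with identical columns).

## Synthetic data

The generator emulates the *structure* of a national endemism study, not
any particular flora. Range sizes mix a narrow-endemic fraction (default
55% with 1–3 cells, mirroring floras where roughly half the taxa are
narrowly distributed) with a log-series tail (default p = 0.99, mean ≈ 21
cells). Ranges grow by spreading-dye accretion on the 4-neighbour grid:
with probability `cohesion` (default 0.8) the next cell is drawn from the
patch frontier, otherwise uniformly — cohesion 0 therefore yields uniform
random cell sets, which makes the matrix exchangeable under the
fixed-margin null and is the calibration scenario. Trees are Yule or
birth–death (extinction < speciation enforced), ultrametric to float
precision. Traits draw 1–2 categories per covered taxon from skewed
(geometric) category frequencies; vocabulary sizes default to the tops of
the most-diverse bands (5 life forms, 3 longevities, 10 growth forms, 7
dispersal modes, 4 pollination types, 39 petal colors). Regions are a
13-label Manhattan-Voronoi partition of the grid; the protected-area mask
is Bernoulli (default 30–35%), optionally forced over planted centers.

Planted endemism centers place n endemics (range 1–2 cells) into a
designated block, optionally as a clade (grafted so the clade MRCA
subtends exactly the planted tips) and optionally with categories cycling
through the full trait vocabularies so the block attains every top band.
Ground truth is exported for recovery tests.

What the generator does **not** emulate: coastline/border effects,
elevation or climate gradients, sampling effort bias, spatial
autocorrelation of traits, and realistic phylogenetic signal in range
sizes. Passing tests therefore demonstrate the estimators' correctness
and calibration under stated conditions, not robustness to those
real-data complications.

## Validation experiments and problem sizes

The reference experiments in `spatdiv.experiments` fix the package's
validation conditions:

- conservation identities on 100 random instances (≤ 200 taxa, ≤ 400
  cells, mixed cohesion and endemism);
- PD/PE versus a naive per-cell branch enumeration (an independent code
  path walking the dendropy tree) on 50 instances of ≤ 40 tips × ≤ 30
  cells;
- star-tree reduction on 20 instances;
- CWE null calibration: 200 exchangeable matrices (100 taxa, 10 × 10
  grid, cohesion 0, log-series p = 0.95) at n_perm = 199, pooling ~20,000
  cells; the rejection rate at α = 0.05 sits slightly below nominal
  because ties are conservative;
- PD_SES calibration: 2,000 cells assembled by the uniform-tip-draw null
  on a 150-tip tree, n_perm = 199; mean ≈ 0, sd ≈ 1 (the Monte-Carlo sd
  inflates the SES spread by about (1 + 1/n_perm)^0.5);
- planted recovery: 100 replicate 20 × 20 floras, 150 background taxa
  with ranges ≥ 3 cells, 20 single-cell endemics split over a 2-cell
  block; both block cells must enter the L1 CWE hotspot set and classify
  significantly high. The background range floor keeps the planted signal
  identifiable — a recovery experiment measures detection of a
  concentrated signal against a diffuse background, not against other
  endemism centers.

Permutation counts in these experiments use 199 replicates rather than
the 999 of a full analysis run; the permutation-p floor scales
accordingly and none of the measured properties depends on the count
beyond Monte-Carlo noise. `scripts/acceptance.py` re-runs all of the
above from a single command-line seed.

## Numerical choices and degenerate inputs

- All metric arithmetic is float64; boolean matrix products use the
  smallest adequate dtypes (float32 for the SES null draws).
- Quantiles (hotspot thresholds, class breaks) use numpy's default
  linear interpolation; class assignment is `searchsorted` on the breaks,
  right-inclusive.
- Sub-seeds derive from the top-level seed by CRC-32 of
  `"{seed}:{stage}"`, kept below 2^31; identical seed + inputs give
  bit-identical ensembles and manifests (timings aside).
- Empty cells are permitted (SR = 0, everything else undefined); taxa
  with empty ranges are rejected on validation. A constant surface bins
  into a single class with a warning; bands above the observed maximum
  flag nothing, with a warning.

## Known limitations

- The curveball chain is a heuristic sampler; uniformity over the
  fixed-margin space is asymptotic in the trade count. The calibration
  experiment bounds the practical consequence.
- PD_SES moments are Monte-Carlo, not the exact recursion; with few
  permutations the SES spread inflates slightly (quantified above).
- Hotspot and binning schemes are reconstructions wherever published
  break values are unstated; outputs carry the scheme and breaks.
- Protected-area overlap is cell-membership accounting only; no polygon
  intersection or area weighting.
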