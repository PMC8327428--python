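# Methods

## The question being computed

A species complex is "barcodable" at threshold t when single-linkage
clustering of pairwise ITS distances at t reproduces the species partition
established independently (multi-locus phylogeny, coalescent
delimitation). `shsweep` computes this directly: distances → partitions
over the 0–3 % grid → per-species statuses → minimal resolving threshold.
Because the real data for any particular complex live in public databases,
the package also ships a generative model of such complexes, so every
claim the code makes can be exercised end-to-end on data with known truth.

## Distance model

Uncorrected p-distance, not a model-corrected distance: database
similarity thresholds ("99.5 %") are complements of raw identity, so the
comparable statistic is mismatches over compared sites. Compared sites are
the columns where both sequences hold one of A/C/G/T. Gaps, `?` and all
IUPAC ambiguity codes exclude the column for that pair — a conservative
choice that treats ambiguity as absence of evidence rather than partial
evidence, and makes distances reproducible without scoring conventions.
Pairs sharing fewer than `min_overlap` comparable sites (default 100 —
below that, a single mismatch already moves the distance by ≥ 1 %) receive
an explicit missing value. Missing is never 0 or 1: in clustering it is
simply the absence of an edge, which is why fragment records cannot chain
clusters together spuriously.

## Clustering

Single linkage via connected components, with an inclusive edge rule
(d ≤ t merges ties at exactly t). Single linkage is the reading of SH
inclusiveness consistent with nesting: because the edge set only grows
with t, the partition at a smaller threshold refines the partition at a
larger one, and cluster counts are non-increasing — properties the test
suite asserts and a brute-force transitive-closure oracle cross-checks.
Complete and average linkage are available behind a flag for sensitivity
analysis; they require complete distance matrices and give up nesting.

## Evaluation

A species is *resolved* at t iff exactly one cluster's reference members
equal the species' reference members ("strictly distinguished" as exact
set equality). Otherwise it is *split* (several clusters, all pure),
*merged* (one impure cluster) or *mixed*. Unlabelled queries never enter
status computation; they are reported with their cluster. The overall
minimal resolving threshold is the smallest grid point at which every
in-scope species is resolved simultaneously. It is computed directly
rather than as the maximum of per-species minima, because resolution is
not monotone in t: a species resolved at 0.5 % can be merged at 1 %, so
the max of minima may not itself resolve everything. Reports carry both
the distance (0.5 %) and similarity (99.5 %) expressions of each
threshold.

## Diagnostic positions and placement

A column is diagnostic for species S with state x when every reference
member of S carries x unambiguously (a `tolerance` fraction of members may
be gap/ambiguous; default 0, the strictest reading) and no member of any
other species carries x there. Queries are never pooled into the
reference, so placement cannot leak.

Placement counts, per species, the diagnostic columns where the query has
an unambiguous base (*covered*, divided into matches and mismatches) and
those where it has an ambiguity code (*uncertain*). Gap/missing columns
count nowhere. The verdict is `assigned(S)` when S is the unique
mismatch-free species with covered ≥ `min_covered` (default 3 — single
diagnostic matches are fragile to sequencing error), `uncertain` when the
unique candidate is under-covered or several species tie at zero
mismatches, and `conflicting` when every species is contradicted (the
signature of a record that matches no species in the reference set, as
chimeric or low-quality database records do).

Fragments are threaded onto reference columns by globally aligning the
query to its closest reference (most shared 8-mers; match 1, mismatch −1,
gap open −5, gap extend −1) with free terminal overhangs — end gaps must
be free, otherwise a fragment's contiguous placement ties with placements
that scatter its last bases, and the tie-break is arbitrary. Query
insertions relative to the reference cannot be represented on a fixed
column set and are dropped.

Quality screening flags single-spacer records (one spacer ≥ 50 % covered,
the other < 10 %), ambiguity-laden records (> 2 % ambiguity codes among
present residues) and domain-deviant records (≥ 2 unambiguous differences
from the reference consensus inside 5.8S). Screening is deliberately
strict: on simulated complexes, genuine fixed interspecific 5.8S
differences can trip the domain check, which mirrors how a conservative
curator would treat deviation in a region expected to be near-invariant.
Flagged records are withheld from clustering by default and routed to
placement; a flag forces their inclusion.

## Simulator

The multispecies coalescent with both θ (population-size parameter) and τ
(divergence times, node heights above the leaves) in expected
substitutions per site — the BP&P convention, so no separate mutation
rate. Within a population, k lineages coalesce after Exp(k(k−1)/θ)
waiting times (pairwise mean θ/2, hence expected pairwise divergence
within a species = θ); survivors enter the parent population at its τ.
Sequences evolve site-independently (JC69 by default, HKY with κ and base
frequencies optionally) along the genealogy, scaled per region. The
default locus is ITS1 (220 sites, ×1.0), 5.8S (160, ×0.1), ITS2 (230,
×1.0), optional partial LSU (300, ×0.2); all lengths and rates are
config-overridable. No indels are simulated — the analysis consumes a
fixed alignment, and gaps would only add alignment confounds the distance
model does not interpret; gaps arise solely from truncation during
degradation. Inverse-gamma hyperpriors IG(shape α, scale β), mean
β/(α−1), can supply θ (shared across branches) and the root height
(internal heights rescaled proportionally); the parameterisation is stated
because IG conventions vary.

The `albonigra_like` preset is a five-species tree,
((albonigra, sp1), (ambusta, (nigrifacta, ustulata))), heights
0.010–0.015, θ = 0.0005. No point estimates of θ/τ are published for such
complexes — coalescent studies report priors, e.g. IG(3, 0.002) — so the
preset is calibrated to the *observed distance structure* instead:
within-species p-distance essentially always below ~0.3 % (with
θ = 0.0005 the probability that a within-species pair diverges beyond
0.5 % is e^(−10)), between-species distance ≥ ~2 %. A `tight_complex`
variant (heights 0.0035–0.0075) places between-species distances around
1 % for experiments where clusters should merge inside the grid.

A caution the package's own tests quantify: at θ = 0.002 with four
sampled lineages, the within-species TMRCA is hypoexponential with
P(2·TMRCA > 0.5 %) ≈ 1.8·e^(−2.5) ≈ 0.15, so at the 0.5 % threshold each
species splits with roughly 10–15 % probability and all five resolve
simultaneously in only ~50–65 % of replicates. Recovery at a fixed
threshold is a property of θ relative to the threshold, not of the method;
the acceptance script reports recovery rates under both θ = 0.002 and the
calibrated θ = 0.0005 so the dependence is visible.

Degradation emulates database records: truncation to a single spacer
(other columns `?`), per-site replacement of bases by IUPAC codes that
contain them, and substitutions planted inside 5.8S. Flags are recorded in
the truth table, and degraded records are written with role `query` so the
pipeline exercises the exclusion-and-placement path by default.

### What the simulator does not emulate

Alignment error and indels (real ITS alignments of congeners contain
both), chimeras, intragenomic ITS polymorphism, rate variation across
sites beyond region multipliers, and base-composition heterogeneity
between lineages. Passing tests therefore demonstrate the correctness of
the clustering/evaluation/placement machinery and the calibration of the
coalescent model — not robustness to alignment artefacts, which real-data
users should assess by inspecting their alignment.

## Numerical and design choices

- Cluster labels are the lexicographically smallest member id:
  deterministic, order-invariant.
- `-` (alignment gap) and `?` (truncation) are distinct in files for
  provenance but identical to distance and diagnostic code.
- Measurement summaries use the sample (n−1) SD and interpret low/high as
  mean ∓ 1 SD — the convention of the description standard the notation
  comes from; it is configurable (5th/95th percentiles) because printed
  descriptions rarely state it. Bounds are clamped into [min, max] before
  rounding so the five numbers are always ordered; extremes are treated as
  observed min/max.
- Monte-Carlo tests assert within 3 standard errors at fixed seeds:
  2000 replicates for coalescent expectations, 10⁵ sites for the JC69
  closed form, 10⁴ draws for the inverse-gamma mean.
- The acceptance script uses 60 replicate complexes for clustering
  quantities and the Monte-Carlo sizes above; everything completes in a
  few seconds on one CPU.

## Known limitations

- The p-distance treats every ambiguity as missing; records that are
  mostly ambiguous retain few comparable sites and drop to the missing
  state rather than receiving a noisy distance.
- `align_query` drops query insertions relative to the reference; a query
  with a genuine insertion at a diagnostic column cannot match there.
- With very low θ, within-species sequences are often identical and the
  minimal resolving threshold is legitimately 0.0 on the grid; the
  interesting statement is then "resolved at every t ≤ 0.5 %", which the
  per-threshold status table shows.
- Complete/average linkage modes require complete distance matrices;
  datasets with short-overlap pairs are single-linkage only.
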