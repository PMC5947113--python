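# Methods

## The phenotyping problem

Root system architecture (RSA) of *Arabidopsis thaliana* is usually
quantified at seedling stage, where one primary root is unambiguous and
everything else is a lateral. In mature plants (roughly three weeks and
older, e.g. grown in hydroponics), several root axes reach comparable
length and diameter and the primary root can no longer be singled out.
The package therefore phenotypes by **mature root units (MRUs)**: each
basal axis with its attached first-order laterals (LR) and second-order
"secondary" laterals (2′-LR) forms one unit, and the *main root* of an
MRU is simply its longest base-to-tip axis. The scheme deliberately stops
at order 3; an axis of order 4 is a hard error, not a silent merge.

## Trait definitions and conventions

Per plant, with all lengths in cm:

- `TRL` — total root length, the sum over all axes.
- `TRTN` — total root-tip number: axes strictly longer than the tip
  threshold (default 0.05 cm = 0.5 mm, the practical limit for calling an
  emerged root on a flatbed scan).
- `TRD = TRTN/TRL`, `LRD = LRN/PRL`, `2′-LRD = 2′-LRN/TRL` — density
  traits. A density with an empty denominator is reported missing, never
  0 or infinity.
- `PRL` — "primary root length" generalized to MRUs. The published trait
  is defined only loosely ("linear stretch of the whole root system"), so
  the default here is the sum of main-axis lengths over MRUs, which makes
  LRD read "laterals per cm of main axis"; `prl_mode="max_extent"`
  switches to the single longest main axis.
- `LRL-1Q..4Q`, `LRN-1Q..4Q` — each main axis is divided into four
  equal-length sections from base (1Q) to tip (4Q); lateral length and
  count are tallied per section. Quarters are half-open intervals, closed
  at the tip, so positions on a boundary go to the more tip-ward quarter
  and the partition is total and deterministic.

Two readings of the 0.5 mm rule exist: filter only the tip count (so LRN
still includes just-emerged laterals, which dominate 4Q), or filter every
count. The default is `tips_only`; `threshold_applies_to="all_counts"`
gives the stricter reading. Raising the threshold can only decrease TRTN
(tested as a monotonicity property).

## Axis resolution from segment graphs

Skeletonizers emit an undirected segment graph, not ordered axes. The
resolution rule: within each subtree hanging off the base node, the main
axis is the maximum-total-length base-to-tip path; branches off that path
become laterals recursively, with insertion position measured from the
parent axis base. Ties between equally heavy continuations are broken
toward the lexicographically smaller node id, and sibling branches are
emitted in node-id order, so the output is invariant under edge
reordering and stable across runs. Cycles and disconnected graphs are
errors (the unreachable nodes are listed). This heaviest-path convention
is this package's own reproducible formalization of "the main root is the
longest root observed in each MRU"; a human scorer facing a lateral
longer than its bearing axis might decide differently.

## RSML and units

RSML 1.0 is the exchange format. Everything internal is cm; files whose
metadata lack a resolvable physical length unit are rejected outright
(no silent pixel assumption). Geometry is optional — all traits depend
only on lengths and insertion positions, so topology-only files (lengths
and insertion positions as RSML properties) are first-class. Round trips
preserve topology exactly and lengths/positions to well below 1e-6 cm.

## Hormone layer

Concentrations are pg per mg root dry weight. The quantification
arithmetic mirrors targeted isotope-dilution LC-MS/MS: an ordinary
least-squares calibration line per analyte, inverted and divided by the
fractional recovery of the labelled internal standard; a response at or
below the intercept is censored (below LOD) rather than clamped to a
negative or zero concentration. No numeric LODs are built in — the
default LOD is 0 (no censoring) and per-analyte thresholds are supplied
by the caller. Censored values are excluded from all summaries (never
zero-imputed) and every summary carries its effective n.

Variation across accessions is expressed by the variance percentage
`Y = ((X − A)/A)·100`, where A is the unweighted mean of the accession
means (replicates averaged first; a replicate-pooled A is a config
option). Per analyte the package reports the *envelope* (max |Y|) and the
*fold range* (max/min of accession means). Both are scale-invariant.
tZ(O,9)G is a single analyte throughout: the O- and 9-glucosides co-elute
chromatographically and are never split.

## Association layer

Input is an accession × variable table (trait means joined with hormone
accession means). Pearson r is computed pairwise-complete, with two-sided
p-values from t = r√(n−2)/√(1−r²) on n−2 df and the per-cell pair count
recorded; pairs with fewer than 3 complete observations or a
zero-variance member are undefined with a warning. Flags mark raw
P < 0.05 (*) and P < 0.01 (**) by default — unadjusted, matching the
usual presentation of such correlation tables; Benjamini–Hochberg is
available behind `adjust="bh"`. The t-based p agrees with a
10,000-permutation null to a few 1e-3 on the test fixture.

PCA is the eigendecomposition of the correlation matrix of the
complete-case table (equivalently, PCA on standardized variables), with
variance fractions eigenvalue/Σeigenvalues and a deterministic sign
convention (each component's largest-magnitude loading is positive),
since eigenvector signs are otherwise arbitrary. Hierarchical clustering
of variables uses 1 − r distance with average linkage by default (both
configurable), and exports an ultrametric Newick string. Both the
complete-case PCA and the pairwise-complete correlations are conventions
the package logs; the underlying study did not state its missing-data
handling.

## Synthetic generator

The generator defines the study conditions every test runs under.

**Architectures.** n_MRU = 1 + Poisson(2.0); main lengths log-normal
(median 8 cm, σ 0.25); lateral counts per quarter Poisson with rates
(3, 4, 3, 1.5) — densest mid-axis, sparse at the tip; lateral lengths
log-normal with per-quarter medians (1.5, 1.0, 0.5, 0.15) cm (σ 0.5),
encoding the basipetal age gradient (tip-ward laterals are younger and
shorter); 10% of laterals are drawn as just-emerged roots below the
0.05 cm tip threshold; each lateral bears a secondary lateral with
probability 0.3 (log-normal, median 0.3 cm). Fresh weight is simulated
as TRL × 0.15 mg/cm with 10% log-normal noise. Poisson and log-normal
are the simplest families matching the qualitative shapes of count and
length data; the rate and length values are this package's choices of a
realistic 23-day-old hydroponic plant, fixed once.

Ground truth is book-kept during generation — never by calling the
extractor — accumulating per-axis contributions in the same axis order
the extractor iterates, so extractor/ground-truth agreement is exact
(bitwise), not approximate. Insertion positions are drawn strictly inside
their quarter (uniform on the central 96% of the interval) so the quarter
label is unambiguous under floating-point arithmetic.

**Hormone panels.** 13 accessions, 6 phenotyped plants and 4 hormone
replicates per accession; 11 analytes (IAA, ABA, GA9 and the eight
cytokinins iP, iPR, tZ, tZR, DZR, tZ7G, tZ(O,9)G, cZ). Baseline
concentrations are plausible invented values (e.g. IAA 50, tZ 1.5 pg/mg
DW). Class envelopes are enforced *exactly* by affine rescaling of the
drawn accession means — free bases ±10%, ribosides ±50%, tZ glucosides
±30%, IAA/ABA ±25%, cZ ±50%, GA9 a three-fold range between extremes —
rather than by rejection sampling, so envelope checks need no tolerance.
Replicate noise (CV 8%) is mean-centred within each accession × analyte
cell, so the accession means realized from the table equal the enforced
means while replicates still scatter.

**Coupling.** One latent factor z per accession drives both sides:
architecture parameters are scaled by exp(0.3·z + g), where g is a fixed
small→large accession gradient (±0.1), and each analyte's accession means
are shifted by loading·z before envelope enforcement (affine rescaling
preserves the correlation sign). Default loadings: IAA +1, tZ −1, ABA −1,
GA9 −0.8, ribosides/glucosides/cZ +0.5, iP 0 — auxin tracks root-system
vigor positively, the active cytokinin, ABA and GA9 negatively. Setting
all loadings to 0 yields a null panel for calibration checks.

What the generator does **not** emulate: measurement error of the
scanning/tracing step, root overlap and disentanglement artifacts,
non-Gaussian accession structure, hormone covariance beyond the single
latent factor, and any mechanistic (auxin-transport) growth dynamics.
Passing tests therefore demonstrate correctness of the arithmetic and
the statistical machinery under a known model, not biological validity
on real scans.

## Problem sizes and numerics

The repeated-seed studies (extractor oracle, sign recovery, null flag
rate) use 200 seeded studies of 13 accessions × 6 plants, which the
package runs in well under a minute; the permutation oracle uses 10,000
permutations of a 10-point fixture. Sign recovery of the imposed IAA(+)
and tZ(−) couplings against TRL succeeds in ≥95% of seeds (observed:
100%), and the null-panel flag rate at P < 0.05 sits within three
binomial standard errors of 5% (2,200 hormone×TRL tests). Arithmetic
identities (TRD·TRL = TRTN, Σ quarters = totals, TRL = PRL + LRL +
2′-LRL) are asserted at 1e-9; RSML round trips at 1e-6 cm.

## Determinism

All randomness flows from one explicit integer seed through
`numpy.random.SeedSequence`. Pipeline bundles embed the package version
and a hash of the canonicalized run manifest in every output file, and
two runs with the same config and seed are byte-identical (verified by
hashing whole bundles in the tests).

## Known limitations

- The heaviest-path main-root rule is a convention; manual phenotyping
  may disagree on pathological topologies (e.g. a lateral outweighing
  its bearing axis).
- PCA/clustering run on accession means (13 rows); replicate-level
  association is out of scope.
- The published correlation tables themselves are not recomputable from
  printed per-accession numbers, so the association layer is validated
  against closed forms, permutation nulls and imposed synthetic
  couplings rather than against the published cell values.
- Hormone quantification covers the calibration arithmetic only; peak
  picking and retention-time alignment are out of scope.
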