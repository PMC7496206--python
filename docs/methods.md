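# Methods

## Study model

The pipeline models a three-condition glucose-stimulation experiment in
a beta-cell line: one RNA-seq library (gene FPKM) and one small-RNA-seq
library (miRNA RPM) per condition (low, moderate, high glucose), with
the moderate condition as the reference. There are no replicates, so no
variance model and no p-values at the differential-expression step:
calls are fold-change-only, which is exactly what the design supports.

## Differential expression

For each comparison (low vs moderate, high vs moderate) an entity is
first checked against the low-abundance floor: abundance strictly below
`min_abundance` (default 10 FPKM / 10 RPM) in *both* compared samples
marks it `filtered` for that comparison; the floor is applied per
comparison, not globally, so an entity can be filtered in one
comparison and called in the other. Fold change is
`(sample + c) / (reference + c)` with pseudocount `c = 0` by default;
with `c = 0` and a zero reference the result is `inf` when the sample
is expressed and 1 when both are zero. In practice the floor removes
double-low entities before zero-handling matters, which is why a
pseudocount of 0 is a safe default; a positive `c` is available for
floor-free analyses.

Default cutoffs are inclusive — a fold change exactly at the bound is
called: genes up ≥ 1.5 / down ≤ 0.67, miRNAs up ≥ 1.4 / down ≤ 0.71.
These are the definitions used for network construction. A second gene
preset (1.2 / 0.83, exclusive bounds) is shipped as
`METHODS_MRNA_THRESHOLDS` for users who want the looser screen; both
are plain `Thresholds` values and fully configurable, including
per-bound inclusivity.

## Profile taxonomy

The verdict pair maps totally onto nine classes (rows = low vs
moderate, columns = high vs moderate):

|        | high up | high nc | high down |
|--------|---------|---------|-----------|
| low down | I     | LD      | M         |
| low nc   | HI    | FLAT    | HD        |
| low up   | V     | LI      | D         |

The inverse map I↔D, M↔V, LD↔LI, HI↔HD is a fixed-point-free involution
on the eight non-FLAT classes and satisfies
`classify(flip(verdicts)) = inverse(classify(verdicts))` over the whole
grid — both are asserted as properties in the test suite. Entities
that pass the floor in only one comparison are kept as FLAT with a
warning rather than dropped: bookkeeping stays total over the measured
entities while pairing (which skips FLAT) never sees them. Entities
filtered in both comparisons are dropped.

## Evidence and the consensus rule

Candidates merge from an experimental table (strong = reporter assay /
Western blot, weak = CLIP-class) and per-tool prediction tables
(miRanda, PITA, TargetScan, RNAhybrid; score plus duplex MFE in
kcal/mol). Merging is keyed on (miRNA, gene), OR-combines the flags and
unions the hit sets, keeping the best duplicate per tool (lowest MFE,
then highest score); it is order-independent.

The consensus rule for predicted-only candidates: at least 3 supporting
tools, at least one hit with MFE ≤ −10 kcal/mol, and — when a miRanda
hit is among the supporters — miRanda score ≥ 140. Three deliberate
interpretations, all configurable:

* The MFE cutoff is on the physical (negative) scale; a nominal "≤ 10"
  reading would accept every duplex, so the implemented test is
  `mfe ≤ −10`.
* The miRanda score constraint binds only when a miRanda hit exists,
  since 3-of-4 must remain satisfiable without miRanda;
  `require_miranda=True` makes it mandatory.
* The MFE constraint is satisfied by *any* supporting hit by default
  (`mfe_all_hits=True` for the strict variant), because no single
  tool's MFE is canonical for a pair.

Levels resolve by precedence 1 (strong) > 2 (weak) > 3 (consensus) >
none; adding evidence can never weaken a level.

## Network assembly

An mti edge requires: resolved level 1–3, both entities non-FLAT, the
gene's profile the inverse of the miRNA's, and the miRNA actually
changed under the requested condition. Condition semantics: LD/LI types
belong only to the low-glucose networks and HI/HD only to high, while
I/D/M/V (changed in both comparisons) contribute to both conditions
with their per-comparison direction — so such pairs are intentionally
present in both condition's outputs, and the manifest notes this.
Edges partition into high-DN / high-UP / low-DN / low-UP by (condition,
miRNA direction). Hub miRNAs are those regulating strictly more than
`min_targets` (default 10) distinct genes. The TF layer keeps
TransmiR-style rows whose TF gene and miRNA are both non-FLAT, carrying
the table's regulation sign. All orderings are lexicographic so outputs
are reproducible byte-for-byte. Exports: SIF (interaction labels
`mti_L1..mti_L4`, `tf_mirna`), GraphML with full node/edge attributes,
and an edge TSV that round-trips exactly.

## Ago2 IP intersection

IP support is decided at the entity level: a gene is supported at
FPKM ≥ 8, a miRNA at RPM ≥ 100, in any provided IP library column
("below the floor is filtered", so a value exactly at the floor is
kept). An edge is promoted to level 4 iff both endpoints are supported;
the operation is a pure reduction (output ⊆ input) and monotone in the
thresholds. Entity-level rather than interaction-level intersection is
the documented choice: IP expression tables identify RISC-loaded
molecules, not binding events.

## Enrichment

Over-representation uses the exact upper-tail hypergeometric
P(X ≥ k) for k query hits in a term of size K, query size n,
background N, via `scipy.stats.hypergeom.sf`; an independent
closed-form enumeration (binomial coefficients) verifies it to 1e-12
for all N ≤ 25 in the tests. Benjamini–Hochberg adjustment is the
default (Bonferroni optional) through `statsmodels`; raw p-values are
always reported. The default background is the expressed
(floor-passing) gene set — the conservative choice when the universe is
unstated — and is configurable. Term sets come from annotations or GMT
files; results are ranked by raw p and truncated to the top 20 by
default. Keyword sub-networks retain an edge in category c ∈
{G, O, E, C} iff its target gene carries c.

## Synthetic data generator

The generator emulates the study's inputs with planted truth. Defaults
(the study conditions at desk scale): 200 genes, 60 miRNAs; half of
each matrix FLAT and the rest uniform over the eight DE types;
moderate abundances 2^N(6, 1.5) (median ~64, a plausible
FPKM/RPM scale), truncated from below at `floor × 2^effect` so a
planted 2-fold drop can never fall through the abundance floor; planted
effect 1.0 log2 units (2-fold, strictly beyond every default DE cutoff
— the configuration refuses effects that are not); multiplicative
log-normal noise with sd 0.1 log2 units (noise is multiplicative
because abundances are positive and the analysis lives in log2
fold-change space); 50 true interactions (frac 50/12000) sampled
uniformly from inverse-profile DE pairs, with evidence tiers 20 %
strong / 20 % weak / 60 % predicted; decoys at half the true rate,
sampled uniformly from non-true pairs, each violating the consensus
rule in one of three ways (too few tools, miRanda score below 140, no
stable duplex); IP support Bernoulli(0.4) per true pair, realised as IP
abundances above both floors for supported entities and below for all
others; 5 TFs with out-degree 4 among DE entities; annotation
categories at 15 % per keyword and 20 terms at 10 % membership.
Profile-mix and tier-mix counts are apportioned exactly
(largest-remainder), so planted count checks are deterministic; all
sampling flows from one `numpy` Generator seeded by `seed`, and runs
are bit-reproducible.

What the generator does *not* emulate: count-level sampling noise
(negative binomial), library-size artefacts, miRNA families and shared
seed sites, correlated tool errors, or the condition dependence of IP
efficiency. Passing tests therefore demonstrate that the pipeline's
logic is correct and self-consistent — filters, taxonomy, consensus
rule, pairing, reduction, enrichment — not that the thresholds are
optimal for real sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run at 200×60 (main run), 100×40 ×
20 seeds (noise robustness) and 200 genes × 20 terms × 20 seeds
(enrichment); these sizes give stable statistics while keeping the
whole suite in seconds. Ties are broken lexicographically everywhere;
manifest hashing excludes the output directory so the same analysis in
two locations hashes identically; the level-4 reduction ratio for an
empty input is defined as 1.0 (nothing was removed).

## Known limitations

Headline counts from any real study (numbers of DEGs/DEmiRs, network
sizes, IP reductions) depend on its libraries and database versions and
are not reproducible from synthetic data; the pipeline reports its own
counts per run. Identifier mapping across species/databases, miRNA
family collapsing, binding-site-level IP analysis and GO DAG
propagation are out of scope.
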