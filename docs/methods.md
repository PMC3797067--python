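# Methods

This note documents the models, conventions and numerical choices behind
mitorho, and what its validation does and does not establish.

## Coordinates, notation and the reference problem

All variants are 1-based rCRS-relative (molecule length 16,569).
Accepted token dialects: `T16298C`, bare `16223T`, transversions by
suffix (`A16318T`), back mutations `@16129` / `@G16129A` (both normalise
to the same reversion variant), insertions `315+C`, deletions `16166d`,
IUPAC point heteroplasmies (`16093Y`, parsed but flagged and dropped by
the default masking policy). Figure-style annotation suffixes (`s`,
`-t`, `-r`, `-nc`, amino-acid parentheses, `*` gene-overlap prefix) are
carried verbatim and never affect equality: two tokens denote the same
variant iff they agree on position, derived state and back-mutation
status. This makes `16223T` and `C16223T` interchangeable across
heterogeneous published tables.

The package does not ship the rCRS sequence. Instead `reference.py`
carries a table of bases *attested* at the positions used by the shipped
motifs (a published token `T16298C` fixes rCRS[16298] = T) plus a few
canonical control-region facts, and a deterministic **synthetic**
full-length stand-in that agrees with the table and is pseudo-random
elsewhere. Reference-base validation is therefore strict at attested
positions and permissive elsewhere (`ref_check="strict" | "warn" |
"off"`). Alignment diffing (`diff_aligned`) defaults to the synthetic
stand-in — fine for simulation and tests; pass a real reference when
diffing real alignments.

Hotspot policy (defaults chosen to match standard founder-dating
practice): positions 16182, 16183, 16519 masked; indels inside the
303–315 length-variable tract dropped; point heteroplasmies dropped.
Point substitutions inside 303–315 are kept. The default HVS-I window is
16024–16400 (some compilations stop at 16365; the window is an explicit
`SeqRange` everywhere, so narrower conventions are a parameter, not a
code change).

## Haplogroup model and classification

A haplogroup tree is an indented text file of named clades, each
carrying the diagnostic variants of its branch; back mutations are
allowed and remove the ancestral variant from the cumulative motif. A
per-tree alias table maps published synonym tokens onto canonical ones
(the packaged tree maps `A16344G` → `A16343G`: the two spellings denote
the same U3 landmark, and 16344's reference base is already attested as
C by the M35b2a1 profile, so the 16343 spelling is the consistent one;
both are recorded).

Classification scores every node as `score = |matched| −
|missing_covered|`. Private variants cost nothing — founder clades are
recognisable despite private mutations. Diagnostics outside the record's
sequenced range are neither penalised nor credited; if any exist at the
winning node the assignment is flagged `candidate` (an HVS-I-only record
can never *confirm* a clade defined partly by coding variants). Ties
break by score, then **fewer uncovered diagnostics**, then depth, then
name. The second key is deliberate: with depth alone, an HVS-I-only
record carrying just a clade's basal control-region variant would slide
to the deepest descendant whose extra diagnostics are all unobserved —
an assignment the data cannot support. With the implemented rule the
record stays at the shallowest clade consistent with everything the
record actually covers, while fully-typed records still descend to the
exact node.

The packaged mini-tree transcribes published control- and coding-region
motifs for the terminal clades it names; stem/scaffold nodes whose
published definitions are relative to non-rCRS ancestors (or simply
unpublished here) carry schematic stand-in diagnostics, marked as such
in the file header. The tree is a classification aid for the shipped
analyses and tests, not a nomenclature authority.

`search_motif` is range-aware: a record lacking coverage of any motif
position is *not evaluable* rather than a non-hit, and hits can be
filtered by classifying them and disregarding named clades (the
"compatible but unrelated branches" problem: the same control-region
pair can occur in distant haplogroups).

## Maximum-parsimony trees

Trees are rooted at a designated basal motif, never midpoint- or
outgroup-rooted: founder dating always measures distance to a named
root haplotype. Differences from the root — gains of new variants and
losses of root variants, the latter becoming back-mutation events —
are binary presence/absence characters; identical haplotypes collapse
to one tip with a multiplicity before any search.

Construction is exact for instances within the verification bounds
(≤ 7 distinct haplotypes, ≤ 12 segregating characters): every rooted
binary topology is scored by Fitch counting with the root state fixed
to the basal motif (bit-plane encoded, so the enumeration is cheap),
and the best topology is reconstructed into explicit per-branch
mutation lists, preferring to keep the parental state so mutations are
placed as late as ties allow. Beyond those bounds a greedy recursive
partition is used: haplotypes split on the character carried by most of
them, ties preferring the *less* mutable site (hotspot-weighted
spectrum), so recurrent events are pushed onto hypermutable positions.
The greedy route was benchmarked against the exhaustive minimum on
thousands of random coalescent instances: it is optimal on the large
majority but not all (typical shortfall one event on adversarial
four-gamete conflicts), which is why small instances use exact search
and why `brute_force_min` — an independently coded enumeration oracle
with set-based Fitch counting — guards the builder in the test suite.
Every built tree is checked against the path-reconstruction invariant:
replaying branch mutations from the root reproduces each tip's variant
set exactly.

Determinism: children are ordered by (first mutation position, smallest
tip id); topology enumeration order is fixed; rebuilding from permuted
input yields byte-identical Newick and branch tables.

## Founder dating

With branches *b* carrying *m_b* mutations above *n_b* tips out of *n*
sampled haplotypes (multiplicities included — identical sequences each
count, since ρ is an average over sampled haplotypes):

ρ = (1/n) Σ m_b n_b,  σ = sqrt((1/n²) Σ m_b n_b²).

ρ equals the plain average of per-tip root distances (asserted both ways
in the tests). The default clock is linear: one substitution per
3,624 years over the whole molecule with hotspots masked, the corrected
(purifying-selection-adjusted) whole-mtDNA rate in standard use for
founder dating; it is a parameter, not a constant. A
`PiecewiseClock` accepts any monotone substitutions→years mapping whose
knots the user supplies, for time-dependent corrections published as
tables. The 95 % interval is ρ ± 1.96 σ pushed through the clock and
truncated at zero — young clades with few mutations legitimately get a
CI touching zero. Clock scope (whole molecule vs control region) must
match the sequenced range the tree was built from unless explicitly
overridden; counting uses all non-hotspot substitutions (no
synonymous-only dating).

## Summaries

Frequency tables map assignments through an ordered category scheme
(clade expressions like `HV(×H)`; first match wins; `other` is the
paragroup of records assignable to no listed category). The ancestry
partition applies rule-set components in order: by default South Asian =
M(×M1), sub-Saharan = L outside M and N, West Eurasian = N-derived plus
M1, with the alternative reading of M1a1 as African shipped as a second
rules file — the partition is data, not code. Both outputs assert their
normalisation invariants on construction. Diversity summaries compare
records on an explicit common range (default: intersection of declared
ranges) and report distinct-haplotype counts and the basal-motif
fraction.

## Synthetic data

The generator emulates the regimes the analyses must handle, with one
seeded NumPy stream per run (same seed ⇒ bit-identical output):

* **Genealogies** — star trees (n branches of exactly the requested
  TMRCA) for founder expansions; Kingman coalescents (exponential waits,
  rate k(k−1)/2 per 2·Ne_f generations, generation time 25 y, default
  Ne_f = 1,000) for deeper structure, optionally rescaled to a fixed
  TMRCA. Trees are ultrametric.
* **Mutations** — per-branch Poisson(rate × years) with positions drawn
  from a hotspot-weighted spectrum (16182/16183/16519 ×50, the 303–315
  tract ×20, a few fast sites ×5–10, baseline 1) and a transition bias
  of 20:1, in the range reported for the control region. No position
  repeats along a root-to-tip lineage, so no back mutations are
  simulated; recurrence across lineages arises naturally from the
  spectrum, and `force_perfect` disables even that for oracle fixtures.
  `observable_spectrum()` restricts draws to non-masked sites; the
  recovery studies use it so that the target μT is defined over events
  the estimator can see.
* **Databases** — records are the cumulative motif of a node drawn from
  a clade-expression composition (counts follow the fractions exactly by
  largest-remainder rounding) plus Poisson private mutations placed away
  from every diagnostic and hotspot position, with a truth table. The
  default study composition (25 % M(×M1), 74.5 % N-derived, 0.5 % L over
  1,000 records) mirrors the ancestry make-up reported for compiled
  European Romani control-region databases.

What passing on synthetic data shows — and what it does not: the
pipeline recovers planted truth under the generator's assumptions
(no recombination, no selection, no heteroplasmy, no sequencing error,
private mutations never on diagnostic positions, ranges exactly as
declared). Real compilations violate several of these (documentation
errors, phantom mutations, ambiguous ranges), so classification
accuracy on real tables should be expected to be lower than the 100 %
generator-truth recovery, and the `candidate` flag plus row-level
diagnostics exist precisely to surface those cases.

## Validation numbers and problem sizes

The shipped studies use: 200 random oracle-sized instances for the
parsimony comparison; 500 star replicates (n = 20, μT = 2) for the
recovery/coverage study, where the mean ρ̂ is required within 3
Monte-Carlo SE of 2 and empirical 95 % CI coverage within [0.90, 0.98]
(observed ≈ 0.93–0.95 — the heuristic σ is mildly anti-conservative, as
expected of a genealogy-plug-in error estimate); 300–1,000-record
databases for classification, search and partition recovery. These
sizes make the whole suite run in well under a minute while leaving the
Monte-Carlo tolerances meaningful.

## Known limitations

Exact parsimony is exponential and deliberately guarded; large clades
get the greedy heuristic with no optimality certificate. The σ
estimator ignores topology uncertainty. The packaged clock is linear;
users wanting the full time-dependent correction must supply its knots.
The mini-tree's scaffold diagnostics are schematic, so classifications
of real records at scaffold level (M, N, L stems) are structural
conveniences, not nomenclature claims. HVS-I-only data cannot confirm
clades defined by coding variants — such assignments are always
`candidate` — and motif searches on partial records report
non-evaluable rather than guessing.
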