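# Methods

## Problem setting

A *mini-barcode* is a short (~100–200 bp) diagnostic DNA region used for
species identification when template DNA is too degraded for full-length
barcodes — typically trace or environmental DNA such as predator scats.
Designing one from an aligned reference database requires two opposing
properties at once: a core region variable enough that every pair of
species differs within it, and flanking sites conserved enough across all
target taxa to carry a single universal primer pair.  `minibarc`
implements the complete in-silico side of that workflow for a reference
alignment of mitochondrial sequences (the motivating application is a
178-bp fragment of the mammalian 12S rRNA gene used to discriminate
Australian mammalian predators from scat DNA).

## Distances

All analyses are built on pairwise distances with **pairwise deletion**:
for each sequence pair, any alignment column in which either member
carries a character outside `{A,C,G,T}` (gap, `N`, or a partial IUPAC
code) is excluded.  Two models are provided:

* the **raw (p) distance**, the proportion of differing valid sites; and
* the **Kimura 2-parameter (K2P) distance**

  d = −½ · ln((1 − 2P − Q) · √(1 − 2Q)),

  where P and Q are the transition (A↔G, C↔T) and transversion
  proportions.  When the log argument is non-positive (saturation) or a
  pair shares no valid site, the distance is *undefined* and propagates
  as missing; undefined distances never count as matches in any
  identification test.  Because P and Q derive from integer counts, a
  distance of exactly 0.0 occurs precisely for pairs identical on all
  mutually valid sites, so all zero-proportion statistics use exact
  equality rather than a floating tolerance.

Distance matrices are computed by one-hot inner products over the
selected columns (BLAS matrix products of exact small integers), which
makes dense sliding-window recomputation cheap: the 175-bp profile of a
174×901 alignment takes on the order of a second.

## Sliding-window diagnostics

For a window width *w* (design widths 100/125/150/175 bp for the barcode
core, 20/25/30 bp for primer sites, stride 1, windows only fully inside
the alignment) each window reports:

* mean K2P distance over defined pairs;
* proportion of zero cells among defined off-diagonal pairs;
* number of **diagnostic nucleotides**: columns where some species is
  fixed for an unambiguous base that no member of any other species
  carries.  The count is the union over species (one column counts once
  even if diagnostic for several species); the per-species sum is also
  reported so either convention can be compared against published
  profiles;
* proportion of zero **non-conspecific** distances — the discrimination
  criterion.

A **barcode candidate** is a maximal run of window starts whose zero
non-conspecific proportion is exactly 0.  Run length is reported as
`last_start − first_start` by default (the convention under which the
published 344-bp candidate equals window starts 66 through 410); the
inclusive (`+1`) and covered-span (`+w`) conventions are available via a
flag because interval conventions in published coordinates are often
ambiguous.  A **primer-site candidate** is a maximal run of
primer-width windows with zero non-conspecific proportion > 0.8 and at
most 1 diagnostic nucleotide.

## Identification tests and threshold choice

Each database sequence is treated in turn as a query against all others
(self excluded), using raw distances by default:

* **nearest neighbour** — true iff a conspecific sits at the minimum
  defined distance;
* **best close match** — among sequences strictly within threshold *t*,
  judge only those at the minimum distance: all conspecific → correct,
  none → incorrect, mixed → ambiguous; none within *t* → no ID;
* **threshold ID** — judge *all* sequences within *t* by the same rule.

The working threshold minimises the **cumulative error** over a grid
(default 0.1 %–10 % in 0.1 % steps): false positives (in-threshold match
set contains a heterospecific) plus false negatives (no in-threshold
match although conspecifics exist).  Singletons without in-threshold
matches are true negatives.

Conventions the literature leaves open were frozen once, before any
evaluation, and are configurable: "within threshold" is strict `d < t`;
nearest-neighbour ties use the optimistic rule (any tied conspecific
counts — this preserves the defining behaviour that a *singleton*
species, with no conspecific in the database, is automatically false);
the scan tie-break takes the smallest threshold attaining the minimum
error.

## Amplicon trimming and query classification

Primer sites are located by IUPAC-aware matching of the primer (reverse
primers reverse-complemented first) against every degapped row with
alignment columns tracked through gaps; the modal span across rows wins,
tolerating up to 4 mismatches per row (20 % of a 20-mer) so that the
0–1 diagnostic mismatches a conserved site may carry do not break
localisation.  Trimming slices every record to the insert between the
two sites.

Query fragments are assigned by semi-global pairwise alignment against
each degapped reference (match +1, mismatch −1, gap −2; reference
overhang free, query aligned end-to-end).  The identity is
`matches / aligned non-terminal columns` (internal gaps are mismatches);
queries must be ≥50 bp, and an assignment requires ≥70 % identity.  The
query overhang is deliberately *not* free: with both ends free, any
short perfect overlap between unrelated sequences would score 100 %
identity.  Best-close-match semantics on the distance `1 − identity`
give the outcome (assigned / ambiguous / no ID, or correct / incorrect
when the true origin is known).  Queries with >5 % ambiguity codes
trigger a mixed-template warning; chromatogram processing is out of
scope.

## Synthetic data generator

The generator plants the structure every stage is tested against: a star
phylogeny (one ancestor, one branch per species, one branch per
individual) with species-branch substitutions confined to a variable
region, individual-branch substitutions anywhere outside two perfectly
conserved flanks, transitions favoured over transversions by κ, verbatim
duplicate copies, and singleton species.

Per-branch, per-site substitution probabilities are calibrated
analytically: with probability *m* on *w* mutable sites out of *L*, the
expected whole-alignment raw distance between two branches is
`(w/L)(2m − (1+c)m²)` with `c = (κ²+2)/(κ+2)²` the chance two
independent substitutions of one base coincide; the quadratic is
inverted for *m*.  Rates implying more than 0.75 expected differences
per mutable site are rejected as infeasible.  A single
`numpy.random.default_rng(seed)` stream drives everything, so one seed
determines the output byte-for-byte across platforms.

Defaults are a scaled-down predator panel chosen to mirror the
motivating study's conditions: 8 species (6 multi-haplotype with 2–4
individuals, 2 singletons; 22 individuals plus 2 duplicate copies),
alignment length 350 bp, a 178-bp variable region (columns 66–243)
flanked by two 20-bp conserved spans, intra-specific divergence 0.005,
inter-specific 0.10 (typical of within- vs between-species mitochondrial
variation in mammals and consistent with working thresholds near 1 %),
κ = 4 (a realistic mammalian mtDNA transition bias).  Query fragments
are 116–178 bp subfragments of the insert with independent per-base
errors (default experiments use 1 %).

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: indels and alignment error (sequences are
generated gapless), rate variation along the sequence within the
variable region, phylogenetic structure deeper than a star (no nested
genera, no unequal branch lengths), ambiguity codes from messy
chromatograms, and taxonomic misassignment in the reference itself (the
kind of GenBank mislabelling the real evaluation uncovered).

## Numerical and degenerate-input choices

* Counts are computed in float64 matrix products and rounded back to
  integers — exact far below 2⁵³.
* Haplotype identity for UNIQUE construction is exact string equality of
  aligned sequences, gaps and ambiguity codes included; collapsing keeps
  the first occurrence, and removal of singleton species happens after
  collapsing, so the operation is idempotent.
* A UNIQUE database that ends up empty (all species singleton) warns
  rather than crashes; identification requires ≥2 records.
* Sequences with no defined distance to any other record are excluded
  from identification counts with a warning, never silently scored.
* No minimum-overlap fraction is imposed on pairwise deletion beyond
  ≥1 valid site (configurable via the column window).
* Duplicate FASTA ids are rejected rather than renamed so report rows
  stay unambiguous.

## Known limitations

Reproducing the published evaluation of the AusPreda_12S marker
(nearest-neighbour 155/19 on the 174-sequence FULL database, and so on)
requires the published reference FASTA files, which are third-party
supplementary data not redistributed here; the corresponding acceptance
checks run only when those files are placed under `data/` (see
`tests/test_acceptance.py`).  All other validation is against
closed-form oracles, exhaustive brute-force reimplementations on small
databases, and planted-structure recovery on synthetic panels of the
sizes above — chosen so the whole suite runs in a few seconds.
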