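# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `pollinet`, in the order data flows through the
pipeline.

## Consensus taxonomic assignment

Input is a 12-column tabular alignment hit file (the classic `outfmt 6`
layout: qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore), fixed at exactly 12 columns and rejected
loudly otherwise — silent column drift is the classic failure mode of
tabular alignment output.

Reads at most 450 bp long are discarded (strictly greater than 450 bp
survives: a 451 bp read is kept, a 450 bp read is not).  Per read:

1. **Top-hit selection.**  "The top 20 bit scores" is deliberately read as
   the top `top_k = 20` *distinct* score values with all ties retained.
   Taking the first 20 rows would make the result depend on file order;
   the distinct-value rule is deterministic and order-invariant, which is
   property-tested with shuffles.
2. **Species rule.**  If every retained hit resolves to one species, assign
   that species.
3. **Genus rule.**  Else, if one genus accounts for ≥ `genus_fraction`
   (default 0.60) of the retained hits — hit-count weighted, not
   score-weighted (the simplest defensible reading) — assign that genus.
   At thresholds > 0.5 at most one genus can qualify; for configured
   thresholds ≤ 0.5 a tie between qualifying genera falls through.
4. **Various / curation / unknown.**  Everything else is `various`.  An
   ordered curation map (keyed on the read id or on the hit set's
   signature, the sorted distinct families of the retained hits) may
   resolve `various` reads to family or tribe; rules naming taxa absent
   from the reference taxonomy are errors.  Unmatched `various` reads and
   reads with zero hits become `unknown`, with distinct logged reason
   codes (`curation_fallthrough` vs `zero_hits`).

Tallying produces an integer insect × taxon matrix whose row sums equal
the number of length-filtered reads per insect (a conservation invariant
checked on every pipeline run), with unknowns in a dedicated column.

No minimum identity or e-value cutoff is applied before the top-k rule;
none is defensible without a specific database, and the thresholds are
configurable where practice differs.

## Profiles and filters

Percentages are computed per insect over identified (non-unknown) reads,
to control for amplification-depth differences; insects with no identified
reads are excluded with a warning.  Presence/absence uses a detection
threshold of `presence_min_reads = 1` read — no detection threshold is
assumed by default, but the knob exists because metabarcoding practice
often uses stricter ones.

The dissimilarity analyses additionally drop taxa identified *above* genus
level (family, tribe, uncurated various) whose study-wide total is
strictly below 1 % of all identified reads; presence/absence otherwise
lets rare coarse taxa dominate the Jaccard index.  The 1 % denominator is
the grand total of identified reads across all insects in the analysis
set, i.e. study-wide, not per insect.  Species- and genus-rank taxa are
never dropped regardless of abundance.

**Entomophilous coverage.**  A site's insect-pollinated flora is its plant
list minus grasses (Poaceae), sedges (Cyperaceae) and rushes (Juncaceae).
A species-rank pollen taxon matches its own species.  A pollen taxon above
species rank is conservatively assumed to represent a single plant
species, however many candidates the sub-list holds, and contributes zero
when it holds none (an absent plant cannot be detected).  Matched species
are counted as a set, so a genus cannot re-count a species already matched
at species rank and the coverage fraction never exceeds 1.  Coverage is
computed per site from the pollen taxa detected at that site.

## Network specialisation

The per-site interaction matrix counts *individuals* of pollinator species
i whose presence/absence profile includes plant taxon j.  The aggregation
from individuals to species is stated explicitly because species-level
indices require one, and summing individual detections is the natural
choice when the underlying data are per-individual presences.

With `m` the grand total, `p_ij = a_ij/m`, marginals `A_i`, `B_j`,
availability `q_j = B_j/m`, natural logarithms:

- `H2 = −Σ p_ij ln p_ij`;
- `H2max` is the entropy of the independence table `A_i B_j/m²` — the
  maximum-entropy coupling of the marginals, possibly non-integer.  Its
  use means `H2′` can in principle exceed 1 by a sliver on integer data;
  values are clipped into [0, 1] with a logged warning;
- `H2min` is the minimum entropy of a *non-negative integer* table with
  the observed marginals.  Table entropy is concave, so this minimum is
  attained at a vertex of the transportation polytope, and every vertex is
  generated by some "allocate min(remaining row, remaining column), cross
  out the exhausted line" order.  `min_table_entropy` runs a dynamic
  programme over remaining-marginal states (keeping the lowest accumulated
  entropy per state), truncated to a beam of 256 states for large
  problems.  The suite verifies it equals exhaustive enumeration on every
  3×3 marginal pair with `m ≤ 12` (1225 instances) and on random 4×4
  instances; beyond that range it is a bounded-effort search without an
  optimality guarantee.  A naive max–max greedy allocation was evaluated
  first and rejected: it misses the optimum on 28 of those 1225 instances
  (subset-sum-like pairings defeat it), and 2×2-cycle local descent cannot
  escape the resulting local minima.
- `d_i = Σ_{a_ij>0} (a_ij/A_i) ln((a_ij/A_i)/q_j)` with
  `dmax_i = ln(m/A_i)`.  Availability includes the focal species' own
  interactions (no self-exclusion), the standard formulation.  `dmin_i` is
  the divergence of the best integer allocation of `A_i` interactions
  proportional to availability.  Because the objective is separable convex
  in the allocation, assigning interactions one at a time to the column
  with the smallest marginal increase is *exactly* optimal (largest-
  remainder rounding, also evaluated, is not: it misses the optimum on
  795 of 6248 small instances).  Ties break on column order.

Degenerate shapes: a 1×n or n×1 network has no meaningful `H2′` and is
flagged rather than scored; a species whose `dmax = dmin` (e.g. a single
column) reports `d′ = 0` with a warning.

## Comparison statistics

**Jaccard distance** is the classic `1 − |x∩y|/|x∪y|` on binary profiles
(scipy's `jaccard`), *not* the binary Bray–Curtis variant some R workflows
produce; the two differ by a monotone rescaling, and the PERMANOVA
pseudo-F is not invariant to it.  Insects with empty profiles are dropped
with a warning.

**PERMANOVA.**  One factor, k groups, n samples:
`SS_total = (1/n) Σ_{i<j} d²_ij`,
`SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`,
`F = (SS_between/(k−1)) / (SS_within/(n−k))`, `R² = SS_between/SS_total`.
Group labels are permuted independently *within* each stratum (collection
site), so insects never move across sites — the analogue of a random site
effect.  The p-value uses the add-one estimator
`(1 + #{F* ≥ F})/(1 + n_perm)` and is never exactly zero; its resolution
is `1/(n_perm+1)`.  `SS_within = 0` (perfectly separated groups) yields
F = +∞ by convention, reported with the minimum-resolution p.  An exact
mode enumerates all distinct within-strata arrangements for small
problems; it exists mainly to validate the sampler.  Degrees of freedom
are reported as `(k−1, n−k)`.

**Contrast battery.**  The a-priori family is one one-vs-rest contrast per
pollinator genus plus one species contrast inside every genus with more
than one species; for the emulated survey's layout (five genera, two of
them multi-species) that family has k = 7 and Dunn–Šidák cutoff
`1 − 0.95^{1/7} ≈ 0.0073008`.  The family size is whatever contrast list
is supplied; omnibus tests are not counted in it.

**Kruskal–Wallis** on site-level d′ values uses mid-ranks and the standard
tie correction (scipy's implementation, cross-checked in the tests against
a direct transcription of the formula), referred to chi-square with
groups − 1 degrees of freedom.  All-identical values leave the statistic
undefined and raise.

## Synthetic survey generator

The generator emulates a three-site, eleven-pollinator-species survey:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 3 | collection sites |
| `n_families × genera_per_family × species_per_genus` | 15 × 2 × 2 = 60 | plant flora |
| `anemophilous_fraction` | 0.2 | flora that is wind-pollinated (up to three families, named Poaceae/Cyperaceae/Juncaceae so entomophilous filtering applies naturally) |
| `ref_length` | 500 bp | barcode reference length |
| `between_genus_divergence` / `within_genus_divergence` | 0.08 / 0.02 | Hamming substitution fractions between congeneric genera / species |
| `n_pollinator_species` / `n_pollinator_genera` | 11 / 5 | pollinator community (round-robin genus assignment) |
| `individuals_per_species_site` | 4 | 132 insects in total |
| `reads_per_individual` | 200 | desk-scale sequencing depth |
| `read_error_rate` | 0.005 | per-base substitution probability |
| `preference_concentration` | 1.0 | Dirichlet concentration: lower ⇒ individuals commit to fewer taxa ⇒ more specialised networks |
| `genus_effect_size` | 1.0 | separation of pollinator-genus preference centroids; 0 makes all pollinator taxa share one preference |
| `site_overlap` | 0.8 | fraction of the flora shared by all sites |
| `anemophilous_background` | 0.01 | constant background load mass on wind-pollinated species |

References evolve hierarchically (family root → genus ancestor at half the
between-genus divergence → species at half the within-genus divergence),
so congeners differ by roughly the configured fractions.  A pollinator
species' preference is a global availability vector modulated by its genus
centroid raised to the genus effect; an individual's true load is
Dirichlet around the site-restricted preference, reads are a multinomial
sample with independent substitution errors, and headers encode the insect
id.  All randomness flows through labelled substreams of one seed
(SHA-256-derived child seeds), so adding a draw to one operation never
shifts another's, and every output is bit-reproducible.

The pseudo-aligner scores reads against every reference by ungapped
identity with bit score `max(0, 2(matches − mismatches))` — a stated
linear ranking, not a Karlin–Altschul score.  References scoring zero
align no better than chance and are not reported.  The reporting depth
`hit_depth` defaults to 1 (ties included): with exactly one reference
accession per species, depth-1 reporting is the analog of a real top-20
hit list against a database holding many near-identical accessions per
species, and it is the only regime in which the species-unanimity rule can
fire at all — at any deeper setting the retained set necessarily spans
congeners and assignment lands at genus level or coarser, a regime the
unit tests exercise explicitly.

**What the generator does not model:** chimeras, primer artifacts, length
polymorphism, PCR amplification bias (the analysis controls for depth only
by converting to percentages), multiple accessions per species,
intraspecific barcode variation, and incomplete reference databases.
Passing tests on synthetic data therefore demonstrate the correctness of
the *analysis chain*, not robustness to those real-data failure modes.

## Problem sizes and numerics

The test suite and the acceptance script run desk-scale configurations
(6–10 plant families, 25–40 reads per individual, 1–3 individuals per
species and site; 20 replicates per condition for parameter-recovery
checks; 500 null datasets × 199 permutations for PERMANOVA calibration) —
chosen as the smallest sizes at which the monotonicity and calibration
properties are stable, and stated here so results are read at the scale
they were computed.  Tolerances: exact-equality claims are asserted to
1e-9 in nats; index values are clipped into [0, 1] only when they stray
beyond by more than floating-point noise, with a logged warning.  Ties
break deterministically everywhere (label order for allocations, stable
sorts elsewhere).

## Known limitations

- `H2max` uses the continuous independence table; an integer-constrained
  maximum would give slightly different (and marginals-dependent) scaling.
- The beam search for `H2min` is exact only where enumeration could verify
  it; very large, very skewed matrices could in principle defeat the beam.
- The stratified PERMANOVA assumes exchangeability within sites; it does
  not model site×genus interactions.
- Published site-level d′ values are reported to two decimals; statistics
  recomputed from them inherit that rounding.
- With a uniform design (species × sites × individuals) the generator
  cannot reproduce ragged real-world sampling such as 143 insects over 26
  species-site combinations; tests that need the ragged layout build it
  from the published tables instead.
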