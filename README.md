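# pollinet

Pollen DNA-metabarcoding analysis for insect pollen-transport surveys:
consensus taxonomic assignment of barcode amplicon reads, per-site bipartite
pollen-transport networks with the specialisation indices H₂′ and d′, and a
presence/absence pollen-load comparison suite (Jaccard distances,
site-stratified PERMANOVA with Dunn–Šidák correction, Kruskal–Wallis on d′).

## The problem

Which plants does each pollinator species actually touch?  Washing the
pollen off individually collected insects, amplicon-sequencing a plant
barcode locus (e.g. chloroplast *rbcL*) and matching the reads against a
reference database turns every insect into a quantitative pollen-load
profile — far more complete than watching flower visits.  Turning millions
of reads into ecological conclusions then takes a specific chain of
decisions: how to call a taxon from a list of alignment hits, how to guard
against amplification bias, how to build and standardise networks, and how
to compare pollen loads between taxa without pseudo-replicating insects
collected at the same site.  `pollinet` implements that chain as a tested,
reusable library and command-line tool, together with a synthetic survey
generator so every stage can be validated end-to-end without any sequence
archive.

## Methods at a glance

**Consensus assignment.**  Reads longer than 450 bp are kept.  For each
read, the hits whose bit scores lie among the top 20 *distinct* score
values are retained (all ties kept, so file order never matters).  If all
retained hits resolve to one species, the read is assigned to that species;
if ≥ 60 % share one genus, to that genus; otherwise it is `various`, which
an expert curation map may resolve to family or tribe; anything left — and
any read without hits — is `unknown`.

**Networks.**  Per site, the interaction matrix `a_ij` counts individuals
of pollinator species *i* carrying plant taxon *j* (presence/absence per
individual).  With `m = Σ a_ij`, `p_ij = a_ij/m`, marginals `A_i, B_j` and
availability `q_j = B_j/m` (natural logs throughout):

- `H₂ = −Σ p_ij ln p_ij`, standardised as
  `H₂′ = (H₂max − H₂) / (H₂max − H₂min)` between the maximum-entropy
  (independence) table and the minimum-entropy integer table with the same
  marginals — 0 is perfect generalisation, 1 perfect specialisation.
- `d_i = Σ_j (a_ij/A_i) ln((a_ij/A_i)/q_j)`, the Kullback–Leibler
  divergence of species *i*'s partner use from availability, standardised
  as `d′ = (d − dmin)/(dmax − dmin)` with `dmax = ln(m/A_i)` — 0 is no
  exclusivity, 1 complete exclusivity.

`H₂min` is found by a dynamic programme over vertices of the transportation
polytope (table entropy is concave, so its minimum is at a vertex); `dmin`
by an exactly optimal incremental allocation (the objective is separable
convex).  Both are verified against exhaustive enumeration in the test
suite.

**Pollen-load comparisons.**  Presence/absence profiles (unknowns excluded;
above-genus taxa carrying < 1 % of identified reads dropped) are compared
with the Jaccard distance `1 − |x∩y|/|x∪y|`, tested with a one-factor
permutational MANOVA whose permutations are restricted to collection sites
(strata), with a battery of a-priori contrasts (each genus vs the rest,
species within multi-species genera) under the Dunn–Šidák cutoff
`1 − (1 − α)^{1/k}`.

**Synthetic surveys.**  A hierarchical plant taxonomy with barcode
references, site floras drawn from a shared pool, Dirichlet–multinomial
pollen loads per individual (a preference concentration controls
specialisation; a genus effect separates pollinator genera), error-prone
reads, and a pseudo-aligner hit table — all deterministic under one seed.

## Worked example

```python
from pollinet import (SimulationConfig, simulate_dataset, length_filter,
                      assign_reads, tally, to_presence_absence,
                      jaccard_input_filter, build_network, network_h2prime,
                      species_dprime, jaccard_distances, permanova)

cfg = SimulationConfig(seed=1, n_families=8, genera_per_family=2,
                       species_per_genus=2, reads_per_individual=40,
                       individuals_per_species_site=3)
refdb, data, hits = simulate_dataset(cfg)
kept = length_filter(data.reads)
assignments = assign_reads(hits, refdb.taxonomy,
                           query_ids=[r[0] for r in kept])

pcm = tally(assignments, data.insects)
pa = to_presence_absence(pcm)
for site in ("S1", "S2", "S3"):
    net = build_network(pa, site)
    spec = network_h2prime(net)
    d = [s.dprime for s in species_dprime(net)]
    print(f"{site}: H2' = {spec.h2prime:.3f}, mean d' = {sum(d)/len(d):.3f}")

dm = jaccard_distances(jaccard_input_filter(pcm))
meta = data.insects.loc[list(dm.ids)]
res = permanova(dm, meta["genus"], strata=meta["site"], n_perm=999, seed=1)
print(f"genus PERMANOVA: F = {res.F:.3f}, R2 = {res.R2:.3f}, p = {res.p:.4f}")
```

Output:

```
S1: H2' = 0.358, mean d' = 0.226
S2: H2' = 0.410, mean d' = 0.245
S3: H2' = 0.372, mean d' = 0.226
genus PERMANOVA: F = 3.315, R2 = 0.124, p = 0.0010
```

All 3,960 filtered reads resolve to species level (error rate 0.5 %,
distinct references).  The three site networks are moderately generalised
(H₂′ well below 1) and species exclusivity is low (mean d′ ≈ 0.23), while
the pollinator genera differ significantly in pollen-load composition
(R² = 0.12 of the Jaccard variation, permutation p = 0.001 with
site-stratified permutations).

The same pipeline runs from the shell:

```bash
pollinet simulate --seed 1 --out survey/
pollinet assign --hits survey/hits.tsv --taxonomy survey/taxonomy.csv \
    --reads survey/reads.fasta --insects survey/insects.csv --out assigned/
pollinet run --config run.yaml     # full configured pipeline with manifest
```

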