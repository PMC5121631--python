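# Methods

This note documents the models and procedures implemented in `dactynet`,
their assumptions, the defaults that matter, and the choices made where the
design was genuinely open.

## Data model and filtering

The unit of analysis is a samples × OTUs table of non-negative integer read
counts; relative abundances are always derived downstream and never stored,
so there is a single canonical representation. Tables are exchanged as
UTF-8 TSV ('.' decimals, no quoting) and round-trip byte-stably; habitat
(`mediterranean`, `peat_bog`, `wetland`, `coastal`, `alpine_boreal`) and
ploidy (`2x`, `3x`, `4x`) are closed enumerations. PCR replicates are
assumed to have been pooled upstream; one metadata row describes one root
sample.

Two column filters define the mycorrhizal community:

1. **Rare-OTU removal** drops OTUs with a whole-dataset total below
   `min_total_count = 3`, i.e. global singletons and doubletons. Retained
   columns are never modified, so this filter and the next commute.
2. **Mycorrhizal subsetting** keeps OTUs whose family/clade is in the
   whitelist {Tulasnellaceae, Ceratobasidiaceae, Sebacinales (A/B),
   Thelephoraceae} *and* whose best-hit percent identity is strictly above
   `min_identity = 90`. The inequality is strict: an identity of exactly
   90.0 fails. The whitelist is configurable for broader family lists.

Presence of an OTU in a group (species or population) means ≥ 1 read in any
sample of the group after filtering; no per-sample minimum is imposed. The
ploidy Venn partition uses species-level presence: each OTU is assigned to
the exact subset of ploidy classes in whose species it occurs.

## Dissimilarity, NMDS and PERMANOVA

The default analysis unit is species-level presence/absence with Jaccard
dissimilarity (each species is one community, pooled over its samples);
Bray–Curtis on summed counts is available, and every output records which
options were used. Bray–Curtis is `1 − 2·Σ min(x,y)/(Σx + Σy)`; Jaccard on
presence is `1 − |A∩B|/|A∪B|`.

NMDS minimises Kruskal stress-1,
`sqrt(Σ(d_ij − d̂_ij)² / Σ d_ij²)`, where the disparities `d̂` are the
isotonic regression of embedded distances on the rank order of the observed
dissimilarities. Ties are treated in the primary (weak) fashion: tied
dissimilarities are pre-ordered by embedded distance and may receive
distinct disparities. Optimisation uses non-metric SMACOF majorisation;
the reported solution is the best of `n_restarts = 20` random starts whose
seeds are spawned deterministically from the user seed, so increasing the
number of restarts can only lower the achieved stress. Coordinates are
centred at the origin.

PERMANOVA uses `SS_total = (1/n)·Σ_{i<j} d²_ij`,
`SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²_ij`, and
`pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k))`. The p-value follows
the add-one convention, `p = (1 + #{F_perm ≥ F_obs})/(1 + B)` under
uniform label permutation (B = 999 by default), which guarantees
`p ≥ 1/(B+1)`. In the Euclidean univariate limit the statistic equals the
classical one-way ANOVA F (tested to 1e-10), and under an exchangeable
null the rejection rate is nominal (simulation in the test suite). Ploidy
is tested at two levels (diploid vs polyploid) by default, three levels
optionally.

## Bipartite modularity

The species × OTU incidence network links a species to every OTU observed
in its roots. Modules are found over the *joint* node set — orchid species
and fungal OTUs partitioned together, using bipartite edges only — by
maximising

    M = Σ_s [ l_s/L − (d_s/(2L))² ]

with `L` the number of links, `l_s` the links internal to module `s` and
`d_s` its summed degree. Cross-module links contribute to no `l_s`. For a
single module M = 0 exactly, and `M ≤ 1 − 1/N_M` always (by
Cauchy–Schwarz on Σd_s = 2L); M can be negative for partitions that cut
links.

Maximisation is simulated annealing from the all-singletons partition:
per temperature, `f·n²` single-node reassignments and `f·n` collective
moves (module merges, and splits proposed as a random bipartition refined
by a few annealed sweeps and accepted or reverted as a whole), with worse
moves accepted with probability `exp(ΔM/T)`. Defaults: `f = 1`; the
starting temperature is calibrated so ~97% of sampled downhill moves would
initially be accepted; cooling factor 0.95. A run stops after 10
consecutive *frozen* temperatures — no improvement of the best partition
and fewer than 1% accepted downhill moves. The freeze qualifier matters:
during the hot phase the best rarely improves even though the search is
far from converged, so counting raw non-improving temperatures stops runs
prematurely. With these defaults a ~130-node study-scale run takes ~0.2 s
on one CPU, and the annealer matches the exhaustive maximum over all
partitions on every one of 50 random ≤10-node test networks; a slower
0.99 cooling gave no better modularity on the study-scale benchmark.
Returned module labels are canonical (size-descending, ties by smallest
member id), and the stored M is recomputed exactly from the returned
assignment. The best partition *seen* is returned, not the final state.

Significance compares `M_obs` with `n_null` (999 by default) random
networks that preserve **both** degree sequences exactly — stricter than
preserving species degrees alone, and standard for binary incidence data;
single-margin preservation is left to sensitivity analyses. Each
randomisation runs `10·L` checkerboard *trial* swaps: two rows and two
columns are sampled uniformly and the 2×2 submatrix is exchanged when it
is a checkerboard. Counting trials rather than successes keeps the Markov
chain symmetric, so its stationary distribution is uniform over all
fillings with the observed margins (verified by exhaustive enumeration and
chi-square in the tests). Null networks are re-optimised with the same
annealing schedule as the observed network, and
`p = (1 + #{M_null ≥ M_obs})/(1 + n_null)`.

## Indicator species analysis

Sites are populations by default (samples summed per population), since
habitat association is a property of where populations grow; individual
samples are available as sites by option. Abundances enter as per-site
relative abundances by default to guard against sequencing-depth
artifacts; raw counts are an option. For a habitat union g,

* A (specificity) = mean abundance over the sites of g, divided by the sum
  of group means over the partition {g} ∪ {each habitat outside g} — the
  group-combination extension, so that unions are compared fairly against
  their complements;
* B (fidelity) = fraction of sites of g where the OTU occurs;
* IndVal = √(A·B).

Every non-trivial union up to `max_order` (default: all proper unions) is
scanned and the maximiser chosen per OTU, ties broken towards the smallest
union then lexicographically. OTUs absent everywhere are reported as not
applicable rather than scored 0. Inference permutes site→habitat labels
and recomputes each OTU's maximum IndVal over all unions,
`p = (1 + #{IndVal_perm ≥ IndVal_obs})/(1 + n_perm)`. Raw p-values are
reported by default; Benjamini–Hochberg adjustment is available and is
what the suite's false-discovery check uses.

## Synthetic data generator

The generator emulates the study design the analyses target: 14 orchid
species allocated 4/2/4/2/2 across the five habitat classes (the
study-scale preset gives ten species three populations and four species
two — 38 populations, 114 samples, three per population), ~115 mycorrhizal
OTUs and ~800 reads per sample. Mycorrhizal OTUs are organised in habitat
blocks: a block-h OTU links to a species of habitat h with probability
`p_within = 0.5` and to any other species with `p_between = 0.02`; a
`generalist_fraction = 0.1` of OTUs instead links to every species with
probability 0.4. Three planted indicator OTUs link to all peat-bog species
only, occur in every peat-bog population, and carry a 4× abundance boost.
OTU relative abundances follow log-normal size effects (σ = 1); a linked
OTU occurs in a given population with probability 0.7 (creating the
within-species turnover real surveys show); read counts are negative
binomial with shape 0.5 around depth-proportional means. Family labels are
drawn Tulasnellaceae-dominated in roughly the proportions of real orchid
root communities, with identities in (91, 99.9).

Nuisance columns exercise the filters deterministically: ~60 junk OTUs
carry saprotrophic genus labels (or whitelist families with identity ≤ 90)
and sparse low counts; a Poisson(30) number of rare OTUs are injected with
whole-dataset totals of exactly 1 or 2. So that the injected rare OTUs are
*exactly* the rare-filter removals, any planted OTU whose sampled total
falls below 3 is topped up to 3 in one random linked sample — a small
departure from pure sampling that buys an exact oracle for filter tests.

Ground truth records the planted block of every mycorrhizal OTU, the
planted module partition (species and block OTUs by habitat; generalists
have no planted module), the planted link structure itself
(`planted_prevalence`), the indicator ids, the nuisance ids, and expected
depths. Module-recovery tests score adjusted Rand index against the
planted partition on the planted link network: downstream read sampling
(population retention, negative-binomial zeros) erodes realized links and
caps the data-path ARI below the detector's actual accuracy; both ARIs
are reported by the acceptance script. What passing tests show is that the
methods recover structure of this planted, block-plus-noise form at study
scale; real communities add phylogenetic correlation among OTUs,
geographic autocorrelation and depth variation that the generator does
not model.

## Pipeline and reproducibility

The pipeline runs filter → NMDS/PERMANOVA → modularity → indicators from
one flat `key = value` config and one seed. The seed expands into
per-stage sub-seeds via `numpy.random.SeedSequence(seed, spawn_key=...)`,
so any stage can be re-run in isolation from the on-disk artifacts of the
previous stage with identical results. Every open default (metric,
aggregation, site unit, annealing schedule, permutation counts) is
recorded in the summary JSON for provenance. `scripts/acceptance.py` uses
99 null networks and 999 permutations — sizes chosen so a full from-scratch
run completes in well under a minute on a single CPU while keeping the
null-ensemble standard error of the modularity mean below 0.001.

## Known limitations

* Modularity is binary (presence/absence); weighted association strengths
  are ignored by design.
* The annealer is stochastic: equal seeds give equal results, but
  different seeds may return different tied or near-tied optima on
  degenerate networks (e.g. complete bipartite graphs, where M = 0 is
  attained by many partitions).
* The permutation tests assume exchangeable sites/species under the null;
  spatial or phylogenetic non-independence is not corrected for.
* The indicator analysis reports raw p-values by default; with a hundred
  OTUs, some false positives at α = 0.05 are expected unless the BH option
  is enabled.
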