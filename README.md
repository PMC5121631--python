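# dactynet

Analysis of orchid mycorrhizal communities from OTU count tables: who
associates with whom, and whether habitat — rather than host ploidy —
structures the plant–fungus network.

`dactynet` is aimed at community ecologists working with amplicon surveys of
root-associated fungi across multiple host species. Starting from three
tab-separated tables (samples × OTUs read counts, per-sample metadata, and
per-OTU taxonomy), it provides:

* **Filtering** — removal of global singleton/doubleton OTUs and retention
  of putative orchid mycorrhizal fungi (family/clade whitelist AND best-hit
  identity strictly > 90%), with prevalence summaries and an OTU-sharing
  partition across ploidy classes (Venn counts).
* **Community analysis** — Bray–Curtis / Jaccard dissimilarities, non-metric
  multidimensional scaling (Kruskal stress-1, best of random restarts), and
  one-way PERMANOVA with pseudo-F

  `F = (SS_between / (k−1)) / (SS_within / (n−k))`,

  where `SS_total = (1/n) Σ_{i<j} d²_ij` and `SS_within` sums the analogous
  within-group terms; significance by label permutation.
* **Bipartite network modularity** — orchid species and fungal OTUs are
  partitioned jointly by simulated annealing to maximise

  `M = Σ_s [ l_s / L − (d_s / 2L)² ]`

  (`L` links in the network, `l_s` links inside module `s`, `d_s` summed
  degree of module `s`), and the observed `M` is compared against random
  networks with both degree sequences preserved exactly (checkerboard
  swaps); `p = (1 + #{M_null ≥ M_obs}) / (1 + n_null)`.
* **Indicator species analysis** — IndVal = √(A·B) over habitats *and*
  habitat combinations (specificity A from group-mean abundances with the
  group-combination extension, fidelity B from occurrence frequency), with
  permutation p-values.
* **Synthetic data** — a generator that plants habitat-block structure,
  generalist fungi, indicator OTUs, rare OTUs and non-mycorrhizal spike-ins
  at study scale (14 species, 5 habitats, 38 populations, 114 samples), with
  full ground truth for recovery testing.

## Worked example

```python
import dactynet as dn

cfg = dn.paperlike_preset(seed=1)
table, meta, taxonomy, truth = dn.simulate(cfg)

filtered, report, _ = dn.apply_filters(table, taxonomy)
print(report.n_input_otus, report.n_removed_rare,
      report.n_removed_nonmycorrhizal, report.n_retained)
# 194 19 60 115

agg = dn.aggregate_by_species(filtered, meta, mode="presence")
dist = dn.dissimilarity(agg, metric="jaccard")
res = dn.permanova(dist, {m.species: m.habitat.value for m in meta},
                   n_permutations=999, seed=2)
print(f"habitat pseudo-F = {res.pseudo_F:.2f}, P = {res.p_value:.3f}")
# habitat pseudo-F = 2.44, P = 0.001

net = dn.build_network(dn.prevalence_by_group(filtered, meta, "species"))
sig = dn.significance(net, n_null=99, seed=3)
print(f"M_obs = {sig.M_obs:.4f}, M_random = {sig.null_mean:.4f} "
      f"± {sig.null_sd:.4f}, P = {sig.p_value:.3g}")
# M_obs = 0.5428, M_random = 0.4535 ± 0.0088, P = 0.01
```

Of 194 simulated OTUs, 19 are global singletons/doubletons and 60 fail the
mycorrhizal rule, leaving 115 putative mycorrhizal OTUs. Their species-level
presence/absence communities differ significantly between habitats
(pseudo-F on Jaccard distances, P at the permutation floor), and the
species × OTU network is significantly more modular than degree-matched
random networks — the planted habitat-block structure is recovered.

The same pipeline runs end to end from a shell:

```bash
dactynet run --config pipeline.cfg     # flat key = value config
dactynet simulate --seed 1 --out-dir sim/
dactynet network --table sim/otu_table.tsv --meta sim/metadata.tsv \
    --n-null 99 --seed 1 --out-dir net/
```

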