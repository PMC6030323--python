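# perchronos

Phylogenomic analysis of ddRAD data for small sets of diploid individuals,
built for studies like the east–west diversification of Australian pygmy
perches: thousands of short (~80 bp) loci over a few dozen samples, used to
resolve species relationships, date divergences against a geological
calibration, and weigh biogeographic scenarios (vicariance vs. founder-event
dispersal) across a barrier such as the Nullarbor Plain.

The package implements the full chain as a tested library plus a CLI:

* **Locus matrices** (`radmatrix`) — per-locus IUPAC consensus sequences
  with locus-level missing data; coverage filtering (e.g. strict = 40/45
  individuals per locus, relaxed = 32/45), concatenation with partition
  maps, SNP / parsimony-informative-site counts, uncorrected *P* distances
  with pairwise deletion, and lineage-mean distance tables.
* **RRHS pseudo-phasing** (`haplosample`) — repeated random haplotype
  sampling: every heterozygous IUPAC site is resolved to one of its two
  bases with probability ½, repeatedly, to carry phasing uncertainty into
  tree inference.
* **ML trees** (`treeinfer`) — Felsenstein-pruning likelihood under
  GTR+Γ (4 discrete categories, no +I), NJ + NNI hill-climbing search,
  nonparametric bootstrap supports, maximum-clade-credibility (MCC) and
  majority-rule summaries of tree sets, outgroup rooting and pruning.
* **Penalized-likelihood dating** (`chronos_pl`) — Sanderson-style PL: a
  continuous-Poisson branch likelihood plus a smoothing-weighted roughness
  penalty on rate changes, optimized jointly over node ages and branch
  rates under MRCA calibrations; smoothing chosen by leave-one-terminal-
  branch-out cross-validation (χ² prediction error); confidence intervals
  by dating topology-matched subsampled trees.
* **Ancestral ranges** (`rangeevol`) — DEC, DIVALIKE, BAYAREALIKE and
  their +J (founder-event) variants on a dated species tree: ML fits of
  (d, e[, j]), AIC comparison, per-node range marginals, and collapse of
  an individual-level chronogram to species.
* **Synthetic data** (`seqsim`) — a generator with known truth (Yule tree,
  clock or autocorrelated rates, GTR+Γ loci, IUPAC heterozygosity, locus
  dropout, simulated tip ranges) so the whole pipeline is testable without
  raw reads.
* **Pipeline** (`cli_pipeline` / `perchronos run`) — one YAML config, one
  master seed, byte-reproducible TSV/Newick outputs.

The model core, in standard notation: site likelihoods are
L = Σ_cat ¼ π′ ∏ P(b·r_cat) with P(t)=e^{Qt} for the normalized GTR Q and
discrete-Γ rates r_cat; dating minimizes
−Σ_k [x_k ln(r_k Δt_k) − r_k Δt_k] + λ[Σ_k (r_k − r_{pa(k)})² +
Var(root-child rates)] with x_k = branch length × sites; range models use
anagenetic gain/loss rates (d, e) with cladogenetic event weights per model
(+J adds founder weight j, scaling the rest by (3−j)/3), compared by
AIC = 2k − 2 lnL.

## Worked example

Simulate a small ddRAD dataset with known truth, infer and date the tree,
and compare range models:

```python
from perchronos import (SimConfig, simulate_dataset, concatenate,
                        site_stats, rrhs_replicates, GTRModel,
                        search_topology, topologies_identical,
                        CalibrationConstraint, PLConfig, pl_date,
                        fit_all_models, compare_models)
from perchronos.treeinfer import root_with_outgroup

sim = SimConfig(seed=42, n_tips=8, n_loci=200, locus_length=80,
                heterozygosity=0.005, dropout=0.1, rate_sigma=0.0,
                mean_rate=2e-3, root_age=15.0)
ds = simulate_dataset(sim)
aln = concatenate(ds.matrix)
stats = site_stats(aln)
print(f"alignment: {aln.n_sites} bp, {stats.n_snps} SNPs, "
      f"{stats.n_pis} informative, {stats.missing_pct:.1f}% missing")

tree = search_topology(aln, GTRModel(alpha=1.0))
print("true topology recovered:", topologies_identical(tree, ds.tree))

rep = rrhs_replicates(aln, 1, master_seed=7)[0]
ml = search_topology(rep.alignment, GTRModel(alpha=1.0))
rooted = root_with_outgroup(ml, sorted(aln.individuals)[0])
cal = CalibrationConstraint.fixed(tuple(aln.individuals), 15.0)
chron = pl_date(rooted, [cal], PLConfig(nsites=aln.n_sites, smoothing=10.0))
mean_rate, sd = chron.rate_summary()
print(f"root age: {chron.root_age():.2f} Ma; mean rate "
      f"{mean_rate:.2e} +/- {sd:.1e} subs/site/Myr")

fits = fit_all_models(ds.tree, ds.ranges, seed=0, compute_marginals=False)
print(compare_models(fits)[["model", "lnL", "J", "AIC", "dAIC"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
```

Output:

```
alignment: 16000 bp, 1728 SNPs, 681 informative, 11.7% missing
true topology recovered: True
root age: 15.00 Ma; mean rate 2.19e-03 +/- 6.8e-05 subs/site/Myr
        model    lnL     J    AIC  dAIC
     DIVALIKE -5.947 0.000 15.895 0.000
  BAYAREALIKE -5.953 0.000 15.906 0.011
BAYAREALIKE+J -5.276 0.240 16.552 0.658
        DEC+J -5.306 0.241 16.613 0.718
   DIVALIKE+J -5.370 0.241 16.739 0.845
          DEC -7.473 0.000 18.946 3.052
```

Reading it: the 8-taxon ML search recovers the generating topology; with
the root fixed at its true 15 Ma the PL mean rate lands near the simulated
2 × 10⁻³ subs/site/Myr; and on an 8-tip range dataset the six biogeographic
models are nearly indistinguishable (ΔAIC < 2 for the top models), which is
the expected behaviour at this size — model separation needs more tips or a
stronger founder signal.

The same analysis runs from the shell:

```bash
perchronos simulate --seed 42 --out simdir
perchronos run --config pipeline.yaml
perchronos date chronogram.nwk --nsites 16000 --cv \
    --cal-tips t1,t2,t3 --cal-min 14 --cal-max 16 --out dated.nwk
perchronos biogeo species_tree.nwk ranges.tsv --all --out models.tsv
```

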