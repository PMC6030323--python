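# Methods

`perchronos` re-implements, as a tested library, a complete ddRAD
phylogenomics workflow for a few dozen diploid individuals: locus-level
filtering and distance summaries, pseudo-phasing by repeated random
haplotype sampling (RRHS), maximum-likelihood tree inference under
GTR+Gamma, maximum-clade-credibility (MCC) summarization of tree sets,
penalized-likelihood divergence dating with resampled confidence intervals,
and ancestral-range model comparison in the DEC family. A synthetic-data
generator with known truth stands in for raw sequencing data, so every
stage is testable end to end.

## Data model and filtering

A dataset is a locus matrix: per-locus aligned IUPAC consensus sequences
(alphabet `ACGT` + two-base heterozygote codes `RYSWKM` + `N`/`-`) over a
fixed individual list, with per-individual locus dropout recorded as
absence, not as all-`N` strings. Filtering is locus-level only: a locus is
retained when scored in at least `min_individuals` individuals (the study
conditions are 40 of 45, ~89%, for the strict dataset and 32 of 45, ~70%,
for the relaxed one; both are config values). Concatenation fills absent
loci with `N` and records a partition map of half-open site intervals.

Conventions applied consistently: `-` and `N` are missing data, never
character states; two-base ambiguity codes are genuine heterozygote
observations but are excluded from SNP/PIS counting and from P-distance
comparisons. P distances use pairwise deletion (each pair compared over
sites where both carry an unambiguous base); a pair with no comparable
sites is reported as undefined (NaN), never silently zero. The choice of
pairwise over complete deletion is a documented convention — with
locus-level dropout, complete deletion would discard most of the matrix.

## RRHS pseudo-phasing

Each heterozygous site is independently resolved to one of its two encoded
bases with probability 1/2; `N` stays `N` (unknown is not a four-way
heterozygote). Replicate `i` draws from
`numpy.random.default_rng([master_seed, i])`, a counter-based scheme that
makes any single replicate reproducible in isolation. The study condition
is 3000 replicate sets; scaled runs use fewer (below).

## Likelihood engine and tree search

Site patterns are compressed with counts; tip characters enter as partial
likelihood vectors (1 for each compatible state), which handles ambiguity
and missingness exactly. The GTR rate matrix is normalized to mean rate 1;
among-site rate variation uses 4 equal-probability discrete-gamma
categories with conditional-mean rates, renormalized to mean exactly 1. No
invariant-sites class is modelled (it is confounded with the gamma shape).
P(t) comes from the symmetrized eigendecomposition, so likelihood
evaluation is a handful of small mat-vecs per node; per-pattern scaling
guards against underflow.

Branch lengths are optimized by exact coordinate ascent: one postorder pass
caches lower partials, then a preorder walk maintains outside partials and
optimizes each branch against a per-edge context in which the likelihood is
a single mat-vec in the P(t) entries; contexts are updated incrementally so
every 1-D optimization sees the true current likelihood. Topology search is
neighbour-joining (on P distances, via scikit-bio) followed by NNI
hill-climbing; NNI candidates are scored from the same cached partials with
the central branch re-optimized, and the best improving move (first index
on ties) is accepted per round. Zero or negative start lengths are floored
at 1e-8. Bootstrap support is standard nonparametric site resampling,
implemented as a multinomial draw over site patterns (identical in
distribution to resampling columns); replicate searches hill-climb from the
ML tree. This replaces engine-specific devices of the original tools
(rapid hill-climbing, RELL-style resampling) with their generic standard
counterparts.

Tree sets are summarized two ways: the MCC tree (the member tree maximizing
the sum of log clade frequencies over the set — always a member tree, ties
to the lowest index, branch lengths retained) and a majority-rule consensus
(threshold ≥ 0.5; polytomies where unresolved). These differ when no member
dominates; the pipeline dates the MCC tree. Rooting uses a designated
outgroup tip; pruning a tip sums the freed branch lengths so remaining
path lengths are unchanged; topology identity is unrooted Robinson–Foulds
distance zero (dendropy).

## Penalized-likelihood dating

Given a rooted tree with branch lengths in expected substitutions/site and
a sequence length `nsites`, each branch contributes a continuous Poisson
log-likelihood `x ln(r Δt) − r Δt` with `x = blen × nsites` (no integer
rounding) and `r` the branch's rate on the per-sequence scale; reported
rates are divided by `nsites` (subs/site/Myr). Rate roughness is penalized
by `λ [ Σ (r_k − r_parent(k))² + Var(root-child rates) ]` — the variance
term is the root convention, since the root has no parent branch. Node ages
and log-rates are optimized jointly with SLSQP under explicit ordering
constraints (parent strictly older than child) and calibration bounds, with
an analytic gradient and five seeded multi-starts (jittered initial ages
scaled from substitution-tree heights). We chose explicit constraints over
an age-transform parameterization: constraint handling is exact, the
problem sizes here (tens of nodes) are trivial for SLSQP, and only the
optimum is part of the contract. Internal node ages are capped at 50× the
largest calibration maximum.

Calibrations are min–max bounds on named MRCAs (a fixed age is min = max;
the study's single calibration is 14–16 Ma, with a config switch for
fixed-midpoint). Infeasible nestings (a descendant's minimum above an
ancestor's maximum) are rejected up front. One property of the objective is
worth knowing: the Poisson term depends only on the products r·Δt, so it is
invariant to stretching all ages by a common factor while shrinking rates —
and stretching strictly *reduces* the roughness penalty. With a single
min–max calibration and λ > 0 the optimum therefore sits at the
calibration's upper bound; a fixed-age calibration pins the scale and is
the right choice for point estimates.

The smoothing parameter is chosen by leave-one-terminal-branch-out
cross-validation: for each λ on a grid (default 10^0 … 10^2 in quarter-
decade steps, the study's stated search interval read as raw smoothing
values 1–100; the raw-0–100 reading remains available by passing an
explicit grid) and each terminal branch, the model is refit with that
branch's Poisson term and penalty contributions removed; its expected count
is predicted as fitted parent-branch rate × duration (mean of the other
root-child rates when the parent is the root), and errors accumulate as
χ² = Σ (x_obs − x_pred)²/x_pred. Confidence intervals follow the study's
resampling design: filter a tree set to members topologically identical to
the reference, subsample k without replacement (seeded), date each, and
report per-node mean ± sample s.d. (ddof = 1).

Numerical behavior, measured on an 8-tip fixture: strict-clock data with
expected counts and λ = 10⁶ recover all node ages to machine precision;
with lognormal rate autocorrelation (σ = 0.2) and Poisson counts at 10⁵
sites, pooled median relative error of internal ages is ~6% at λ = 10. The
strict-clock recovery test deliberately uses expected counts (the
infinite-sites limit): at 10⁵ sites Poisson noise alone leaves 3–5% error
on shallow nodes, which would test the generator rather than the
estimator.

## Ancestral ranges (DEC family)

States are the non-empty subsets of the area list up to `max_range` (the
null range is excluded, so single-area loss is disallowed — the simplest
internally consistent convention for a two-area problem). Anagenesis is a
CTMC with per-area gain rate `d` and loss rate `e`; transition matrices use
`scipy.linalg.expm` (scaling-and-squaring) even in the 3-state case.
Cladogenesis distributes the ancestral range over ordered daughter pairs:
narrow sympatry, subset sympatry, vicariance (one daughter a singleton),
widespread copy, and (+J) founder events into a single area outside the
range, with per-event weights {DEC: y=s=v=1, w=0; DIVALIKE: y=v=1;
BAYAREALIKE: y=w=1}; +J gives founder events weight `j` and scales the
others by `(3−j)/3`. Each state's table is normalized to a proper
distribution; a state with no allowed event (possible only at degenerate
weightings) falls back to a sympatric copy.

The likelihood is a pruning pass: matrix exponentials along branches, the
cladogenesis distribution at every internal node including the root
(reading the root convention as "no extra origin event above the root";
a `root_cladogenesis=False` flag gives the alternative root treatment),
and a uniform prior over states at the root. Node marginals are computed
by state clamping — the likelihood with a node restricted to each state,
normalized — which is exact and cheap at these sizes. Fits maximize lnL
over (log₁₀ d, log₁₀ e[, j]) with bounded L-BFGS-B multi-starts
(d, e ∈ [10⁻¹², 10]; j ∈ [0, 3), including a j = 0 start so +J never falls
below its nested base model); k = 2 or 3 and AIC = 2k − 2 lnL. Collapsing
an individual-level chronogram to species keeps one representative tip per
(monophyletic) species with its pendant branch extended to the crown's
parent edge, preserving between-species ages; the collapsed tree keeps the
ages estimated upstream rather than re-smoothing them.

## Synthetic data generator

The generator emulates the structure, not the history, of the study data:
a Yule tree conditioned on `n_tips` and rescaled to a fixed root age;
branch rates either strict-clock or autocorrelated lognormal (child rate =
parent rate × LogNormal(0, σ²); root children start at the mean rate);
sequences evolved under GTR+Gamma along rate × duration branch lengths;
diploid heterozygosity applied phenomenologically (with probability `h`
per tip site, a second allele one jump-chain substitution away, encoded as
the IUPAC two-base code); per-individual per-locus dropout; and tip ranges
simulated forward with Gillespie anagenesis plus one cladogenetic draw per
node. Defaults mirror the study conditions: 45 tips, 80 bp loci, a 20 Ma
root, mean rate 9.67 × 10⁻⁴ subs/site/Myr, dropout 0.15 (≈ the 5–30%
missing-data range), and a founder-dominated DIVALIKE+J range process
(d = e = 10⁻¹², j = 0.0972) from an eastern root.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: no coalescent gene trees or ILS (heterozygosity is
per-site, unlinked), no read-level errors or assembly artifacts, no indels,
no base-composition or rate heterogeneity among loci, and dropout is
independent rather than phylogenetically structured (real outgroups drop
out far more). Recovery results on this generator demonstrate correctness
of the estimators under their own assumptions, not robustness to violations
of them.

## Pipeline, seeds and scaled problem sizes

`run_pipeline` executes: load → strict/relaxed filter (+ site-statistics
summary) → P distances and group means → empirical frequencies + gamma
shape estimation on the NJ tree → ML tree + bootstrap supports → RRHS
replicate trees → outgroup rooting, MCC, optional outgroup pruning →
PL dating with CIs from topology-matched subsamples → species collapse →
six-model range comparison with node marginals. All randomness derives
from one master seed through named substreams; outputs are written with
fixed numeric formats, so a re-run reproduces every artifact byte for
byte. A stage failure raises an error naming the stage and leaves earlier
artifacts on disk.

Test and acceptance runs use scaled sizes chosen to exercise every code
path at desk scale: the end-to-end check runs 10 tips × 300 loci × 80 bp,
50 RRHS replicates, 100 bootstraps, 20 CI subsamples and all six range
models (about a minute per run); study-scale defaults (3000 RRHS, 1000
bootstraps, 100 subsamples) remain the config defaults. Oracle suites
compare the pruning engines against exhaustive enumeration on trees of ≤5
tips (GTR+Gamma, 100 random parameter draws) and ≤4 tips (all six range
models), MCC against naive scoring on 50-tree sets, and P distances
against a per-site loop.

## Known limitations

* NNI hill-climbing can stop at local optima on low-signal data; there is
  no SPR/TBR and no partitioned model.
* The PL optimizer is a general constrained quasi-Newton; extremely large
  trees (hundreds of tips) would want the specialized truncated-Newton
  machinery of dedicated dating software.
* Range estimation supports neither time-stratified dispersal matrices nor
  more than a few areas (state clamping for marginals scales with
  #nodes × #states × one pruning pass).
* The CV grid interpretation (smoothing 1–100) follows the study's stated
  interval; the selected smoothing is data-dependent and the paper's own
  optimum (44.00) is not reproducible without the original data.
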