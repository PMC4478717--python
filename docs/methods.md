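# Methods

## Problem and approach

Carriers of pathogenic BRCA1/2 mutations differ widely in breast-cancer
risk, and mitochondrial genetic background is one candidate modifier:
mtDNA haplogroups differ in electron-transport-chain efficiency and
reactive-oxygen-species output, and ROS cause the double-strand breaks that
BRCA1/2-dependent repair handles. `mitorisk` implements a phylogeny-based
analysis of this hypothesis for cohorts genotyped on a sparse mtDNA SNP
panel (~93 of 16,569 positions):

1. impute each carrier's haplogroup by matching her panel-restricted
   haplotype against haplotypes reconstructed at every node of a reference
   mtDNA phylogeny;
2. test clades of the reference tree for differential enrichment of
   affected carriers with nested permutation homogeneity tests;
3. localize candidate susceptibility sites through the correlated evolution
   of each site with a per-haplotype disease character S;
4. quantify the effect of an implicated haplogroup as a hazard ratio from a
   weighted, country-stratified Cox model with family-clustered robust
   variance.

Because individual-level carrier data of this kind are not public, the
package ships a synthetic-cohort generator that provides ground truth for
every stage; all tests and the bundled reproduction studies run on it.

## Reference tree and haplogroup imputation

The reference phylogeny is a rooted tree whose edges carry point
substitutions (tokens like `G13708A`; a trailing `!` marks a back mutation
and is accepted and stripped).  The root carries the reference allele at
every panel position, so any node's state is obtained by replaying the
substitutions on its root path; repeated mutation of a position applies
sequentially, which supports back mutations.  Only single-nucleotide
substitutions are represented — indels and length variants are out of
scope, matching a biallelic SNP panel.  The canonical serialization is a
TSV edge list sorted by (parent, child); a Newick export (topology + names)
is provided for viewers.

Restricted to the panel, many nodes share a "short haplotype".  Each
distinct short haplotype is labelled with the MRCA of the nodes sharing it;
individuals are assigned by exact lookup of their own short haplotype.
There is deliberately no nearest-haplotype rescue: one genotyping error
produces a chimeric haplotype that matches no node and the individual is
left unassigned (and excluded downstream) rather than guessed.  Accuracy
against known labels is scored at two levels: *main* (top-level clade
below the root agrees) and *exact* (the truth is the assigned label or one
of its descendants — an MRCA label is coarse by construction, so a
covering ancestral call counts as correct).

## Quality control

Loci are dropped in a fixed order — annotated triallelic, annotated
cross-mapping (both consumed as panel flags, not computed), monoallelic
(minor-allele count 0 among non-missing, non-heterozygous calls), missing
fraction > 5%, heterozygous-call fraction > 5% (both strict inequalities),
and "private" loci that appear in no tree edge.  The fixed order makes
reports deterministic; each locus is attributed the first applicable
reason.  Surviving heterozygous calls (heteroplasmy on a haploid genome)
are recoded to missing, and the sample filter then keeps exactly the
individuals with complete haplotypes over the retained loci.

One caveat is documented rather than hidden: because the H→N recode runs
after the missingness check, a locus just under both thresholds can exceed
the missingness threshold on a second pass, and a genotyping-error
singleton whose carrier is later removed can make the monoallelic criterion
fire on re-application.  The filter is therefore a single fixed-order pass,
and the idempotence regression test runs on error-free noise where
stability holds.

## Association testing

For a clade root, level *d* collapses every individual into her ancestor at
depth *d* below the root; individuals whose assigned label sits above the
level form their own paragroup branch.  Empty branches are pruned, levels
with fewer than two occupied branches are skipped.  The per-level statistic
is the Pearson chi-square of the 2×k affected/unaffected table (df = k−1),
the classic homogeneity statistic.  Per-level p-values come from permuting
affection labels: raw_p = (b+1)/(B+1), B = 1,000 by default; when the
number of distinct affected-label placements C(n, n_affected) is below a
configurable cap the permutation distribution is enumerated exhaustively
instead.

The tree-level correction is Westfall–Young min-p: each permutation's
statistics are converted to p-values through their pooled rank
(observed labeling included in the pool), and the corrected p is the
fraction of the pool whose minimum p over levels is at least as extreme as
the observed minimum.  This construction guarantees corrected_p ≥ min raw p
and reduces exactly to the raw p for a single-level tree.

Relatives share mtDNA, so tests run on genetically independent subsets:
one individual drawn uniformly per (family, short haplotype) group —
members of the same family with different haplotypes (non-maternal
relatives) are distinct groups.  The analysis is repeated over R = 1,000
resamplings (default) and averaged; branch counts are reported as mean and
[min, max] across resamplings.

## Localization

Each observed short haplotype receives the binary character S:
case-associated iff n_affected × N_unaffected > ε × n_unaffected ×
N_affected (ε = 1 by default; larger ε demands a stronger case excess;
equality conservatively falls to control-associated).  Panel sites are
encoded 0/1 (ancestral/derived relative to the root state — biallelic
after QC), observed haplotypes are attached as pendant leaves under their
assigned node, the clade subtree is pruned to observed lineages, and
states are reconstructed at ancestral nodes by either

- **fitch_acctran** (default): unit-cost minimum-change parsimony via a
  Sankoff-style DP, ties broken by placing changes on the edge closest to
  the root (accelerated-transformation convention), deterministic given the
  canonical (sorted) child order; or
- **ml_unit_branch**: marginal maximum likelihood under a symmetric
  two-state model with unit branch lengths (the reference tree carries
  none) and uniform prior, ties to the ancestral state.

The correlated-evolution index of a site, per direction of change, is the
Pearson correlation across tree edges between the indicator of a site
change in that direction and a signed S-change variable (+1 toward
case-associated, −1 toward control-associated, 0 otherwise).  When all S
changes share one direction this is exactly the phi coefficient of the two
binary indicators; the signed form was chosen so that swapping the polarity
of S negates every index exactly.  Sites are ranked by index, descending;
an index is undefined (reported NA) when either variable is constant over
edges.  Note that parsimony co-places all changes of a nested lineage on
the same edge, so substitutions that define the same causal lineage tie at
the same index — the index identifies an equivalence class of candidate
sites, not a unique site.

## Risk quantification

The survival record of a carrier is her age at diagnosis (affected) or age
at interview (censored); age is the time scale, with no left truncation.
Carrier cohorts over-sample affected women, so the model is a weighted Cox
regression: within each (gene, 5-year age class) cell with n members,
n_aff affected, and external target probability p of being affected,
affected individuals get weight p·n/n_aff and unaffected individuals
(1−p)·n/(n−n_aff).  The defining property — the weighted affected fraction
equals p exactly in every cell — holds to machine precision and is
asserted in tests.  Cells with no affected or no unaffected members fall
back to unit weights with a warning.  The fit maximizes the weighted
partial likelihood with baseline hazards stratified by country, the
haplogroup contrast as covariate, Efron tie handling, and a weight-aware
sandwich variance clustered on family (delegated to
`lifelines.CoxPHFitter`; an independent partial-likelihood implementation,
`statsmodels` PHReg, serves as a cross-check in the test suite).
Haplogroup-assignment uncertainty is not propagated into the model.

## Synthetic cohorts

The generator emulates a multi-centre carrier cohort: families drawn from a
size distribution (default 80% singletons, 15% pairs, 5% trios) share
their maternal haplotype deterministically by default (a parameter admits
discordant paternal-side relatives); countries follow configurable
proportions; disease histories follow a piecewise-exponential hazard on
age (chosen for closed-form inverse sampling and easy calibration to an
incidence table) multiplied by per-haplogroup hazard ratios that apply to
a named haplogroup and its whole subclade; censoring is at a drawn
interview age (normal, mean 50, SD 12, clipped to 21–80).  Genotypes are
emitted from the true node state and then corrupted at per-call rates —
defaults 0.2% missing, 0.1% heterozygous, 0.05% allele flips, i.e. rates
at which the 5% QC thresholds and the complete-haplotype filter leave
roughly 90% of samples assignable, matching realistic array data.  One
global seed governs everything through numpy `SeedSequence` stream
splitting (demography / disease / genotype noise), so stages are
independently reproducible and byte-identical under a fixed seed.

A hand-built miniature reference tree (`curated_tree`) provides clades H,
T (with T1→T1a→T1a1 and the T2 subclades), U/K, J and X at full panel
resolution; `clade_t_frequencies` mirrors the observed clade-T mix (~5%
paragroup T, ~17% T1a1 lineage, ~78% T2) and `clade_th_frequencies` adds
clade H at the observed T:H ratio (~651:1,967).  What the generator does
*not* emulate: realistic mutation spectra or hypervariable regions,
haplotypes absent from the reference tree, population stratification
between countries, or ascertainment that depends on family history.
Passing tests therefore demonstrate correctness of the machinery under the
stated generative model, not robustness to those real-data features.

## Reproduction studies

`mitorisk.studies.hazard_ratio_recovery` simulates ≥200 replicate cohorts
with a known generative hazard ratio for the T1a1 lineage — clade-T
cohorts of ~650 carriers (T1a1 vs rest of T), or mixed T+H cohorts of
~2,618 (T1a1 vs everyone else) — runs QC, imputation and the weighted Cox
fit per replicate, and reports the mean estimated HR with its Monte-Carlo
standard error.  The incidence input for the weights is estimated once
from a single 40,000-individual pilot cohort at the same generative
parameters, playing the role of external population incidence.  These
cohorts are simulated without genotyping noise so that recovery isolates
the hazard model rather than imputation attenuation.  Problem sizes (200
replicates, B = 200 / R ≤ 50 in calibration checks) were chosen so the
studies complete in minutes on one core while keeping Monte-Carlo error
well below the effects of interest.

## Numerical and design notes

- p-value estimators use the add-one form (b+1)/(B+1): valid and never 0.
- Permutation statistics reuse fixed expected counts per level (branch and
  status margins are permutation-invariant), so B=1,000 permutations cost
  one matrix product per level.
- Degenerate inputs: all-affected (or all-unaffected) cohorts give p = 1
  with a warning; clades emptied by resampling are skipped and counted;
  strata without events contribute nothing (warning); an exposure group
  with no events raises a separation error rather than returning a
  divergent estimate.
- The hand-crafted miniature tree, the concrete weight formula, the Pearson
  homogeneity statistic and the signed-phi index are the package's own
  instantiations of their respective method families; each is pinned by the
  invariants above rather than by comparison to any external
  implementation.

## Known limitations

- Exact-match assignment cannot rescue near-miss haplotypes; cohorts with
  high genotyping error lose samples (by design).
- The correlated-evolution index cannot separate susceptibility sites that
  co-segregate on one lineage at panel resolution.
- The weighted Cox model assumes the incidence table is correct and
  exhaustive over the observed age range; records outside it are an error.
- Cluster-robust variance assumes many families; with few large families
  the CI coverage degrades.
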