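# mitorisk

Phylogeny-based analysis of mitochondrial haplogroups as breast-cancer
risk modifiers in BRCA1/2 mutation carriers.

Mitochondria are the main cellular source of reactive oxygen species, ROS
cause the DNA double-strand breaks that BRCA1/2-dependent repair handles,
and mtDNA haplogroups differ in metabolic efficiency — so mitochondrial
background is a natural candidate modifier of breast-cancer risk in
mutation carriers.  `mitorisk` provides the full analysis chain for
testing this on cohorts genotyped at a sparse mtDNA SNP panel:

- **Haplogroup imputation** — reconstruct the allele state of every node of
  a mutation-annotated reference mtDNA tree (PhyloTree-style edge lists),
  restrict to the genotyped panel, label each distinct "short haplotype"
  with the most recent common ancestor (MRCA) of the haplogroups sharing
  it, and assign individuals by exact matching.
- **Quality control** — the panel filters used for mitochondrial array
  data: triallelic/cross-mapping flags, monoallelic loci, >5% missingness,
  >5% heterozygous (heteroplasmic) calls, private mutations; then a
  complete-haplotype sample filter.
- **Clade association** — per-level homogeneity tests on a clade subtree
  (Pearson χ² over affected/unaffected counts across branches), permutation
  p-values, Westfall–Young min-p correction over the nested levels, and
  family-aware resampling (one carrier per family × haplotype group,
  averaged over R resamplings).
- **Susceptibility-site localization** — attach a binary disease character
  S to each haplotype (case-associated iff
  n_aff·N_unaff > ε·n_unaff·N_aff), reconstruct ancestral states
  (Fitch/ACCTRAN parsimony or two-state ML), and rank sites by the
  correlation of their changes with the changes of S along tree edges.
- **Effect quantification** — weighted Cox regression on the age scale
  (weights calibrate the affected fraction per gene × age class to external
  incidence: w_aff = p·n/n_aff, w_unaff = (1−p)·n/(n−n_aff)), stratified by
  country, with a family-clustered robust sandwich variance.
- **Synthetic cohorts** — a generator with known truth (maternal families,
  haplogroup frequencies, piecewise-exponential age-dependent hazard,
  multiplicative haplogroup effects, genotyping noise) so every stage is
  testable without access to real carrier data.

## Worked example

Simulate a clade-T carrier cohort in which the T1a1 lineage halves the
hazard, then run the pipeline:

```python
import numpy as np
import mitorisk as mr
from mitorisk.assign import assignments_to_frame

tree, panel = mr.curated_tree()                   # miniature reference tree
cfg = mr.SimConfig(n_individuals=650, hazard_ratios={"T1a1": 0.55}, seed=1)
gm, meta, truth = mr.simulate_cohort(tree, panel, cfg, seed=1)

clean, report = mr.run_qc(gm, tree)               # SNP + sample filters
index = mr.build_short_haplotype_index(tree, clean.panel)
assignments = mr.assign_individuals(clean, index)
print(f"assignment rate: {mr.assignment_rate(assignments):.3f}")

data = assignments_to_frame(assignments).query("matched").merge(meta, on="sample_id")
agg = mr.run_resampled_association(
    tree, data, "T", plan=mr.ResamplingPlan(R=50, seed=2), B=500
)
print(f"clade T mean corrected p: {agg.mean_corrected_p:.4f}")

sf = mr.survival_frame(data)
sf = sf.assign(exposure=np.where(
    sf["haplogroup"].isin(tree.subtree_nodes("T1a1")), "T1a1", "other"))
res = mr.fit_weighted_cox(sf, exposure="exposure", reference="other")
print(f"HR = {res.hazard_ratio:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})")
```

Output for this seed:

```
assignment rate: 0.984
clade T mean corrected p: 0.0253
HR = 0.37 (0.21-0.63)
```

The assignment rate reflects carriers dropped for incomplete haplotypes or
chimeric (error-bearing) haplotypes; the corrected p is the resampled
min-p-adjusted evidence that some clade-T branch is differentially
enriched in affected carriers; the hazard ratio recovers the simulated
protective effect of T1a1 (generative value 0.55) within its confidence
interval.

The same stages are available from the shell:

```bash
mitorisk simulate --n 650 --hazard-ratio 0.55 --seed 1 --outdir sim
mitorisk filter --tree sim/tree.tsv --panel sim/panel.tsv \
    --genotypes sim/genotypes.tsv --outdir qc
mitorisk assign --tree sim/tree.tsv --panel qc/panel_filtered.tsv \
    --genotypes qc/genotypes_filtered.tsv --out assignments.tsv
mitorisk assoc --tree sim/tree.tsv --panel qc/panel_filtered.tsv \
    --assignments assignments.tsv --metadata sim/metadata.tsv --clade T \
    --permutations 1000 --resamplings 1000 --seed 2 --outdir assoc
mitorisk run --config pipeline.yaml        # full pipeline from YAML
```

File formats are documented in `docs/formats.md`; the scientific details
and design choices in `docs/methods.md`.

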