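# File formats

All tables are tab-separated with a single header row.  Column orders are
fixed as listed.

## Reference tree (`tree.tsv`)

| column | content |
|---|---|
| parent | parent haplogroup name |
| child | child haplogroup name |
| mutations | comma-separated tokens `<from><position><to>`, e.g. `G13708A`; trailing `!` (back mutation) accepted |

Rows sorted by (parent, child).  Exactly one node never appears as a child
(the root, e.g. `RSRS`).

## Locus panel (`panel.tsv`)

| column | content |
|---|---|
| position | 1-based position on the 16,569-bp mtDNA coordinate system |
| ref | reference (root) allele, A/C/G/T |
| alt | alternate allele |
| label | free text (e.g. rs identifier), may be empty |
| flags | comma-separated subset of {triallelic, crossmap}, may be empty |

Positions strictly increasing.

## Genotypes (`genotypes.tsv`)

`sample_id` followed by one column per panel position (same order as the
panel).  Codes: `A/C/G/T` call, `N` missing, `H` heterozygous call.

## Sample metadata (`metadata.tsv`)

sample_id, family_id, country, gene (BRCA1|BRCA2), status (1 = affected),
age_diagnosis (empty if unaffected), age_censor.

## Incidence table (`incidence.tsv`)

gene, age_low, age_high, p — probability that a carrier of that gene
observed in the age class is affected.  Classes partition the study age
range per gene.

## Assignments (`assignments.tsv`)

sample_id, haplogroup (empty if unmatched), matched (True/False),
short_haplotype (allele string in panel order).

## Association outputs

`assoc_<clade>_levels.tsv`: level, mean_raw_p, n_resamplings.
`assoc_<clade>_branches.tsv`: level, branch, mean/min/max affected and
unaffected counts over resamplings.  JSON summaries mirror these plus
mean_corrected_p, R, B and the skipped-resampling count.

## Localization (`localization_<clade>.tsv`)

site (panel index), mutation (e.g. `G13708A`), direction
(`ancestral->derived` / `derived->ancestral`), index, rank (empty when the
index is undefined).

## Cox result (`cox.json`)

exposure, hazard_ratio, log_hazard, robust_se, ci_low, ci_high, p_value,
n_used, n_events, n_strata.

## Run manifest (`manifest.json`)

Package version, seed, config hash, full config, QC summary, assignment
rate, per-clade association summaries, flagged clades, Cox summary.
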