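# File formats

All tabular files are tab-separated with an optional leading block of
`# key: value` comments (provenance: tool, config hash, seed). Sequence
catalogs are FASTA (wrapped lines joined on read, residues upper-cased,
duplicate ids rejected). Schemas are validated by `soilmep.io.read_table`;
unknown columns are preserved.

## Inputs (written by `simulate`, consumed by the stages)

| file | required columns | notes |
| --- | --- | --- |
| `psm.tsv` | `spectrum_id, peptide, proteins, score, is_decoy, is_modified, is_contaminant, sample, spectral_count, intensity` | `proteins` is a `;`-separated id list; decoy rows map only to `DECOY_*` ids |
| `coverage.tsv` | `orf_id` + one numeric column per sample | mean read depth per ORF |
| `lineages.tsv` | `taxon, domain, phylum, class, order, family, genus, species` | complete 7-rank lineage per taxon |
| `catalog.tsv` | `orf_id, family, cluster_id, lineage` | SCG ORFs with cluster and assigned lineage (`;`-joined 7 ranks) |
| `scores.tsv` | `orf_id, family, score` | one row per ORF × marker family |
| `hits.tsv` | `orf_id, ref_taxon, evalue` (+ optional `lineage`) | reference hits for marker taxonomy |
| `meta.tsv` | `sample, compartment` | compartment is `bulk` or `rhizosphere` |
| `orfs.fasta`, `references.fasta` | — | ORF catalog and lineage-bearing references |

## Outputs

| file | contents |
| --- | --- |
| `clusters.tsv` | `cluster_id, representative, member, identity` (partition of the catalog) |
| `groups.tsv` | `group_id, representative, members, n_members, unique_peptides, peptides, best_score, q_value` |
| `filter_audit.tsv` | `rule, groups_removed` — what each inference filter removed |
| `abundance_nsaf.tsv` | group × sample NSAF values (`mode: NSAF` in the header; columns sum to 1) |
| `abundance_lfq.tsv` | group × sample median-centered log2 intensities (`mode: normalized-LFQ`; blanks are missing) |
| `enrichment.tsv` | per group: `fold_change, log2_fold_change, t_stat, p_value, q_value, n_obs_*, enriched_in` |
| `profile.tsv` | taxon × sample relative abundance from SCG coverage (`rank` in the header) |
| `marker_abundance.tsv` | `family, taxon` × sample SCG-normalized marker abundance |
| `stats.tsv` | per data layer: ANOSIM R and p, PERMANOVA pseudo-F, R², p, permutation count |

## Configuration

`config.yaml` round-trips `soilmep.io.RunConfig` (YAML, flat keys; unknown
keys rejected). Every stochastic stage receives a seed derived from the
single top-level `seed`.
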