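# soilmep

Analysis pipeline for **soil metaexoproteomics**: identifying and
quantifying the extracellular protein fraction of soil microbial
communities (bulk soil vs. rhizosphere) against a metagenome-derived
search database, and contrasting the *metabolically active* community seen
by the proteome with the *total* community seen by the metagenome.

It is aimed at microbial-ecology and metaproteomics researchers who want a
tested, fully seeded implementation of this workflow, exercised end-to-end
on synthetic soil-community data with known ground truth (no downloads
required).

## What it implements

1. **Search-database reduction** — greedy longest-first identity
   clustering of an ORF catalog (CD-HIT convention: identity = identical
   aligned residues / length of the shorter sequence, with a short-sequence
   coverage rule), at 90% for the proteome database and 95% for
   single-copy-gene de-replication.
2. **Two-tier target-decoy FDR protein inference** — peptide q-values from
   the decoy competition, `FDR(t) = D(t)/max(T(t),1)` with monotone
   step-down q-values, filtered at q ≤ 0.05; parsimony protein grouping
   (identical peptide sets merge, strict subsets are absorbed);
   group-level q-values over best member scores filtered at q ≤ 0.10;
   evidence rules (≥ 2 unique peptides, no modified-only groups, no
   contaminants) and a deterministic group representative.
3. **Quantification** — NSAF spectral counting,
   `NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j)` per sample; normalized
   label-free intensities (log2, per-sample median centering, no
   imputation); per-protein Z-score profiles over condition means; taxon
   and function rollups by count ("diversity") or abundance.
4. **Compartment enrichment** — per-protein Welch tests on log abundances
   with Benjamini-Hochberg control; rhizosphere-enriched at q < 0.05 and
   fold change > 2, bulk-enriched at q < 0.05 and inverse fold change > 1.5.
5. **Community statistics** — Bray-Curtis dissimilarities, one-way ANOSIM
   (rank statistic R) and PERMANOVA (pseudo-F, R² = SS_between/SS_total)
   with seeded permutation p-values, `p = (1 + exceedances)/(1 + permutations)`,
   or exact enumeration for small designs.
6. **SCG taxonomic profiling** — community composition from the coverage
   of 36 single-copy core-gene families: per-family clustering,
   nearest-reference lineage assignment (k-mer cosine distance), coverage
   summed per taxon and family, median across families, normalized by the
   per-sample median total SCG coverage. Using single-copy genes only makes
   the estimate insensitive to genome size.
7. **Marker-gene profiling** — alkaline phosphatase families (PhoX, PhoD,
   PhoA) classified by score thresholds, taxonomy by best reference hit at
   e ≤ 1e-20, abundance normalized by the SCG normalizer.
8. **Synthetic data generation** — every input the pipeline consumes
   (ORF catalogs, coverage tables, PSM tables, lineages, marker evidence)
   with the generative truth retained, fully reproducible from one seed.

## Worked example

```python
from soilmep.io import RunConfig
from soilmep.pipeline import run_pipeline

config = RunConfig(seed=17, n_taxa=6, n_samples=4, orfs_per_megabase=5.0,
                   ms_depth=10000.0, n_permutations=999)
result = run_pipeline(config, "example_run")

print("protein groups kept:", len(result.group_set.groups))
print("enrichment labels:", result.enrichment["enriched_in"].value_counts().to_dict())
print(result.stats.round(3).to_string(index=False))
```

prints

```
protein groups kept: 292
enrichment labels: {'none': 220, 'rhizosphere': 53, 'not_tested': 12, 'bulk': 7}
          dataset  anosim_R  anosim_p  permanova_F  permanova_R2  permanova_p  n_permutations
metaproteome_nsaf     1.000     0.039       66.007         0.917        0.026             999
   metagenome_scg    -0.135     0.716        0.476         0.074        0.783             999
```

The bundled scenario applies a rhizosphere effect to protein output only,
not to community composition. The numbers show exactly that contrast: 292
protein groups survive the two-tier FDR and evidence filters; far more of
them are rhizosphere-enriched (53) than bulk-enriched (7); the
metaexoproteome separates the compartments decisively (PERMANOVA
R² = 0.917, p = 0.026) while the SCG-based metagenome profile of the same
samples shows no compartment structure (R² = 0.074, p = 0.783) — an
activity shift invisible to composition.

The same workflow is available from the shell:

```bash
soilmep run --out example_run --seed 17
soilmep cluster --fasta example_run/inputs/orfs.fasta --identity 0.9 --out db
soilmep infer --psm example_run/inputs/psm.tsv --pep-fdr 0.05 --prot-fdr 0.10 --out proteins
```

Every run directory contains the nine stage outputs (`clusters.tsv`,
`groups.tsv`, `filter_audit.tsv`, `abundance_nsaf.tsv`,
`abundance_lfq.tsv`, `enrichment.tsv`, `profile.tsv`,
`marker_abundance.tsv`, `stats.tsv`), the generated inputs under
`inputs/`, and provenance (config hash + seed) in every table header.
Re-running with the same configuration reproduces the numeric outputs
byte-for-byte.

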