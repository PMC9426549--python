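# Methods

This note documents the models and procedures implemented in `soilmep`,
the assumptions they make, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## The problem

Shotgun metagenomics describes who is *present* in a soil community;
metaexoproteomics (mass spectrometry of the extracellular protein
fraction) describes who is *active* and what they are doing. Comparing
bulk soil with rhizosphere soil, the interesting phenomenon is an activity
shift — particular taxa exporting far more protein near roots — that may
occur with little or no change in community composition. The pipeline
implements both measurement channels on a common synthetic community so
that this contrast can be tested against ground truth.

## Synthetic community model (`synthgen`)

**Composition.** Per-taxon base abundances are log-normal(0, σ=1) across
taxa — heavy-tailed, as soil communities are, with only two parameters —
then renormalized per sample. Each sample adds independent
log-normal(0, σ=0.25) replicate noise. A rhizosphere effect multiplies
selected taxa in rhizosphere samples before renormalization; the effect
`mode` decides whether it acts on *abundance* (visible to DNA) or on
*activity* (visible only to protein output). Neither the abundance
distribution nor the noise level of a real field soil is identifiable
from desk-scale reasoning; these are declared modelling choices, not
estimates.

**Metagenome.** Every taxon carries exactly one ORF per each of 36
single-copy core-gene (SCG) families plus `round(genome_size ×
orfs_per_megabase / 1e6)` other ORFs, so ORF count scales with genome
size while SCG copy number does not. SCG sequences descend from a
per-family ancestral sequence; each taxon diverges by 15% substitutions
(so 95%-identity clustering separates taxa) and each taxon's RefSeq-like
reference diverges a further 1% from the taxon's own gene. ORF read
coverage is Poisson(depth × taxon abundance); an optional gamma
overdispersion parameter is available but off by default, since the
profiler's contract assumes Poisson-like noise. Read-level simulation,
assembly and gene calling are intentionally not modelled — coverage is
generated directly at the level the profiler consumes.

**Proteome.** Each database protein belongs to a taxon and owns 2+
tryptic-style peptides (random length 7–25, ending K/R); decoy peptides
are sequence reversals preserving the terminal residue, the standard decoy
construction, mapped to dedicated decoy ids. Spectral counts are
Poisson(ms_depth × relative protein abundance × length/300); intensities
are log-normal around the expected count signal (σ = 0.5 in log-e units).
A configurable fraction of target proteins are *false* identifications
whose PSM scores come from the same Gaussian as the decoys
(target N(25, 4) vs. null N(15, 4)), which is what makes FDR calibration
measurable. Rhizosphere enrichment multiplies expected counts and
intensities of enriched proteins. Protein mass is scaled against the
enrichment-free baseline rather than renormalized per sample: activity
adds protein to a sample, mirroring the larger protein yield of
rhizosphere samples, rather than redistributing a fixed total. Spectra,
retention times and modification chemistry are not modelled; the
`is_modified` flag is sampled directly.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; identical seed and parameters give
byte-identical outputs.

## Database reduction (`seqcluster`)

Identity follows the CD-HIT convention: identical residues in an optimal
global alignment (match +1, mismatch 0, linear gap −1) divided by the
*shorter* sequence length, with membership additionally requiring that the
aligned fraction of the shorter sequence reach `min_short_coverage`
(default 0.80). Clustering is greedy longest-first with first-fit
assignment — deterministic, order-canonicalized, and the behaviour the
incremental tools it emulates have. Word-filter heuristics are deliberately
omitted (correctness over speed at desk scale); two exact shortcuts — a
duplicate-sequence map and a shared-residue-multiset upper bound on
identity — skip alignments without changing the partition. Among
co-optimal alignments the aligner's deterministic traceback fixes the
match count; argument order is canonicalized so identity is symmetric.
The greedy first-fit rule makes "more clusters at higher thresholds"
typical-case rather than provable behaviour, and it is tested as such.

## Protein inference (`inference`)

The FDR estimator is D(t)/max(T(t),1), capped at 1, without the +1 decoy
correction (available as a switch); q-values are running minima from the
worst threshold upward, so they are monotone in rank and ties share a
value. Grouping applies two parsimony rules exhaustively: proteins with
identical peptide sets merge, and a protein whose set is a strict subset
of another's is absorbed. When several incomparable supersets exist the
absorbing group is chosen deterministically (largest peptide set, then
lexicographically smallest); shared peptides are never unique to any
group, and there is no razor reassignment — the ≥2-unique-peptides rule is
the only uniqueness criterion applied. Group-level FDR is classic
target-decoy competition on best member scores. The group representative
is the member with most globally unique peptides, ties broken by summed
peptide scores, then by smallest id. Manual curation of borderline
identifications is out of scope; the filter-audit table records what each
rule removed so a human can review the decisions.

## Quantification (`quant`)

NSAF columns sum to one by construction and are scale-invariant to
per-sample count multipliers; percent abundance is 100 × NSAF. The
label-free route is deliberately simple: log2 of nonzero intensities,
per-sample median centered to the global median, zeros kept missing, no
imputation. This is a declared stand-in for delayed-normalization LFQ
(pairwise-ratio methods are not reimplemented) and is recorded in the
output metadata; it is valid exactly when most proteins are unchanged
between samples, which the bundled scenario respects (see below). Z-score
profiles standardize each protein across *condition means* (replicates
averaged first) with sample standard deviation; zero-variance rows come
back as zeros. Rollups conserve total abundance per sample and route
unannotated proteins to an explicit `unannotated` category.

## Enrichment and community statistics (`diffstats`)

Per-protein testing uses Welch's unequal-variance t-test on log-scale
values — the safer default when per-group variances are unknown — with
pairwise-complete observations gated at ≥2 observed values per group
(excluded proteins are reported as `not_tested`, never silently dropped)
and Benjamini-Hochberg step-up correction. The labelling rule is
asymmetric by design: rhizosphere at q < 0.05 and fold change > 2, bulk at
q < 0.05 and inverse fold change > 1.5.

Bray-Curtis dissimilarity is computed on non-negative feature-by-sample
values. ANOSIM ranks all n(n−1)/2 dissimilarities with average ranks for
ties; R = (r̄_between − r̄_within)/(n(n−1)/4). PERMANOVA partitions squared
dissimilarities: SS_T = (1/N)Σ_{i<j} d²_ij, SS_W summed within groups
scaled by group size, pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)),
R² = SS_A/SS_T; SS_W = 0 reports pseudo-F as +inf. Permutation p-values
include the observed statistic ((1 + exceedances)/(1 + permutations)), so
they are never zero and are bounded below by 1/(permutations+1); small
designs can be evaluated exactly by enumerating all distinct label
arrangements. Only one-way designs are implemented; stratified or two-way
permutation schemes are out of scope.

## SCG taxonomic profiling (`scgprofile`)

Profiles are built from SCG coverage only: coverage summed per
(taxon-at-rank, family, sample); where several families support the same
taxon, the *median* family coverage is taken — robust against
repeat-inflated or collapsed families; the per-sample normalizer N_s is
the median over the 36 families of total family coverage. Because non-SCG
ORFs never enter, the estimate is invariant to genome size by
construction.

Two open choices were resolved as follows. The median for a taxon is
taken over families with *nonzero* coverage by default (zeros from
undetected families would bias low-abundance taxa toward zero); the
all-36-families behaviour is available behind a flag. Nearest-reference
assignment uses cosine distance between k-mer (k=4) frequency vectors
instead of per-family phylogenetic trees — tree building is out of scope;
the contract (argmin distance to a lineage-bearing reference, ties to the
lexicographically smallest id) is preserved and the distance function is
pluggable. References are per (taxon, family), since a single per-taxon
sequence cannot carry family-specific k-mer signal. Profiles are
recomputed per rank from scratch (prefix matching on fixed 7-rank
lineages); coarser ranks are *not* obtained by summing finer-rank outputs,
because the median is taken after regrouping.

## Marker profiling (`markerprofile`)

Profile-HMM scoring itself is out of scope: the score table is an input
(the generator emits scores from configured Gaussians for true and false
family members), preserving the thresholding contract. An ORF joins the
family with the highest score among families whose threshold it strictly
exceeds; taxonomy is single-winner best hit at e ≤ 1e-20 with no
lowest-common-ancestor fallback; unassignable ORFs are removed and
counted. Marker abundance is coverage summed per (family, taxon) divided
by the SCG normalizer N_s — the same normalizer as the taxonomic profile,
keeping the two tables on one scale and cancelling sequencing depth.

## Pipeline and reproducibility (`io`, `pipeline`, `cli`)

All tables are TSV with `# key: value` provenance headers (config hash
and seed); timestamps live only in `provenance.yaml` so numeric outputs
are byte-stable across reruns. One top-level seed is derived per stage via
CRC-keyed `SeedSequence` spawning. Stage failures halt the run with the
stage name and cause; configuration is validated before any stage runs.

## The bundled scenario and problem sizes

The default `RunConfig` encodes the scenario the end-to-end validation
uses: 8 taxa, 6 samples per compartment, sequencing depth 100, ~15 ORFs
per megabase, one taxon with a 4-fold *activity-only* rhizosphere effect,
and 15% of proteins 4-fold enriched. The enriched minority is kept well
under half of the proteome so the median-centering normalization's
majority-unchanged assumption holds — with near-half of a proteome
enriched, any compositional normalization misattributes direction, a real
failure mode of label-free normalization worth knowing about. Validation
experiments use 10k/10k target/decoy PSM sets (30–50 replicates),
50-replicate genome-size comparisons, 10-taxon recovery scenarios at
depth 50, 50×1000-protein null and 10×1000-protein spiked enrichment
panels, and 200-replicate permutation-null calibrations; these sizes give
Monte-Carlo standard errors small enough for the two-standard-error checks
used throughout.

## What passing tests do and do not show

The generator matches the *assumptions* of the analysis (log-normal
abundances, Poisson coverage, Gaussian score separation, exactly
single-copy SCGs, honest decoys). Real soil data violates several of
them: coverage is overdispersed and GC-biased, search-engine scores are
not Gaussian and decoys are not perfectly exchangeable with false targets,
SCGs are occasionally duplicated or fragmented by assembly, peptides map
across genuinely homologous proteins far more densely, and lineages are
incomplete. Passing tests therefore demonstrate correctness of the
procedures under their stated models and calibration of their error
control under exchangeability — not field-data performance. Numerical
edge cases are handled explicitly: all-zero samples are rejected by name,
zero-variance rows give zero Z-scores or p = 1, SS_W = 0 reports an
infinite pseudo-F with a valid permutation p, and every tie (scores,
cluster order, representatives, references, marker families) has a
documented deterministic break.
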