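"""End-to-end orchestration: simulate -> cluster -> infer -> quant ->
enrich -> scg-profile -> marker-profile -> stats.

Each stage writes its outputs as TSV with provenance header comments
(config hash + seed); rerunning with an identical configuration reproduces
identical numeric outputs.  A stage failure halts the run with the stage
name and cause.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffstats, inference, markerprofile, quant, scgprofile, synthgen
from .io import RunConfig, write_fasta, write_table
from .seqcluster import SequenceRecord, greedy_cluster
from .synthgen import (
    DEFAULT_MARKER_THRESHOLDS,
    EffectConfig,
    ProteomeConfig,
    RANKS,
    SCG_FAMILIES,
    spawn_seed,
)

logger = logging.getLogger(__name__)

OUTPUT_TABLES = [
    "clusters.tsv",
    "groups.tsv",
    "filter_audit.tsv",
    "abundance_nsaf.tsv",
    "abundance_lfq.tsv",
    "enrichment.tsv",
    "profile.tsv",
    "marker_abundance.tsv",
    "stats.tsv",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """Handles to every stage's in-memory product and written table."""

    out_dir: Path
    scenario: synthgen.CommunityScenario = None
    metagenome: synthgen.SyntheticMetagenome = None
    psm_set: synthgen.SyntheticPsmSet = None
    group_set: inference.ProteinGroupSet = None
    nsaf: quant.AbundanceMatrix = None
    lfq: quant.AbundanceMatrix = None
    enrichment: pd.DataFrame = None
    profile: scgprofile.TaxonProfile = None
    marker_abundance: pd.DataFrame = None
    stats: pd.DataFrame = None
    tables: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - halting with context
                raise StageError(name, exc) from exc
        return inner
    return wrap


def group_quant_tables(
    psms: pd.DataFrame, group_set: inference.ProteinGroupSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group spectral counts and intensities by sample.

    Counts/intensities of a group's PSMs are summed per sample; peptides
    whose evidence spans more than one kept group are excluded to avoid
    double counting.
    """
    pep_owner: dict[str, int | None] = {}
    for idx, g in enumerate(group_set.groups):
        for pep in g.peptides:
            pep_owner[pep] = None if pep in pep_owner else idx
    rows = psms[psms["peptide"].map(lambda p: pep_owner.get(p) is not None)]
    owner = rows["peptide"].map(pep_owner).astype(int)
    group_ids = [f"G{i:05d}" for i in range(len(group_set.groups))]
    counts = (
        rows.groupby([owner, rows["sample"]])["spectral_count"].sum().unstack(fill_value=0)
    )
    intensities = (
        rows.groupby([owner, rows["sample"]])["intensity"].sum().unstack(fill_value=0.0)
    )
    counts.index = [group_ids[i] for i in counts.index]
    intensities.index = [group_ids[i] for i in intensities.index]
    samples = sorted(psms["sample"].unique())
    counts = counts.reindex(columns=samples, fill_value=0).reindex(
        group_ids, fill_value=0
    )
    intensities = intensities.reindex(columns=samples, fill_value=0.0).reindex(
        group_ids, fill_value=0.0
    )
    return counts, intensities


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow and write all nine output tables."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    inputs_dir = out / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    meta = config.provenance()
    result = PipelineResult(out_dir=out)

    # ---------------------------------------------------------------- simulate
    @_stage("simulate")
    def simulate():
        effect = EffectConfig(
            enrichment_factor=config.enrichment_factor,
            n_enriched=config.n_enriched_taxa,
            mode=config.enrichment_mode,
        )
        scenario = synthgen.simulate_community(
            n_taxa=config.n_taxa,
            n_samples=config.n_samples,
            depth=config.depth,
            effect_config=effect,
            seed=spawn_seed(config.seed, "community"),
        )
        metagenome = synthgen.simulate_metagenome(
            scenario,
            orfs_per_megabase=config.orfs_per_megabase,
            seed=spawn_seed(config.seed, "metagenome"),
        )
        scores, hits = synthgen.simulate_marker_evidence(
            metagenome, seed=spawn_seed(config.seed, "markers")
        )
        return scenario, metagenome, scores, hits

    scenario, metagenome, marker_scores, marker_hits = simulate()
    result.scenario = scenario
    result.metagenome = metagenome

    write_fasta(
        [SequenceRecord(i, s) for i, s in metagenome.orfs["sequence"].items()],
        inputs_dir / "orfs.fasta",
    )
    write_fasta(
        [SequenceRecord(i, s) for i, s in metagenome.references["sequence"].items()],
        inputs_dir / "references.fasta",
    )
    write_table(
        metagenome.coverage.rename_axis("orf_id").reset_index(),
        inputs_dir / "coverage.tsv", meta,
    )
    write_table(
        scenario.lineages.reset_index(), inputs_dir / "lineages.tsv", meta
    )
    write_table(
        pd.DataFrame(
            {"sample": scenario.samples,
             "compartment": scenario.compartment.values}
        ),
        inputs_dir / "meta.tsv", meta,
    )
    write_table(marker_scores, inputs_dir / "scores.tsv", meta)
    write_table(marker_hits, inputs_dir / "hits.tsv", meta)

    # ------------------------------------------------------------------ cluster
    @_stage("cluster")
    def cluster():
        records = [
            SequenceRecord(orf_id, seq)
            for orf_id, seq in metagenome.orfs["sequence"].items()
        ]
        clusters = greedy_cluster(
            records, config.db_identity, config.min_short_coverage
        )
        rows = []
        for i, cl in enumerate(clusters):
            for member in cl.member_ids:
                rows.append(
                    {
                        "cluster_id": f"C{i:05d}",
                        "representative": cl.representative_id,
                        "member": member,
                        "identity": cl.identity_to_rep[member],
                    }
                )
        return clusters, pd.DataFrame(rows)

    clusters, cluster_table = cluster()
    write_table(cluster_table, out / "clusters.tsv", meta)
    result.tables["clusters.tsv"] = out / "clusters.tsv"

    # -------------------------------------------------------------------- infer
    @_stage("infer")
    def infer():
        # search database: one representative per cluster, with taxon and a
        # function label for downstream rollups
        reps = [cl.representative_id for cl in clusters]
        rep_info = metagenome.orfs.loc[reps]
        protein_table = pd.DataFrame(
            {
                "protein_id": rep_info.index,
                "length": rep_info["length"].to_numpy(),
                "taxon": rep_info["taxon"].to_numpy(),
            }
        )
        proteome_cfg = ProteomeConfig(
            protein_table=protein_table,
            frac_enriched=config.frac_enriched_proteins,
            fold_change=config.protein_fold_change,
            ms_depth=config.ms_depth,
        )
        psm_set = synthgen.simulate_psm_table(
            scenario, proteome_cfg, seed=spawn_seed(config.seed, "psms")
        )
        group_set = inference.infer_protein_groups(
            psm_set.psms,
            pep_fdr=config.pep_fdr,
            prot_fdr=config.prot_fdr,
            min_unique=config.min_unique,
        )
        return psm_set, group_set

    psm_set, group_set = infer()
    result.psm_set = psm_set
    result.group_set = group_set
    write_table(psm_set.psms, inputs_dir / "psm.tsv", meta)
    write_table(group_set.to_frame(), out / "groups.tsv", meta)
    audit = pd.DataFrame(
        sorted(group_set.audit.items()), columns=["rule", "groups_removed"]
    )
    write_table(audit, out / "filter_audit.tsv", meta)
    result.tables["groups.tsv"] = out / "groups.tsv"
    result.tables["filter_audit.tsv"] = out / "filter_audit.tsv"

    # -------------------------------------------------------------------- quant
    @_stage("quant")
    def quantify():
        counts, intensities = group_quant_tables(psm_set.psms, group_set)
        lengths = pd.Series(
            {
                f"G{i:05d}": psm_set.proteins.loc[g.representative, "length"]
                if g.representative in psm_set.proteins.index
                else 300
                for i, g in enumerate(group_set.groups)
            }
        )
        nsaf_matrix = quant.nsaf(counts, lengths)
        lfq_matrix = quant.lfq_normalize(intensities)
        return nsaf_matrix, lfq_matrix

    nsaf_matrix, lfq_matrix = quantify()
    result.nsaf = nsaf_matrix
    result.lfq = lfq_matrix
    write_table(
        nsaf_matrix.values.rename_axis("group_id").reset_index(),
        out / "abundance_nsaf.tsv", {**meta, "mode": "NSAF"},
    )
    write_table(
        lfq_matrix.values.rename_axis("group_id").reset_index(),
        out / "abundance_lfq.tsv", {**meta, "mode": "normalized-LFQ"},
    )
    result.tables["abundance_nsaf.tsv"] = out / "abundance_nsaf.tsv"
    result.tables["abundance_lfq.tsv"] = out / "abundance_lfq.tsv"

    # ------------------------------------------------------------------- enrich
    @_stage("enrich")
    def enrich():
        return diffstats.differential_enrichment(
            lfq_matrix.values,
            scenario.compartment,
            fc_threshold_rhizo=config.fc_rhizo,
            fc_threshold_bulk=config.fc_bulk,
            alpha=config.alpha,
        )

    enrichment = enrich()
    result.enrichment = enrichment
    write_table(
        enrichment.rename_axis("group_id").reset_index(),
        out / "enrichment.tsv", meta,
    )
    result.tables["enrichment.tsv"] = out / "enrichment.tsv"

    # -------------------------------------------------------------- scg-profile
    @_stage("scg-profile")
    def scg_profile():
        scg_orfs = metagenome.orfs[metagenome.orfs["family"].isin(SCG_FAMILIES)]
        catalog_rows = []
        for fam in SCG_FAMILIES:
            fam_orfs = scg_orfs[scg_orfs["family"] == fam]
            records = [
                SequenceRecord(orf_id, seq)
                for orf_id, seq in fam_orfs["sequence"].items()
            ]
            fam_clusters = greedy_cluster(
                records, config.scg_identity, config.min_short_coverage
            )
            reps = pd.Series(
                {
                    f"{fam}|{cl.representative_id}": scg_orfs.loc[
                        cl.representative_id, "sequence"
                    ]
                    for cl in fam_clusters
                }
            )
            fam_refs = metagenome.references[
                metagenome.references["family"] == fam
            ]
            assigned = scgprofile.assign_nearest_reference(reps, fam_refs)
            for cl in fam_clusters:
                key = f"{fam}|{cl.representative_id}"
                lineage = assigned.loc[key, "lineage"]
                for member in cl.member_ids:
                    catalog_rows.append(
                        {
                            "orf_id": member,
                            "family": fam,
                            "cluster_id": key,
                            "lineage": lineage,
                        }
                    )
        catalog = pd.DataFrame(catalog_rows).set_index("orf_id")
        profile = scgprofile.profile_metagenome(
            metagenome.coverage, catalog, rank=config.rank
        )
        return catalog, profile

    catalog, profile = scg_profile()
    result.profile = profile
    write_table(
        catalog.reset_index(), inputs_dir / "catalog.tsv", meta
    )
    write_table(
        profile.abundance.rename_axis("taxon").reset_index(),
        out / "profile.tsv", {**meta, "rank": config.rank},
    )
    result.tables["profile.tsv"] = out / "profile.tsv"

    # ----------------------------------------------------------- marker-profile
    @_stage("marker-profile")
    def marker_profile():
        classification = markerprofile.classify_markers(
            marker_scores, DEFAULT_MARKER_THRESHOLDS
        )
        taxonomy = markerprofile.assign_marker_taxonomy(marker_hits)
        table = markerprofile.marker_relative_abundance(
            metagenome.coverage,
            classification.assignments,
            taxonomy.assignments,
            profile.normalizers,
        )
        return table

    marker_abundance = marker_profile()
    result.marker_abundance = marker_abundance
    write_table(
        marker_abundance.reset_index(), out / "marker_abundance.tsv", meta
    )
    result.tables["marker_abundance.tsv"] = out / "marker_abundance.tsv"

    # -------------------------------------------------------------------- stats
    @_stage("stats")
    def community_stats():
        rows = []
        for name, matrix in (
            ("metaproteome_nsaf", nsaf_matrix.values),
            ("metagenome_scg", profile.abundance),
        ):
            dist = diffstats.bray_curtis(matrix)
            labels = scenario.compartment
            ano = diffstats.anosim(
                dist, labels, n_perm=config.n_permutations,
                seed=spawn_seed(config.seed, f"anosim-{name}"),
                method="permutation",
            )
            per = diffstats.permanova(
                dist, labels, n_perm=config.n_permutations,
                seed=spawn_seed(config.seed, f"permanova-{name}"),
                method="permutation",
            )
            rows.append(
                {
                    "dataset": name,
                    "anosim_R": ano.R,
                    "anosim_p": ano.p_value,
                    "permanova_F": per.pseudo_F,
                    "permanova_R2": per.R2,
                    "permanova_p": per.p_value,
                    "n_permutations": config.n_permutations,
                }
            )
        return pd.DataFrame(rows)

    stats_table = community_stats()
    result.stats = stats_table
    write_table(stats_table, out / "stats.tsv", meta)
    result.tables["stats.tsv"] = out / "stats.tsv"

    # provenance record (timestamped; numeric tables stay byte-stable)
    provenance = {
        **meta,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": sorted(result.tables),
    }
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))
    config.to_yaml(out / "config.yaml")

    return result
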