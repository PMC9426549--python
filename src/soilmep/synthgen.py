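"""Synthetic soil-community data with known ground truth.

Every downstream stage of the analysis (database reduction, protein
inference, quantification, enrichment, taxonomic profiling) is exercised on
data produced here, so each generator encodes the statistical structure the
corresponding stage assumes:

* taxon abundances are heavy-tailed (log-normal across taxa) and
  column-normalized per sample, with an optional multiplicative rhizosphere
  effect that can act either on community composition (DNA) or on
  metabolic activity (protein) alone;
* every taxon carries exactly one copy of each of the 36 single-copy
  core-gene (SCG) families, plus non-SCG ORFs in proportion to genome size;
* ORF read coverage is Poisson around depth x taxon abundance (optionally
  gamma-overdispersed);
* peptide-spectrum matches (PSMs) carry separated target/decoy score
  distributions, spectral counts proportional to protein abundance x
  length, and log-normal intensities with a configured compartment fold
  change on enriched proteins.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so identical seed + parameters give
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .seqcluster import AMINO_ACIDS

N_SCG_FAMILIES = 36
SCG_FAMILIES = [f"SCG-{i}" for i in range(1, N_SCG_FAMILIES + 1)]
MARKER_FAMILIES = ["PhoA", "PhoD", "PhoX"]
RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]

_PHYLA = [
    ("Proteobacteria", "Gammaproteobacteria"),
    ("Proteobacteria", "Betaproteobacteria"),
    ("Proteobacteria", "Alphaproteobacteria"),
    ("Actinobacteria", "Actinomycetia"),
    ("Bacteroidetes", "Flavobacteriia"),
    ("Acidobacteria", "Acidobacteriia"),
    ("Firmicutes", "Bacilli"),
    ("Verrucomicrobia", "Verrucomicrobiae"),
]

FUNCTION_CATEGORIES = [
    "Amino acid transport and metabolism",
    "Carbohydrate transport and metabolism",
    "Inorganic ion transport and metabolism",
    "Cell envelope biogenesis",
    "Protein synthesis",
    "Central metabolism",
    "Hydrolytic enzyme",
    "Hypothetical",
]


def _child_rng(seed_seq: np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in seed_seq.spawn(n)]


def spawn_seed(seed: int, label: str) -> int:
    """Derive a stage seed (< 2**31) deterministically from a run seed."""
    digest = zlib.crc32(label.encode("utf-8"))
    h = np.random.SeedSequence([seed, digest])
    return int(h.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Community scenario
# ---------------------------------------------------------------------------


@dataclass
class EffectConfig:
    """Rhizosphere effect specification.

    ``enrichment_factor`` multiplies the affected taxa in rhizosphere
    samples; ``mode`` chooses whether the effect acts on community
    composition ("abundance", visible to the metagenome) or on protein
    output alone ("activity", visible only to the proteome).  ``n_enriched``
    selects how many taxa (the first ones, deterministically) receive the
    factor; per-taxon factors can be given directly instead.
    """

    enrichment_factor: float | Sequence[float] = 1.0
    n_enriched: int = 0
    mode: Literal["abundance", "activity"] = "activity"

    def per_taxon(self, n_taxa: int) -> np.ndarray:
        if np.isscalar(self.enrichment_factor):
            factors = np.ones(n_taxa)
            factors[: self.n_enriched] = float(self.enrichment_factor)
        else:
            factors = np.asarray(self.enrichment_factor, dtype=float)
            if factors.shape != (n_taxa,):
                raise ValueError("per-taxon enrichment_factor length mismatch")
        if (factors < 0).any():
            raise ValueError("enrichment_factor must be >= 0")
        return factors


@dataclass
class CommunityScenario:
    """Ground-truth community: who is there, how big their genomes are, and
    how abundant they are in every sample."""

    taxa: list[str]
    lineages: pd.DataFrame  # index: taxon, columns: the 7 ranks
    genome_size: pd.Series  # bases per genome
    abundance: pd.DataFrame  # taxon x sample, columns sum to 1
    compartment: pd.Series  # sample -> "bulk" | "rhizosphere"
    enrichment_factor: pd.Series  # per-taxon activity/abundance effect
    enrichment_mode: str
    depth: float
    seed: int

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def validate(self) -> None:
        sums = self.abundance.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("abundance columns must sum to 1")
        if self.lineages.isna().any().any():
            raise ValueError("every taxon needs a complete 7-rank lineage")
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")


def _make_lineages(taxa: list[str], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i, taxon in enumerate(taxa):
        phylum, cls = _PHYLA[i % len(_PHYLA)]
        rows.append(
            {
                "domain": "Bacteria",
                "phylum": phylum,
                "class": cls,
                "order": f"{cls}_order_{i % 4}",
                "family": f"Family_{i}",
                "genus": f"Genus_{i}",
                "species": f"{taxon}_sp",
            }
        )
    return pd.DataFrame(rows, index=pd.Index(taxa, name="taxon"))


def simulate_community(
    n_taxa: int,
    n_samples: int,
    depth: float,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    abundance_sigma: float = 1.0,
    sample_sigma: float = 0.25,
    genome_size_range: tuple[int, int] = (2_000_000, 6_000_000),
) -> CommunityScenario:
    """Simulate a two-compartment community.

    ``n_samples`` is the number of samples per compartment (bulk and
    rhizosphere), so the scenario has ``2 * n_samples`` samples in total.
    Per-taxon base abundances are log-normal(0, ``abundance_sigma``); each
    sample draws independent log-normal(0, ``sample_sigma``) replicate noise
    around the base, applies the rhizosphere effect when the effect mode is
    "abundance", and renormalizes to sum to 1.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa to form a community")
    if n_samples < 2:
        raise ValueError("need at least 2 samples per compartment")
    if depth <= 0:
        raise ValueError("depth must be positive")
    effect_config = effect_config or EffectConfig()

    ss = np.random.SeedSequence([seed, 101])
    rng_base, rng_noise, rng_genome = _child_rng(ss, 3)

    taxa = [f"T{i:03d}" for i in range(n_taxa)]
    base = rng_base.lognormal(mean=0.0, sigma=abundance_sigma, size=n_taxa)
    genome_size = rng_genome.integers(
        genome_size_range[0], genome_size_range[1] + 1, size=n_taxa
    )
    factors = effect_config.per_taxon(n_taxa)

    samples = [f"bulk_{i + 1}" for i in range(n_samples)] + [
        f"rhizo_{i + 1}" for i in range(n_samples)
    ]
    compartment = pd.Series(
        ["bulk"] * n_samples + ["rhizosphere"] * n_samples,
        index=pd.Index(samples, name="sample"),
        name="compartment",
    )

    cols = {}
    for s in samples:
        noise = rng_noise.lognormal(mean=0.0, sigma=sample_sigma, size=n_taxa)
        ab = base * noise
        if effect_config.mode == "abundance" and compartment[s] == "rhizosphere":
            ab = ab * factors
        cols[s] = ab / ab.sum()
    abundance = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon"))

    scenario = CommunityScenario(
        taxa=taxa,
        lineages=_make_lineages(taxa, rng_base),
        genome_size=pd.Series(genome_size, index=taxa, name="genome_size"),
        abundance=abundance,
        compartment=compartment,
        enrichment_factor=pd.Series(factors, index=taxa, name="enrichment_factor"),
        enrichment_mode=effect_config.mode,
        depth=float(depth),
        seed=seed,
    )
    scenario.validate()
    return scenario


# ---------------------------------------------------------------------------
# Metagenome: ORF catalog, references, coverage
# ---------------------------------------------------------------------------


@dataclass
class SyntheticMetagenome:
    """ORF catalog with per-sample read coverage and a reference set.

    ``orfs`` columns: orf_id, taxon, family (SCG-1..SCG-36, a marker family,
    or "other"), length, sequence.  ``coverage`` is ORF x sample.
    ``references`` emulates a RefSeq-like outgroup: per (taxon, SCG family)
    a lightly diverged relative of the taxon's gene, carrying the taxon's
    lineage, used for nearest-reference taxonomic assignment.
    """

    orfs: pd.DataFrame
    coverage: pd.DataFrame
    references: pd.DataFrame
    scenario: CommunityScenario
    marker_copies: pd.DataFrame  # taxon x marker family copy numbers


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute a ``rate`` fraction of positions with a different residue."""
    n_mut = int(round(rate * len(seq)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        choices = [aa for aa in AMINO_ACIDS if aa != chars[pos]]
        chars[pos] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def simulate_metagenome(
    scenario: CommunityScenario,
    orfs_per_megabase: float,
    seed: int = 0,
    scg_length: int = 300,
    taxon_divergence: float = 0.15,
    reference_divergence: float = 0.01,
    overdispersion: float = 0.0,
    marker_copy_max: int = 2,
) -> SyntheticMetagenome:
    """Simulate an ORF catalog and its multisample coverage profile.

    Each taxon contributes exactly one ORF per SCG family plus
    ``round(genome_size * orfs_per_megabase / 1e6)`` non-SCG ORFs.  SCG
    sequences descend from a per-family ancestor, each taxon diverging by
    ``taxon_divergence`` substitutions; the reference relative of each gene
    diverges a further ``reference_divergence``.  Marker-gene (alkaline
    phosphatase) ORFs are drawn from the non-SCG budget with 0..
    ``marker_copy_max`` copies per family per taxon.  Coverage is
    Poisson(depth x abundance), or gamma-Poisson when ``overdispersion`` > 0.
    """
    if orfs_per_megabase <= 0:
        raise ValueError("orfs_per_megabase must be positive")
    scenario.validate()

    ss = np.random.SeedSequence([seed, 202])
    rng_anc, rng_tax, rng_other, rng_cov, rng_marker = _child_rng(ss, 5)

    ancestors = {fam: _random_protein(rng_anc, scg_length) for fam in SCG_FAMILIES}
    marker_ancestors = {
        fam: _random_protein(rng_anc, scg_length) for fam in MARKER_FAMILIES
    }

    orf_rows = []
    ref_rows = []
    marker_copy_rows = {}
    for taxon in scenario.taxa:
        lineage = scenario.lineages.loc[taxon]
        # exactly one copy of each SCG family
        for fam in SCG_FAMILIES:
            gene = _mutate(ancestors[fam], taxon_divergence, rng_tax)
            orf_rows.append(
                {
                    "orf_id": f"{taxon}_{fam}",
                    "taxon": taxon,
                    "family": fam,
                    "length": len(gene),
                    "sequence": gene,
                }
            )
            ref_rows.append(
                {
                    "ref_id": f"REF_{taxon}_{fam}",
                    "taxon": taxon,
                    "family": fam,
                    "sequence": _mutate(gene, reference_divergence, rng_tax),
                    "lineage": ";".join(lineage[r] for r in RANKS),
                }
            )
        # marker-gene copies (0..marker_copy_max per family)
        copies = {}
        for fam in MARKER_FAMILIES:
            k = int(rng_marker.integers(0, marker_copy_max + 1))
            copies[fam] = k
            for c in range(k):
                gene = _mutate(marker_ancestors[fam], taxon_divergence, rng_marker)
                orf_rows.append(
                    {
                        "orf_id": f"{taxon}_{fam}_{c + 1}",
                        "taxon": taxon,
                        "family": fam,
                        "length": len(gene),
                        "sequence": gene,
                    }
                )
        marker_copy_rows[taxon] = copies
        # non-SCG ORFs proportional to genome size
        n_other = int(round(scenario.genome_size[taxon] * orfs_per_megabase / 1e6))
        lengths = rng_other.integers(100, 401, size=n_other)
        for j in range(n_other):
            orf_rows.append(
                {
                    "orf_id": f"{taxon}_ORF{j:05d}",
                    "taxon": taxon,
                    "family": "other",
                    "length": int(lengths[j]),
                    "sequence": _random_protein(rng_other, int(lengths[j])),
                }
            )

    orfs = pd.DataFrame(orf_rows).set_index("orf_id")
    references = pd.DataFrame(ref_rows).set_index("ref_id")
    marker_copies = pd.DataFrame(marker_copy_rows).T.rename_axis("taxon")

    # coverage: Poisson(depth * abundance of the ORF's taxon)
    taxon_idx = orfs["taxon"].to_numpy()
    lam = scenario.depth * scenario.abundance.loc[taxon_idx].to_numpy()
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = lam * rng_cov.gamma(shape, scale=1.0 / shape, size=lam.shape)
    cov = rng_cov.poisson(lam).astype(float)
    coverage = pd.DataFrame(cov, index=orfs.index, columns=scenario.samples)

    return SyntheticMetagenome(
        orfs=orfs,
        coverage=coverage,
        references=references,
        scenario=scenario,
        marker_copies=marker_copies,
    )


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------


@dataclass
class ProteomeConfig:
    """Generative settings for the synthetic search-engine output.

    Target and decoy PSM scores are Gaussian with ``target_score_mean`` >
    ``decoy_score_mean``; a ``frac_false_targets`` fraction of target
    proteins are "false" identifications whose PSM scores come from the
    decoy (null) distribution, giving the two-tier FDR something real to
    control.  ``frac_enriched`` of the true proteins get
    ``fold_change``-fold higher expected counts and intensities in
    rhizosphere samples.
    """

    n_proteins: int = 400
    protein_table: pd.DataFrame | None = None  # optional: id, length, taxon, function
    peptides_per_protein: float = 4.0
    shared_peptide_fraction: float = 0.05
    target_score_mean: float = 25.0
    decoy_score_mean: float = 15.0
    score_sd: float = 4.0
    decoy_fraction: float = 0.5
    frac_false_targets: float = 0.10
    frac_enriched: float = 0.25
    fold_change: float = 4.0
    frac_modified_only: float = 0.03
    modified_rate: float = 0.05
    n_contaminants: int = 5
    ms_depth: float = 20000.0
    intensity_sigma: float = 0.5
    expression_sigma: float = 1.0

    def validate(self) -> None:
        if self.target_score_mean <= self.decoy_score_mean:
            raise ValueError("target score mean must exceed decoy score mean")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")


@dataclass
class SyntheticPsmSet:
    """Peptide-spectrum matches plus the generative truth."""

    psms: pd.DataFrame
    proteins: pd.DataFrame  # protein_id -> length, taxon, function, flags
    truth_present: set[str] = field(default_factory=set)
    truth_enriched: set[str] = field(default_factory=set)
    truth_false: set[str] = field(default_factory=set)

    PSM_COLUMNS = [
        "spectrum_id",
        "peptide",
        "proteins",
        "score",
        "is_decoy",
        "is_modified",
        "is_contaminant",
        "sample",
        "spectral_count",
        "intensity",
    ]


def _tryptic_peptide(rng: np.random.Generator) -> str:
    """Random tryptic-style peptide: length 7-25, ending in K or R."""
    length = int(rng.integers(7, 26))
    body = "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length - 1)
    )
    terminal = "K" if rng.integers(0, 2) == 0 else "R"
    return body + terminal


def reverse_decoy(peptide: str) -> str:
    """Decoy peptide by sequence reversal preserving the terminal residue."""
    return peptide[:-1][::-1] + peptide[-1]


def simulate_psm_table(
    scenario: CommunityScenario,
    proteome_config: ProteomeConfig | None = None,
    seed: int = 0,
) -> SyntheticPsmSet:
    """Emulate search-engine output for the scenario's samples.

    Each protein belongs to a taxon and carries a set of tryptic peptides;
    per sample, its expected spectral count is ``ms_depth`` x its relative
    abundance (taxon abundance x log-normal expression) x length/300, with
    the activity enrichment factor (scenario, mode "activity") and the
    per-protein enrichment fold change applied in rhizosphere samples.
    Decoy PSMs carry reversed peptides mapped to decoy protein ids and
    scores from the null distribution.
    """
    cfg = proteome_config or ProteomeConfig()
    cfg.validate()
    scenario.validate()

    ss = np.random.SeedSequence([seed, 303])
    rng_prot, rng_pep, rng_count, rng_score, rng_int = _child_rng(ss, 5)

    # --- protein catalog -------------------------------------------------
    if cfg.protein_table is not None:
        proteins = cfg.protein_table.copy()
        required = {"protein_id", "length", "taxon"}
        if not required.issubset(proteins.columns):
            raise ValueError(f"protein_table needs columns {sorted(required)}")
        if "function" not in proteins.columns:
            proteins["function"] = [
                FUNCTION_CATEGORIES[i % len(FUNCTION_CATEGORIES)]
                for i in range(len(proteins))
            ]
    else:
        n = cfg.n_proteins
        taxa = [scenario.taxa[i] for i in rng_prot.integers(0, len(scenario.taxa), n)]
        proteins = pd.DataFrame(
            {
                "protein_id": [f"P{i:05d}" for i in range(n)],
                "length": rng_prot.integers(100, 601, size=n),
                "taxon": taxa,
                "function": [
                    FUNCTION_CATEGORIES[i % len(FUNCTION_CATEGORIES)]
                    for i in range(n)
                ],
            }
        )
    proteins = proteins.reset_index(drop=True)
    contaminant_ids = [f"CONT_{i:02d}" for i in range(cfg.n_contaminants)]
    if set(contaminant_ids) & set(proteins["protein_id"]):
        raise ValueError("contaminant ids overlap target protein ids")

    n_prot = len(proteins)
    n_false = int(round(cfg.frac_false_targets * n_prot))
    is_false = np.zeros(n_prot, dtype=bool)
    if n_false:
        is_false[rng_prot.choice(n_prot, size=n_false, replace=False)] = True
    true_idx = np.nonzero(~is_false)[0]
    n_enriched = int(round(cfg.frac_enriched * len(true_idx)))
    is_enriched = np.zeros(n_prot, dtype=bool)
    if n_enriched and cfg.fold_change != 1.0:
        is_enriched[rng_prot.choice(true_idx, size=n_enriched, replace=False)] = True
    n_modonly = int(round(cfg.frac_modified_only * len(true_idx)))
    is_modonly = np.zeros(n_prot, dtype=bool)
    if n_modonly:
        pool = [i for i in true_idx if not is_enriched[i]]
        is_modonly[rng_prot.choice(pool, size=n_modonly, replace=False)] = True
    proteins["is_false"] = is_false
    proteins["is_enriched"] = is_enriched
    proteins["is_modified_only"] = is_modonly
    proteins = proteins.set_index("protein_id")

    # --- peptide repertoires --------------------------------------------
    peptide_map: dict[str, list[str]] = {}
    protein_peptides: dict[str, list[str]] = {}
    ids = list(proteins.index)
    for i, pid in enumerate(ids):
        k = max(2, int(rng_pep.poisson(cfg.peptides_per_protein)))
        peps = []
        for _ in range(k):
            pep = _tryptic_peptide(rng_pep)
            while pep in peptide_map:
                pep = _tryptic_peptide(rng_pep)
            owners = [pid]
            if (
                cfg.shared_peptide_fraction > 0
                and rng_pep.random() < cfg.shared_peptide_fraction
                and n_prot > 1
            ):
                other = ids[int(rng_pep.integers(0, n_prot))]
                if other != pid:
                    owners.append(other)
                    protein_peptides.setdefault(other, []).append(pep)
            peptide_map[pep] = owners
            peps.append(pep)
        protein_peptides.setdefault(pid, []).extend(peps)

    cont_peptides: dict[str, list[str]] = {}
    for cid in contaminant_ids:
        peps = []
        for _ in range(3):
            pep = _tryptic_peptide(rng_pep)
            while pep in peptide_map:
                pep = _tryptic_peptide(rng_pep)
            peptide_map[pep] = [cid]
            peps.append(pep)
        cont_peptides[cid] = peps

    # --- per-sample expression ------------------------------------------
    expression = rng_count.lognormal(0.0, cfg.expression_sigma, size=n_prot)
    taxon_ab = scenario.abundance.loc[proteins["taxon"]].to_numpy()  # prot x sample
    activity = np.ones(n_prot)
    if scenario.enrichment_mode == "activity":
        activity = scenario.enrichment_factor.loc[proteins["taxon"]].to_numpy()
    rhizo = (scenario.compartment == "rhizosphere").to_numpy()

    base = expression[:, None] * taxon_ab  # prot x sample
    eff = np.ones((n_prot, len(scenario.samples)))
    eff[:, rhizo] *= activity[:, None]
    eff[np.ix_(is_enriched, rhizo)] *= cfg.fold_change
    weights = base * eff
    # scale against the enrichment-free baseline: rhizosphere activity adds
    # protein mass rather than redistributing a fixed total, mirroring the
    # larger protein yield of rhizosphere samples
    weights = weights / base.sum(axis=0).mean()
    lam = cfg.ms_depth * weights * (proteins["length"].to_numpy()[:, None] / 300.0)

    counts = rng_count.poisson(lam)
    # every truly present protein must leave at least one PSM somewhere
    silent = counts.sum(axis=1) == 0
    for i in np.nonzero(silent)[0]:
        s = int(rng_count.integers(0, counts.shape[1]))
        counts[i, s] = 1

    rows = []
    spectrum = 0
    samples = scenario.samples
    for i, pid in enumerate(ids):
        peps = protein_peptides[pid]
        own_peps = [p for p in peps if pid in peptide_map[p]]
        mod_only = bool(is_modonly[i])
        for s_idx, sample in enumerate(samples):
            c = int(counts[i, s_idx])
            if c == 0:
                continue
            # distribute spectral counts over the protein's peptides
            alloc = rng_count.multinomial(c, np.full(len(own_peps), 1 / len(own_peps)))
            for pep, n_spec in zip(own_peps, alloc):
                if n_spec == 0:
                    continue
                if is_false[i]:
                    score = rng_score.normal(cfg.decoy_score_mean, cfg.score_sd)
                else:
                    score = rng_score.normal(cfg.target_score_mean, cfg.score_sd)
                intensity = float(
                    n_spec
                    * rng_int.lognormal(np.log(1e6 * lam[i, s_idx] / c + 1e-9),
                                        cfg.intensity_sigma)
                )
                modified = mod_only or (rng_int.random() < cfg.modified_rate)
                spectrum += 1
                rows.append(
                    {
                        "spectrum_id": f"S{spectrum:07d}",
                        "peptide": pep,
                        "proteins": ";".join(sorted(peptide_map[pep])),
                        "score": float(score),
                        "is_decoy": False,
                        "is_modified": modified,
                        "is_contaminant": False,
                        "sample": sample,
                        "spectral_count": int(n_spec),
                        "intensity": intensity,
                    }
                )

    # contaminant PSMs: steady across samples
    for cid, peps in cont_peptides.items():
        for sample in samples:
            for pep in peps:
                spectrum += 1
                rows.append(
                    {
                        "spectrum_id": f"S{spectrum:07d}",
                        "peptide": pep,
                        "proteins": cid,
                        "score": float(
                            rng_score.normal(cfg.target_score_mean, cfg.score_sd)
                        ),
                        "is_decoy": False,
                        "is_modified": False,
                        "is_contaminant": True,
                        "sample": sample,
                        "spectral_count": 1,
                        "intensity": float(rng_int.lognormal(np.log(1e5), 0.5)),
                    }
                )

    # decoy PSMs: reversed peptides, null scores, decoy protein ids
    n_target_psms = len(rows)
    n_decoys = int(round(cfg.decoy_fraction / (1 - cfg.decoy_fraction) * n_target_psms)) if cfg.decoy_fraction < 1 else 0
    if cfg.decoy_fraction == 0:
        n_decoys = 0
    target_peps = list(peptide_map.keys())
    for d in range(n_decoys):
        src = target_peps[int(rng_score.integers(0, len(target_peps)))]
        pep = reverse_decoy(src)
        sample = samples[int(rng_score.integers(0, len(samples)))]
        spectrum += 1
        rows.append(
            {
                "spectrum_id": f"S{spectrum:07d}",
                "peptide": pep,
                "proteins": f"DECOY_{d:05d}",
                "score": float(rng_score.normal(cfg.decoy_score_mean, cfg.score_sd)),
                "is_decoy": True,
                "is_modified": False,
                "is_contaminant": False,
                "sample": sample,
                "spectral_count": 1,
                "intensity": 0.0,
            }
        )

    psms = pd.DataFrame(rows, columns=SyntheticPsmSet.PSM_COLUMNS)

    truth_present = set(ids) | set(contaminant_ids)
    return SyntheticPsmSet(
        psms=psms,
        proteins=proteins,
        truth_present=truth_present,
        truth_enriched={ids[i] for i in np.nonzero(is_enriched)[0]},
        truth_false={ids[i] for i in np.nonzero(is_false)[0]},
    )


# ---------------------------------------------------------------------------
# Marker evidence tables (hmmsearch/BLASTP stand-ins)
# ---------------------------------------------------------------------------

DEFAULT_MARKER_THRESHOLDS = {"PhoA": 30.0, "PhoD": 30.0, "PhoX": 30.0}


def simulate_marker_evidence(
    metagenome: SyntheticMetagenome,
    seed: int = 0,
    true_score_mean: float = 60.0,
    false_score_mean: float = 10.0,
    score_sd: float = 5.0,
    hit_evalue_exponent_range: tuple[float, float] = (25.0, 60.0),
    frac_unalignable: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit marker-family score and best-hit tables for the ORF catalog.

    Scores emulate profile-HMM search output: an ORF scores high against its
    own family and low against the others.  Hits emulate BLASTP output
    against a curated reference database: true marker ORFs hit a reference
    of their own taxon at e-values well below 1e-20, except for a small
    ``frac_unalignable`` fraction given only weak hits (these get removed
    downstream, mirroring unclassifiable sequences).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 404])))
    marker_orfs = metagenome.orfs[metagenome.orfs["family"].isin(MARKER_FAMILIES)]

    score_rows = []
    hit_rows = []
    lo, hi = hit_evalue_exponent_range
    for orf_id, row in marker_orfs.iterrows():
        for fam in MARKER_FAMILIES:
            mean = true_score_mean if fam == row["family"] else false_score_mean
            score_rows.append(
                {
                    "orf_id": orf_id,
                    "family": fam,
                    "score": float(rng.normal(mean, score_sd)),
                }
            )
        lineage = ";".join(
            metagenome.scenario.lineages.loc[row["taxon"], r] for r in RANKS
        )
        if rng.random() < frac_unalignable:
            evalue = 10.0 ** (-float(rng.uniform(2.0, 10.0)))
        else:
            evalue = 10.0 ** (-float(rng.uniform(lo, hi)))
        hit_rows.append(
            {
                "orf_id": orf_id,
                "ref_taxon": row["taxon"],
                "lineage": lineage,
                "evalue": evalue,
            }
        )
        # a worse secondary hit to a random other taxon
        other = metagenome.scenario.taxa[
            int(rng.integers(0, len(metagenome.scenario.taxa)))
        ]
        hit_rows.append(
            {
                "orf_id": orf_id,
                "ref_taxon": other,
                "lineage": ";".join(
                    metagenome.scenario.lineages.loc[other, r] for r in RANKS
                ),
                "evalue": evalue * 10.0 ** float(rng.uniform(3.0, 10.0)),
            }
        )

    scores = pd.DataFrame(score_rows, columns=["orf_id", "family", "score"])
    hits = pd.DataFrame(hit_rows, columns=["orf_id", "ref_taxon", "lineage", "evalue"])
    return scores, hits


# ---------------------------------------------------------------------------
# Score-calibration sets for FDR validation
# ---------------------------------------------------------------------------


def simulate_calibration_psms(
    n_targets: int,
    n_decoys: int,
    frac_false: float,
    target_mean: float = 25.0,
    null_mean: float = 15.0,
    sd: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score/decoy/truth table for FDR calibration experiments.

    ``frac_false`` of the targets are incorrect matches whose scores come
    from the same null distribution as the decoys, so the decoy count is an
    unbiased estimate of the incorrect-target count at any threshold.
    """
    if n_targets < 1:
        raise ValueError("need at least one target")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 505])))
    n_false = int(round(frac_false * n_targets))
    n_true = n_targets - n_false
    scores = np.concatenate(
        [
            rng.normal(target_mean, sd, size=n_true),
            rng.normal(null_mean, sd, size=n_false),
            rng.normal(null_mean, sd, size=n_decoys),
        ]
    )
    is_decoy = np.concatenate(
        [np.zeros(n_targets, dtype=bool), np.ones(n_decoys, dtype=bool)]
    )
    is_false = np.concatenate(
        [
            np.zeros(n_true, dtype=bool),
            np.ones(n_false, dtype=bool),
            np.zeros(n_decoys, dtype=bool),
        ]
    )
    return pd.DataFrame({"score": scores, "is_decoy": is_decoy, "is_false": is_false})
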