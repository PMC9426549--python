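"""Taxonomic profiling from single-copy core-gene (SCG) coverage.

16S rRNA genes assemble poorly from shotgun metagenomes and vary in copy
number, so community composition is estimated instead from 36 single-copy
core gene families present exactly once per bacterial genome.  The
procedure:

1. SCG ORFs are de-replicated per family (greedy identity clustering) and
   each cluster representative is assigned the lineage of its nearest
   reference sequence (here a k-mer cosine distance; the distance function
   is pluggable);
2. per sample, coverage is summed per (taxon-at-rank, family); where a
   taxon is supported by more than one family, the median family coverage
   is taken — the median is robust to repeat-inflated or collapsed
   outlier families;
3. per-sample normalizers N_s are the median over the 36 families of total
   family coverage; dividing by N_s yields relative abundance.

Because only the 36 single-copy families enter the estimate, it is
insensitive to genome size: organisms with large genomes do not appear more
abundant than those with small ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthgen import RANKS, SCG_FAMILIES


# ---------------------------------------------------------------------------
# Nearest-reference assignment
# ---------------------------------------------------------------------------


def _kmer_vector(sequence: str, k: int) -> Counter:
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    return Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def _cosine_distance(a: Counter, b: Counter) -> float:
    dot = sum(v * b[key] for key, v in a.items() if key in b)
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def assign_nearest_reference(
    cluster_representatives: pd.Series,
    reference_set: pd.DataFrame,
    k: int = 4,
) -> pd.DataFrame:
    """Assign each cluster representative to its nearest reference.

    ``cluster_representatives`` maps cluster id -> amino-acid sequence;
    ``reference_set`` needs columns ``sequence`` and ``lineage`` indexed by
    reference id.  Distance is 1 - cosine similarity between
    length-normalized k-mer frequency vectors (normalization cancels in the
    cosine).  Exact distance ties go to the lexicographically smallest
    reference id.

    Returns a DataFrame indexed by cluster id with columns ``ref_id,
    lineage, distance``.
    """
    if reference_set.empty:
        raise ValueError("reference set is empty")
    if not {"sequence", "lineage"}.issubset(reference_set.columns):
        raise ValueError("reference_set needs 'sequence' and 'lineage' columns")

    ref_ids = sorted(reference_set.index)
    ref_vecs = {rid: _kmer_vector(reference_set.loc[rid, "sequence"], k)
                for rid in ref_ids}

    rows = []
    for cluster_id, seq in cluster_representatives.items():
        vec = _kmer_vector(seq, k)
        best_id, best_d = None, np.inf
        for rid in ref_ids:  # sorted: first hit wins ties
            d = _cosine_distance(vec, ref_vecs[rid])
            if d < best_d - 1e-12:
                best_id, best_d = rid, d
        rows.append(
            {
                "cluster_id": cluster_id,
                "ref_id": best_id,
                "lineage": reference_set.loc[best_id, "lineage"],
                "distance": float(best_d),
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------


@dataclass
class TaxonProfile:
    """Taxon-by-sample abundance derived from SCG coverage."""

    abundance: pd.DataFrame  # taxon (at rank) x sample
    family_totals: pd.DataFrame  # family x sample total coverage
    rank: str
    normalized: bool = False
    normalizers: pd.Series | None = None
    excluded_samples: list[str] = field(default_factory=list)


def lineage_at_rank(lineage: str, rank: str) -> str:
    """Truncate a 7-rank semicolon lineage at the requested rank."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    parts = lineage.split(";")
    if len(parts) != len(RANKS):
        raise ValueError(f"lineage {lineage!r} does not have {len(RANKS)} ranks")
    return ";".join(parts[: RANKS.index(rank) + 1])


def scg_taxon_profile(
    coverage: pd.DataFrame,
    catalog: pd.DataFrame,
    rank: str = "species",
    include_zero_families: bool = False,
) -> TaxonProfile:
    """Unnormalized taxon profile from SCG ORF coverage.

    ``coverage`` is ORF x sample; ``catalog`` needs columns ``family``
    (SCG-1..SCG-36) and ``lineage`` indexed by ORF id.  Coverage is summed
    per (taxon-at-rank, family, sample); the taxon's per-sample abundance
    is the median over families with nonzero coverage (or over all 36
    families when ``include_zero_families``).  Taxa with no covered SCG in
    a sample get 0 there; taxa never covered are omitted.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    scg_catalog = catalog[catalog["family"].isin(SCG_FAMILIES)]
    missing = scg_catalog.index.difference(coverage.index)
    if len(missing):
        raise ValueError(f"coverage missing for catalog ORFs: {list(missing[:5])}")

    cov = coverage.loc[scg_catalog.index].astype(float)
    if (cov.values < 0).any():
        raise ValueError("coverage must be non-negative")
    taxa = scg_catalog["lineage"].map(lambda lin: lineage_at_rank(lin, rank))
    fam = scg_catalog["family"]

    sums = cov.groupby([taxa.to_numpy(), fam.to_numpy()]).sum()
    sums.index.names = ["taxon", "family"]

    def _median(col: pd.Series) -> pd.Series:
        def per_taxon(g: pd.Series) -> float:
            vals = g.to_numpy()
            if not include_zero_families:
                vals = vals[vals > 0]
                if len(vals) == 0:
                    return 0.0
            else:
                # pad with zeros for families absent from the catalog sums
                n_pad = len(SCG_FAMILIES) - len(vals)
                if n_pad > 0:
                    vals = np.concatenate([vals, np.zeros(n_pad)])
            return float(np.median(vals))

        return col.groupby(level="taxon").apply(per_taxon)

    abundance = sums.apply(_median, axis=0)
    abundance = abundance.loc[abundance.sum(axis=1) > 0]
    abundance.index.name = "taxon"

    family_totals = cov.groupby(fam.to_numpy()).sum()
    family_totals = family_totals.reindex(SCG_FAMILIES, fill_value=0.0)
    family_totals.index.name = "family"

    return TaxonProfile(
        abundance=abundance,
        family_totals=family_totals,
        rank=rank,
        normalized=False,
    )


def normalize_profile(profile: TaxonProfile) -> TaxonProfile:
    """Relative taxon profile: divide by the per-sample median total SCG
    coverage N_s (median over the 36 families of summed coverage).

    Samples with N_s = 0 are flagged and excluded from the relative output.
    """
    if profile.normalized:
        raise ValueError("profile is already normalized")
    normalizers = profile.family_totals.median(axis=0)
    excluded = normalizers.index[normalizers == 0].tolist()
    keep = [s for s in profile.abundance.columns if s not in excluded]
    relative = profile.abundance[keep].div(normalizers[keep], axis=1)
    return TaxonProfile(
        abundance=relative,
        family_totals=profile.family_totals,
        rank=profile.rank,
        normalized=True,
        normalizers=normalizers,
        excluded_samples=excluded,
    )


def profile_metagenome(
    coverage: pd.DataFrame,
    catalog: pd.DataFrame,
    rank: str = "species",
    include_zero_families: bool = False,
) -> TaxonProfile:
    """Convenience: unnormalized profile followed by median-normalization."""
    return normalize_profile(
        scg_taxon_profile(
            coverage, catalog, rank=rank, include_zero_families=include_zero_families
        )
    )
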