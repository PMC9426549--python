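"""Marker-gene (alkaline phosphatase) classification and abundance.

Functional marker ORFs — here the PhoX/PhoD/PhoA alkaline phosphatase
families used to assay organic-phosphorus mineralization potential — are
classified from a per-family score table (emulating profile-HMM search
bit scores) by family-specific thresholds, assigned taxonomy by their best
reference hit at a stringent e-value cutoff, and quantified as read
coverage normalized by the per-sample single-copy core-gene normalizer
N_s, which corrects for sequencing-depth differences between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class MarkerClassification:
    """Per-ORF family assignments plus the count left unclassified."""

    assignments: pd.DataFrame  # orf_id -> family, score
    n_unclassified: int = 0


def classify_markers(
    score_table: pd.DataFrame,
    family_thresholds: Mapping[str, float],
) -> MarkerClassification:
    """Assign each ORF to a marker family by score thresholds.

    ``score_table`` is long format with columns ``orf_id, family, score``
    (one row per ORF x family).  An ORF is assigned to the family with the
    maximal score among families whose threshold it strictly exceeds; with
    no qualifying family it is ``unclassified``; exact score ties go to the
    lexicographically smallest family name.
    """
    required = {"orf_id", "family", "score"}
    if not required.issubset(score_table.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    scored_families = set(score_table["family"])
    missing = scored_families - set(family_thresholds)
    if missing:
        raise ValueError(f"no threshold for scored family(s): {sorted(missing)}")

    rows = []
    n_unclassified = 0
    for orf_id, sub in score_table.groupby("orf_id", sort=True):
        qualifying = sub[
            sub["score"] > sub["family"].map(family_thresholds)
        ]
        if qualifying.empty:
            n_unclassified += 1
            rows.append({"orf_id": orf_id, "family": "unclassified",
                         "score": float("nan")})
            continue
        best = qualifying.sort_values(
            ["score", "family"], ascending=[False, True], kind="stable"
        ).iloc[0]
        rows.append(
            {"orf_id": orf_id, "family": best["family"], "score": float(best["score"])}
        )
    assignments = pd.DataFrame(rows).set_index("orf_id")
    return MarkerClassification(assignments=assignments,
                                n_unclassified=n_unclassified)


@dataclass
class MarkerTaxonomy:
    """Best-hit taxonomic assignments and the tally of removed ORFs."""

    assignments: pd.DataFrame  # orf_id -> ref_taxon, lineage, evalue
    n_removed: int = 0


def assign_marker_taxonomy(
    hits: pd.DataFrame,
    evalue_cutoff: float = 1e-20,
) -> MarkerTaxonomy:
    """Best-hit taxonomy at an e-value cutoff.

    ``hits`` has columns ``orf_id, ref_taxon, evalue`` (optionally
    ``lineage``).  The best (lowest e-value) hit assigns taxonomy when its
    e-value is at or below the cutoff; ORFs with no qualifying hit are
    removed and counted, mirroring the removal of sequences that align to
    no curated reference.
    """
    required = {"orf_id", "ref_taxon", "evalue"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hits table needs columns {sorted(required)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("e-values must be non-negative")

    rows = []
    n_removed = 0
    for orf_id, sub in hits.groupby("orf_id", sort=True):
        sub = sub.sort_values(["evalue", "ref_taxon"], kind="stable")
        best = sub.iloc[0]
        if best["evalue"] <= evalue_cutoff:
            row = {"orf_id": orf_id, "ref_taxon": best["ref_taxon"],
                   "evalue": float(best["evalue"])}
            if "lineage" in sub.columns:
                row["lineage"] = best["lineage"]
            rows.append(row)
        else:
            n_removed += 1
    assignments = (
        pd.DataFrame(rows).set_index("orf_id") if rows else
        pd.DataFrame(columns=["ref_taxon", "evalue"]).rename_axis("orf_id")
    )
    return MarkerTaxonomy(assignments=assignments, n_removed=n_removed)


def marker_relative_abundance(
    marker_coverage: pd.DataFrame,
    assignments: pd.DataFrame,
    taxonomy: pd.DataFrame,
    scg_normalizers: pd.Series,
) -> pd.DataFrame:
    """SCG-normalized marker abundance per (family, taxon, sample).

    ``marker_coverage`` is ORF x sample read coverage; ``assignments`` maps
    ORF -> family (classified ORFs only); ``taxonomy`` maps ORF ->
    ref_taxon.  Coverage is summed per (family, taxon) and divided by the
    per-sample SCG normalizer N_s, making values comparable across samples
    of different sequencing depth.
    """
    missing = [s for s in marker_coverage.columns if s not in scg_normalizers.index]
    if missing:
        raise ValueError(f"sample(s) missing an SCG normalizer: {missing}")
    if (scg_normalizers.reindex(marker_coverage.columns) <= 0).any():
        raise ValueError("SCG normalizers must be positive")

    keep = (
        assignments.index.intersection(taxonomy.index)
        .intersection(marker_coverage.index)
    )
    fam = assignments.loc[keep, "family"]
    keep = keep[fam.reindex(keep) != "unclassified"]

    cov = marker_coverage.loc[keep].astype(float)
    keys = pd.DataFrame(
        {
            "family": assignments.loc[keep, "family"],
            "taxon": taxonomy.loc[keep, "ref_taxon"],
        }
    )
    sums = cov.groupby([keys["family"], keys["taxon"]]).sum()
    normalized = sums.div(scg_normalizers.reindex(cov.columns), axis=1)
    normalized.index.names = ["family", "taxon"]
    return normalized
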