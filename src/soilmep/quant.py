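"""Protein quantification: NSAF spectral counting, normalized label-free
intensities, condition Z-score profiles and taxonomic/functional rollups.

NSAF (normalized spectral abundance factor) divides each protein's spectral
count by its length and renormalizes per sample, so every sample column
sums to 1 and proteins of different size are comparable.  The label-free
intensity route log2-transforms nonzero intensities and median-centers each
sample to the global median; zeros stay missing (no imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("NSAF", "percent", "normalized-LFQ")


@dataclass
class AbundanceMatrix:
    """Protein/group-by-sample abundance values with a mode tag."""

    values: pd.DataFrame  # protein x sample
    mode: str
    lengths: pd.Series | None = None
    annotations: pd.DataFrame | None = None  # per-protein taxon/function
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown abundance mode {self.mode!r}")

    def to_percent(self) -> "AbundanceMatrix":
        if self.mode != "NSAF":
            raise ValueError("percent abundance is defined from NSAF values")
        return AbundanceMatrix(
            values=self.values * 100.0,
            mode="percent",
            lengths=self.lengths,
            annotations=self.annotations,
            meta=dict(self.meta),
        )


def nsaf(spectral_counts: pd.DataFrame, lengths: pd.Series) -> AbundanceMatrix:
    """NSAF_{i,s} = (SpC_{i,s}/L_i) / sum_j (SpC_{j,s}/L_j).

    ``spectral_counts`` is protein x sample; ``lengths`` gives each
    protein's residue count.  Samples with no nonzero count are rejected by
    name, since their NSAF column would be undefined.
    """
    counts = spectral_counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("spectral counts must be non-negative")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for proteins: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive")
    zero_cols = counts.columns[(counts.sum(axis=0) == 0)].tolist()
    if zero_cols:
        raise ValueError(f"sample(s) with all-zero counts: {zero_cols}")
    saf = counts.div(lengths, axis=0)
    values = saf.div(saf.sum(axis=0), axis=1)
    return AbundanceMatrix(values=values, mode="NSAF", lengths=lengths)


def lfq_normalize(intensities: pd.DataFrame) -> AbundanceMatrix:
    """Median-centered log2 intensities; zeros are treated as missing.

    Each sample's nonzero log2 intensities are shifted so its median equals
    the global median of the uncentered values.  This removes per-sample
    loading differences while leaving relative protein patterns intact; no
    missing-value imputation is performed.
    """
    vals = intensities.astype(float)
    if (vals.values < 0).any():
        raise ValueError("intensities must be non-negative")
    log_vals = np.log2(vals.where(vals > 0))
    empty = log_vals.columns[log_vals.notna().sum(axis=0) == 0].tolist()
    if empty:
        raise ValueError(f"sample(s) with no nonzero intensities: {empty}")
    global_median = float(np.nanmedian(log_vals.values))
    sample_medians = log_vals.median(axis=0)
    centered = log_vals.sub(sample_medians - global_median, axis=1)
    return AbundanceMatrix(
        values=centered,
        mode="normalized-LFQ",
        meta={"normalization": "log2 median centering", "log_base": 2},
    )


def zscore_profiles(
    percent_matrix: pd.DataFrame, condition_labels: pd.Series
) -> pd.DataFrame:
    """Per-protein Z-scores across condition means.

    Replicate samples are averaged per condition first; each protein row is
    then standardized ((x - mean) / sd, sample sd) across conditions.  Rows
    with zero variance come back as all zeros.
    """
    labels = pd.Series(condition_labels)
    missing = [s for s in percent_matrix.columns if s not in labels.index]
    if missing:
        raise ValueError(f"no condition label for sample(s): {missing}")
    cond_means = percent_matrix.T.groupby(labels.reindex(percent_matrix.columns)).mean().T
    if cond_means.shape[1] < 2:
        raise ValueError("need at least 2 conditions for Z-score profiles")
    mu = cond_means.mean(axis=1)
    sd = cond_means.std(axis=1, ddof=1)
    z = cond_means.sub(mu, axis=0).div(sd, axis=0)
    z[sd == 0] = 0.0
    return z.fillna(0.0)


def rollup(
    abundance: pd.DataFrame,
    annotations: pd.Series,
    mode: str = "abundance",
) -> pd.DataFrame:
    """Aggregate a protein-by-sample matrix into categories.

    ``annotations`` maps protein id -> category (taxon or function).
    ``mode="count"`` reports the number of distinct proteins per category
    (per sample: proteins with an observed, nonzero value); ``"abundance"``
    sums values.  Unannotated proteins are routed to an "unannotated"
    category with a logged warning.
    """
    if mode not in ("count", "abundance"):
        raise ValueError("mode must be 'count' or 'abundance'")
    cats = annotations.reindex(abundance.index)
    n_missing = int(cats.isna().sum())
    if n_missing:
        logger.warning("%d proteins missing annotation; routed to 'unannotated'",
                       n_missing)
        cats = cats.fillna("unannotated")
    if mode == "abundance":
        return abundance.groupby(cats).sum()
    observed = abundance.notna() & (abundance.fillna(0) != 0)
    return observed.groupby(cats).sum().astype(int)
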