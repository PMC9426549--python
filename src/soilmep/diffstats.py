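"""Compartment enrichment tests and community dissimilarity statistics.

Per-protein enrichment between bulk and rhizosphere uses a Welch two-sample
t-test on log-scale abundances with Benjamini-Hochberg FDR control, and
labels a protein rhizosphere-enriched when q < alpha and its linear fold
change exceeds the rhizosphere threshold (default 2), or bulk-enriched when
q < alpha and the inverse fold change exceeds the bulk threshold (default
1.5) — the asymmetric rule used for compartment comparisons of soil
metaproteomes.

Community-level structure is assessed on Bray-Curtis dissimilarities with
one-way ANOSIM (rank-based R statistic) and PERMANOVA (pseudo-F and R^2 =
SS_between / SS_total on squared dissimilarities).  Permutation p-values
use the (1 + exceedances) / (1 + permutations) convention and a caller
seed; for small designs an exact p over all distinct label arrangements is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Differential enrichment
# ---------------------------------------------------------------------------


def differential_enrichment(
    abundance: pd.DataFrame,
    compartment_labels: pd.Series,
    fc_threshold_rhizo: float = 2.0,
    fc_threshold_bulk: float = 1.5,
    alpha: float = 0.05,
    min_obs: int = 2,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-protein Welch test between rhizosphere and bulk samples.

    ``abundance`` is protein x sample.  With ``log_scale=True`` the values
    are already logarithmic (normalized-LFQ); otherwise positive linear
    values (e.g. NSAF) are log2-transformed with zeros treated as missing.
    Proteins with fewer than ``min_obs`` observed values in either group
    are excluded from testing and labelled ``not_tested``.

    Returns a DataFrame with fold_change (linear, rhizosphere/bulk),
    t_stat, p_value, q_value (BH) and enriched_in (bulk | rhizosphere |
    none | not_tested).
    """
    labels = pd.Series(compartment_labels).reindex(abundance.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a compartment label")
    present = set(labels)
    if not {"bulk", "rhizosphere"} <= present:
        raise ValueError("need both bulk and rhizosphere samples")

    values = abundance.astype(float)
    if not log_scale:
        values = np.log2(values.where(values > 0))

    rh = values.loc[:, labels == "rhizosphere"].to_numpy()
    bk = values.loc[:, labels == "bulk"].to_numpy()
    n_rh = np.sum(~np.isnan(rh), axis=1)
    n_bk = np.sum(~np.isnan(bk), axis=1)
    testable = (n_rh >= min_obs) & (n_bk >= min_obs)

    with np.errstate(invalid="ignore"):
        mean_rh = np.where(n_rh > 0, np.nansum(rh, axis=1) / np.maximum(n_rh, 1),
                           np.nan)
        mean_bk = np.where(n_bk > 0, np.nansum(bk, axis=1) / np.maximum(n_bk, 1),
                           np.nan)
    log2_fc = mean_rh - mean_bk
    fold_change = np.power(2.0, log2_fc)

    t_stat = np.full(len(values), np.nan)
    p_value = np.full(len(values), np.nan)
    if testable.any():
        res = sps.ttest_ind(
            rh[testable], bk[testable], axis=1, equal_var=False, nan_policy="omit"
        )
        t_stat[testable] = res.statistic
        p_value[testable] = res.pvalue
    # constant identical rows give nan p-values; they are plainly null
    degenerate = testable & np.isnan(p_value)
    p_value[degenerate] = 1.0
    t_stat[degenerate] = 0.0

    q_value = np.full(len(values), np.nan)
    if testable.any():
        q_value[testable] = multipletests(p_value[testable], method="fdr_bh")[1]

    enriched_in = np.full(len(values), "none", dtype=object)
    enriched_in[~testable] = "not_tested"
    sig = testable & (q_value < alpha)
    enriched_in[sig & (fold_change > fc_threshold_rhizo)] = "rhizosphere"
    with np.errstate(divide="ignore"):
        inv_fc = np.where(fold_change > 0, 1.0 / fold_change, np.inf)
    enriched_in[sig & (inv_fc > fc_threshold_bulk)] = "bulk"

    return pd.DataFrame(
        {
            "fold_change": fold_change,
            "log2_fold_change": log2_fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "n_obs_rhizosphere": n_rh,
            "n_obs_bulk": n_bk,
            "enriched_in": enriched_in,
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(abundance_by_sample: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns.

    d_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk) on non-negative
    feature-by-sample values; missing values are treated as absent (0).
    """
    mat = abundance_by_sample.fillna(0.0).astype(float)
    if (mat.values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    totals = mat.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total abundance: {zero}")
    d = squareform(pdist(mat.T.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _check_groups(labels: np.ndarray, min_size: int = 2) -> list[np.ndarray]:
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < min_size).any():
        small = values[counts < min_size].tolist()
        raise ValueError(f"group(s) with fewer than {min_size} samples: {small}")
    return [np.nonzero(labels == v)[0] for v in values]


def _n_distinct_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = factorial(len(labels))
    for c in counts:
        total //= factorial(int(c))
    return total


def _iter_label_permutations(labels: np.ndarray):
    """All distinct arrangements of the label multiset (identity included).

    Enumerated directly by choosing index sets for each label value, so the
    cost is the multinomial coefficient rather than n!.
    """
    values, counts = np.unique(labels, return_counts=True)
    n = len(labels)

    def assign(free: tuple[int, ...], level: int, out: np.ndarray):
        if level == len(values) - 1:
            out[list(free)] = values[level]
            yield out.copy()
            return
        for chosen in _combinations(free, int(counts[level])):
            out[list(chosen)] = values[level]
            remaining = tuple(i for i in free if i not in set(chosen))
            yield from assign(remaining, level + 1, out)

    template = np.empty(n, dtype=labels.dtype)
    yield from assign(tuple(range(n)), 0, template)


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    method: str


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    method: str


def _anosim_R(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    ranks = rank_matrix[iu]
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return (r_b - r_w) / (n * (n - 1) / 4.0)


def anosim(
    distances: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "auto",
    exact_limit: int = 5000,
) -> AnosimResult:
    """One-way ANOSIM on a symmetric dissimilarity matrix.

    All n(n-1)/2 dissimilarities are ranked with average ranks for ties;
    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).
    ``method`` is "permutation", "exact" (enumerate all distinct label
    arrangements) or "auto" (exact when the arrangement count is at most
    ``exact_limit``).
    """
    d, lab = _align_distance_labels(distances, labels)
    _check_groups(lab)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros_like(d)
    ranks[iu] = sps.rankdata(d[iu], method="average")
    ranks = ranks + ranks.T

    observed = _anosim_R(ranks, lab)
    p, n_used, used_method = _permutation_pvalue(
        lambda perm_labels: _anosim_R(ranks, perm_labels),
        lab,
        observed,
        n_perm=n_perm,
        seed=seed,
        method=method,
        exact_limit=exact_limit,
    )
    return AnosimResult(R=float(observed), p_value=p, n_permutations=n_used,
                        method=used_method)


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_t = d2[iu].sum() / n
    ss_w = 0.0
    values = np.unique(labels)
    for v in values:
        idx = np.nonzero(labels == v)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    a = len(values)
    if ss_w == 0:
        return float("inf"), (ss_a / ss_t if ss_t > 0 else 0.0)
    f = (ss_a / (a - 1)) / (ss_w / (n - a))
    r2 = ss_a / ss_t if ss_t > 0 else 0.0
    return f, r2


def permanova(
    distances: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "auto",
    exact_limit: int = 5000,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) on a symmetric dissimilarity matrix.

    SS_T = (1/N) sum_{i<j} d_ij^2; SS_W sums within-group squared
    dissimilarities scaled by group size; pseudo-F = (SS_A/(a-1)) /
    (SS_W/(N-a)) and R^2 = SS_A/SS_T.  When SS_W = 0 the pseudo-F is
    reported as +inf and the permutation p is still computed.
    """
    d, lab = _align_distance_labels(distances, labels)
    _check_groups(lab)
    d2 = d**2

    observed_f, observed_r2 = _permanova_stats(d2, lab)

    def stat(perm_labels: np.ndarray) -> float:
        return _permanova_stats(d2, perm_labels)[0]

    p, n_used, used_method = _permutation_pvalue(
        stat, lab, observed_f, n_perm=n_perm, seed=seed, method=method,
        exact_limit=exact_limit,
    )
    return PermanovaResult(
        pseudo_F=float(observed_f),
        R2=float(observed_r2),
        p_value=p,
        n_permutations=n_used,
        method=used_method,
    )


def _align_distance_labels(
    distances: pd.DataFrame, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    lab = pd.Series(labels).reindex(distances.index)
    if lab.isna().any():
        raise ValueError("every sample in the distance matrix needs a label")
    return d, lab.to_numpy()


def _permutation_pvalue(
    stat_fn,
    labels: np.ndarray,
    observed: float,
    n_perm: int,
    seed: int | None,
    method: str,
    exact_limit: int,
) -> tuple[float, int, str]:
    """Shared permutation scaffold.

    Sampled: p = (1 + #{permuted stat >= observed}) / (1 + n_perm).
    Exact: proportion of all distinct label arrangements (identity
    included) with stat >= observed.  Infinite statistics compare as equal
    when both are infinite.
    """
    if method == "auto":
        method = (
            "exact" if _n_distinct_arrangements(labels) <= exact_limit
            else "permutation"
        )
    tol = 1e-12

    def geq(x: float) -> bool:
        if np.isinf(observed):
            return np.isinf(x)
        return x >= observed - tol

    if method == "exact":
        count = 0
        total = 0
        for arrangement in _iter_label_permutations(labels):
            total += 1
            if geq(stat_fn(arrangement)):
                count += 1
        return count / total, total, "exact"
    if method != "permutation":
        raise ValueError(f"unknown permutation method {method!r}")
    rng = np.random.Generator(np.random.PCG64(seed))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if geq(stat_fn(perm)):
            count += 1
    return (1 + count) / (1 + n_perm), n_perm, "permutation"
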