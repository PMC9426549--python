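"""Protein inference from peptide-spectrum matches.

The identification workflow mirrors common metaproteomic practice:

1. peptide-level target-decoy q-values over PSM scores, filtered at a
   peptide FDR threshold (default 5%);
2. parsimony grouping of proteins by their surviving peptide evidence
   (proteins with identical peptide sets merge; a protein whose peptide set
   is a strict subset of another's is absorbed);
3. protein-group-level target-decoy q-values over best member scores,
   filtered at a protein FDR threshold (default 10%);
4. evidence filters: at least two unique peptides per group, removal of
   groups identified only by modified peptides, removal of contaminants;
5. a deterministic representative per group (most unique peptides, then
   highest aggregate score, then smallest id).

The FDR estimator is D(t)/max(T(t), 1), capped at 1, without the +1
correction (available via ``plus_one=True``); q-values are the running
minimum of the FDR from the worst-scoring threshold upward, so they are
monotone non-increasing in score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Target-decoy q-values
# ---------------------------------------------------------------------------


def target_decoy_qvalues(
    scores: np.ndarray, is_decoy: np.ndarray, plus_one: bool = False
) -> pd.DataFrame:
    """Score-threshold FDR table and q-values for a target-decoy competition.

    At each score threshold t (accept everything scoring >= t),
    FDR(t) = D(t) / max(T(t), 1), capped at 1, with an optional +1 decoy
    correction.  q(s) is the minimum FDR over thresholds at or below s; ties
    in score share a q-value.

    Returns a DataFrame aligned to the input order with columns
    ``score, cum_targets, cum_decoys, fdr, q_value``.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != is_decoy.shape or scores.ndim != 1:
        raise ValueError("scores and is_decoy must be 1-D and equal length")
    if len(scores) == 0:
        raise ValueError("empty score list")
    if is_decoy.all():
        raise ValueError("all PSMs are decoys; need at least one target")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_decoy = is_decoy[order]
    cum_t = np.cumsum(~sorted_decoy)
    cum_d = np.cumsum(sorted_decoy)

    # ties share the threshold at the tie's worst rank
    n = len(scores)
    last_of_tie = np.ones(n, dtype=bool)
    last_of_tie[:-1] = sorted_scores[:-1] != sorted_scores[1:]
    tie_last_idx = np.empty(n, dtype=int)
    last_positions = np.nonzero(last_of_tie)[0]
    start = 0
    for pos in last_positions:
        tie_last_idx[start : pos + 1] = pos
        start = pos + 1

    eff_t = cum_t[tie_last_idx]
    eff_d = cum_d[tie_last_idx]
    numer = eff_d + (1 if plus_one else 0)
    fdr = np.minimum(numer / np.maximum(eff_t, 1), 1.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]

    out = pd.DataFrame(
        {
            "score": sorted_scores,
            "cum_targets": eff_t,
            "cum_decoys": eff_d,
            "fdr": fdr,
            "q_value": q,
        }
    )
    # restore the caller's row order
    inverse = np.empty(n, dtype=int)
    inverse[order] = np.arange(n)
    return out.iloc[inverse].reset_index(drop=True)


def peptide_qvalues(psms: pd.DataFrame, plus_one: bool = False) -> pd.DataFrame:
    """Attach target-decoy q-values to a PSM table (columns score, is_decoy)."""
    table = target_decoy_qvalues(
        psms["score"].to_numpy(), psms["is_decoy"].to_numpy(), plus_one=plus_one
    )
    out = psms.reset_index(drop=True).copy()
    out["fdr"] = table["fdr"].to_numpy()
    out["q_value"] = table["q_value"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Parsimony grouping
# ---------------------------------------------------------------------------


@dataclass
class ProteinGroup:
    """Proteins indistinguishable (or subsumed) by their peptide evidence."""

    members: list[str]
    peptides: frozenset[str]
    unique_peptides: int = 0
    best_score: float = float("nan")
    aggregate_score: float = float("nan")
    q_value: float = float("nan")
    representative: str | None = None
    is_decoy: bool = False
    is_contaminant: bool = False
    modified_only: bool = False


def group_proteins(
    peptide_to_protein_map: Mapping[str, Iterable[str]],
) -> list[ProteinGroup]:
    """Group proteins by shared peptide evidence (parsimony).

    Rules, applied exhaustively:

    * proteins with identical peptide sets merge into one group;
    * a protein whose peptide set is a strict subset of another protein's
      set is absorbed into that protein's group.  When several incomparable
      supersets exist, the absorbing group is chosen deterministically: the
      one with the largest peptide set, ties broken by the lexicographically
      smallest sorted peptide tuple.

    Peptides mapping to proteins of more than one group are shared and do
    not count as unique for any group.  Returns groups sorted by their
    smallest member id.
    """
    protein_sets: dict[str, frozenset[str]] = {}
    for pep, prots in peptide_to_protein_map.items():
        prots = list(prots)
        if not prots:
            raise ValueError(f"peptide {pep!r} maps to no protein")
        for p in prots:
            protein_sets.setdefault(p, set())  # type: ignore[arg-type]
    for pep, prots in peptide_to_protein_map.items():
        for p in prots:
            protein_sets[p] = protein_sets[p] | {pep}  # type: ignore[operator]
    protein_sets = {p: frozenset(s) for p, s in protein_sets.items()}
    if not protein_sets:
        return []

    distinct = sorted(set(protein_sets.values()), key=lambda s: tuple(sorted(s)))
    maximal = [
        s
        for s in distinct
        if not any(s < other for other in distinct)
    ]

    # deterministic choice: largest superset, then lexicographically smallest
    def choose(supersets: list[frozenset[str]]) -> frozenset[str]:
        return sorted(supersets, key=lambda m: (-len(m), tuple(sorted(m))))[0]

    grouped: dict[frozenset[str], list[str]] = {m: [] for m in maximal}
    for protein, s in protein_sets.items():
        supersets = [m for m in maximal if s <= m]
        grouped[choose(supersets)].append(protein)

    # peptide -> set of groups it touches, to mark shared peptides
    group_of_protein = {}
    groups = []
    for idx, (pepset, members) in enumerate(
        sorted(grouped.items(), key=lambda kv: sorted(kv[1])[0])
    ):
        members = sorted(members)
        for m in members:
            group_of_protein[m] = idx
        groups.append(ProteinGroup(members=members, peptides=pepset))

    peptide_groups: dict[str, set[int]] = {}
    for pep, prots in peptide_to_protein_map.items():
        peptide_groups[pep] = {group_of_protein[p] for p in prots}
    for idx, g in enumerate(groups):
        g.unique_peptides = sum(
            1 for pep in g.peptides if peptide_groups[pep] == {idx}
        )
    return groups


# ---------------------------------------------------------------------------
# Group-level FDR and filters
# ---------------------------------------------------------------------------


def protein_group_fdr(
    groups: list[ProteinGroup], plus_one: bool = False
) -> list[ProteinGroup]:
    """Attach target-decoy q-values to groups ranked by best member score."""
    if not groups:
        return groups
    scores = np.array([g.best_score for g in groups])
    decoys = np.array([g.is_decoy for g in groups])
    if decoys.all():
        raise ValueError("all protein groups are decoys")
    table = target_decoy_qvalues(scores, decoys, plus_one=plus_one)
    for g, q in zip(groups, table["q_value"].to_numpy()):
        g.q_value = float(q)
    return groups


def apply_evidence_filters(
    groups: list[ProteinGroup],
    min_unique: int = 2,
    drop_modified_only: bool = True,
    contaminant_ids: Iterable[str] = (),
) -> tuple[list[ProteinGroup], dict[str, int]]:
    """Apply the evidence rules, returning (kept groups, removal tallies).

    A group failing several rules is tallied once, under the first rule in
    the order contaminant -> modified-only -> too few unique peptides, so
    the tallies sum to the number of removed groups.
    """
    contaminants = set(contaminant_ids)
    kept: list[ProteinGroup] = []
    audit = {"contaminant": 0, "modified_only": 0, "min_unique": 0}
    for g in groups:
        if g.is_contaminant or any(m in contaminants for m in g.members):
            audit["contaminant"] += 1
        elif drop_modified_only and g.modified_only:
            audit["modified_only"] += 1
        elif g.unique_peptides < min_unique:
            audit["min_unique"] += 1
        else:
            kept.append(g)
    return kept, audit


def select_representative(
    group: ProteinGroup,
    unique_counts: Mapping[str, int] | None = None,
    scores: Mapping[str, float] | None = None,
) -> str:
    """Pick the group's representative protein deterministically.

    Order of preference: most unique peptides, then highest aggregate
    score, then lexicographically smallest id.  Per-member unique-peptide
    counts and aggregate scores default to 0 when not supplied (e.g. all
    peptides shared within the group).
    """
    if not group.members:
        raise ValueError("cannot select a representative for an empty group")
    unique_counts = unique_counts or {}
    scores = scores or {}
    return min(
        group.members,
        key=lambda m: (-unique_counts.get(m, 0), -scores.get(m, 0.0), m),
    )


# ---------------------------------------------------------------------------
# End-to-end inference stage
# ---------------------------------------------------------------------------


@dataclass
class ProteinGroupSet:
    """Filtered protein groups plus the audit of what each rule removed."""

    groups: list[ProteinGroup]
    audit: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups):
            rows.append(
                {
                    "group_id": f"G{i:05d}",
                    "representative": g.representative,
                    "members": ";".join(g.members),
                    "n_members": len(g.members),
                    "unique_peptides": g.unique_peptides,
                    "peptides": ";".join(sorted(g.peptides)),
                    "best_score": g.best_score,
                    "q_value": g.q_value,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "group_id",
                "representative",
                "members",
                "n_members",
                "unique_peptides",
                "peptides",
                "best_score",
                "q_value",
            ],
        )


def infer_protein_groups(
    psms: pd.DataFrame,
    pep_fdr: float = 0.05,
    prot_fdr: float = 0.10,
    min_unique: int = 2,
    drop_modified_only: bool = True,
    contaminant_ids: Iterable[str] = (),
    plus_one: bool = False,
) -> ProteinGroupSet:
    """Run the full two-tier inference on a PSM table.

    The PSM table needs columns ``peptide, proteins`` (semicolon-separated
    ids), ``score, is_decoy`` and optionally ``is_modified,
    is_contaminant``.  Decoy groups are used for the protein-level FDR and
    then discarded; the audit records counts removed by every rule.
    """
    scored = peptide_qvalues(psms, plus_one=plus_one)
    accepted = scored[scored["q_value"] <= pep_fdr]
    audit = {"peptide_fdr": int(len(scored) - len(accepted))}
    if accepted.empty:
        return ProteinGroupSet(groups=[], audit=audit)

    pep_map: dict[str, set[str]] = {}
    pep_best: dict[str, float] = {}
    pep_modified: dict[str, bool] = {}
    for row in accepted.itertuples(index=False):
        prots = set(row.proteins.split(";"))
        pep_map.setdefault(row.peptide, set()).update(prots)
        pep_best[row.peptide] = max(pep_best.get(row.peptide, -np.inf), row.score)
        modified = bool(getattr(row, "is_modified", False))
        pep_modified[row.peptide] = pep_modified.get(row.peptide, True) and modified

    groups = group_proteins(pep_map)

    contaminants = set(contaminant_ids)
    if "is_contaminant" in accepted.columns:
        flagged = accepted.loc[accepted["is_contaminant"], "proteins"]
        for entry in flagged:
            contaminants.update(entry.split(";"))

    for g in groups:
        g.is_decoy = all(m.startswith("DECOY_") for m in g.members)
        g.is_contaminant = any(m in contaminants for m in g.members)
        g.modified_only = all(pep_modified.get(p, False) for p in g.peptides)
        g.best_score = max(pep_best[p] for p in g.peptides)
        g.aggregate_score = float(sum(pep_best[p] for p in g.peptides))

    groups = protein_group_fdr(groups, plus_one=plus_one)
    passing = [g for g in groups if g.q_value <= prot_fdr]
    audit["protein_fdr"] = len(groups) - len(passing)
    n_decoy = sum(g.is_decoy for g in passing)
    passing = [g for g in passing if not g.is_decoy]
    audit["decoy_groups"] = n_decoy

    kept, filter_audit = apply_evidence_filters(
        passing,
        min_unique=min_unique,
        drop_modified_only=drop_modified_only,
        contaminant_ids=contaminants,
    )
    audit.update(filter_audit)

    # per-member unique peptide counts and aggregate scores for the
    # representative rule
    protein_peptides: dict[str, set[str]] = {}
    for pep, prots in pep_map.items():
        for p in prots:
            protein_peptides.setdefault(p, set()).add(pep)
    for g in kept:
        uniq = {
            m: sum(1 for pep in protein_peptides[m] if len(pep_map[pep]) == 1)
            for m in g.members
        }
        agg = {
            m: float(sum(pep_best[pep] for pep in protein_peptides[m]))
            for m in g.members
        }
        g.representative = select_representative(g, uniq, agg)

    logger.info(
        "inference kept %d groups (audit: %s)", len(kept), audit
    )
    return ProteinGroupSet(groups=kept, audit=audit)
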