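"""Greedy identity-based clustering of protein sequence catalogs.

Metaproteomic search databases built from assembled metagenomes are highly
redundant: near-identical open reading frames (ORFs) from closely related
strains inflate the database and dilute peptide-spectrum evidence.  The
standard remedy is incremental greedy clustering (CD-HIT style): sort
sequences longest-first, let each sequence join the first existing cluster
representative it matches at or above an identity threshold, otherwise found
a new cluster.  The same primitive, at a higher threshold, is used to
de-replicate single-copy core-gene (SCG) sequences before taxonomic
assignment.

Identity here follows the CD-HIT convention: the number of identical aligned
residues under an optimal global alignment (match +1, mismatch 0, linear gap
-1), divided by the length of the shorter sequence.  A short-sequence
coverage rule (aligned fraction of the shorter sequence) guards against
spurious matches of small fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SequenceRecord:
    """A single amino-acid sequence with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class ClusterAssignment:
    """One cluster: a representative plus its members.

    The representative is always its own member with identity 1.0; member
    ids across all clusters partition the input catalog.
    """

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identity_to_rep: dict[str, float] = field(default_factory=dict)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _align_stats(a: str, b: str) -> tuple[int, int]:
    """Return (identities, aligned residue pairs) for an optimal global
    alignment of ``a`` and ``b``.

    Sequences are passed to the aligner in lexicographic order so the result
    is symmetric by construction (co-optimal alignments can differ in match
    count; fixing the argument order fixes the traceback).
    """
    if b < a:
        a, b = b, a
    counts = _ALIGNER.align(a, b)[0].counts()
    return counts.identities, counts.aligned


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical residues over the shorter sequence length.

    Uses an optimal global alignment with match +1, mismatch 0 and linear
    gap penalty -1.  Symmetric, and 1.0 for identical sequences.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot compute identity of an empty sequence")
    identities, _ = _align_stats(a.residues, b.residues)
    return identities / min(a.length, b.length)


def _residue_counts(residues: str) -> np.ndarray:
    counts = np.zeros(len(AMINO_ACIDS), dtype=np.int64)
    for ch in residues:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    return counts


def greedy_cluster(
    records: Iterable[SequenceRecord],
    identity_threshold: float,
    min_short_coverage: float = 0.80,
) -> list[ClusterAssignment]:
    """Cluster sequences by greedy longest-first, first-fit assignment.

    Records are sorted by length descending (ties broken by id) so the
    result is independent of input order.  Each record joins the earliest
    founded cluster whose representative it matches with identity >=
    ``identity_threshold`` and aligned fraction of the shorter sequence >=
    ``min_short_coverage``; otherwise it founds a new cluster.

    A shared-residue multiset bound (matches cannot exceed the number of
    residues the two sequences share, counted with multiplicity) is used to
    skip alignments that provably cannot reach the threshold; exact
    duplicates short-circuit to the cluster of their first occurrence.
    Neither shortcut changes the resulting partition.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if not 0 < min_short_coverage <= 1:
        raise ValueError("min_short_coverage must be in (0, 1]")

    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    seen_ids = set()
    for rec in ordered:
        if rec.id in seen_ids:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen_ids.add(rec.id)

    clusters: list[ClusterAssignment] = []
    rep_records: list[SequenceRecord] = []
    rep_counts: list[np.ndarray] = []
    rep_lengths: list[int] = []
    by_residues: dict[str, int] = {}

    for rec in ordered:
        dup_idx = by_residues.get(rec.residues)
        if dup_idx is not None:
            cl = clusters[dup_idx]
            rep = rep_records[dup_idx]
            ident = 1.0 if rec.residues == rep.residues else pairwise_identity(rec, rep)
            cl.member_ids.append(rec.id)
            cl.identity_to_rep[rec.id] = ident
            continue

        assigned = False
        if rep_records:
            counts = _residue_counts(rec.residues)
            count_mat = np.stack(rep_counts)
            shared = np.minimum(count_mat, counts[None, :]).sum(axis=1)
            min_len = np.minimum(np.asarray(rep_lengths), rec.length)
            bound = shared / min_len
            candidates = np.nonzero(bound >= identity_threshold - 1e-12)[0]
            for idx in candidates:
                rep = rep_records[idx]
                identities, aligned = _align_stats(rec.residues, rep.residues)
                short_len = min(rec.length, rep.length)
                identity = identities / short_len
                coverage = aligned / short_len
                if identity >= identity_threshold and coverage >= min_short_coverage:
                    cl = clusters[idx]
                    cl.member_ids.append(rec.id)
                    cl.identity_to_rep[rec.id] = identity
                    assigned = True
                    break
        if not assigned:
            clusters.append(
                ClusterAssignment(
                    representative_id=rec.id,
                    member_ids=[rec.id],
                    identity_to_rep={rec.id: 1.0},
                )
            )
            rep_records.append(rec)
            rep_counts.append(_residue_counts(rec.residues))
            rep_lengths.append(rec.length)
            by_residues[rec.residues] = len(clusters) - 1

    return clusters


def cluster_members(clusters: Sequence[ClusterAssignment]) -> dict[str, str]:
    """Flatten cluster assignments into a member id -> representative id map."""
    mapping: dict[str, str] = {}
    for cl in clusters:
        for member in cl.member_ids:
            mapping[member] = cl.representative_id
    return mapping
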