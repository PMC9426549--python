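"""File formats and run configuration.

All tabular data is tab-separated text with an optional block of
``# key: value`` header comments carrying provenance (config hash, seed).
Sequence catalogs are FASTA.  Schemas for the pipeline's tables are
declared here and validated on read, so a missing or mistyped column fails
early with the offending name and row.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcluster import SequenceRecord

__version__ = "0.1.0"


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# required column -> dtype kind ("str", "float", "int", "bool")
SCHEMAS: dict[str, dict[str, str]] = {
    "psm": {
        "spectrum_id": "str",
        "peptide": "str",
        "proteins": "str",
        "score": "float",
        "is_decoy": "bool",
        "is_modified": "bool",
        "is_contaminant": "bool",
        "sample": "str",
        "spectral_count": "int",
        "intensity": "float",
    },
    "coverage": {"orf_id": "str"},  # remaining columns: per-sample floats
    "lineages": {"taxon": "str", "domain": "str", "phylum": "str", "class": "str",
                 "order": "str", "family": "str", "genus": "str", "species": "str"},
    "catalog": {"orf_id": "str", "family": "str", "cluster_id": "str",
                "lineage": "str"},
    "scores": {"orf_id": "str", "family": "str", "score": "float"},
    "hits": {"orf_id": "str", "ref_taxon": "str", "evalue": "float"},
    "meta": {"sample": "str", "compartment": "str"},
    "groups": {"group_id": "str", "representative": "str", "members": "str",
               "unique_peptides": "int", "q_value": "float"},
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "True": True, "False": False}


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an amino-acid FASTA file into SequenceRecords.

    Wrapped lines are joined, residues upper-cased; duplicate ids and empty
    records are rejected with their position in the file.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} (record {i})")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} (record {i})")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=seq))
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.residues), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV with header-comment metadata against a declared schema.

    Required columns are validated by name and coerced to their declared
    dtype; a non-numeric value in a numeric column is rejected with its row
    number.  Unknown columns are preserved untouched.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    spec = SCHEMAS[schema]
    for col in spec:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col, kind in spec.items():
        if kind == "str":
            continue
        if kind == "bool":
            bad = ~df[col].isin(_BOOL_MAP)
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based, plus header line
                raise SchemaError(
                    f"{path}: non-boolean value {df[col][bad.idxmax()]!r} in "
                    f"column {col!r} at line {row}"
                )
            df[col] = df[col].map(_BOOL_MAP)
        else:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2
                raise SchemaError(
                    f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                    f"column {col!r} at line {row}"
                )
            df[col] = converted.astype(int if kind == "int" else float)
    if schema == "coverage":
        for col in df.columns:
            if col != "orf_id":
                converted = pd.to_numeric(df[col], errors="coerce")
                bad = converted.isna() & df[col].notna()
                if bad.any():
                    row = int(bad.idxmax()) + 2
                    raise SchemaError(
                        f"{path}: non-numeric coverage value in column {col!r} "
                        f"at line {row}"
                    )
                df[col] = converted.astype(float)
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None,
    index: bool = False,
) -> None:
    """Write a TSV with ``# key: value`` provenance header comments."""
    buf = _io.StringIO()
    for key, value in (meta or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=index, float_format="%.10g")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    One top-level seed drives every stochastic stage through deterministic
    per-stage derivation, so a run is reproducible from this object alone.
    """

    seed: int = 17
    out_dir: str = "run_out"
    # scenario
    n_taxa: int = 8
    n_samples: int = 6  # per compartment
    depth: float = 100.0
    # bundled scenario: one rhizosphere-specialist taxon responds with a
    # 4-fold activity increase, without any composition change
    enrichment_factor: float = 4.0
    n_enriched_taxa: int = 1
    enrichment_mode: str = "activity"
    orfs_per_megabase: float = 15.0
    # clustering
    db_identity: float = 0.90
    scg_identity: float = 0.95
    min_short_coverage: float = 0.80
    # inference
    pep_fdr: float = 0.05
    prot_fdr: float = 0.10
    min_unique: int = 2
    # proteome simulation: a minority of proteins is upregulated, so the
    # majority-unchanged assumption of median LFQ normalization holds
    frac_enriched_proteins: float = 0.15
    protein_fold_change: float = 4.0
    ms_depth: float = 20000.0
    # enrichment thresholds
    fc_rhizo: float = 2.0
    fc_bulk: float = 1.5
    alpha: float = 0.05
    # community statistics
    n_permutations: int = 999
    rank: str = "species"

    def validate(self) -> None:
        if not 0 < self.db_identity <= 1:
            raise ValueError("db_identity must be in (0, 1]")
        if not 0 < self.scg_identity <= 1:
            raise ValueError("scg_identity must be in (0, 1]")
        if not 0 < self.min_short_coverage <= 1:
            raise ValueError("min_short_coverage must be in (0, 1]")
        if not 0 < self.pep_fdr < 1 or not 0 < self.prot_fdr < 1:
            raise ValueError("FDR thresholds must be in (0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_taxa < 2 or self.n_samples < 2:
            raise ValueError("need >= 2 taxa and >= 2 samples per compartment")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.enrichment_mode not in ("abundance", "activity"):
            raise ValueError("enrichment_mode must be 'abundance' or 'activity'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]

    def provenance(self) -> dict:
        return {
            "tool": f"soilmep {__version__}",
            "config_hash": self.config_hash(),
            "seed": self.seed,
        }
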