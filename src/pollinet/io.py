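"""Readers and writers for the pipeline's on-disk formats.

Formats: FASTA (reads and references, via biopython), 12-column tab-separated
alignment hit tables (the classic BLAST ``outfmt 6`` layout), and CSV for
taxonomy, insect metadata, site plant lists, curation maps and labelled
matrices.  CSV quoting follows RFC 4180 (pandas defaults).

The hit-table dialect is fixed at exactly 12 columns; rows with more or fewer
fields fail loudly with their line number, because silent column drift is the
classic failure mode of tabular alignment output.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ReferenceDB

logger = logging.getLogger(__name__)

__all__ = [
    "HIT_TABLE_COLUMNS",
    "IUPAC_NUCLEOTIDES",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "read_reference",
    "read_hit_table",
    "write_hit_table",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_insect_table",
    "write_insect_table",
    "read_site_plant_list",
    "write_site_plant_list",
    "write_json",
]

#: The 12 columns of the classic tabular alignment format.
HIT_TABLE_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

_HIT_DTYPES = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path) -> None:
    recs = [
        r if isinstance(r, SeqRecord) else SeqRecord(Seq(r[1]), id=r[0], description="")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def _strip_strings(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.strip()
    return df


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy CSV: ref_id,species,genus,tribe,family[,native_flag]."""
    df = pd.read_csv(path, dtype=str).pipe(_strip_strings)
    required = {"ref_id", "species", "genus", "tribe", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy file missing columns: {sorted(missing)}")
    df = df.set_index("ref_id")
    return df


def read_reference(fasta_path, taxonomy_path) -> ReferenceDB:
    """Load and cross-validate a reference FASTA with its taxonomy table.

    Every FASTA id must have exactly one taxonomy row; sequences must use
    IUPAC nucleotide codes only.
    """
    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"empty reference FASTA: {fasta_path}")
    taxonomy = read_taxonomy(taxonomy_path)
    sequences: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in reference {rec.id!r}"
            )
        if rec.id in sequences:
            raise ValueError(f"duplicate reference id in FASTA: {rec.id!r}")
        if rec.id not in taxonomy.index:
            raise ValueError(f"reference id missing from taxonomy: {rec.id!r}")
        sequences[rec.id] = seq
    return ReferenceDB(sequences=sequences, taxonomy=taxonomy)


def read_hit_table(path) -> pd.DataFrame:
    """Parse a 12-column tabular hit file.

    Returns a DataFrame with :data:`HIT_TABLE_COLUMNS`; all hits for a query
    are preserved, and downstream consensus assignment is invariant to row
    order.  An empty file yields an empty table with a warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            rows.append(fields)
    if not rows:
        logger.warning("hit table %s is empty", path)
        return pd.DataFrame(columns=list(HIT_TABLE_COLUMNS)).astype(
            {k: v for k, v in _HIT_DTYPES.items()}
        )
    df = pd.DataFrame(rows, columns=list(HIT_TABLE_COLUMNS))
    for col, dtype in _HIT_DTYPES.items():
        try:
            df[col] = df[col].astype(float if dtype is int else dtype)
            if dtype is int:
                as_int = df[col].astype(int)
                if (as_int != df[col]).any():
                    raise ValueError("non-integer value")
                df[col] = as_int
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = int(bad[0]) + 1 if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data line {lineno}"
            ) from None
    if (df["bitscore"] < 0).any() or (df["length"] < 1).any():
        raise ValueError(f"{path}: bitscore must be >= 0 and length >= 1")
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise ValueError(f"{path}: pident outside [0, 100]")
    return df


def write_hit_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=list(HIT_TABLE_COLUMNS))


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    """Write a labelled matrix; duplicate row/column labels are rejected."""
    if pd.Index(matrix.index).has_duplicates or pd.Index(matrix.columns).has_duplicates:
        raise ValueError("matrix has duplicate row or column labels")
    matrix.to_csv(path, index=True, index_label="")


def read_matrix_csv(path) -> pd.DataFrame:
    """Read a labelled matrix; counts round-trip exactly, proportions to 1e-12."""
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: non-rectangular matrix file ({exc})") from None
    if df.isna().any().any():
        raise ValueError(f"{path}: non-rectangular matrix file (missing cells)")
    if pd.Index(df.index).has_duplicates or pd.Index(df.columns).has_duplicates:
        raise ValueError(f"{path}: duplicate row or column labels")
    values = df.to_numpy()
    if np.issubdtype(values.dtype, np.number) and np.allclose(values, values.astype(np.int64), atol=0):
        df = df.astype(np.int64)
    df.index.name = None
    return df


def read_insect_table(path) -> pd.DataFrame:
    """Insect metadata CSV: insect_id,pollinator_species,site[,genus].

    A missing genus column is derived from the first token of the pollinator
    species binomial.
    """
    df = pd.read_csv(path, dtype=str).pipe(_strip_strings)
    required = {"insect_id", "pollinator_species", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"insect table missing columns: {sorted(missing)}")
    if "genus" not in df.columns:
        df["genus"] = df["pollinator_species"].str.split().str[0]
    df = df.set_index("insect_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate insect ids in metadata")
    return df


def write_insect_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="insect_id")


def read_site_plant_list(path) -> pd.DataFrame:
    """Site plant list CSV: site,plant_species,family; (site, species) unique."""
    df = pd.read_csv(path, dtype=str).pipe(_strip_strings)
    required = {"site", "plant_species", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site plant list missing columns: {sorted(missing)}")
    if df.duplicated(["site", "plant_species"]).any():
        dupes = df[df.duplicated(["site", "plant_species"])]
        raise ValueError(
            f"duplicate (site, plant_species) rows: {dupes.head(3).to_dict('records')}"
        )
    return df


def write_site_plant_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        value = float(obj)
        return value if math.isfinite(value) else repr(value)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
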