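"""Consensus taxonomic assignment of reads from alignment hit tables.

The classification rule, applied per read after a strict length filter
(> 450 bp by default):

1. keep the hits whose bit score lies among the ``top_k`` highest *distinct*
   score values for the read (all ties retained, so the result is invariant
   to hit-file row order);
2. if every retained hit resolves to one species, assign that species;
3. otherwise, if at least ``genus_fraction`` (default 60%) of the retained
   hits share one genus, assign that genus;
4. otherwise the read is labelled ``various``; a curation map may later
   resolve such reads to family or tribe level, and anything left over - as
   well as reads with no hits at all - is ``unknown``.

The genus vote is hit-count weighted.  At the default threshold (> 0.5) at
most one genus can qualify; for configured thresholds <= 0.5 a tie between
qualifying genera falls through to ``various``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import (
    PollenCountMatrix,
    UNKNOWN_LABEL,
    VARIOUS_LABEL,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentRule",
    "CurationRule",
    "CurationMap",
    "length_filter",
    "select_top_hits",
    "consensus_assign",
    "assign_reads",
    "apply_curation",
    "tally",
]


@dataclass(frozen=True)
class AssignmentRule:
    """Thresholds of the consensus classifier."""

    top_k: int = 20
    genus_fraction: float = 0.60
    min_length_exclusive: int = 450

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 < self.genus_fraction <= 1.0:
            raise ValueError("genus_fraction must be in (0, 1]")
        if self.min_length_exclusive < 0:
            raise ValueError("min_length_exclusive must be >= 0")


def length_filter(reads, rule: AssignmentRule = AssignmentRule()):
    """Retain reads strictly longer than the length cutoff.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs or biopython
    ``SeqRecord`` objects; the number of removed reads is logged.
    """
    kept, removed = [], 0
    for read in reads:
        length = len(read[1]) if isinstance(read, tuple) else len(read.seq)
        if length > rule.min_length_exclusive:
            kept.append(read)
        else:
            removed += 1
    logger.info("length filter: kept %d reads, removed %d (<= %d bp)",
                len(kept), removed, rule.min_length_exclusive)
    return kept


def select_top_hits(hits: pd.DataFrame,
                    rule: AssignmentRule = AssignmentRule()) -> pd.DataFrame:
    """Hits whose bit score is among the top ``top_k`` distinct values.

    Ties at any retained score level are all included; with fewer than
    ``top_k`` distinct values every hit is returned.
    """
    if hits.empty:
        raise ValueError("select_top_hits requires at least one hit")
    scores = hits["bitscore"].to_numpy()
    distinct = sorted(set(scores), reverse=True)[: rule.top_k]
    return hits[hits["bitscore"] >= distinct[-1]]


def _resolve(taxonomy: pd.DataFrame, subject_ids, column: str) -> list:
    try:
        return taxonomy.loc[list(subject_ids), column].tolist()
    except KeyError:
        missing = [s for s in subject_ids if s not in taxonomy.index]
        raise ValueError(
            f"hit subject ids absent from taxonomy: {missing[:5]}"
        ) from None


def _signature(families) -> str:
    return ";".join(sorted({f for f in families if isinstance(f, str) and f}))


def consensus_assign(hits: pd.DataFrame, taxonomy: pd.DataFrame,
                     rule: AssignmentRule = AssignmentRule()) -> dict:
    """Classify one read from its retained top hits.

    Returns a dict with ``query_id``, ``label``, ``rank``,
    ``n_hits_considered`` and the hit-set ``signature`` (sorted distinct
    families of the retained hits, used by curation).  Deterministic and
    invariant to hit ordering.
    """
    top = select_top_hits(hits, rule)
    query_id = top["qseqid"].iloc[0]
    subjects = top["sseqid"].tolist()
    species = _resolve(taxonomy, subjects, "species")
    genera = _resolve(taxonomy, subjects, "genus")
    families = _resolve(taxonomy, subjects, "family")
    signature = _signature(families)
    n = len(top)

    distinct_species = {s for s in species if isinstance(s, str) and s}
    if len(distinct_species) == 1 and all(
        isinstance(s, str) and s for s in species
    ):
        return {"query_id": query_id, "label": distinct_species.pop(),
                "rank": "species", "n_hits_considered": n,
                "signature": signature}

    votes = pd.Series([g for g in genera if isinstance(g, str) and g]).value_counts()
    if len(votes):
        qualifying = votes[votes >= rule.genus_fraction * n - 1e-9]
        if len(qualifying) == 1:
            return {"query_id": query_id, "label": qualifying.index[0],
                    "rank": "genus", "n_hits_considered": n,
                    "signature": signature}
    return {"query_id": query_id, "label": VARIOUS_LABEL, "rank": "various",
            "n_hits_considered": n, "signature": signature}


def assign_reads(hit_table: pd.DataFrame, taxonomy: pd.DataFrame,
                 rule: AssignmentRule = AssignmentRule(),
                 query_ids=None) -> pd.DataFrame:
    """Consensus-classify every read of a hit table.

    ``query_ids``, if given, lists every read that survived the length
    filter; reads among them with zero hits are assigned ``unknown`` (reason
    ``zero_hits``).  The result is sorted by query id, making the output
    independent of hit-table row order.
    """
    records = []
    if not hit_table.empty:
        records = _assign_bulk(hit_table, taxonomy, rule)
    seen = {r["query_id"] for r in records}
    if query_ids is not None:
        for qid in query_ids:
            if qid not in seen:
                records.append({
                    "query_id": qid, "label": UNKNOWN_LABEL, "rank": "unknown",
                    "n_hits_considered": 0, "signature": "",
                    "reason": "zero_hits",
                })
    df = pd.DataFrame(
        records,
        columns=["query_id", "label", "rank", "n_hits_considered",
                 "signature", "reason"],
    )
    return df.sort_values("query_id", kind="stable").reset_index(drop=True)


def _assign_bulk(hit_table: pd.DataFrame, taxonomy: pd.DataFrame,
                 rule: AssignmentRule) -> list[dict]:
    """Vectorised consensus over all queries; same semantics as
    :func:`consensus_assign` applied per query (property-tested)."""
    df = hit_table[["qseqid", "sseqid", "bitscore"]].copy()
    unknown_subjects = sorted(set(df["sseqid"]) - set(taxonomy.index))
    if unknown_subjects:
        raise ValueError(
            f"hit subject ids absent from taxonomy: {unknown_subjects[:5]}")
    for col in ("species", "genus", "family"):
        mapped = df["sseqid"].map(taxonomy[col])
        blank = mapped.isna() | (mapped.astype(str).str.strip() == "")
        df[col] = mapped.where(~blank)
    rank = df.groupby("qseqid")["bitscore"].rank(method="dense", ascending=False)
    top = df[rank <= rule.top_k]
    n = top.groupby("qseqid").size()

    signature = (
        top.dropna(subset=["family"])
        .drop_duplicates(["qseqid", "family"])
        .sort_values("family")
        .groupby("qseqid")["family"].agg(";".join)
        .reindex(n.index, fill_value="")
    )

    grouped = top.groupby("qseqid")
    any_null_species = top["species"].isna().groupby(top["qseqid"]).any()
    unanimous = (~any_null_species) & (grouped["species"].nunique() == 1)
    species_label = grouped["species"].first()

    with_genus = top.dropna(subset=["genus"])
    votes = (with_genus.groupby(["qseqid", "genus"]).size()
             .rename("votes").reset_index())
    votes["needed"] = rule.genus_fraction * votes["qseqid"].map(n) - 1e-9
    qualifying = votes[votes["votes"] >= votes["needed"]]
    n_qualifying = qualifying.groupby("qseqid").size().reindex(n.index, fill_value=0)
    genus_label = qualifying.drop_duplicates("qseqid", keep="first").set_index("qseqid")["genus"]

    records = []
    for qid in n.index:
        if unanimous[qid]:
            label, rank_name = species_label[qid], "species"
        elif n_qualifying[qid] == 1:
            label, rank_name = genus_label[qid], "genus"
        else:
            label, rank_name = VARIOUS_LABEL, "various"
        records.append({
            "query_id": qid, "label": label, "rank": rank_name,
            "n_hits_considered": int(n[qid]), "signature": signature[qid],
            "reason": "",
        })
    return records


@dataclass(frozen=True)
class CurationRule:
    """One expert-knowledge remapping for ``various`` assignments.

    ``match_type`` is ``"signature"`` (the rule keys on the sorted distinct
    families of the retained hits) or ``"query"`` (an explicit read id).
    ``rank`` is ``family``, ``tribe`` or ``unknown``.
    """

    match_type: str
    key: str
    rank: str
    label: str

    def __post_init__(self) -> None:
        if self.match_type not in ("signature", "query"):
            raise ValueError(f"invalid match_type: {self.match_type!r}")
        if self.rank not in ("family", "tribe", "unknown"):
            raise ValueError(f"invalid curation rank: {self.rank!r}")


@dataclass
class CurationMap:
    """Ordered curation rules; unmatched ``various`` reads become unknown."""

    rules: list[CurationRule]

    @classmethod
    def from_csv(cls, path) -> "CurationMap":
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"match_type", "key", "rank", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"curation map missing columns: {sorted(missing)}")
        return cls([CurationRule(r.match_type.strip(), r.key.strip(),
                                 r.rank.strip(), r.label.strip())
                    for r in df.itertuples()])

    def lookup(self, query_id: str, signature: str) -> CurationRule | None:
        for rule in self.rules:
            if rule.match_type == "query" and rule.key == query_id:
                return rule
            if rule.match_type == "signature" and rule.key == signature:
                return rule
        return None


def apply_curation(assignments: pd.DataFrame, curation: CurationMap,
                   taxonomy: pd.DataFrame):
    """Resolve ``various`` assignments to family/tribe level where possible.

    Only ``various`` rows are touched; anything they do not match falls
    through to ``unknown`` (reason ``curation_fallthrough``).  Returns the
    curated table and an audit log of every remap.  A rule naming a family
    or tribe absent from the taxonomy is an error.
    """
    known_families = set(taxonomy["family"].dropna())
    known_tribes = set(taxonomy["tribe"].dropna())
    for rule in curation.rules:
        if rule.rank == "family" and rule.label not in known_families:
            raise ValueError(f"curation rule names unknown family: {rule.label!r}")
        if rule.rank == "tribe" and rule.label not in known_tribes:
            raise ValueError(f"curation rule names unknown tribe: {rule.label!r}")

    out = assignments.copy()
    audit = []
    for idx in out.index[out["rank"] == "various"]:
        row = out.loc[idx]
        rule = curation.lookup(row["query_id"], row["signature"])
        if rule is None or rule.rank == "unknown":
            new_label, new_rank = UNKNOWN_LABEL, "unknown"
            reason = "curation_fallthrough" if rule is None else "curated_unknown"
        else:
            new_label, new_rank = rule.label, rule.rank
            reason = "curated"
        audit.append({"query_id": row["query_id"], "old_label": row["label"],
                      "old_rank": row["rank"], "new_label": new_label,
                      "new_rank": new_rank, "reason": reason})
        out.loc[idx, ["label", "rank", "reason"]] = [new_label, new_rank, reason]
    return out, pd.DataFrame(
        audit, columns=["query_id", "old_label", "old_rank",
                        "new_label", "new_rank", "reason"])


def tally(assignments: pd.DataFrame, insects: pd.DataFrame,
          query_to_insect=None) -> PollenCountMatrix:
    """Aggregate per-read assignments into an insect x taxon count matrix.

    The insect id is parsed from the read header (text before the first
    ``|``) unless ``query_to_insect`` provides an explicit mapping.  Row sums
    equal the number of length-filtered reads per insect; unknowns occupy a
    dedicated column.
    """
    if query_to_insect is None:
        owner = assignments["query_id"].str.split("|").str[0]
    else:
        owner = assignments["query_id"].map(query_to_insect)
        if owner.isna().any():
            bad = assignments["query_id"][owner.isna()].tolist()
            raise ValueError(f"reads without an insect mapping: {bad[:5]}")
    orphans = sorted(set(owner) - set(insects.index))
    if orphans:
        raise ValueError(f"reads from insects absent from metadata: {orphans[:5]}")

    work = assignments.assign(_insect=owner.to_numpy())
    counts = (
        work.pivot_table(index="_insect", columns="label", values="query_id",
                         aggfunc="count", fill_value=0)
        .reindex(insects.index, fill_value=0)
    )
    counts.index.name = None
    counts.columns.name = None
    counts = counts[sorted(counts.columns)]

    rank_map = {}
    for label, group in work.groupby("label"):
        ranks = set(group["rank"])
        if len(ranks) > 1:
            raise ValueError(
                f"taxon label {label!r} appears at multiple ranks: {sorted(ranks)}"
            )
        rank_map[label] = ranks.pop()
    ranks = pd.Series(rank_map).reindex(counts.columns)
    return PollenCountMatrix(counts=counts.astype(int), ranks=ranks,
                             insects=insects.loc[counts.index])
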