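"""In-memory containers shared across the pipeline stages.

Labels (taxon names, insect ids, site codes) are case-sensitive opaque
strings; nothing is normalised beyond whitespace trimming, so names like
"Rubus fruticosus agg." survive verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "UNKNOWN_LABEL",
    "VARIOUS_LABEL",
    "WIND_POLLINATED_FAMILIES",
    "RANKS",
    "ReferenceDB",
    "PollenCountMatrix",
    "PollenPercentMatrix",
    "PresenceAbsenceMatrix",
    "InteractionMatrix",
]

#: Column label reserved for reads that could not be identified.
UNKNOWN_LABEL = "unknown"
#: Label for multi-genus consensus results awaiting curation.
VARIOUS_LABEL = "various"
#: Families excluded when building the entomophilous (insect-pollinated)
#: sub-list of a site's flora: grasses, sedges and rushes.
WIND_POLLINATED_FAMILIES = frozenset({"Poaceae", "Cyperaceae", "Juncaceae"})
#: Ranks an assignment can carry, from most to least specific.
RANKS = ("species", "genus", "tribe", "family", "various", "unknown")


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ReferenceDB:
    """Barcode reference sequences paired with their ranked lineage.

    ``taxonomy`` is indexed by reference id and carries the columns
    ``species``, ``genus``, ``tribe`` (each possibly NA) and ``family``
    (required non-empty).
    """

    sequences: dict[str, str]
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference database has no sequences")
        _check_unique(self.taxonomy.index, "reference ids in taxonomy")
        missing = [r for r in self.sequences if r not in self.taxonomy.index]
        if missing:
            raise ValueError(
                f"reference ids without a taxonomy row: {missing[:5]}"
            )
        tax = self.taxonomy
        if tax["family"].isna().any() or (tax["family"].astype(str).str.strip() == "").any():
            bad = tax.index[tax["family"].isna() | (tax["family"].astype(str).str.strip() == "")]
            raise ValueError(f"empty family for reference ids: {list(bad[:5])}")
        has_species = tax["species"].notna() & (tax["species"].astype(str).str.strip() != "")
        no_genus = tax["genus"].isna() | (tax["genus"].astype(str).str.strip() == "")
        bad = tax.index[has_species & no_genus]
        if len(bad):
            raise ValueError(
                f"species set but genus blank for reference ids: {list(bad[:5])}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def lineage(self, ref_id: str) -> pd.Series:
        try:
            return self.taxonomy.loc[ref_id]
        except KeyError:
            raise KeyError(f"reference id not in taxonomy: {ref_id!r}") from None


def _validate_insects(insects: pd.DataFrame) -> pd.DataFrame:
    required = {"pollinator_species", "genus", "site"}
    missing = required - set(insects.columns)
    if missing:
        raise ValueError(f"insect table missing columns: {sorted(missing)}")
    _check_unique(insects.index, "insect ids")
    return insects


@dataclass
class PollenCountMatrix:
    """Integer read counts per insect and assigned pollen taxon.

    ``counts`` rows are insects, columns are rank-annotated taxon labels
    (ranks held in ``ranks``); a dedicated ``unknown`` column collects
    unidentified reads.  ``insects`` holds per-insect metadata
    (``pollinator_species``, ``genus``, ``site``) indexed by insect id.
    """

    counts: pd.DataFrame
    ranks: pd.Series
    insects: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.columns, "taxon labels")
        _check_unique(self.counts.index, "insect ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unranked = [c for c in self.counts.columns if c not in self.ranks.index]
        if unranked:
            raise ValueError(f"taxa without a rank annotation: {unranked[:5]}")
        bad = [c for c in self.counts.columns if self.ranks[c] not in RANKS]
        if bad:
            raise ValueError(f"taxa with invalid rank: {bad[:5]}")
        self.insects = _validate_insects(self.insects)
        orphans = [i for i in self.counts.index if i not in self.insects.index]
        if orphans:
            raise ValueError(f"insects without metadata: {orphans[:5]}")

    @property
    def identified(self) -> pd.DataFrame:
        """Counts restricted to identified (non-unknown) taxa."""
        cols = [c for c in self.counts.columns if c != UNKNOWN_LABEL]
        return self.counts[cols]


@dataclass
class PollenPercentMatrix:
    """Per-insect pollen composition as percentages of identified reads."""

    percent: pd.DataFrame
    ranks: pd.Series
    insects: pd.DataFrame


@dataclass
class PresenceAbsenceMatrix:
    """Boolean insect-by-taxon detection matrix with insect metadata."""

    data: pd.DataFrame
    insects: pd.DataFrame
    ranks: pd.Series | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(bool)
        _check_unique(self.data.columns, "taxon labels")
        _check_unique(self.data.index, "insect ids")
        self.insects = _validate_insects(self.insects)


@dataclass
class InteractionMatrix:
    """Per-site bipartite pollen-transport matrix.

    Rows are pollinator species, columns plant taxa; cell (i, j) counts the
    individuals of species i at the site that carried taxon j.  All-zero rows
    and columns are not retained.
    """

    site: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        values = tab.to_numpy()
        if (values < 0).any():
            raise ValueError("interaction counts must be non-negative")
        if (values != values.astype(int)).any():
            raise ValueError("interaction counts must be integers")
        self.table = tab.astype(int)
        if len(tab) and ((self.table.sum(axis=1) == 0).any() or (self.table.sum(axis=0) == 0).any()):
            raise ValueError("all-zero rows/columns must be dropped before construction")

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())
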