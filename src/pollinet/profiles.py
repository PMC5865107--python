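"""Pollen-load profiles: percentages, presence/absence, filters, coverage.

Read counts are converted to within-insect percentages to control for
amplification differences between samples; network and dissimilarity
analyses use qualitative presence/absence instead, to avoid biases in pollen
retrieval, extraction and sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import (
    PollenCountMatrix,
    PollenPercentMatrix,
    PresenceAbsenceMatrix,
    UNKNOWN_LABEL,
    WIND_POLLINATED_FAMILIES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "to_percent",
    "to_presence_absence",
    "jaccard_input_filter",
    "CoverageResult",
    "entomophilous_coverage",
]

#: Ranks above genus, subject to the rare-taxon filter.
_ABOVE_GENUS = ("family", "tribe", "various")


def to_percent(pcm: PollenCountMatrix) -> PollenPercentMatrix:
    """Row-normalise identified counts to percentages.

    The unknown column is excluded from both numerator and denominator;
    insects with zero identified reads are excluded with a warning.
    """
    identified = pcm.identified
    totals = identified.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        logger.warning("excluding %d insect(s) with no identified reads: %s",
                       len(empty), empty[:5])
    kept = identified.loc[totals > 0]
    percent = kept.div(kept.sum(axis=1), axis=0) * 100.0
    return PollenPercentMatrix(
        percent=percent,
        ranks=pcm.ranks.reindex(percent.columns),
        insects=pcm.insects.loc[percent.index],
    )


def to_presence_absence(pcm: PollenCountMatrix,
                        presence_min_reads: int = 1) -> PresenceAbsenceMatrix:
    """Threshold identified counts to presence/absence.

    A taxon is present in an insect when its read count reaches
    ``presence_min_reads``; taxa present in no insect are dropped, as is the
    unknown column (unidentified reads are not a taxon).
    """
    if presence_min_reads < 1:
        raise ValueError("presence_min_reads must be >= 1")
    pa = pcm.identified >= presence_min_reads
    pa = pa.loc[:, pa.any(axis=0)]
    return PresenceAbsenceMatrix(
        data=pa,
        insects=pcm.insects.loc[pa.index],
        ranks=pcm.ranks.reindex(pa.columns),
    )


def jaccard_input_filter(pcm: PollenCountMatrix,
                         rare_threshold: float = 0.01,
                         presence_min_reads: int = 1) -> PresenceAbsenceMatrix:
    """Presence/absence input for the dissimilarity analyses.

    Unknown reads are excluded, and taxa identified above genus level
    (family, tribe or uncurated ``various``) are dropped when they
    contribute strictly less than ``rare_threshold`` (default 1%) of all
    identified reads study-wide; presence/absence keeps rare taxa from
    dominating the Jaccard index.  Species- and genus-rank taxa are never
    dropped regardless of abundance.
    """
    identified = pcm.identified
    grand_total = identified.to_numpy().sum()
    keep = []
    for taxon in identified.columns:
        rank = pcm.ranks[taxon]
        if rank in _ABOVE_GENUS and grand_total > 0:
            if identified[taxon].sum() < rare_threshold * grand_total:
                logger.info("dropping rare above-genus taxon %r (%.3f%% of reads)",
                            taxon, 100.0 * identified[taxon].sum() / grand_total)
                continue
        keep.append(taxon)
    filtered = PollenCountMatrix(
        counts=identified[keep],
        ranks=pcm.ranks.reindex(keep),
        insects=pcm.insects,
    )
    return to_presence_absence(filtered, presence_min_reads)


@dataclass(frozen=True)
class CoverageResult:
    site: str
    n_entomophilous: int
    n_detected: int

    @property
    def fraction(self) -> float:
        return self.n_detected / self.n_entomophilous if self.n_entomophilous else 0.0


def entomophilous_coverage(site_list: pd.DataFrame, pollen_taxa,
                           site: str,
                           taxonomy: pd.DataFrame | None = None) -> CoverageResult:
    """Fraction of a site's insect-pollinated flora found in pollen loads.

    The entomophilous sub-list is the site's species list minus grasses
    (Poaceae), sedges (Cyperaceae) and rushes (Juncaceae).  A species-rank
    pollen taxon matches its own species; a pollen taxon above species rank
    contributes at most ONE matched species when the sub-list holds at least
    one member (and zero when it holds none).  Matches are counted as a set
    of distinct site species, so the fraction never exceeds 1.

    ``pollen_taxa`` maps taxon label to rank; ``taxonomy`` (optional)
    resolves tribe membership via its genus -> tribe pairs.
    """
    rows = site_list[site_list["site"] == site]
    if rows.empty:
        raise ValueError(f"site {site!r} absent from the site plant list")
    sub = rows[~rows["family"].isin(WIND_POLLINATED_FAMILIES)]
    species = sub["plant_species"].tolist()
    species_set = set(species)
    genus_of = {sp: sp.split()[0] for sp in species}
    family_of = dict(zip(sub["plant_species"], sub["family"]))
    tribe_genera: dict[str, set] = {}
    if taxonomy is not None:
        for _, row in taxonomy.dropna(subset=["tribe", "genus"]).iterrows():
            tribe_genera.setdefault(row["tribe"], set()).add(row["genus"])

    if isinstance(pollen_taxa, pd.Series):
        items = list(pollen_taxa.items())
    else:
        items = list(dict(pollen_taxa).items())

    matched: set[str] = set()
    # species-rank taxa first: they name their species outright
    for label, rank in items:
        if rank == "species" and label in species_set:
            matched.add(label)
    for label, rank in items:
        if rank == "species":
            continue
        if rank == "genus":
            members = [sp for sp in species if genus_of[sp] == label]
        elif rank == "family":
            members = [sp for sp in species if family_of[sp] == label]
        elif rank == "tribe":
            genera = tribe_genera.get(label, set())
            members = [sp for sp in species if genus_of[sp] in genera]
        else:  # various / unknown cannot detect a plant
            members = []
        novel = sorted(set(members) - matched)
        if novel:
            matched.add(novel[0])
    return CoverageResult(site=site, n_entomophilous=len(species_set),
                          n_detected=len(matched))
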