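"""Synthetic study generator.

Emulates the sampling design of a multi-site hoverfly pollen-transport
survey: a hierarchical plant taxonomy with barcode reference sequences, site
floras drawn from a largely shared species pool, per-insect pollen loads
drawn from a Dirichlet-multinomial preference model, error-prone amplicon
reads, and a pseudo-alignment hit table standing in for a MegaBlast run
against the reference database.

Model sketch
------------
* Reference sequences evolve down the taxonomy: a root per family, genus
  ancestors at ``between_genus_divergence / 2`` substitutions from the root,
  species at ``within_genus_divergence / 2`` from their genus ancestor, so
  congeneric species differ by roughly ``within_genus_divergence`` and
  confamilial genera by roughly ``between_genus_divergence`` (Hamming
  fraction).
* Each pollinator genus has a preference centroid over entomophilous plant
  species; a pollinator species' preference is the element-wise product of a
  global availability vector with its genus centroid raised to
  ``genus_effect_size`` (so effect 0 makes all pollinator taxa share one
  preference).
* An individual's true load is Dirichlet with concentration
  ``preference_concentration`` around its species' site-restricted
  preference: lower concentration means individuals commit to fewer plant
  taxa, i.e. a more specialised network.  Wind-pollinated (anemophilous)
  species present at the site share a small constant background mass.
* Reads are a multinomial sample of the load with independent per-base
  substitution errors; headers encode the insect id (``<insect>|r<k>``).

All randomness flows through labelled substreams of one top-level seed, so
every output is reproducible and adding a draw to one operation never shifts
another's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import ReferenceDB, WIND_POLLINATED_FAMILIES
from .io import HIT_TABLE_COLUMNS

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_taxonomy_and_refs",
    "simulate_loads_and_reads",
    "simulate_hit_table",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated survey: three sites, eleven pollinator
    species in five genera sampled repeatedly per site, and a flora of sixty
    plant species (15 families x 2 genera x 2 species) of which a fifth are
    wind-pollinated.  ``reads_per_individual`` is a desk-scale sequencing
    depth; divergences are Hamming substitution fractions.
    """

    seed: int = 0
    n_sites: int = 3
    n_families: int = 15
    genera_per_family: int = 2
    species_per_genus: int = 2
    ref_length: int = 500
    between_genus_divergence: float = 0.08
    within_genus_divergence: float = 0.02
    n_pollinator_species: int = 11
    n_pollinator_genera: int = 5
    individuals_per_species_site: int = 4
    reads_per_individual: int = 200
    read_error_rate: float = 0.005
    preference_concentration: float = 1.0
    genus_effect_size: float = 1.0
    anemophilous_fraction: float = 0.2
    site_overlap: float = 0.8
    anemophilous_background: float = 0.01
    hit_depth: int = 1

    def validate(self) -> "SimulationConfig":
        if min(self.n_sites, self.n_families, self.genera_per_family,
               self.species_per_genus, self.n_pollinator_species,
               self.n_pollinator_genera, self.individuals_per_species_site,
               self.ref_length, self.reads_per_individual) < 1:
            raise ValueError("all counts must be >= 1")
        for name in ("between_genus_divergence", "within_genus_divergence"):
            value = getattr(self, name)
            if not 0.0 < value < 0.5:
                raise ValueError(f"{name} must be in (0, 0.5), got {value}")
        if self.within_genus_divergence >= self.between_genus_divergence:
            raise ValueError(
                "within_genus_divergence must be below between_genus_divergence"
            )
        if self.preference_concentration <= 0:
            raise ValueError("preference_concentration must be > 0")
        if self.genus_effect_size < 0:
            raise ValueError("genus_effect_size must be >= 0")
        if not 0.0 <= self.read_error_rate < 1.0:
            raise ValueError("read_error_rate must be in [0, 1)")
        if not 0.0 <= self.anemophilous_fraction < 1.0:
            raise ValueError("anemophilous_fraction must be in [0, 1)")
        if not 0.0 <= self.site_overlap <= 1.0:
            raise ValueError("site_overlap must be in [0, 1]")
        if not 0.0 <= self.anemophilous_background < 1.0:
            raise ValueError("anemophilous_background must be in [0, 1)")
        if self.hit_depth < 1:
            raise ValueError("hit_depth must be >= 1")
        return self

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**payload).validate()


@dataclass
class SimulatedDataset:
    """Ground truth plus observable outputs of one simulated survey."""

    config: SimulationConfig
    true_loads: pd.DataFrame          # insect x plant species, proportions
    true_counts: pd.DataFrame         # insect x plant species, read counts
    reads: list                       # (read_id, sequence) tuples
    insects: pd.DataFrame             # insect metadata (index insect_id)
    site_lists: pd.DataFrame          # site, plant_species, family

    @property
    def reads_per_insect(self) -> pd.Series:
        ids = pd.Series([rid.split("|")[0] for rid, _ in self.reads])
        return ids.value_counts()


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    n = int(mask.sum())
    if n:
        # substitute with one of the three other bases
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_taxonomy_and_refs(config: SimulationConfig) -> ReferenceDB:
    """Hierarchical taxonomy with one barcode reference per plant species.

    Wind-pollinated species are grouped into up to three leading families
    named Poaceae, Cyperaceae and Juncaceae (so downstream entomophilous
    filtering applies naturally); the remaining families carry synthetic
    names.  Deterministic under a fixed config seed.
    """
    config.validate()
    n_wind = min(3, round(config.anemophilous_fraction * config.n_families))
    n_wind = min(n_wind, config.n_families - 1)  # keep >= 1 entomophilous family
    wind_names = ["Poaceae", "Cyperaceae", "Juncaceae"][:n_wind]

    rows = []
    sequences: dict[str, str] = {}
    ref_counter = 0
    for fi in range(config.n_families):
        family = wind_names[fi] if fi < n_wind else f"Familia{fi:02d}"
        tribe = f"Tribus{fi:02d}"
        root = substream(config.seed, f"family-root:{fi}").choice(4, size=config.ref_length).astype(np.uint8)
        for gi in range(config.genera_per_family):
            genus = f"Genus{fi:02d}{chr(ord('a') + gi)}"
            genus_rng = substream(config.seed, f"genus:{fi}:{gi}")
            genus_seq = _mutate(genus_rng, root, config.between_genus_divergence / 2.0)
            for si in range(config.species_per_genus):
                species = f"{genus} sp{si + 1}"
                sp_rng = substream(config.seed, f"species:{fi}:{gi}:{si}")
                sp_seq = _mutate(sp_rng, genus_seq, config.within_genus_divergence / 2.0)
                ref_id = f"ref{ref_counter:04d}"
                ref_counter += 1
                sequences[ref_id] = "".join("ACGT"[b] for b in sp_seq)
                rows.append({
                    "ref_id": ref_id, "species": species, "genus": genus,
                    "tribe": tribe, "family": family,
                    "anemophilous": family in WIND_POLLINATED_FAMILIES,
                })
    taxonomy = pd.DataFrame(rows).set_index("ref_id")
    return ReferenceDB(sequences=sequences, taxonomy=taxonomy)


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw robust to very small concentrations."""
    gam = rng.gamma(shape=alpha, scale=1.0)
    total = gam.sum()
    if total <= 0.0 or not np.isfinite(total):
        # all gamma draws underflowed: put the mass on one category drawn
        # from the mean of the distribution
        out = np.zeros_like(alpha)
        out[rng.choice(alpha.size, p=alpha / alpha.sum())] = 1.0
        return out
    return gam / total


def simulate_loads_and_reads(config: SimulationConfig,
                             refdb: ReferenceDB) -> SimulatedDataset:
    """Site floras, insect metadata, true pollen loads and amplicon reads."""
    config.validate()
    if config.reads_per_individual < 1:
        raise ValueError("reads_per_individual must be >= 1")
    tax = refdb.taxonomy
    species = tax["species"].tolist()
    families = tax["family"].tolist()
    anemo = np.array([f in WIND_POLLINATED_FAMILIES for f in families])
    n_species = len(species)
    species_seq = {
        sp: np.frombuffer(refdb.sequences[rid].encode(), dtype=np.uint8)
        for rid, sp in zip(tax.index, species)
    }
    encode = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        encode[b] = i
    species_codes = {sp: encode[arr] for sp, arr in species_seq.items()}

    sites = [f"S{i + 1}" for i in range(config.n_sites)]

    # --- site communities: a shared pool plus independent extras ----------
    site_rng = substream(config.seed, "site-communities")
    n_shared = round(config.site_overlap * n_species)
    shared = np.zeros(n_species, dtype=bool)
    shared[site_rng.choice(n_species, size=n_shared, replace=False)] = True
    community: dict[str, np.ndarray] = {}
    for site in sites:
        present = shared | (site_rng.random(n_species) < 0.5)
        # a site must host at least two entomophilous species for any
        # downstream network to exist
        ento_idx = np.flatnonzero(~anemo)
        if (present & ~anemo).sum() < 2:
            present[ento_idx[:2]] = True
        community[site] = present

    site_lists = pd.DataFrame([
        {"site": site, "plant_species": species[j], "family": families[j]}
        for site in sites for j in np.flatnonzero(community[site])
    ])

    # --- pollinator preferences ------------------------------------------
    ento = ~anemo
    n_ento = int(ento.sum())
    base = _dirichlet(substream(config.seed, "availability"), np.ones(n_ento))
    centroids = {
        g: _dirichlet(substream(config.seed, f"pollinator-centroid:{g}"), np.ones(n_ento))
        for g in range(config.n_pollinator_genera)
    }
    pollinators = []
    genus_count: dict[int, int] = {}
    for i in range(config.n_pollinator_species):
        g = i % config.n_pollinator_genera
        genus_count[g] = genus_count.get(g, 0) + 1
        genus_name = f"Hovgen{g + 1}"
        pollinators.append({
            "code": f"hsp{i:02d}",
            "pollinator_species": f"{genus_name} sp{genus_count[g]}",
            "genus": genus_name,
            "preference": _preference(base, centroids[g], config.genus_effect_size),
        })

    # --- individuals, loads, reads ----------------------------------------
    insect_rows = []
    load_rows = {}
    count_rows = {}
    reads: list[tuple[str, str]] = []
    L = config.ref_length
    for site in sites:
        present = community[site]
        ento_present = np.flatnonzero(present & ento)
        anemo_present = np.flatnonzero(present & anemo)
        for p in pollinators:
            pref_full = np.zeros(n_species)
            pref_ento = p["preference"][_ento_positions(ento)[ento_present]]
            pref_ento = pref_ento / pref_ento.sum()
            background = config.anemophilous_background if anemo_present.size else 0.0
            pref_full[ento_present] = (1.0 - background) * pref_ento
            if anemo_present.size:
                pref_full[anemo_present] = background / anemo_present.size
            for k in range(config.individuals_per_species_site):
                insect_id = f"{site}-{p['code']}-{k:02d}"
                rng = substream(config.seed, f"insect:{insect_id}")
                support = np.flatnonzero(pref_full > 0)
                alpha = config.preference_concentration * pref_full[support]
                load = np.zeros(n_species)
                load[support] = _dirichlet(rng, alpha)
                counts = np.zeros(n_species, dtype=int)
                counts[support] = rng.multinomial(config.reads_per_individual,
                                                  load[support])
                insect_rows.append({
                    "insect_id": insect_id,
                    "pollinator_species": p["pollinator_species"],
                    "genus": p["genus"],
                    "site": site,
                })
                load_rows[insect_id] = load
                count_rows[insect_id] = counts
                ridx = 0
                for j in np.flatnonzero(counts):
                    template = species_codes[species[j]]
                    block = np.tile(template, (counts[j], 1))
                    if config.read_error_rate > 0:
                        mask = rng.random(block.shape) < config.read_error_rate
                        n_err = int(mask.sum())
                        if n_err:
                            block[mask] = (block[mask] + rng.integers(1, 4, size=n_err)) % 4
                    for row in block:
                        reads.append((f"{insect_id}|r{ridx:04d}",
                                      _BASES[row].tobytes().decode()))
                        ridx += 1

    insects = pd.DataFrame(insect_rows).set_index("insect_id")
    true_loads = pd.DataFrame.from_dict(load_rows, orient="index", columns=species)
    true_counts = pd.DataFrame.from_dict(count_rows, orient="index", columns=species)
    return SimulatedDataset(
        config=config, true_loads=true_loads, true_counts=true_counts,
        reads=reads, insects=insects, site_lists=site_lists,
    )


def _ento_positions(ento_mask: np.ndarray) -> np.ndarray:
    """Map a global species index to its rank among entomophilous species."""
    pos = np.cumsum(ento_mask) - 1
    return pos


def _preference(base: np.ndarray, centroid: np.ndarray, effect: float) -> np.ndarray:
    pref = base * np.power(centroid, effect)
    total = pref.sum()
    if total <= 0:
        pref = base.copy()
        total = pref.sum()
    return pref / total


def simulate_hit_table(reads, refdb: ReferenceDB, top_n: int = 1) -> pd.DataFrame:
    """Score every read against every reference by ungapped identity.

    The pseudo bit score is ``max(0, 2 * (matches - mismatches))`` - a stated
    linear function of the ungapped comparison, not a Karlin-Altschul score;
    downstream assignment only consumes the ranking.  The ``top_n``
    best-scoring references per read are emitted, extended through ties at
    the cutoff score; references scoring zero align no better than chance
    and are never reported (a read with no scoring reference has no hits).
    Reads may be at most as long as the (equal-length) references; the
    comparison runs over the read's length.

    With one reference accession per species, reporting depth ``top_n``
    plays the role that hit-list depth plays against a real database with
    many near-identical accessions per species: at depth 1 a clean read
    resolves to its species, deeper reporting pulls in congeners and shifts
    the consensus towards genus or coarser.  The default depth of 1 is the
    regime in which species-level assignment is attainable at all under a
    one-accession-per-species database.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ref_ids = list(refdb.sequences)
    lengths = {len(s) for s in refdb.sequences.values()}
    if len(lengths) != 1:
        raise ValueError("references must be of equal length")
    L = lengths.pop()
    reads = list(reads)
    if not reads:
        return pd.DataFrame(columns=list(HIT_TABLE_COLUMNS))

    refs = np.frombuffer(
        "".join(refdb.sequences[r] for r in ref_ids).encode(), dtype=np.uint8
    ).reshape(len(ref_ids), L)

    rows = []
    chunk_size = max(1, int(2_000_000 // max(1, len(ref_ids) * L)) * 64)
    for start in range(0, len(reads), chunk_size):
        chunk = reads[start:start + chunk_size]
        read_lens = np.array([len(seq) for _, seq in chunk])
        if (read_lens > L).any():
            raise ValueError("read longer than the references")
        width = int(read_lens.max())
        block = np.zeros((len(chunk), width), dtype=np.uint8)
        for i, (_, seq) in enumerate(chunk):
            block[i, : len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)
        # padded tail positions always mismatch; subtract them per read below
        mism = (block[:, None, :] != refs[None, :, :width]).sum(axis=2)
        pad = width - read_lens
        for i, (read_id, _) in enumerate(chunk):
            alen = int(read_lens[i])
            mm = mism[i] - pad[i]
            matches = alen - mm
            bits = np.maximum(0, 2 * (matches - mm))
            order = np.lexsort((np.array(ref_ids), -bits))
            cutoff = max(1, bits[order[min(top_n, len(ref_ids)) - 1]])
            keep = order[bits[order] >= cutoff]
            for j in keep:
                bit = float(bits[j])
                rows.append((
                    read_id, ref_ids[j],
                    round(100.0 * matches[j] / alen, 3), alen, int(mm[j]), 0,
                    1, alen, 1, alen,
                    max(alen * 2.0 ** (-bit), 1e-180), bit,
                ))
    return pd.DataFrame(rows, columns=list(HIT_TABLE_COLUMNS))


def simulate_dataset(config: SimulationConfig, top_n: int | None = None):
    """Convenience wrapper: taxonomy, dataset and hit table in one call."""
    refdb = simulate_taxonomy_and_refs(config)
    data = simulate_loads_and_reads(config, refdb)
    depth = config.hit_depth if top_n is None else top_n
    hits = simulate_hit_table(data.reads, refdb, top_n=depth)
    return refdb, data, hits
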