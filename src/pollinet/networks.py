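"""Bipartite pollen-transport networks and the specialisation indices H2' and d'.

Definitions (natural logarithms throughout; ``a_ij`` interaction counts,
``m`` the grand total, ``A_i`` and ``B_j`` the marginals, ``p_ij = a_ij/m``,
``q_j = B_j/m``):

* two-dimensional Shannon entropy ``H2 = -sum p_ij ln p_ij``;
* ``H2max``: entropy of the independence table ``A_i B_j / m^2`` (the
  maximum-entropy coupling of the marginals, possibly non-integer);
* ``H2min``: the smallest entropy achievable by a non-negative integer table
  with the observed marginals;
* ``H2' = (H2max - H2) / (H2max - H2min)``, 0 for perfect generalisation,
  1 for perfect specialisation;
* per-species ``d_i = sum_j (a_ij/A_i) ln((a_ij/A_i)/q_j)``, the
  Kullback-Leibler divergence of the species' partner use from overall
  partner availability (availability includes the focal species' own
  interactions);
* ``dmax_i = ln(m/A_i)``; ``dmin_i``: the divergence of the best integer
  allocation of ``A_i`` interactions proportional to availability;
* ``d' = (d - dmin) / (dmax - dmin)``, 0 = no exclusivity, 1 = complete.

``H2min`` exploits that table entropy is concave, so its minimum under
fixed marginals is attained at a vertex of the transportation polytope, and
every vertex arises from some "allocate min(row, col) remainder, cross out
an exhausted line" order.  A dynamic programme over remaining-marginal
states (keeping the lowest accumulated entropy per state, beam-truncated
for large problems) searches these orders; it is exact wherever exhaustive
enumeration is feasible and a bounded-effort search beyond.

``dmin`` is the minimum of a separable convex function over the integer
simplex, so allocating the ``A_i`` interactions one at a time to the column
with the smallest marginal increase is provably optimal.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InteractionMatrix, PresenceAbsenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSpecialization",
    "SpeciesSpecialization",
    "build_network",
    "network_h2prime",
    "species_dprime",
    "min_table_entropy",
    "min_divergence_allocation",
]


def build_network(pa: PresenceAbsenceMatrix, site: str) -> InteractionMatrix:
    """Per-site interaction matrix from individual presence/absence profiles.

    Cell (species, taxon) counts the individuals of that pollinator species
    at the site whose profile includes the taxon; all-zero rows and columns
    are removed.  The per-individual aggregation is the natural reading of
    species-level metrics computed from individual detections.
    """
    at_site = pa.insects.index[pa.insects["site"] == site]
    if len(at_site) == 0:
        raise ValueError(f"no insects recorded at site {site!r}")
    profiles = pa.data.loc[at_site].astype(int)
    table = profiles.groupby(pa.insects.loc[at_site, "pollinator_species"]).sum()
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    table.index.name = None
    table.columns.name = None
    return InteractionMatrix(site=site, table=table.sort_index(axis=0).sort_index(axis=1))


def _entropy(values: np.ndarray, total: float) -> float:
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def min_table_entropy(row_totals, col_totals, beam_width: int = 256) -> float:
    """Minimum Shannon entropy of integer tables with the given marginals.

    Dynamic programme over vertices of the transportation polytope (see
    module docstring); states are the sorted remaining marginals, each kept
    with the lowest entropy accumulated so far, truncated to ``beam_width``
    states per step.
    """
    rows = tuple(sorted((int(r) for r in row_totals if r > 0), reverse=True))
    cols = tuple(sorted((int(c) for c in col_totals if c > 0), reverse=True))
    if sum(rows) != sum(cols):
        raise ValueError("row and column totals must agree")
    m = sum(rows)
    if m == 0:
        return 0.0
    states: dict[tuple, float] = {(rows, cols): 0.0}
    best = math.inf
    while states:
        nxt: dict[tuple, float] = {}
        for (rs, cs), acc in states.items():
            if not rs:
                best = min(best, acc)
                continue
            for r in set(rs):
                for c in set(cs):
                    a = min(r, c)
                    p = a / m
                    acc2 = acc - p * math.log(p)
                    if acc2 >= best:
                        continue
                    rl = list(rs)
                    rl.remove(r)
                    if r - a:
                        rl.append(r - a)
                    cl = list(cs)
                    cl.remove(c)
                    if c - a:
                        cl.append(c - a)
                    key = (tuple(sorted(rl, reverse=True)),
                           tuple(sorted(cl, reverse=True)))
                    if acc2 < nxt.get(key, math.inf):
                        nxt[key] = acc2
        if len(nxt) > beam_width:
            nxt = dict(sorted(nxt.items(), key=lambda kv: kv[1])[:beam_width])
        states = nxt
    return best


@dataclass(frozen=True)
class NetworkSpecialization:
    h2: float
    h2min: float
    h2max: float
    h2prime: float
    degenerate: bool = False


def network_h2prime(im: InteractionMatrix,
                    beam_width: int = 256) -> NetworkSpecialization:
    """Network-level standardised two-dimensional Shannon specialisation."""
    table = im.table.to_numpy(dtype=float)
    m = table.sum()
    if m < 1:
        raise ValueError("interaction matrix has no interactions")
    if min(table.shape) < 2:
        logger.warning("degenerate %dx%d network at %s: H2' undefined",
                       *table.shape, im.site)
        return NetworkSpecialization(
            h2=_entropy(table.ravel(), m), h2min=math.nan, h2max=math.nan,
            h2prime=math.nan, degenerate=True)
    h2 = _entropy(table.ravel(), m)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    indep = np.outer(rows, cols) / (m * m)
    h2max = _entropy(indep.ravel() * m, m)
    h2min = min_table_entropy(rows, cols, beam_width=beam_width)
    if h2max > h2min:
        h2prime = (h2max - h2) / (h2max - h2min)
    else:
        h2prime = 0.0
    if h2prime < -1e-12 or h2prime > 1 + 1e-12:
        logger.warning("clipping H2' = %.6f into [0, 1] (continuous H2max bound)",
                       h2prime)
    h2prime = min(1.0, max(0.0, h2prime))
    return NetworkSpecialization(h2=h2, h2min=h2min, h2max=h2max, h2prime=h2prime)


def min_divergence_allocation(total: int, availability: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` units minimising KL from ``availability``.

    The objective ``sum_j (a_j/A) ln((a_j/A)/q_j)`` is separable convex in
    the integer allocation, so assigning units one at a time to the column
    with the smallest marginal increase is exactly optimal.  Columns with
    zero availability receive nothing.  Ties break on column order.
    """
    q = np.asarray(availability, dtype=float)
    if total < 1:
        raise ValueError("total must be >= 1")
    if (q < 0).any() or q.sum() <= 0:
        raise ValueError("availability must be non-negative with positive sum")
    alloc = np.zeros(q.size, dtype=int)

    def marginal(j: int, a: int) -> float:
        def f(x: int) -> float:
            return 0.0 if x == 0 else (x / total) * math.log(x / (total * q[j]))
        return f(a + 1) - f(a)

    heap = [(marginal(j, 0), j) for j in range(q.size) if q[j] > 0]
    heapq.heapify(heap)
    for _ in range(total):
        _, j = heapq.heappop(heap)
        alloc[j] += 1
        heapq.heappush(heap, (marginal(j, alloc[j]), j))
    return alloc


def _divergence(alloc: np.ndarray, total: int, q: np.ndarray) -> float:
    use = alloc[alloc > 0] / total
    return float((use * np.log(use / q[alloc > 0])).sum())


@dataclass(frozen=True)
class SpeciesSpecialization:
    species: str
    d: float
    dmin: float
    dmax: float
    dprime: float


def species_dprime(im: InteractionMatrix) -> list[SpeciesSpecialization]:
    """Standardised partner-use exclusivity d' for every pollinator species."""
    table = im.table.to_numpy(dtype=float)
    m = table.sum()
    if m < 1:
        raise ValueError("interaction matrix has no interactions")
    q = table.sum(axis=0) / m
    out = []
    for label, row in zip(im.table.index, table):
        total = int(row.sum())
        if total < 1:
            raise ValueError(f"species {label!r} has no interactions")
        d = _divergence(row.astype(int), total, q)
        dmax = math.log(m / total)
        dmin = _divergence(min_divergence_allocation(total, q), total, q)
        if dmax > dmin:
            dprime = (d - dmin) / (dmax - dmin)
        else:
            logger.warning("species %r: dmax == dmin, reporting d' = 0", label)
            dprime = 0.0
        if dprime < -1e-12 or dprime > 1 + 1e-12:
            logger.warning("clipping d' = %.6f into [0, 1] for %r", dprime, label)
        dprime = min(1.0, max(0.0, dprime))
        out.append(SpeciesSpecialization(species=str(label), d=d, dmin=dmin,
                                         dmax=dmax, dprime=dprime))
    return out
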