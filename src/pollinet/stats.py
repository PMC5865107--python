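"""Pollen-load comparison suite.

Jaccard distances on presence/absence profiles, one-factor permutational
MANOVA (pseudo-F on a distance matrix) with site-stratified permutations,
a battery of a-priori contrasts under the Dunn-Sidak family-wise
correction, and the tie-corrected Kruskal-Wallis rank test.

The Jaccard distance is the classic ``1 - |intersection| / |union|`` on
binary data (not the binary Bray-Curtis variant some R workflows produce;
the two differ by a monotone rescaling that the pseudo-F is not invariant
to).  Permutation p-values use the add-one estimator
``(1 + #{F* >= F}) / (1 + n_perm)`` and are therefore never exactly zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from skbio import DistanceMatrix

from ._rng import substream
from .containers import PresenceAbsenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PermanovaResult",
    "Contrast",
    "ComparisonSuite",
    "KruskalWallisResult",
    "jaccard_distances",
    "permanova",
    "sidak_cutoff",
    "default_contrast_battery",
    "run_contrast_battery",
    "kruskal_wallis",
]


def jaccard_distances(pa: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances between insect pollen profiles.

    Insects with an empty profile are dropped with a warning (the distance
    is undefined for them); an entirely empty matrix is an error.
    """
    data = pa.data.to_numpy(dtype=bool)
    occupied = data.any(axis=1)
    if not occupied.any():
        raise ValueError("all presence/absence profiles are empty")
    if (~occupied).any():
        dropped = pa.data.index[~occupied].tolist()
        logger.warning("dropping %d insect(s) with empty profiles: %s",
                       len(dropped), dropped[:5])
    ids = pa.data.index[occupied].tolist()
    condensed = pdist(data[occupied], metric="jaccard")
    return DistanceMatrix(squareform(condensed), ids=ids)


@dataclass(frozen=True)
class PermanovaResult:
    F: float
    R2: float
    p: float
    df_between: int
    df_resid: int
    n_perm: int
    seed: int | None = None
    method: str = "permutation"

    def as_dict(self) -> dict:
        return {
            "F": self.F if math.isfinite(self.F) else "inf",
            "R2": self.R2, "p": self.p, "df_between": self.df_between,
            "df_resid": self.df_resid, "n_perm": self.n_perm,
            "seed": self.seed, "method": self.method,
        }


def _align(dm: DistanceMatrix, series: pd.Series, what: str) -> np.ndarray:
    missing = [i for i in dm.ids if i not in series.index]
    if missing:
        raise ValueError(f"{what} missing for samples: {missing[:5]}")
    return series.loc[list(dm.ids)].to_numpy()


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int, ss_total: float):
    n = d2.shape[0]
    ss_within = _ss_within(d2, codes, k)
    ss_between = ss_total - ss_within
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        return math.inf, (ss_between / ss_total if ss_total > 0 else 0.0)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _strata_blocks(strata: np.ndarray | None, n: int) -> list[np.ndarray]:
    if strata is None:
        return [np.arange(n)]
    blocks = []
    for value in pd.unique(strata):
        blocks.append(np.flatnonzero(strata == value))
    return blocks


def permanova(dm: DistanceMatrix, grouping: pd.Series,
              strata: pd.Series | None = None, n_perm: int = 9999,
              seed: int = 0, permutations: str = "random",
              check_strata: bool = False) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix, permuting within strata.

    ``grouping`` and ``strata`` are Series indexed by the distance-matrix
    ids.  With ``permutations="exact"`` all distinct within-strata label
    arrangements are enumerated (identity included) and the p-value is the
    exact permutation tail probability; otherwise ``n_perm`` seeded random
    permutations are drawn and the add-one estimator applies.  When the
    within-group sum of squares vanishes, F is reported as +inf with the
    minimum-resolution p-value.
    """
    labels = _align(dm, grouping, "group labels")
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n = len(labels)
    strata_arr = _align(dm, strata, "strata") if strata is not None else None
    blocks = _strata_blocks(strata_arr, n)
    for block in blocks:
        if block.size == 1 and len(set(codes)) > 1:
            logger.warning("stratum of size 1: its label cannot be permuted")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    f_obs, r2 = _pseudo_f(d2, codes, k, ss_total)

    if math.isinf(f_obs):
        p = 1.0 / (1 + n_perm)
        return PermanovaResult(F=math.inf, R2=r2, p=p, df_between=k - 1,
                               df_resid=n - k, n_perm=n_perm, seed=seed)

    if permutations == "exact":
        count = 0
        total = 0
        for perm_codes in _enumerate_arrangements(codes, blocks):
            f_perm, _ = _pseudo_f(d2, perm_codes, k, ss_total)
            total += 1
            if f_perm >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(F=f_obs, R2=r2, p=count / total,
                               df_between=k - 1, df_resid=n - k,
                               n_perm=total, seed=None, method="exact")

    rng = substream(seed, "permanova")
    count = 0
    work = codes.copy()
    for _ in range(n_perm):
        for block in blocks:
            work[block] = work[block][rng.permutation(block.size)]
        if check_strata and strata_arr is not None:
            for block in blocks:
                assert sorted(work[block]) == sorted(codes[block]), \
                    "permutation moved a label across strata"
        f_perm, _ = _pseudo_f(d2, work, k, ss_total)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(F=f_obs, R2=r2, p=p, df_between=k - 1,
                           df_resid=n - k, n_perm=n_perm, seed=seed)


def _enumerate_arrangements(codes: np.ndarray, blocks: list[np.ndarray],
                            limit: int = 500_000):
    """All distinct within-block permutations of a label vector."""
    from sympy.utilities.iterables import multiset_permutations

    per_block = []
    total = 1
    for block in blocks:
        perms = list(multiset_permutations(codes[block].tolist()))
        total *= len(perms)
        if total > limit:
            raise ValueError(
                f"exact enumeration infeasible (> {limit} arrangements)")
        per_block.append(perms)
    for combo in itertools.product(*per_block):
        arrangement = codes.copy()
        for block, labels in zip(blocks, combo):
            arrangement[block] = labels
        yield arrangement


def sidak_cutoff(alpha: float, k: int) -> float:
    """Dunn-Sidak per-test cutoff controlling family-wise error over k tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


@dataclass(frozen=True)
class Contrast:
    """A named label partition over a subset of the insects."""

    name: str
    groups: pd.Series                 # insect id -> group label (the subset)
    strata: pd.Series | None = None   # insect id -> stratum

    def __post_init__(self) -> None:
        if self.groups.nunique() < 2:
            raise ValueError(f"contrast {self.name!r} has fewer than two groups")
        if (self.groups.value_counts() < 1).any():
            raise ValueError(f"contrast {self.name!r} has an empty side")


def default_contrast_battery(insects: pd.DataFrame) -> list[Contrast]:
    """The a-priori battery: each genus vs the rest, plus within-genus species.

    One one-vs-rest contrast per pollinator genus over all insects, and one
    species contrast within every genus holding more than one species
    (restricted to that genus's insects).  Permutations are stratified by
    site throughout.
    """
    contrasts = []
    site = insects["site"]
    for genus in sorted(insects["genus"].unique()):
        labels = pd.Series(
            np.where(insects["genus"] == genus, genus, "other"),
            index=insects.index,
        )
        contrasts.append(Contrast(name=f"{genus} vs rest", groups=labels,
                                  strata=site))
    for genus in sorted(insects["genus"].unique()):
        members = insects[insects["genus"] == genus]
        if members["pollinator_species"].nunique() > 1:
            contrasts.append(Contrast(
                name=f"species within {genus}",
                groups=members["pollinator_species"],
                strata=site.loc[members.index],
            ))
    return contrasts


@dataclass
class ComparisonSuite:
    results: dict[str, PermanovaResult]
    alpha: float
    k: int
    sidak_cutoff: float
    significant: dict[str, bool]

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha, "k": self.k,
            "sidak_cutoff": self.sidak_cutoff,
            "contrasts": {name: {**res.as_dict(),
                                 "significant": self.significant[name]}
                          for name, res in self.results.items()},
        }


def run_contrast_battery(dm: DistanceMatrix, contrasts: list[Contrast],
                         alpha: float = 0.05, n_perm: int = 9999,
                         seed: int = 0) -> ComparisonSuite:
    """Run every contrast and flag significance at the Dunn-Sidak cutoff.

    The correction family is exactly the supplied contrast list (k = its
    length).  Each contrast runs on the distance sub-matrix of its insects.
    """
    if not contrasts:
        raise ValueError("no contrasts supplied")
    k = len(contrasts)
    cutoff = sidak_cutoff(alpha, k)
    results: dict[str, PermanovaResult] = {}
    flags: dict[str, bool] = {}
    available = set(dm.ids)
    for contrast in contrasts:
        ids = [i for i in contrast.groups.index if i in available]
        if pd.Series(contrast.groups.loc[ids]).nunique() < 2:
            raise ValueError(
                f"contrast {contrast.name!r} lost a side after filtering")
        sub = dm.filter(ids)
        res = permanova(sub, contrast.groups, strata=contrast.strata,
                        n_perm=n_perm,
                        seed=substream(seed, f"contrast:{contrast.name}")
                        .integers(2**31))
        results[contrast.name] = res
        flags[contrast.name] = res.p < cutoff
    return ComparisonSuite(results=results, alpha=alpha, k=k,
                           sidak_cutoff=cutoff, significant=flags)


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    df: int
    p: float


def kruskal_wallis(groups) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis rank test across value groups.

    ``groups`` is a mapping or sequence of value arrays.  Mid-ranks are used
    for ties; the statistic is referred to a chi-square with
    ``len(groups) - 1`` degrees of freedom.  All values identical leaves the
    statistic undefined and raises.
    """
    values = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(values) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(v) == 0 for v in values):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    flat = np.concatenate([np.asarray(v, dtype=float) for v in values])
    if np.all(flat == flat[0]):
        raise ValueError("all values identical: Kruskal-Wallis undefined")
    h, p = kruskal(*values)
    return KruskalWallisResult(H=float(h), df=len(values) - 1, p=float(p))
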