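import itertools
import math

import numpy as np
import pandas as pd
import pytest

import oracles
from pollinet.containers import PresenceAbsenceMatrix
from pollinet.stats import (
    Contrast,
    default_contrast_battery,
    jaccard_distances,
    kruskal_wallis,
    permanova,
    run_contrast_battery,
    sidak_cutoff,
)


def make_pa(data: pd.DataFrame, genus=None, site=None):
    insects = pd.DataFrame({
        "pollinator_species": ["x"] * len(data),
        "genus": genus if genus is not None else ["G"] * len(data),
        "site": site if site is not None else ["S1"] * len(data),
    }, index=data.index)
    return PresenceAbsenceMatrix(data=data, insects=insects)


class TestJaccard:
    def test_textbook_values(self):
        data = pd.DataFrame(
            [[1, 1, 1, 0], [0, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 1]],
            index=["abc", "bcd", "abc2", "d"], columns=list("ABCD"),
        ).astype(bool)
        dm = jaccard_distances(make_pa(data))
        assert dm["abc", "abc2"] == 0.0
        assert dm["abc", "d"] == 1.0          # disjoint profiles
        assert dm["abc", "bcd"] == pytest.approx(0.5)  # 1 - 2/4

    def test_empty_profiles_dropped_with_warning(self, caplog):
        data = pd.DataFrame([[1, 0], [0, 0]], index=["a", "b"],
                            columns=["A", "B"]).astype(bool)
        with caplog.at_level("WARNING"):
            dm = jaccard_distances(make_pa(data))
        assert list(dm.ids) == ["a"]

    def test_all_empty_is_an_error(self):
        data = pd.DataFrame([[0], [0]], index=["a", "b"], columns=["A"]).astype(bool)
        with pytest.raises(ValueError):
            jaccard_distances(make_pa(data))

    def test_metric_axioms_on_random_binary_matrices(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            n, t = rng.integers(3, 7), rng.integers(2, 6)
            data = rng.random((n, t)) < 0.5
            data[~data.any(axis=1), 0] = True
            frame = pd.DataFrame(data, index=[f"i{j}" for j in range(n)])
            d = jaccard_distances(make_pa(frame)).data
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()
            for i, j, k in itertools.permutations(range(n), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPermanova:
    def profiles(self, rng, n, t=8):
        data = rng.random((n, t)) < 0.4
        data[~data.any(axis=1), 0] = True
        return pd.DataFrame(data, index=[f"i{j}" for j in range(n)])

    def test_exact_enumeration_matches_independent_oracle(self):
        """n = 6, two groups of 3, one stratum: p from the package's exact
        mode equals the tail probability over all 20 label arrangements
        computed with an independent pseudo-F transcription."""
        rng = np.random.default_rng(41)
        data = self.profiles(rng, 6)
        pa = make_pa(data)
        dm = jaccard_distances(pa)
        labels = pd.Series(["g1"] * 3 + ["g2"] * 3, index=data.index)
        res = permanova(dm, labels, permutations="exact")

        d2 = np.asarray(dm.data) ** 2
        f_obs = oracles.permanova_f_direct(d2, labels.to_numpy())
        assert res.F == pytest.approx(f_obs, abs=1e-12)
        arrangements = sorted(set(itertools.permutations(labels.tolist())))
        assert len(arrangements) == 20
        tail = sum(
            oracles.permanova_f_direct(d2, np.array(arr)) >= f_obs - 1e-12
            for arr in arrangements
        )
        assert res.p == pytest.approx(tail / 20)

    def test_pseudo_f_matches_skbio_without_strata(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(43)
        data = self.profiles(rng, 18)
        dm = jaccard_distances(make_pa(data))
        labels = pd.Series(rng.choice(["a", "b", "c"], size=18), index=data.index)
        if labels.loc[list(dm.ids)].nunique() < 2:
            labels.iloc[0] = "b"
        ours = permanova(dm, labels, n_perm=49, seed=0)
        theirs = skbio_stats.permanova(dm, labels.loc[list(dm.ids)].to_numpy(),
                                       permutations=49)
        assert ours.F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_identical_group_multisets_rarely_reject(self):
        """Two groups drawn as identical profile multisets are exchangeable:
        the test should almost never reject across seeded runs."""
        rng = np.random.default_rng(47)
        base = self.profiles(rng, 8)
        data = pd.concat([base, base.set_index(pd.Index([f"j{j}" for j in range(8)]))])
        labels = pd.Series(["g1"] * 8 + ["g2"] * 8, index=data.index)
        rejections = 0
        for seed in range(20):
            dm = jaccard_distances(make_pa(data))
            res = permanova(dm, labels, n_perm=199, seed=seed)
            rejections += res.p <= 0.05
        assert rejections <= 3

    def test_separated_groups_give_infinite_f_at_minimum_p(self):
        data = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1], [0, 1]],
            index=list("abcd"), columns=["A", "B"]).astype(bool)
        dm = jaccard_distances(make_pa(data))
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=data.index)
        res = permanova(dm, labels, n_perm=99, seed=1)
        assert math.isinf(res.F)
        assert res.p == pytest.approx(1 / 100)

    def test_single_group_is_an_error(self):
        rng = np.random.default_rng(53)
        data = self.profiles(rng, 5)
        dm = jaccard_distances(make_pa(data))
        with pytest.raises(ValueError, match="two groups"):
            permanova(dm, pd.Series(["g"] * 5, index=data.index))

    def test_strata_constraint_enforced_on_every_permutation(self):
        rng = np.random.default_rng(59)
        data = self.profiles(rng, 12)
        site = pd.Series(["S1"] * 6 + ["S2"] * 6, index=data.index)
        labels = pd.Series(rng.choice(["a", "b"], 12), index=data.index)
        labels.iloc[0], labels.iloc[6] = "a", "b"
        pa = make_pa(data, site=site.tolist())
        dm = jaccard_distances(pa)
        # check_strata asserts inside every permutation
        permanova(dm, labels, strata=site, n_perm=99, seed=3, check_strata=True)

    def test_seed_reproducibility_and_cross_seed_stability(self):
        rng = np.random.default_rng(61)
        data = self.profiles(rng, 20)
        labels = pd.Series(rng.choice(["a", "b"], 20), index=data.index)
        if labels.nunique() < 2:
            labels.iloc[0] = "b"
        dm = jaccard_distances(make_pa(data))
        p1 = permanova(dm, labels, n_perm=999, seed=5).p
        p1_again = permanova(dm, labels, n_perm=999, seed=5).p
        p2 = permanova(dm, labels, n_perm=999, seed=6).p
        assert p1 == p1_again
        se = math.sqrt(p1 * (1 - p1) / 999)
        assert abs(p1 - p2) <= max(3 * se * math.sqrt(2), 0.01)


class TestSidakAndBattery:
    def test_printed_cutoff_for_seven_comparisons(self):
        assert round(sidak_cutoff(0.05, 7), 7) == 0.0073008

    def test_no_correction_for_single_comparison(self):
        assert sidak_cutoff(0.05, 1) == pytest.approx(0.05)

    def test_study_shaped_metadata_yields_family_of_seven(self):
        insects = []
        layout = {"Cheilosia": 1, "Eristalis": 6, "Rhingia": 1,
                  "Sericomyia": 2, "Volucella": 1}
        i = 0
        for genus, n_species in layout.items():
            for s in range(n_species):
                for rep in range(3):
                    insects.append({
                        "insect_id": f"i{i}", "genus": genus,
                        "pollinator_species": f"{genus} sp{s}",
                        "site": f"S{rep % 3}"})
                    i += 1
        meta = pd.DataFrame(insects).set_index("insect_id")
        contrasts = default_contrast_battery(meta)
        assert len(contrasts) == 7  # 5 one-vs-rest + 2 within-genus

    def test_battery_flags_against_the_corrected_cutoff(self):
        rng = np.random.default_rng(67)
        n = 24
        data = pd.DataFrame(rng.random((n, 8)) < 0.4,
                            index=[f"i{j}" for j in range(n)])
        data.iloc[:, 0] = True
        genus = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        # make genus A strongly distinct
        data.iloc[:8, 1:4] = True
        data.iloc[8:, 1:4] = False
        pa = make_pa(data, genus=genus)
        meta = pa.insects
        dm = jaccard_distances(pa)
        suite = run_contrast_battery(dm, default_contrast_battery(meta),
                                     alpha=0.05, n_perm=199, seed=2)
        assert suite.k == 3
        assert suite.sidak_cutoff == pytest.approx(sidak_cutoff(0.05, 3))
        for name, res in suite.results.items():
            assert suite.significant[name] == (res.p < suite.sidak_cutoff)
        assert suite.significant["A vs rest"]

    def test_p_just_above_cutoff_is_not_significant(self):
        # the corrected cutoff for 7 tests rejects p = 0.013
        assert not 0.013 < sidak_cutoff(0.05, 7)


class TestKruskalWallis:
    def test_no_tie_textbook_value(self):
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.H == pytest.approx(2.4)
        assert res.df == 1

    def test_tied_identical_groups_are_null(self):
        res = kruskal_wallis([[1, 2], [1, 2]])
        assert res.H == pytest.approx(0.0)
        assert res.p > 0.5

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([[2, 2], [2, 2]])

    def test_matches_direct_formula_with_ties(self):
        rng = np.random.default_rng(71)
        for _ in range(50):
            groups = [rng.integers(0, 6, size=rng.integers(2, 6)).tolist()
                      for _ in range(rng.integers(2, 5))]
            flat = [v for g in groups for v in g]
            if len(set(flat)) < 2:
                continue
            res = kruskal_wallis(groups)
            h_direct, df = oracles.kruskal_wallis_formula(groups)
            assert res.H == pytest.approx(h_direct, abs=1e-9)
            assert res.df == df
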