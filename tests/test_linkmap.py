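"""Segregation screen, two-point linkage statistics, grouping and ordering."""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sporemap.genotyper import GenotypeMatrix
from sporemap.linkmap import (
    LinkageMap,
    MapParams,
    PairTable,
    build_map,
    form_groups,
    lod_score,
    map_distance,
    order_markers,
    pairwise_linkage_table,
    pairwise_rf,
    segregation_screen,
)
from sporemap.simdata import SimConfig, simulate_meiosis, simulate_parents, truth_to_matrix


def matrix_from_codes(rows: dict[str, str]) -> GenotypeMatrix:
    """Build a matrix from strings of codes, one per marker."""
    markers = list(rows)
    isolates = [f"I{i + 1}" for i in range(len(next(iter(rows.values()))))]
    codes = pd.DataFrame(
        [list(v) for v in rows.values()], index=markers, columns=isolates
    )
    return GenotypeMatrix(
        codes=codes,
        n_a=(codes == "A").astype(int),
        n_b=(codes == "B").astype(int),
    )


@pytest.fixture(scope="module")
def truth_matrix():
    """Full-information genotypes: 2 chromosomes, 20 markers, 100 isolates."""
    cfg = SimConfig(n_chromosomes=2, chrom_genetic_lengths=(60.0, 60.0),
                    n_scaffolds=20, scaffold_lengths=8000, n_isolates=100,
                    coverage=1.0, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = simulate_parents(cfg)
    t = simulate_meiosis(cfg, g.scaffold_map)
    return truth_to_matrix(t, g.scaffold_map["length_bp"].to_dict()), g.scaffold_map


class TestSegregationScreen:
    def test_perfect_1_to_1_retained(self):
        m = matrix_from_codes({"M1": "AB" * 10})
        res = segregation_screen(m)
        row = res.loc["M1"]
        assert row.chi2 == 0.0 and row.p_value == 1.0 and row.retained

    def test_distorted_marker_rejected(self):
        # 18 A / 2 B: chi2 = (18-10)^2/10 + (2-10)^2/10 = 12.8
        m = matrix_from_codes({"M1": "A" * 18 + "B" * 2})
        row = segregation_screen(m, alpha=0.05).loc["M1"]
        assert row.chi2 == pytest.approx(12.8)
        assert row.p_value == pytest.approx(stats.chi2.sf(12.8, 1))
        assert row.p_value == pytest.approx(3.47e-4, rel=0.01)
        assert not row.retained

    def test_uninformative_marker_flagged(self):
        m = matrix_from_codes({"M1": "X-" * 10, "M2": "A" + "-" * 19})
        res = segregation_screen(m)
        assert not res.loc["M1"].retained  # zero informative calls
        assert not res.loc["M2"].retained  # a single call is uninformative


class TestPairwiseLinkage:
    def test_identical_vectors_give_lod_n_log2(self):
        m = matrix_from_codes({"M1": "AB" * 10, "M2": "AB" * 10})
        pl = pairwise_rf(m, "M1", "M2")
        assert (pl.n, pl.r_count, pl.r_hat) == (20, 0, 0.0)
        assert pl.lod == pytest.approx(20 * math.log10(2))  # 6.0206

    def test_four_recombinants_of_twenty(self):
        # r_hat = 0.2, LOD = 4 log10(0.4) + 16 log10(1.6) = 1.674
        v1 = "AB" * 10
        v2 = "BABA" + v1[4:]  # flip first 4 calls
        m = matrix_from_codes({"M1": v1, "M2": v2})
        pl = pairwise_rf(m, "M1", "M2")
        assert (pl.n, pl.r_count) == (20, 4)
        # independent likelihood-ratio evaluation of the same quantity
        r = 0.2
        ll_r = 4 * math.log10(r) + 16 * math.log10(1 - r)
        ll_half = 20 * math.log10(0.5)
        assert pl.lod == pytest.approx(ll_r - ll_half) == pytest.approx(1.674, abs=5e-4)

    def test_free_recombination_gives_zero_lod(self):
        v1 = "A" * 10 + "B" * 10
        v2 = "A" * 5 + "B" * 10 + "A" * 5
        m = matrix_from_codes({"M1": v1, "M2": v2})
        pl = pairwise_rf(m, "M1", "M2")
        assert pl.r_hat == 0.5 and pl.lod == 0.0

    def test_missing_codes_excluded_and_n_min_enforced(self):
        m = matrix_from_codes({"M1": "ABX-AB", "M2": "AB--AB"})
        pl = pairwise_rf(m, "M1", "M2")
        assert pl.n == 4
        assert pl.lod == 0.0  # below n_min = 5
        with pytest.raises(KeyError):
            pairwise_rf(m, "M1", "nope")

    def test_vectorised_table_matches_per_pair(self, truth_matrix):
        m, _ = truth_matrix
        markers = m.markers[:8]
        table = pairwise_linkage_table(m, markers)
        for i, j in itertools.combinations(range(len(markers)), 2):
            pl = pairwise_rf(m, markers[i], markers[j])
            assert table.n[i, j] == pl.n
            assert table.r_count[i, j] == pl.r_count
            assert table.lod[i, j] == pytest.approx(pl.lod)

    def test_lod_nonnegative_at_mle(self):
        for n in (5, 10, 40):
            for r_count in range(n + 1):
                assert lod_score(n, r_count) >= 0.0


class TestMapDistance:
    def test_closed_forms(self):
        assert map_distance(0.0) == 0.0
        assert map_distance(0.2, "kosambi") == pytest.approx(25 * math.log(1.4 / 0.6))
        assert map_distance(0.2, "kosambi") == pytest.approx(21.18, abs=0.005)
        assert map_distance(0.25, "kosambi") == pytest.approx(27.47, abs=0.005)
        assert map_distance(0.25, "haldane") == pytest.approx(34.66, abs=0.005)

    def test_unlinked_is_infinite(self):
        assert map_distance(0.5) == math.inf
        assert map_distance(0.7) == math.inf

    def test_monotone_and_kosambi_below_haldane(self):
        rs = np.linspace(0.001, 0.499, 200)
        k = [map_distance(r, "kosambi") for r in rs]
        h = [map_distance(r, "haldane") for r in rs]
        assert all(a < b for a, b in zip(k, k[1:]))
        assert all(a <= b for a, b in zip(k, h))

    def test_small_r_linear_regime(self):
        for r in (0.001, 0.005, 0.01):
            assert map_distance(r, "kosambi") == pytest.approx(100 * r, rel=0.01)


def _chain_table(markers, r_by_pair, n=50):
    """PairTable with specified r (and LOD from closed form) for listed pairs."""
    k = len(markers)
    N = np.full((k, k), n)
    R = np.zeros((k, k))
    r_hat = np.full((k, k), 0.5)
    lod = np.zeros((k, k))
    for (i, j), r in r_by_pair.items():
        rc = round(r * n)
        for a, b in ((i, j), (j, i)):
            R[a, b] = rc
            r_hat[a, b] = rc / n
            lod[a, b] = lod_score(n, rc)
    np.fill_diagonal(r_hat, 0.0)
    return PairTable(markers=list(markers), n=N, r_count=R.astype(int), r_hat=r_hat, lod=lod)


class TestFormGroups:
    def test_transitive_chain_forms_one_group(self):
        # A-B and B-C tightly linked, A-C only through transitivity
        t = _chain_table(["A", "B", "C"], {(0, 1): 0.05, (1, 2): 0.05, (0, 2): 0.10})
        groups, singles = form_groups(t)
        assert groups == [["A", "B", "C"]] and singles == []

    def test_both_conditions_required(self):
        # strong LOD but 30 cM apart -> not grouped
        t = _chain_table(["A", "B"], {(0, 1): 0.27}, n=100)  # kosambi(0.27) = 30.2 cM
        assert t.lod[0, 1] >= 3
        groups, singles = form_groups(t)
        assert groups == [] and singles == ["A", "B"]

    def test_input_order_and_label_swap_invariance(self, truth_matrix):
        m, _ = truth_matrix
        t1 = pairwise_linkage_table(m, m.markers)
        perm = list(np.random.default_rng(1).permutation(m.markers))
        t2 = pairwise_linkage_table(m, perm)
        t3 = pairwise_linkage_table(m.swapped_labels(), m.markers)
        g1, _ = form_groups(t1)
        g2, _ = form_groups(t2)
        g3, _ = form_groups(t3)
        assert g1 == g2 == g3

    def test_single_linkage_separation(self, truth_matrix):
        """No cross-group pair satisfies both the LOD and the gap condition."""
        m, _ = truth_matrix
        params = MapParams()
        t = pairwise_linkage_table(m, m.markers)
        groups, singles = form_groups(t, params)
        member = {mk: gi for gi, g in enumerate(groups) for mk in g}
        for i, mi in enumerate(t.markers):
            for j, mj in enumerate(t.markers):
                if i >= j or member.get(mi) == member.get(mj):
                    continue
                linked = (
                    t.lod[i, j] >= params.lod_min
                    and map_distance(t.r_hat[i, j]) <= params.max_gap_cm
                )
                assert not linked


class TestOrderMarkers:
    def test_recovers_true_order_up_to_reversal(self, truth_matrix):
        m, smap = truth_matrix
        params = MapParams()
        lmap = build_map(m, params)
        for lg in lmap.groups:
            true_pos = smap.loc[lg.markers, "cm_mid"].to_numpy()
            assert (np.diff(true_pos) > 0).all() or (np.diff(true_pos) < 0).all()

    def test_two_marker_group(self):
        t = _chain_table(["B", "A"], {(0, 1): 0.1})
        ordered, pos = order_markers(["B", "A"], t)
        assert ordered == ["A", "B"]  # lexicographically smaller terminal first
        assert pos == [0.0, pytest.approx(map_distance(0.1))]

    def test_dp_matches_factorial_enumeration(self):
        """Held-Karp order equals brute-force minimum SARF on random instances."""
        rng = np.random.default_rng(5)
        for trial in range(20):
            k = int(rng.integers(4, 9))
            d = np.round(rng.uniform(1, 30, size=(k, k)), 3)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            markers = [f"M{i}" for i in range(k)]
            t = PairTable(markers=markers, n=np.full((k, k), 50),
                          r_count=np.zeros((k, k), dtype=int),
                          r_hat=np.full((k, k), 0.1), lod=np.full((k, k), 9.0))
            # feed the distance matrix through r: invert kosambi numerically
            r = (np.exp(d / 25.0) - 1) / (2 * (np.exp(d / 25.0) + 1))
            np.fill_diagonal(r, 0.0)
            t.r_hat = r
            ordered, pos = order_markers(markers, t)
            got = pos[-1]
            best = min(
                sum(d[p[i], p[i + 1]] for i in range(k - 1))
                for p in itertools.permutations(range(k))
            )
            assert got == pytest.approx(best, rel=1e-6)

    def test_singleton_group_rejected(self):
        t = _chain_table(["A"], {})
        with pytest.raises(ValueError):
            order_markers(["A"], t)


class TestBuildMap:
    def test_end_to_end_recovery(self, truth_matrix):
        m, smap = truth_matrix
        lmap = build_map(m)
        # most seeds recover the two simulated chromosomes
        assert 2 <= len(lmap.groups) <= 4
        assert lmap.total_length_cm > 0

    def test_deterministic(self, truth_matrix):
        m, _ = truth_matrix
        m1, m2 = build_map(m), build_map(m)
        assert [g.markers for g in m1.groups] == [g.markers for g in m2.groups]
        for a, b in zip(m1.groups, m2.groups):
            assert a.positions == b.positions

    def test_too_few_retained_markers(self):
        m = matrix_from_codes({"M1": "A" * 20, "M2": "A" * 19 + "B"})
        with pytest.raises(ValueError, match="segregation screen"):
            build_map(m)

    def test_headline_and_minor_groups_partition(self, truth_matrix):
        m, _ = truth_matrix
        lmap = build_map(m)
        assert set(g.name for g in lmap.headline_groups()) | set(
            g.name for g in lmap.minor_groups()
        ) == set(g.name for g in lmap.groups)
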