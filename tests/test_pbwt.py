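"""PBWT construction and msh extraction against the brute-force oracle."""

import numpy as np
import pytest

from mshtc import (brute_force_msh, build_pbwt, msh_at_position,
                   msh_multicopy, msh_singleton)


def random_matrix(rng, max_rows=50, max_sites=200):
    from tests.conftest import make_matrix

    rows = int(rng.integers(2, max_rows + 1))
    sites = int(rng.integers(2, max_sites + 1))
    alleles = (rng.random((rows, sites)) <
               rng.uniform(0.05, 0.5)).astype(np.uint8)
    positions = np.sort(rng.choice(np.arange(1, 10 * sites + 1),
                                   size=sites, replace=False))
    return make_matrix(alleles, positions)


def same_tracts(a, b):
    return (a.msh5_bp, a.trunc5, a.term5_pos, a.msh3_bp, a.trunc3,
            a.term3_pos) == (b.msh5_bp, b.trunc5, b.term5_pos, b.msh3_bp,
                             b.trunc3, b.term3_pos)


class TestBuildPbwt:
    def test_single_row(self):
        arrays = build_pbwt(np.array([[0, 1, 0]], dtype=np.uint8))
        assert arrays.a.shape == (4, 1)
        np.testing.assert_array_equal(arrays.a, 0)
        # sole row of each group carries the sentinel (column index)
        np.testing.assert_array_equal(arrays.d[:, 0], [0, 1, 2, 3])

    def test_three_by_two_matches_hand_run(self):
        # hand execution of Durbin's algorithm 2 on ((0,0),(0,1),(1,0))
        alleles = np.array([[0, 0], [0, 1], [1, 0]], dtype=np.uint8)
        arrays = build_pbwt(alleles)
        np.testing.assert_array_equal(arrays.a,
                                      [[0, 1, 2], [0, 1, 2], [0, 2, 1]])
        np.testing.assert_array_equal(arrays.d,
                                      [[0, 0, 0], [1, 0, 1], [2, 1, 2]])

    def test_divergence_marks_suffix_agreement(self, rng):
        # consecutive rows in a-order agree on columns d..k-1 and (when
        # d > 0) disagree at column d-1
        for _ in range(20):
            mat = random_matrix(rng, max_rows=20, max_sites=50)
            arrays = build_pbwt(mat.alleles)
            for k in range(1, mat.n_sites + 1):
                a, d = arrays.a[k], arrays.d[k]
                for i in range(1, mat.n_rows):
                    r, s = a[i - 1], a[i]
                    start = d[i]
                    assert np.array_equal(mat.alleles[r, start:k],
                                          mat.alleles[s, start:k])
                    if start > 0:
                        assert mat.alleles[r, start - 1] != \
                            mat.alleles[s, start - 1]

    def test_columns_are_permutations(self, rng):
        mat = random_matrix(rng, max_rows=30, max_sites=60)
        arrays = build_pbwt(mat.alleles)
        ref = np.arange(mat.n_rows)
        for k in range(mat.n_sites + 1):
            np.testing.assert_array_equal(np.sort(arrays.a[k]), ref)


class TestMshSingleton:
    def setup_fixture(self, row1_last):
        from tests.conftest import make_matrix

        # 4 rows, 5 sites at bp 10..50, focal row 0 singleton at bp 30;
        # row 1 matches row 0 except (maybe) at bp 50;
        # rows 2-3 differ at bp 10 and 50
        alleles = np.array([
            [0, 0, 1, 0, 0],
            [0, 0, 0, 0, row1_last],
            [1, 0, 0, 0, 1],
            [1, 0, 0, 0, 1],
        ], dtype=np.uint8)
        mat = make_matrix(alleles, np.array([10, 20, 30, 40, 50]))
        return mat, build_pbwt(alleles), build_pbwt(alleles[:, ::-1])

    def test_best_match_reaches_both_chromosome_ends(self):
        mat, fwd, rev = self.setup_fixture(row1_last=0)
        o = msh_singleton(mat, fwd, rev, 0, 2)
        assert o.trunc5 and o.trunc3
        assert (o.partner5, o.partner3) == (1, 1)
        ref = brute_force_msh(mat, 0, 2)
        assert same_tracts(o, ref)

    def test_mismatch_at_last_site_ends_msh3(self):
        mat, fwd, rev = self.setup_fixture(row1_last=1)
        o = msh_singleton(mat, fwd, rev, 0, 2)
        assert o.trunc5 and not o.trunc3
        assert o.term3_pos == 50 and o.msh3_bp == 20
        assert same_tracts(o, brute_force_msh(mat, 0, 2))

    def test_two_rows_both_directions_truncated(self):
        from tests.conftest import make_matrix

        mat = make_matrix(np.array([[0, 1, 0], [0, 0, 0]], dtype=np.uint8))
        fwd, rev = build_pbwt(mat.alleles), build_pbwt(mat.alleles[:, ::-1])
        o = msh_singleton(mat, fwd, rev, 0, 1)
        assert o.trunc5 and o.trunc3

    def test_non_carrier_rejected(self):
        mat, fwd, rev = self.setup_fixture(row1_last=0)
        with pytest.raises(ValueError):
            msh_singleton(mat, fwd, rev, 1, 2)


class TestMshMulticopy:
    def test_symmetric_doubleton_gives_identical_tracts(self):
        from tests.conftest import make_matrix

        alleles = np.array([
            [0, 1, 0],
            [0, 1, 0],
            [0, 0, 0],
            [0, 0, 0],
        ], dtype=np.uint8)
        mat = make_matrix(alleles)
        fwd, rev = build_pbwt(alleles), build_pbwt(alleles[:, ::-1])
        a, b = msh_multicopy(mat, fwd, rev, 1)
        assert (a.msh5_bp, a.msh3_bp) == (b.msh5_bp, b.msh3_bp)
        assert (a.trunc5, a.trunc3) == (b.trunc5, b.trunc3)

    def test_directions_can_use_different_non_carriers(self):
        from tests.conftest import make_matrix

        # carrier row 0: best 5' match is row 2, best 3' match is row 3
        alleles = np.array([
            [0, 0, 1, 0, 0],
            [1, 1, 1, 1, 1],
            [0, 0, 0, 0, 1],   # matches 5' side, breaks at bp 50
            [1, 0, 0, 0, 0],   # breaks at bp 10, matches 3' side
            [1, 1, 0, 1, 1],
        ], dtype=np.uint8)
        mat = make_matrix(alleles, np.array([10, 20, 30, 40, 50]))
        fwd, rev = build_pbwt(alleles), build_pbwt(alleles[:, ::-1])
        (obs0, obs1) = msh_multicopy(mat, fwd, rev, 2, carriers=[0, 1])
        assert obs0.partner5 == 2 and obs0.partner3 == 3
        assert obs0.trunc5 and obs0.trunc3
        ref = brute_force_msh(mat, 0, 2, exclude_rows=[0, 1])
        assert same_tracts(obs0, ref)

    def test_all_rows_carry_raises(self):
        from tests.conftest import make_matrix

        mat = make_matrix(np.array([[1, 1], [1, 0]], dtype=np.uint8))
        fwd, rev = build_pbwt(mat.alleles), build_pbwt(mat.alleles[:, ::-1])
        with pytest.raises(ValueError):
            msh_multicopy(mat, fwd, rev, 0)


class TestBruteForce:
    def test_duplicate_focal_row_truncates_both_ends(self):
        from tests.conftest import make_matrix

        alleles = np.array([
            [1, 1, 0, 1],
            [1, 0, 0, 1],   # identical to row 0 off the focal column
            [0, 0, 1, 0],
        ], dtype=np.uint8)
        mat = make_matrix(alleles)
        o = brute_force_msh(mat, 0, 1)
        assert o.trunc5 and o.trunc3

    def test_exclude_all_but_one_is_pairwise(self):
        from tests.conftest import make_matrix

        alleles = np.array([
            [0, 1, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 0, 1],
        ], dtype=np.uint8)
        mat = make_matrix(alleles, np.array([5, 15, 25, 35]))
        o = brute_force_msh(mat, 0, 1, exclude_rows=[2])
        assert o.term5_pos == 5 and not o.trunc5
        assert o.trunc3


class TestOracleEquivalence:
    @pytest.mark.parametrize("convention", ["mismatch", "match"])
    def test_pbwt_equals_brute_force_on_random_matrices(self, rng,
                                                        convention):
        checked = 0
        for _ in range(60):
            mat = random_matrix(rng)
            fwd = build_pbwt(mat.alleles)
            rev = build_pbwt(mat.alleles[:, ::-1])
            sites = rng.choice(mat.n_sites, size=min(4, mat.n_sites),
                               replace=False)
            for site in sites:
                carriers = np.flatnonzero(mat.alleles[:, site])
                if carriers.size in (0, mat.n_rows):
                    continue
                if carriers.size == 1:
                    observations = [msh_singleton(mat, fwd, rev,
                                                  int(carriers[0]),
                                                  int(site),
                                                  convention=convention)]
                else:
                    observations = msh_multicopy(mat, fwd, rev, int(site),
                                                 carriers,
                                                 convention=convention)
                for o in observations:
                    ref = brute_force_msh(mat, o.row, int(site),
                                          exclude_rows=carriers.tolist(),
                                          convention=convention)
                    assert same_tracts(o, ref)
                    checked += 1
        assert checked > 100

    def test_match_convention_is_one_interval_shorter(self):
        from tests.conftest import make_matrix

        alleles = np.array([
            [0, 0, 1, 0, 0],
            [0, 0, 0, 0, 1],
            [1, 0, 0, 0, 1],
        ], dtype=np.uint8)
        mat = make_matrix(alleles, np.array([10, 20, 30, 40, 50]))
        fwd, rev = build_pbwt(alleles), build_pbwt(alleles[:, ::-1])
        by_mismatch = msh_singleton(mat, fwd, rev, 0, 2,
                                    convention="mismatch")
        by_match = msh_singleton(mat, fwd, rev, 0, 2, convention="match")
        # 3' tract vs row 1 ends at bp 50; last matching site is bp 40
        assert by_mismatch.term3_pos == 50 and by_mismatch.msh3_bp == 20
        assert by_match.term3_pos == 40 and by_match.msh3_bp == 10

    def test_virtual_position_query_matches_oracle(self, rng):
        # querying between columns equals an oracle scan that ignores
        # no extra sites
        from tests.conftest import make_matrix

        for _ in range(20):
            mat = random_matrix(rng, max_rows=20, max_sites=60)
            fwd = build_pbwt(mat.alleles)
            rev = build_pbwt(mat.alleles[:, ::-1])
            row = int(rng.integers(mat.n_rows))
            site = int(rng.integers(mat.n_sites))
            pos = int(mat.positions[site])
            o = msh_at_position(mat, fwd, rev, row, pos)
            # oracle: same matrix with the focal column zeroed for "row"
            alleles = mat.alleles.copy()
            alleles[:, site] = 0
            alleles[row, site] = 1
            mat2 = make_matrix(alleles, mat.positions)
            ref = brute_force_msh(mat2, row, site)
            assert same_tracts(o, ref)


class TestMonotoneRefinement:
    def test_adding_a_row_never_shortens_msh(self, rng):
        from tests.conftest import make_matrix

        for _ in range(20):
            mat = random_matrix(rng, max_rows=20, max_sites=60)
            site = int(rng.integers(mat.n_sites))
            alleles = mat.alleles.copy()
            alleles[:, site] = 0
            alleles[0, site] = 1  # force a singleton focal
            new_row = (rng.random(mat.n_sites) < 0.3).astype(np.uint8)
            new_row[site] = 0
            small = make_matrix(alleles, mat.positions)
            big = make_matrix(np.vstack([alleles, new_row]), mat.positions)
            o_small = brute_force_msh(small, 0, site)
            o_big = brute_force_msh(big, 0, site)
            assert o_big.msh5_bp >= o_small.msh5_bp
            assert o_big.msh3_bp >= o_small.msh3_bp


class TestComplexity:
    def test_runtime_roughly_linear_in_rows(self, rng):
        import time

        sites = 300
        times = {}
        for rows in (100, 400):
            alleles = (rng.random((rows, sites)) < 0.2).astype(np.uint8)
            t0 = time.perf_counter()
            build_pbwt(alleles)
            times[rows] = time.perf_counter() - t0
        # 4x rows should cost well under 4x^2; generous bound for noise
        assert times[400] < 16 * max(times[100], 1e-4)
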