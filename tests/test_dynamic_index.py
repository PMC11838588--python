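"""End-to-end behaviour of the dynamic index: build, edits, reconstruction."""

import numpy as np
import pytest

from pbwtree.boundary_samples import BOTTOM
from pbwtree.dynamic_index import DynIndex
from pbwtree.pbwt_oracle import DensePBWT

from conftest import example_panel, random_panel, random_query


class TestBuild:
    def test_worked_example_column(self):
        idx = DynIndex.from_panel(example_panel(), t=2)
        col = idx.columns[1]
        assert col.bits() == [int(c) for c in "00001000010010110000"]
        assert col.n_runs == 9

    def test_single_haplotype_runs(self):
        N = 7
        idx = DynIndex.from_panel(np.ones((1, N), dtype=int), t=2)
        assert all(c.n_runs == 1 for c in idx.columns)
        assert idx.total_runs == N

    def test_columns_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            P = random_panel(rng, int(rng.integers(1, 40)), int(rng.integers(1, 40)))
            idx = DynIndex.from_panel(P, t=int(rng.integers(2, 8)))
            ora = DensePBWT(P)
            for k in range(P.shape[1]):
                assert idx.columns[k].bits() == ora.col_bits(k)
            assert idx.store.a_last == ora.a[P.shape[1]]

    def test_decode_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            P = random_panel(rng, int(rng.integers(1, 30)), int(rng.integers(1, 30)))
            idx = DynIndex.from_panel(P, t=3)
            assert (idx.decode_panel() == P).all()

    def test_rejects_bad_panels(self):
        with pytest.raises(ValueError):
            DynIndex.from_panel(np.array([[0, 2]]))
        with pytest.raises(ValueError):
            DynIndex.from_panel(np.zeros(4))


class TestAlleleAccess:
    def test_allele_at_equals_panel(self):
        rng = np.random.default_rng(2)
        P = random_panel(rng, 15, 20)
        idx = DynIndex.from_panel(P, t=3)
        for h in range(15):
            for k in range(20):
                assert idx.allele_at(h, k) == P[h, k]

    def test_constant_panel(self):
        idx = DynIndex.from_panel(np.zeros((4, 5), dtype=int), t=2)
        assert all(idx.allele_at(h, k) == 0 for h in range(4) for k in range(5))

    def test_errors(self):
        idx = DynIndex.from_panel(np.zeros((2, 2), dtype=int), t=2)
        with pytest.raises(IndexError):
            idx.allele_at(2, 0)
        with pytest.raises(IndexError):
            idx.allele_at(0, 2)


class TestVirtualInsert:
    def test_against_dense_insertion(self):
        """(pos, below-id, zStart, tStart) equal a dense build of panel + z."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            M = int(rng.integers(1, 30))
            N = int(rng.integers(1, 30))
            P = random_panel(rng, M, N)
            z = random_query(rng, P)
            idx = DynIndex.from_panel(P, t=3)
            vi = idx.virtual_insert(z)
            ora = DensePBWT(np.vstack([P, z[None, :]]))
            for k in range(N + 1):
                row = ora.row_of[k][M]
                assert vi.t[k][0] == row
                expect_bid = ora.a[k][row + 1] if row + 1 < M + 1 else BOTTOM
                assert vi.t[k][1] == expect_bid
                assert vi.zstart[k] == ora.d[k][row]
                expect_ts = ora.d[k][row + 1] if row + 1 < M + 1 else k
                assert vi.tstart[k] == expect_ts

    def test_duplicate_haplotype_full_match(self):
        P = np.array([[0, 1, 1, 0], [1, 1, 0, 0]])
        idx = DynIndex.from_panel(P, t=2)
        vi = idx.virtual_insert(P[0])
        # the query ties with haplotype 0 and sits directly below it
        for k in range(1, 5):
            assert vi.zstart[k] == 0

    def test_length_mismatch(self):
        idx = DynIndex.from_panel(np.zeros((2, 3), dtype=int), t=2)
        with pytest.raises(ValueError):
            idx.virtual_insert([0, 1])


class TestInsertion:
    def test_insert_into_empty(self):
        idx = DynIndex(4, t=2)
        idx.insert_haplotype([0, 1, 1, 0])
        ref = DynIndex.from_panel(np.array([[0, 1, 1, 0]]), t=2)
        assert idx.same_as(ref)

    def test_insert_equals_rebuild(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            M = int(rng.integers(0, 25))
            N = int(rng.integers(1, 30))
            P = (
                random_panel(rng, M, N)
                if M
                else np.zeros((0, N), dtype=np.int8)
            )
            z = random_query(rng, P) if M else rng.integers(0, 2, N)
            idx = DynIndex.from_panel(P, t=3)
            idx.insert_haplotype(z)
            ref = DynIndex.from_panel(
                np.vstack([P, np.asarray(z)[None, :]]), t=3
            )
            assert idx.same_as(ref)
            for c in idx.columns:
                c.tree.validate()

    def test_duplicate_insert(self):
        """Inserting a copy of haplotype h: rebuild equality holds and the
        new haplotype carries a full-length zero divergence somewhere in its
        neighbourhood (it ties h through every column)."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            P = random_panel(rng, 10, 15)
            h = int(rng.integers(0, 10))
            idx = DynIndex.from_panel(P, t=2)
            vi = idx.virtual_insert(P[h])
            # the copy ties its twin at every column: its own divergence or
            # the one of the haplotype below it starts at 0
            assert vi.zstart[15] == 0 or vi.tstart[15] == 0
            idx.insert_haplotype(P[h])
            ref = DynIndex.from_panel(np.vstack([P, P[h][None, :]]), t=2)
            assert idx.same_as(ref)

    def test_run_delta_law_on_insert(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            P = random_panel(rng, int(rng.integers(1, 20)), int(rng.integers(1, 20)))
            idx = DynIndex.from_panel(P, t=3)
            before = [c.n_runs for c in idx.columns]
            idx.insert_haplotype(random_query(rng, P))
            after = [c.n_runs for c in idx.columns]
            assert all(a - b in (0, 1, 2) for a, b in zip(after, before))


class TestDeletion:
    def test_delete_last_haplotype_gives_empty(self):
        idx = DynIndex.from_panel(np.array([[1, 0, 1]]), t=2)
        idx.delete_haplotype(0)
        assert idx.M == 0
        assert all(c.size == 0 for c in idx.columns)

    def test_insert_then_delete_restores(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            M = int(rng.integers(1, 20))
            N = int(rng.integers(1, 25))
            P = random_panel(rng, M, N)
            idx = DynIndex.from_panel(P, t=3)
            before = idx.state()
            idx.insert_haplotype(random_query(rng, P))
            idx.delete_haplotype(M)
            assert idx.state() == before

    def test_delete_equals_rebuild(self):
        """Deletion matches a fresh build with the bottom row moved into the slot."""
        rng = np.random.default_rng(8)
        for _ in range(40):
            M = int(rng.integers(1, 25))
            N = int(rng.integers(1, 30))
            P = random_panel(rng, M, N)
            h = int(rng.integers(0, M))
            idx = DynIndex.from_panel(P, t=3)
            idx.delete_haplotype(h)
            Q = P.copy()
            Q[h] = P[M - 1]
            ref = DynIndex.from_panel(Q[: M - 1], t=3)
            assert idx.same_as(ref)
            for c in idx.columns:
                c.tree.validate()

    def test_run_delta_law_on_bottom_delete(self):
        """Deleting the bottom haplotype is one bit per column: deltas 0/-1/-2."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            M = int(rng.integers(2, 20))
            P = random_panel(rng, M, int(rng.integers(1, 20)))
            idx = DynIndex.from_panel(P, t=3)
            before = [c.n_runs for c in idx.columns]
            idx.delete_haplotype(M - 1)
            after = [c.n_runs for c in idx.columns]
            assert all(a - b in (0, -1, -2) for a, b in zip(after, before))

    def test_errors(self):
        idx = DynIndex.from_panel(np.zeros((2, 2), dtype=int), t=2)
        with pytest.raises(IndexError):
            idx.delete_haplotype(2)
        with pytest.raises(IndexError):
            idx.delete_haplotype(-1)


class TestSerialization:
    def test_round_trip(self):
        rng = np.random.default_rng(10)
        P = random_panel(rng, 12, 18)
        idx = DynIndex.from_panel(P, t=2)
        clone = DynIndex.from_dict(idx.to_dict())
        assert idx.same_as(clone)
        # the clone stays fully functional
        clone.insert_haplotype(rng.integers(0, 2, 18))
        ref = DynIndex.from_panel(
            np.vstack([P, clone.hap_alleles(12)]), t=2
        )
        assert clone.same_as(ref)

    def test_rejects_foreign_payload(self):
        with pytest.raises(ValueError):
            DynIndex.from_dict({"format": "something-else"})


class TestScaling:
    def test_visits_grow_with_runs_not_panel_size(self):
        """Tree-node visits per insertion track log(run count), not M."""
        from pbwtree.panel_io import generate_panel

        import math

        def visits_per_insert(M: int) -> tuple:
            panel = generate_panel(
                M, 48, seed=11, mutation_density=0.01, recomb_rate=0.005
            )
            idx = DynIndex.from_panel(panel, t=4)
            rng = np.random.default_rng(12)
            start = idx.node_visits
            n_ins = 8
            for _ in range(n_ins):
                idx.insert_haplotype(rng.integers(0, 2, 48))
            return (idx.node_visits - start) / n_ins, idx.max_runs

        small, r_small = visits_per_insert(60)
        big, r_big = visits_per_insert(480)
        ratio = big / small
        # the panel grew 8x; visits may only track the log of the run count
        assert ratio < 8 / 2
        assert ratio < 2.5 * math.log(r_big) / math.log(r_small)
        assert r_big < 480  # still in the compressed regime
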