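"""Unit and property tests for the run-length B+ tree."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbwtree.runlen_btree import RunLenTree, RunPair

from conftest import EXAMPLE_COLUMN


def direct_runs(bits) -> int:
    return sum(1 for i, b in enumerate(bits) if i == 0 or b != bits[i - 1])


class TestBuildAndQueries:
    def test_empty(self):
        tree = RunLenTree.from_bits("", t=2)
        assert tree.totals == (0, 0, 0)
        assert tree.decode() == []
        assert tree.first_bit() == 0

    @pytest.mark.parametrize(
        "bits,expected",
        [
            (EXAMPLE_COLUMN, (20, 5, 9)),
            ("0101", (4, 2, 4)),
            ("1", (1, 1, 1)),
            ("0", (1, 0, 1)),
            ("1111", (4, 4, 1)),
        ],
    )
    def test_totals(self, bits, expected):
        tree = RunLenTree.from_bits(bits, t=2)
        assert tuple(tree.totals) == expected
        assert tree.decode_str() == bits
        tree.validate()

    def test_worked_example_rank_and_runs(self):
        tree = RunLenTree.from_bits(EXAMPLE_COLUMN, t=2)
        assert tree.rank_pair(10) == (8, 2)
        assert tree.rank_pair(16) == (11, 5)
        assert tree.rank_pair(0) == (0, 0)
        assert tree.runs_before(10) == 4
        assert tree.runs_before(16) == 8
        assert tree.first_pair() == RunPair(4, 1)
        assert tree.last_pair() == RunPair(4, 0)

    @pytest.mark.parametrize("i,expected", [(4, 1), (19, 0), (0, 0), (15, 1)])
    def test_access_bit(self, i, expected):
        tree = RunLenTree.from_bits(EXAMPLE_COLUMN, t=2)
        assert tree.access_bit(i) == expected

    def test_access_bit_single(self):
        assert RunLenTree.from_bits("1", t=2).access_bit(0) == 1

    @pytest.mark.parametrize("ri,expected", [(0, 0), (1, 4), (8, 16)])
    def test_select_run_head(self, ri, expected):
        tree = RunLenTree.from_bits(EXAMPLE_COLUMN, t=2)
        assert tree.select_run_head(ri) == expected

    def test_runs_before_single_run(self):
        assert RunLenTree.from_bits("0", t=2).runs_before(0) == 0

    def test_errors(self):
        tree = RunLenTree.from_bits("0101", t=2)
        with pytest.raises(IndexError):
            tree.rank_pair(5)
        with pytest.raises(IndexError):
            tree.access_bit(4)
        with pytest.raises(IndexError):
            tree.select_run_head(4)
        with pytest.raises(ValueError):
            RunLenTree.from_bits("012", t=2)
        with pytest.raises(ValueError):
            RunLenTree(t=1)
        with pytest.raises(ValueError):
            tree.insert_bit(0, 2)
        with pytest.raises(IndexError):
            tree.insert_bit(5, 0)
        with pytest.raises(IndexError):
            RunLenTree(t=2).delete_bit(0)


class TestEditCases:
    """The insertion/deletion case contract on run counts."""

    @pytest.mark.parametrize(
        "bits,i,b,decoded,delta",
        [
            ("0000", 2, 1, "00100", 2),  # split an interior run
            ("0000", 2, 0, "00000", 0),  # extend the containing run
            ("0000", 0, 1, "10000", 1),  # new run at the top
            ("0000", 4, 1, "00001", 1),  # new run at the bottom
            ("0011", 2, 1, "00111", 0),  # boundary, joins the following run
            ("0011", 2, 0, "00011", 0),  # boundary, joins the preceding run
            ("1100", 0, 0, "01100", 1),  # zero-run created before leading ones
            ("", 0, 1, "1", 1),
        ],
    )
    def test_insert_cases(self, bits, i, b, decoded, delta):
        tree = RunLenTree.from_bits(bits, t=2)
        assert tree.insert_bit(i, b) == delta
        assert tree.decode_str() == decoded
        tree.validate()

    def test_insert_top_key_shape(self):
        # inserting a one above a leading zero-run creates a [0, 1] first key
        tree = RunLenTree.from_bits("0000", t=2)
        tree.insert_bit(0, 1)
        assert tree.first_pair() == RunPair(0, 1)

    @pytest.mark.parametrize(
        "bits,i,decoded,delta",
        [
            ("00100", 2, "0000", -2),  # interior singleton: flanks merge
            ("00000", 2, "0000", 0),  # decrement inside a long run
            ("10000", 0, "0000", -1),  # singleton at the top
            ("00001", 4, "0000", -1),  # singleton at the bottom
            ("1", 0, "", -1),
            ("0110", 2, "010", 0),  # shrink a length-2 run
        ],
    )
    def test_delete_cases(self, bits, i, decoded, delta):
        tree = RunLenTree.from_bits(bits, t=2)
        assert tree.delete_bit(i) == delta
        assert tree.decode_str() == decoded
        tree.validate()


@settings(deadline=None, max_examples=200)
@given(
    bits=st.lists(st.integers(0, 1), max_size=260),
    t=st.integers(2, 8),
)
def test_round_trip_and_totals(bits, t):
    """decode(build(bits)) == bits and aggregates equal direct counts."""
    tree = RunLenTree.from_bits(bits, t)
    assert tree.decode() == bits
    assert tree.num == len(bits)
    assert tree.ones == sum(bits)
    assert tree.runs == direct_runs(bits)
    tree.validate()


@settings(deadline=None, max_examples=100)
@given(
    bits=st.lists(st.integers(0, 1), min_size=1, max_size=150),
    t=st.integers(2, 5),
)
def test_rank_consistency(bits, t):
    """Adjacent rank deltas agree with access_bit at every position."""
    tree = RunLenTree.from_bits(bits, t)
    z, o = 0, 0
    for i, b in enumerate(bits):
        assert tree.access_bit(i) == b
        z2, o2 = tree.rank_pair(i + 1)
        assert (z2 - z, o2 - o) == ((1, 0) if b == 0 else (0, 1))
        z, o = z2, o2


@settings(deadline=None, max_examples=60)
@given(
    seed=st.integers(0, 2**31 - 1),
    t=st.integers(2, 6),
)
def test_edit_oracle_equivalence(seed, t):
    """Random interleaved edits match a plain list; deltas obey the case law."""
    rng = np.random.default_rng(seed)
    ref = [int(b) for b in rng.integers(0, 2, int(rng.integers(0, 50)))]
    tree = RunLenTree.from_bits(ref, t)
    for _ in range(40):
        if ref and rng.random() < 0.45:
            i = int(rng.integers(0, len(ref)))
            delta = tree.delete_bit(i)
            del ref[i]
            assert delta in (0, -1, -2)
        else:
            i = int(rng.integers(0, len(ref) + 1))
            b = int(rng.integers(0, 2))
            delta = tree.insert_bit(i, b)
            ref.insert(i, b)
            assert delta in (0, 1, 2)
        assert tree.runs == direct_runs(ref)
        assert tree.num == len(ref) and tree.ones == sum(ref)
    assert tree.decode() == ref
    tree.validate()


def test_internal_keys_cumulative():
    """The derived cumulative keys match a fresh recount of the left subtrees."""
    rng = np.random.default_rng(0)
    bits = [int(b) for b in rng.integers(0, 2, 300)]
    tree = RunLenTree.from_bits(bits, t=2)
    root = tree.root
    keys = root.keys()
    assert keys[-1].num <= len(bits)
    # recount by decoding each child subtree prefix
    from pbwtree.runlen_btree import _Internal

    def subtree_bits(node):
        if not isinstance(node, _Internal):
            out = []
            for f, s in node.pairs:
                out += [0] * f + [1] * s
            return out
        return [b for ch in node.children for b in subtree_bits(ch)]

    acc = []
    for key, child in zip(keys, root.children):
        acc += subtree_bits(child)
        assert key.num == len(acc)
        assert key.ones == sum(acc)
        assert key.runs == direct_runs(acc)
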