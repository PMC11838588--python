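"""Count-augmented B+ tree over a run-length encoded binary sequence.

A PBWT column is a binary string whose maximal constant blocks ("runs") are
few when the panel haplotypes are locally similar.  This module stores such a
string as alternating zero-run/one-run length pairs in the leaves of a B+
tree of minimum degree ``t``.  Every node carries the aggregate
``(num, ones, runs)`` of its subtree — total bits, total one-bits, total
runs — so positional rank queries, run lookups and single-bit edits all cost
``O(t log_t r)`` for ``r`` runs, independent of the number of bits.

Leaf key convention
-------------------
A leaf key is a pair ``[f, s]``: ``f`` bits of zeros followed by ``s`` bits
of ones.  Concatenating the keys in leaf order spells the whole sequence.
Alternation is global: ``f == 0`` is permitted only for the very first key
(a sequence that starts with ones) and ``s == 0`` only for the very last key
(a sequence that ends with zeros); a ``[0, 0]`` key never survives an
operation.  Runs therefore never span key or leaf boundaries, which makes
the per-subtree run count well defined.
"""

from __future__ import annotations

from typing import Iterator, List, NamedTuple, Optional, Tuple


class RunPair(NamedTuple):
    """A zero-run of length ``f`` followed by a one-run of length ``s``."""

    f: int
    s: int


class InternalKey(NamedTuple):
    """Cumulative (bits, ones, runs) over the left subtrees of a node."""

    num: int
    ones: int
    runs: int


class _Leaf:
    __slots__ = ("parent", "pairs", "prev", "next", "agg")

    def __init__(self) -> None:
        self.parent: Optional[_Internal] = None
        self.pairs: List[List[int]] = []
        self.prev: Optional[_Leaf] = None
        self.next: Optional[_Leaf] = None
        self.agg: Tuple[int, int, int] = (0, 0, 0)

    def recount(self) -> Tuple[int, int, int]:
        num = ones = runs = 0
        for f, s in self.pairs:
            num += f + s
            ones += s
            runs += (f > 0) + (s > 0)
        return (num, ones, runs)

    @property
    def nkeys(self) -> int:
        return len(self.pairs)


class _Internal:
    __slots__ = ("parent", "children", "agg")

    def __init__(self) -> None:
        self.parent: Optional[_Internal] = None
        self.children: List = []
        self.agg: Tuple[int, int, int] = (0, 0, 0)

    def recount(self) -> Tuple[int, int, int]:
        num = ones = runs = 0
        for ch in self.children:
            a = ch.agg
            num += a[0]
            ones += a[1]
            runs += a[2]
        return (num, ones, runs)

    @property
    def nkeys(self) -> int:
        return len(self.children) - 1

    def keys(self) -> List[InternalKey]:
        """Cumulative keys in the classic B+ layout (one per left subtree)."""
        out, num, ones, runs = [], 0, 0, 0
        for ch in self.children[:-1]:
            a = ch.agg
            num, ones, runs = num + a[0], ones + a[1], runs + a[2]
            out.append(InternalKey(num, ones, runs))
        return out


class RunLenTree:
    """Run-length compressed dynamic bit sequence.

    Parameters
    ----------
    t:
        Minimum degree of the B+ tree (``t >= 2``).  Non-root nodes hold
        between ``t - 1`` and ``2t - 1`` keys; a node is split exactly when
        it holds ``2t - 1`` keys.
    """

    DEFAULT_DEGREE = 8

    def __init__(self, t: int = DEFAULT_DEGREE) -> None:
        if not isinstance(t, int) or t < 2:
            raise ValueError(f"minimum degree t must be an integer >= 2, got {t!r}")
        self.t = t
        self.root = _Leaf()
        #: number of tree nodes touched by descents; instrumentation only.
        self.visits = 0

    # ------------------------------------------------------------------ totals

    @property
    def num(self) -> int:
        """Total number of bits."""
        return self.root.agg[0]

    @property
    def ones(self) -> int:
        """Total number of one-bits."""
        return self.root.agg[1]

    @property
    def zeros(self) -> int:
        return self.root.agg[0] - self.root.agg[1]

    @property
    def runs(self) -> int:
        """Number of maximal constant blocks."""
        return self.root.agg[2]

    @property
    def totals(self) -> InternalKey:
        return InternalKey(*self.root.agg)

    def __len__(self) -> int:
        return self.num

    # ------------------------------------------------------------ construction

    @classmethod
    def from_bits(cls, bits, t: int = DEFAULT_DEGREE) -> "RunLenTree":
        """Bulk-build a tree encoding ``bits`` (any iterable of 0/1 or '0'/'1')."""
        runs: List[List[int]] = []  # [bit, length]
        pos = 0
        for raw in bits:
            if raw in (0, "0"):
                b = 0
            elif raw in (1, "1"):
                b = 1
            else:
                raise ValueError(f"non-binary symbol {raw!r} at position {pos}")
            pos += 1
            if runs and runs[-1][0] == b:
                runs[-1][1] += 1
            else:
                runs.append([b, 1])
        pairs: List[List[int]] = []
        i = 0
        if runs and runs[0][0] == 1:
            pairs.append([0, runs[0][1]])
            i = 1
        while i < len(runs):
            f = runs[i][1]
            if i + 1 < len(runs):
                pairs.append([f, runs[i + 1][1]])
                i += 2
            else:
                pairs.append([f, 0])
                i += 1
        return cls.from_pairs(pairs, t)

    @classmethod
    def from_pairs(cls, pairs, t: int = DEFAULT_DEGREE) -> "RunLenTree":
        """Bulk-build from an explicit list of ``(f, s)`` run pairs."""
        tree = cls(t)
        pairs = [list(p) for p in pairs]
        for idx, (f, s) in enumerate(pairs):
            if f < 0 or s < 0 or (f + s == 0):
                raise ValueError(f"invalid run pair {(f, s)} at key {idx}")
            if f == 0 and idx != 0:
                raise ValueError("zero-length zero-run only allowed in the first key")
            if s == 0 and idx != len(pairs) - 1:
                raise ValueError("zero-length one-run only allowed in the last key")
        if not pairs:
            return tree
        cap = 2 * t - 2  # leave headroom below the 2t-1 split trigger
        lo = t - 1
        chunks = [pairs[i : i + cap] for i in range(0, len(pairs), cap)]
        if len(chunks) > 1 and len(chunks[-1]) < lo:
            need = lo - len(chunks[-1])
            chunks[-1] = chunks[-2][-need:] + chunks[-1]
            chunks[-2] = chunks[-2][:-need]
        leaves: List[_Leaf] = []
        prev: Optional[_Leaf] = None
        for ch in chunks:
            leaf = _Leaf()
            leaf.pairs = ch
            leaf.agg = leaf.recount()
            leaf.prev = prev
            if prev is not None:
                prev.next = leaf
            prev = leaf
            leaves.append(leaf)
        level: List = leaves
        child_cap = 2 * t - 1
        while len(level) > 1:
            groups = [level[i : i + child_cap] for i in range(0, len(level), child_cap)]
            if len(groups) > 1 and len(groups[-1]) < t:
                need = t - len(groups[-1])
                groups[-1] = groups[-2][-need:] + groups[-1]
                groups[-2] = groups[-2][:-need]
            nxt: List = []
            for g in groups:
                node = _Internal()
                node.children = g
                for c in g:
                    c.parent = node
                node.agg = node.recount()
                nxt.append(node)
            level = nxt
        tree.root = level[0]
        tree.root.parent = None
        return tree

    # ----------------------------------------------------------------- queries

    def _find_leaf(self, i: int) -> Tuple[_Leaf, int]:
        """Descend to the leaf holding bit ``i`` (``i == num`` lands past-end)."""
        node = self.root
        while isinstance(node, _Internal):
            self.visits += 1
            for ch in node.children[:-1]:
                if i < ch.agg[0]:
                    node = ch
                    break
                i -= ch.agg[0]
            else:
                node = node.children[-1]
        self.visits += 1
        return node, i

    @staticmethod
    def _locate(leaf: _Leaf, li: int) -> Tuple[int, str, int]:
        """Within-leaf position: (key index, 'f' or 's', offset in that run)."""
        for j, (f, s) in enumerate(leaf.pairs):
            if li < f:
                return j, "f", li
            li -= f
            if li < s:
                return j, "s", li
            li -= s
        raise IndexError("bit offset beyond leaf")

    def rank_pair(self, i: int) -> Tuple[int, int]:
        """Return ``(zeros, ones)`` strictly before bit position ``i``.

        ``i`` may equal the total bit count, giving the column totals.
        """
        if not 0 <= i <= self.num:
            raise IndexError(f"rank index {i} out of range 0..{self.num}")
        node = self.root
        zeros = ones = 0
        while isinstance(node, _Internal):
            self.visits += 1
            for ch in node.children[:-1]:
                if i < ch.agg[0]:
                    node = ch
                    break
                i -= ch.agg[0]
                zeros += ch.agg[0] - ch.agg[1]
                ones += ch.agg[1]
            else:
                node = node.children[-1]
        self.visits += 1
        for f, s in node.pairs:
            if i < f:
                zeros += i
                return zeros, ones
            i -= f
            zeros += f
            if i < s:
                ones += i
                return zeros, ones
            i -= s
            ones += s
        return zeros, ones  # i == num

    def access_bit(self, i: int) -> int:
        """The ``i``-th bit of the decoded sequence."""
        if not 0 <= i < self.num:
            raise IndexError(f"bit index {i} out of range 0..{self.num - 1}")
        leaf, li = self._find_leaf(i)
        _, part, _ = self._locate(leaf, li)
        return 0 if part == "f" else 1

    def runs_before(self, i: int) -> int:
        """0-based index of the run containing bit ``i`` (= complete runs before it)."""
        if not 0 <= i < self.num:
            raise IndexError(f"bit index {i} out of range 0..{self.num - 1}")
        node = self.root
        acc = 0
        while isinstance(node, _Internal):
            self.visits += 1
            for ch in node.children[:-1]:
                if i < ch.agg[0]:
                    node = ch
                    break
                i -= ch.agg[0]
                acc += ch.agg[2]
            else:
                node = node.children[-1]
        self.visits += 1
        for f, s in node.pairs:
            if i < f:
                return acc
            i -= f
            acc += f > 0
            if i < s:
                return acc
            i -= s
            acc += s > 0
        raise IndexError("unreachable")

    def select_run_head(self, run_idx: int) -> int:
        """Bit position of the first bit of run ``run_idx`` (the p_k sample)."""
        if not 0 <= run_idx < self.runs:
            raise IndexError(f"run index {run_idx} out of range 0..{self.runs - 1}")
        node = self.root
        pos = 0
        while isinstance(node, _Internal):
            self.visits += 1
            for ch in node.children[:-1]:
                if run_idx < ch.agg[2]:
                    node = ch
                    break
                run_idx -= ch.agg[2]
                pos += ch.agg[0]
            else:
                node = node.children[-1]
        self.visits += 1
        for f, s in node.pairs:
            if f > 0:
                if run_idx == 0:
                    return pos
                run_idx -= 1
            pos += f
            if s > 0:
                if run_idx == 0:
                    return pos
                run_idx -= 1
            pos += s
        raise IndexError("unreachable")

    def first_pair(self) -> RunPair:
        """Leftmost leaf key (the leading zero-run/one-run of the sequence)."""
        if self.num == 0:
            raise IndexError("empty tree has no keys")
        leaf, _ = self._find_leaf(0)
        return RunPair(*leaf.pairs[0])

    def last_pair(self) -> RunPair:
        """Rightmost leaf key (the trailing zero-run/one-run of the sequence)."""
        if self.num == 0:
            raise IndexError("empty tree has no keys")
        leaf, _ = self._find_leaf(self.num - 1)
        return RunPair(*leaf.pairs[-1])

    def iter_pairs(self) -> Iterator[RunPair]:
        leaf: Optional[_Leaf] = self._leftmost_leaf()
        while leaf is not None:
            for f, s in leaf.pairs:
                yield RunPair(f, s)
            leaf = leaf.next

    def run_lengths(self) -> List[int]:
        """Lengths of the runs in order (first run bit is :meth:`first_bit`)."""
        out: List[int] = []
        for f, s in self.iter_pairs():
            if f > 0:
                out.append(f)
            if s > 0:
                out.append(s)
        return out

    def first_bit(self) -> int:
        """Bit value of the first run (0 for the empty sequence, by convention)."""
        if self.num == 0:
            return 0
        return 1 if self.first_pair().f == 0 else 0

    def decode(self) -> List[int]:
        out: List[int] = []
        for f, s in self.iter_pairs():
            out.extend([0] * f)
            out.extend([1] * s)
        return out

    def decode_str(self) -> str:
        return "".join(str(b) for b in self.decode())

    def _leftmost_leaf(self) -> _Leaf:
        node = self.root
        while isinstance(node, _Internal):
            node = node.children[0]
        return node

    # ------------------------------------------------------------ maintenance

    def _refresh_up(self, node) -> None:
        while node is not None:
            node.agg = node.recount()
            node = node.parent

    def _is_full(self, node) -> bool:
        return node.nkeys >= 2 * self.t - 1

    def _split_child(self, parent: _Internal, j: int) -> None:
        """Split the full child ``parent.children[j]`` in two."""
        t = self.t
        child = parent.children[j]
        if isinstance(child, _Leaf):
            # t - 1 keys after the median move right; the left keeps t keys.
            new = _Leaf()
            new.pairs = child.pairs[t:]
            child.pairs = child.pairs[:t]
            new.next = child.next
            if new.next is not None:
                new.next.prev = new
            child.next = new
            new.prev = child
        else:
            new = _Internal()
            new.children = child.children[t:]
            child.children = child.children[:t]
            for c in new.children:
                c.parent = new
        new.parent = parent
        parent.children.insert(j + 1, new)
        child.agg = child.recount()
        new.agg = new.recount()

    def _find_leaf_splitting(self, i: int) -> Tuple[_Leaf, int]:
        """Descend to bit ``i`` splitting every full node on the way down."""
        if self._is_full(self.root):
            old = self.root
            new_root = _Internal()
            new_root.children = [old]
            old.parent = new_root
            new_root.agg = new_root.recount()
            self.root = new_root
            self._split_child(new_root, 0)
        node = self.root
        while isinstance(node, _Internal):
            self.visits += 1
            j = len(node.children) - 1
            local = i
            for idx, ch in enumerate(node.children[:-1]):
                if local < ch.agg[0]:
                    j = idx
                    break
                local -= ch.agg[0]
            child = node.children[j]
            if self._is_full(child):
                self._split_child(node, j)
                left = node.children[j]
                if local >= left.agg[0]:
                    local -= left.agg[0]
                    j += 1
                child = node.children[j]
            node = child
            i = local
        self.visits += 1
        return node, i

    # ------------------------------------------------------------------- edits

    def insert_bit(self, i: int, b: int) -> int:
        """Splice bit ``b`` in at position ``i``; return the run-count delta.

        The delta is 0 when the bit joins an existing run, +1 when a new run
        appears at the top or bottom of the sequence, and +2 when an existing
        run is split in two.
        """
        if b not in (0, 1):
            raise ValueError(f"bit must be 0 or 1, got {b!r}")
        n = self.num
        if not 0 <= i <= n:
            raise IndexError(f"insert index {i} out of range 0..{n}")
        runs_before_edit = self.runs
        if n == 0:
            self.root = _Leaf() if isinstance(self.root, _Internal) else self.root
            leaf = self.root
            leaf.pairs = [[1, 0]] if b == 0 else [[0, 1]]
            self._refresh_up(leaf)
            return self.runs - runs_before_edit
        prev_bit = self.access_bit(i - 1) if i > 0 else None
        next_bit = self.access_bit(i) if i < n else None
        if prev_bit == b:
            leaf, li = self._find_leaf(i - 1)
            j, part, _ = self._locate(leaf, li)
            leaf.pairs[j][0 if part == "f" else 1] += 1
            self._refresh_up(leaf)
        elif next_bit == b:
            leaf, li = self._find_leaf(i)
            j, part, _ = self._locate(leaf, li)
            leaf.pairs[j][0 if part == "f" else 1] += 1
            self._refresh_up(leaf)
        elif prev_bit is None:
            # mismatching bit at the very top
            leaf, _ = self._find_leaf_splitting(0)
            if b == 1:
                leaf.pairs.insert(0, [0, 1])
            else:
                leaf.pairs[0][0] = 1  # sequence started with ones: f was 0
            self._refresh_up(leaf)
        elif next_bit is None:
            # mismatching bit at the very bottom
            leaf, _ = self._find_leaf_splitting(n - 1)
            if b == 0:
                leaf.pairs.append([1, 0])
            else:
                leaf.pairs[-1][1] = 1  # sequence ended with zeros: s was 0
            self._refresh_up(leaf)
        else:
            # strictly inside a run of the opposite bit: split it
            leaf, li = self._find_leaf_splitting(i)
            j, part, off = self._locate(leaf, li)
            f, s = leaf.pairs[j]
            if part == "f":
                leaf.pairs[j] = [off, 1]
                leaf.pairs.insert(j + 1, [f - off, s])
            else:
                leaf.pairs[j] = [f, off]
                leaf.pairs.insert(j + 1, [1, s - off])
            self._refresh_up(leaf)
        return self.runs - runs_before_edit

    def delete_bit(self, i: int) -> int:
        """Remove the bit at position ``i``; return the run-count delta.

        The delta is 0 inside a longer run, -1 when a length-1 run vanishes
        at the top or bottom, and -2 when a vanished interior run lets its
        two flanking runs merge.
        """
        n = self.num
        if n == 0:
            raise IndexError("delete from empty tree")
        if not 0 <= i < n:
            raise IndexError(f"delete index {i} out of range 0..{n - 1}")
        runs_before_edit = self.runs
        leaf, li = self._find_leaf(i)
        j, part, _ = self._locate(leaf, li)
        f, s = leaf.pairs[j]
        global_first = leaf.prev is None and j == 0
        global_last = leaf.next is None and j == len(leaf.pairs) - 1
        if part == "f":
            if f > 1:
                leaf.pairs[j][0] -= 1
                self._refresh_up(leaf)
            elif global_first:
                leaf.pairs[j][0] = 0
                if leaf.pairs[j][1] == 0:
                    self._remove_key(leaf, j)
                else:
                    self._refresh_up(leaf)
            else:
                # zero-run vanishes: flanking one-runs merge into the predecessor
                pleaf, pj = self._pred_key(leaf, j)
                pleaf.pairs[pj][1] += s
                self._refresh_up(pleaf)
                self._remove_key(leaf, j)
        else:
            if s > 1:
                leaf.pairs[j][1] -= 1
                self._refresh_up(leaf)
            elif global_last:
                leaf.pairs[j][1] = 0
                if leaf.pairs[j][0] == 0:
                    self._remove_key(leaf, j)
                else:
                    self._refresh_up(leaf)
            else:
                # one-run vanishes: flanking zero-runs merge into the successor
                sleaf, sj = self._succ_key(leaf, j)
                sleaf.pairs[sj][0] += f
                self._refresh_up(sleaf)
                self._remove_key(leaf, j)
        return self.runs - runs_before_edit

    @staticmethod
    def _pred_key(leaf: _Leaf, j: int) -> Tuple[_Leaf, int]:
        if j > 0:
            return leaf, j - 1
        assert leaf.prev is not None
        return leaf.prev, len(leaf.prev.pairs) - 1

    @staticmethod
    def _succ_key(leaf: _Leaf, j: int) -> Tuple[_Leaf, int]:
        if j + 1 < len(leaf.pairs):
            return leaf, j + 1
        assert leaf.next is not None
        return leaf.next, 0

    def _remove_key(self, leaf: _Leaf, j: int) -> None:
        leaf.pairs.pop(j)
        if leaf is self.root or len(leaf.pairs) >= self.t - 1:
            self._refresh_up(leaf)
            return
        self._rebalance_leaf(leaf)

    def _rebalance_leaf(self, leaf: _Leaf) -> None:
        t = self.t
        parent = leaf.parent
        idx = parent.children.index(leaf)
        left = parent.children[idx - 1] if idx > 0 else None
        right = parent.children[idx + 1] if idx + 1 < len(parent.children) else None
        if left is not None and len(left.pairs) > t - 1:
            leaf.pairs.insert(0, left.pairs.pop())
            left.agg = left.recount()
            self._refresh_up(leaf)
            return
        if right is not None and len(right.pairs) > t - 1:
            leaf.pairs.append(right.pairs.pop(0))
            right.agg = right.recount()
            self._refresh_up(leaf)
            return
        # merge with a sibling
        if left is not None:
            survivor, dead, dead_idx = left, leaf, idx
        else:
            survivor, dead, dead_idx = leaf, right, idx + 1
        survivor.pairs.extend(dead.pairs)
        survivor.next = dead.next
        if dead.next is not None:
            dead.next.prev = survivor
        parent.children.pop(dead_idx)
        survivor.agg = survivor.recount()
        self._after_child_removal(parent)

    def _after_child_removal(self, node: _Internal) -> None:
        if node is self.root:
            if len(node.children) == 1:
                self.root = node.children[0]
                self.root.parent = None
                self._refresh_up(self.root)
            else:
                self._refresh_up(node)
            return
        if len(node.children) >= self.t:
            self._refresh_up(node)
            return
        self._rebalance_internal(node)

    def _rebalance_internal(self, node: _Internal) -> None:
        t = self.t
        parent = node.parent
        idx = parent.children.index(node)
        left = parent.children[idx - 1] if idx > 0 else None
        right = parent.children[idx + 1] if idx + 1 < len(parent.children) else None
        if left is not None and len(left.children) > t:
            moved = left.children.pop()
            moved.parent = node
            node.children.insert(0, moved)
            left.agg = left.recount()
            self._refresh_up(node)
            return
        if right is not None and len(right.children) > t:
            moved = right.children.pop(0)
            moved.parent = node
            node.children.append(moved)
            right.agg = right.recount()
            self._refresh_up(node)
            return
        if left is not None:
            survivor, dead, dead_idx = left, node, idx
        else:
            survivor, dead, dead_idx = node, right, idx + 1
        for c in dead.children:
            c.parent = survivor
        survivor.children.extend(dead.children)
        parent.children.pop(dead_idx)
        survivor.agg = survivor.recount()
        self._after_child_removal(parent)

    # -------------------------------------------------------------- validation

    def validate(self) -> None:
        """Check every structural invariant; raise AssertionError on breakage."""
        t = self.t
        leaves: List[_Leaf] = []

        def walk(node, depth: int, is_root: bool) -> int:
            assert node.agg == node.recount(), "stale aggregate"
            if isinstance(node, _Leaf):
                if not is_root:
                    assert t - 1 <= len(node.pairs) <= 2 * t - 1, (
                        f"leaf key count {len(node.pairs)} outside [{t - 1}, {2 * t - 1}]"
                    )
                else:
                    assert len(node.pairs) <= 2 * t - 1
                leaves.append(node)
                return depth
            assert len(node.children) >= 2
            if not is_root:
                assert t <= len(node.children) <= 2 * t, (
                    f"internal child count {len(node.children)} outside [{t}, {2 * t}]"
                )
            else:
                assert len(node.children) <= 2 * t
            depths = set()
            for c in node.children:
                assert c.parent is node, "broken parent pointer"
                depths.add(walk(c, depth + 1, False))
            assert len(depths) == 1, "leaves at unequal depth"
            return depths.pop()

        walk(self.root, 0, True)
        # leaf chain and run alternation
        chain: List[_Leaf] = []
        leaf: Optional[_Leaf] = self._leftmost_leaf()
        prev = None
        while leaf is not None:
            assert leaf.prev is prev
            chain.append(leaf)
            prev, leaf = leaf, leaf.next
        assert chain == leaves, "leaf chain disagrees with tree order"
        flat = [p for lf in leaves for p in lf.pairs]
        for idx, (f, s) in enumerate(flat):
            assert f >= 0 and s >= 0 and f + s >= 1, "degenerate run pair"
            if f == 0:
                assert idx == 0, "zero f outside the first key"
            if s == 0:
                assert idx == len(flat) - 1, "zero s outside the last key"
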