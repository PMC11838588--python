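"""Long-match queries: all matches of length >= L between a query and a panel.

A *long match* between query ``z`` and panel haplotype ``x`` is a maximal
agreement interval ``[s, e)`` with ``e - s >= L`` sites: the alleles agree on
``s..e-1``, and each end is either a mismatch or the panel boundary.

The query algorithm virtually inserts ``z`` (forward FL sweep + backward
divergence sweep) and then walks every column: starting from the query's
insertion point it expands upward via phi and downward via phi-inverse as
long as the running match start — the maximum of the divergence values
crossed — is old enough to leave at least ``L`` matching sites.  A match is
emitted exactly at the column where it stops extending (allele mismatch or
panel end), which makes every report maximal and unique.

The same sweep runs against two index flavours: the editable
:class:`~pbwtree.dynamic_index.DynIndex` and a :class:`StaticIndex` frozen
into plain arrays (no trees), which shares the identical accessor surface.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Dict, List, NamedTuple, Sequence, Set

from .boundary_samples import BOTTOM, TOP, SortedMap
from .dynamic_index import DynIndex, _as_bits, virtual_insert


class Match(NamedTuple):
    """A maximal query/panel match over sites ``[start, end)`` (0-based)."""

    hap_id: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def sort_matches(matches) -> List[Match]:
    """Deterministic report order: by (start, hap_id)."""
    return sorted(matches, key=lambda m: (m.start, m.hap_id, m.end))


def _long_matches(idx, z, L: int) -> Set[Match]:
    N = idx.n_sites
    zb = _as_bits(z, N)
    if not 1 <= L <= N:
        raise ValueError(f"L must be in 1..{N}, got {L}")
    out: Set[Match] = set()
    if idx.n_haps == 0:
        return out
    vi = virtual_insert(idx, zb)
    for k in range(N + 1):
        limit = k - L
        if limit < 0:
            continue
        pos, bid = vi.t[k]
        # upward: rows above the query's insertion point
        if pos > 0:
            h = idx.last_hap(k) if bid == BOTTOM else idx.phi(bid, k)
            s = vi.zstart[k]
            while h != TOP and s <= limit:
                if k == N or idx.hap_alleles(h)[k] != zb[k]:
                    out.add(Match(h, s, k))
                nxt_s = idx.divergence_at(h, k)
                if nxt_s > s:
                    s = nxt_s
                h = idx.phi(h, k)
        # downward: the below-haplotype and the rows under it
        h = bid
        s = vi.tstart[k]
        while h != BOTTOM and s <= limit:
            if k == N or idx.hap_alleles(h)[k] != zb[k]:
                out.add(Match(h, s, k))
            nxt = idx.phi_inv(h, k)
            if nxt == BOTTOM:
                break
            nxt_s = idx.divergence_at(nxt, k)
            if nxt_s > s:
                s = nxt_s
            h = nxt
    return out


def query_long_matches(index: DynIndex, z, L: int) -> Set[Match]:
    """All maximal matches of length >= ``L`` against a dynamic index."""
    return _long_matches(index, z, L)


def query_long_matches_static(index: "StaticIndex", z, L: int) -> Set[Match]:
    """Same contract as :func:`query_long_matches` on a frozen index."""
    return _long_matches(index, z, L)


class _StaticColumn:
    """One frozen run-length column: arrays instead of a tree."""

    __slots__ = ("b", "heads", "zeros_before", "ones_before", "size", "c")

    def __init__(self, first_bit: int, run_lens: List[int]) -> None:
        self.b = first_bit
        self.heads: List[int] = []
        self.zeros_before: List[int] = []
        self.ones_before: List[int] = []
        pos = z = o = 0
        for i, ln in enumerate(run_lens):
            self.heads.append(pos)
            self.zeros_before.append(z)
            self.ones_before.append(o)
            if first_bit ^ (i & 1):
                o += ln
            else:
                z += ln
            pos += ln
        self.size = pos
        self.c = z

    def run_of(self, i: int) -> int:
        if not 0 <= i < self.size:
            raise IndexError(f"row {i} out of range")
        return bisect_right(self.heads, i) - 1

    def bit_at(self, i: int) -> int:
        return self.b ^ (self.run_of(i) & 1)

    def rank_pair(self, i: int):
        if not 0 <= i <= self.size:
            raise IndexError(f"rank index {i} out of range")
        if i == self.size:
            return self.c, self.size - self.c
        ri = self.run_of(i)
        off = i - self.heads[ri]
        if self.b ^ (ri & 1):  # one-run
            return self.zeros_before[ri], self.ones_before[ri] + off
        return self.zeros_before[ri] + off, self.ones_before[ri]

    def fl_map(self, i: int, bit: int) -> int:
        zeros, ones = self.rank_pair(i)
        return zeros if bit == 0 else self.c + ones


class StaticIndex:
    """Immutable run-length PBWT index sharing the query accessor surface.

    Built by freezing a :class:`DynIndex` (or directly from a panel); holds
    per-column run-length arrays with prefix counts plus the same boundary
    samples, but no editable trees.
    """

    def __init__(self) -> None:
        self.M = 0
        self.N = 0
        self.cols: List[_StaticColumn] = []
        self.start_ids: List[List[int]] = []
        self.end_ids: List[List[int]] = []
        self.start_divs: List[List[int]] = []
        self.a_last: List[int] = []
        self._above: Dict[int, SortedMap] = {}
        self._below: Dict[int, SortedMap] = {}
        self._row_cache: Dict[int, List[int]] = {}

    @classmethod
    def from_dynamic(cls, idx: DynIndex) -> "StaticIndex":
        st = idx.store
        out = cls()
        out.M, out.N = idx.M, idx.N
        out.cols = [
            _StaticColumn(c.b, c.tree.run_lengths()) for c in idx.columns
        ]
        out.start_ids = [list(x) for x in st.start_ids]
        out.end_ids = [list(x) for x in st.end_ids]
        out.start_divs = [list(x) for x in st.start_divs]
        out.a_last = list(st.a_last)
        out._above = {h: m.copy() for h, m in st._above.items()}
        out._below = {h: m.copy() for h, m in st._below.items()}
        return out

    @classmethod
    def from_panel(cls, panel, t: int = 8) -> "StaticIndex":
        return cls.from_dynamic(DynIndex.from_panel(panel, t))

    # --------------------------------------------------- accessor surface

    @property
    def n_haps(self) -> int:
        return self.M

    @property
    def n_sites(self) -> int:
        return self.N

    def col_size(self, k: int) -> int:
        return self.cols[k].size

    def fl_map(self, k: int, i: int, bit: int) -> int:
        if bit not in (0, 1):
            raise ValueError(f"bit must be 0 or 1, got {bit!r}")
        return self.cols[k].fl_map(i, bit)

    def bit_at(self, k: int, row: int) -> int:
        return self.cols[k].bit_at(row)

    def n_runs(self, k: int) -> int:
        return len(self.cols[k].heads)

    def run_of(self, k: int, row: int) -> int:
        return self.cols[k].run_of(row)

    def run_bit(self, k: int, ri: int) -> int:
        return self.cols[k].b ^ (ri & 1)

    def run_start_id(self, k: int, ri: int) -> int:
        return self.start_ids[k][ri]

    def last_hap(self, k: int) -> int:
        if k == self.N:
            return self.a_last[-1]
        return self.end_ids[k][-1]

    def phi(self, h: int, k: int) -> int:
        _, (above, _d) = self._above[h].succ_item(k)
        return above

    def phi_inv(self, h: int, k: int) -> int:
        _, below = self._below[h].succ_item(k)
        return below

    def divergence_at(self, h: int, k: int) -> int:
        _, (_a, div) = self._above[h].succ_item(k)
        return div

    def hap_alleles(self, h: int) -> List[int]:
        cached = self._row_cache.get(h)
        if cached is not None:
            return cached
        row = h
        out: List[int] = []
        for k in range(self.N):
            col = self.cols[k]
            b = col.bit_at(row)
            out.append(b)
            row = col.fl_map(row, b)
        self._row_cache[h] = out
        return out
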