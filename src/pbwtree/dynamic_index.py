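"""The dynamic run-length compressed PBWT index.

A :class:`DynIndex` holds one :class:`~pbwtree.dynamic_column.DynamicColumn`
per site plus a :class:`~pbwtree.boundary_samples.BoundaryStore`.  It is
built from a panel in a single left-to-right scan and afterwards supports:

- ``virtual_insert(z)``: where a query haplotype *would* sit in every
  column, and the divergence values it and the haplotype below it would
  have — without modifying the index;
- ``insert_haplotype(z)``: materialize the insertion, updating each
  column's run tree and the boundary samples with a constant number of
  key-level updates per column;
- ``delete_haplotype(h)``: remove a haplotype, merging flanking runs where
  its bits formed singleton runs, then relabel the bottom haplotype into
  the freed id so ids stay in ``0..M-1``;
- ``allele_at`` / ``hap_alleles``: reconstruct panel values from the
  compressed form by walking FL maps (memoized per haplotype).

Insertion works in three sweeps.  Forward: track ``t_k`` — the row where
the new haplotype ``z`` would sit and the id of the haplotype below that
row — via FL extension, starting from the bottom of column 0 (all reverse
prefixes are empty ties there, and ties sort above ``z``).  Backward:
compute ``zStart``/``tStart``, the divergence values of ``z`` and of the
haplotype below it, by allele comparison against the neighbours given by
phi, exploiting that divergence values never decrease from one column to
the next.  Forward again: apply the single-bit tree edit in every column
and patch the touched run boundaries.
"""

from __future__ import annotations

from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .boundary_samples import BOTTOM, TOP, BoundaryStore
from .dynamic_column import DynamicColumn
from .runlen_btree import RunLenTree


def _as_bits(z, n: Optional[int] = None) -> List[int]:
    if isinstance(z, str):
        out = []
        for ch in z:
            if ch not in "01":
                raise ValueError(f"non-binary symbol {ch!r} in haplotype")
            out.append(int(ch))
    else:
        out = [int(b) for b in z]
        if any(b not in (0, 1) for b in out):
            raise ValueError("haplotype must be binary (0/1)")
    if n is not None and len(out) != n:
        raise ValueError(f"haplotype length {len(out)} != panel sites {n}")
    return out


class VirtualInsertion(NamedTuple):
    """Result of virtually inserting a query haplotype.

    ``t[k] = (pos, hap_id)``: the row the query would occupy in column ``k``
    and the id of the haplotype that would sit below it (BOTTOM at the end
    of the column).  ``zstart[k]`` / ``tstart[k]`` are the divergence values
    (match start positions) of the query and of that below-haplotype.
    """

    t: List[Tuple[int, int]]
    zstart: List[int]
    tstart: List[int]


def _below_after_extension(idx, k: int, pos: int, below_id: int, b: int) -> int:
    """Id of the haplotype below the query in column ``k + 1``.

    The query sits at row ``pos`` of column ``k`` with allele ``b``.  The
    haplotype landing directly below it after the FL map is the first
    bit-``b`` row at or after ``pos`` — or, when ``b`` is 0 and no zero row
    remains below, the head of the column's first one-run (all one-rows map
    after every zero-row).  Everything needed is a run-boundary sample.
    """
    n = idx.col_size(k)
    if pos < n and idx.bit_at(k, pos) == b:
        return below_id
    if pos < n:
        ri = idx.run_of(k, pos)  # this run has bit != b; the next has bit b
        if ri + 1 < idx.n_runs(k):
            return idx.run_start_id(k, ri + 1)
        if b == 1:
            return BOTTOM
        return idx.run_start_id(k, 0 if idx.run_bit(k, 0) == 1 else 1)
    if b == 1 or n == 0:
        return BOTTOM
    if idx.run_bit(k, 0) == 1:
        return idx.run_start_id(k, 0)
    if idx.n_runs(k) >= 2:
        return idx.run_start_id(k, 1)
    return BOTTOM  # all-zero column


def virtual_insert(idx, z, at: Optional[Tuple[int, int]] = None) -> VirtualInsertion:
    """Compute insert positions and divergence values for query ``z``.

    Works against any index exposing the compressed accessor surface
    (:class:`DynIndex` or the frozen index in :mod:`pbwtree.match_query`).

    ``at`` overrides the starting position ``(pos, below_id)`` in column 0.
    The default — the bottom of the column, below all the (tied) empty
    reverse prefixes — is what queries and ordinary insertions use; the
    deletion algorithm reinserts the bottom haplotype at an interior slot
    to reproduce the tie order of a from-scratch build.
    """
    N = idx.n_sites
    M = idx.n_haps
    zb = _as_bits(z, N)
    pos, bid = (M, BOTTOM) if at is None else at
    t: List[Tuple[int, int]] = [(pos, bid)]
    for k in range(N):
        b = zb[k]
        nxt = _below_after_extension(idx, k, pos, bid, b) if M else BOTTOM
        pos = idx.fl_map(k, pos, b)
        t.append((pos, nxt))
        bid = nxt
    zstart = [N] * (N + 1)
    tstart = [N] * (N + 1)
    ez = et = N
    for k in range(N, -1, -1):
        pk, bk = t[k]
        if pk == 0:
            ez = k  # query at the top: empty match above
        else:
            above = idx.last_hap(k) if bk == BOTTOM else idx.phi(bk, k)
            row = idx.hap_alleles(above)
            if ez > k:
                ez = k
            while ez > 0 and zb[ez - 1] == row[ez - 1]:
                ez -= 1
        zstart[k] = ez
        if bk == BOTTOM:
            et = k  # nothing below the query
        else:
            row = idx.hap_alleles(bk)
            if et > k:
                et = k
            while et > 0 and zb[et - 1] == row[et - 1]:
                et -= 1
        tstart[k] = et
    return VirtualInsertion(t, zstart, tstart)


class DynIndex:
    """Dynamic run-length compressed PBWT of an ``M x N`` binary panel."""

    def __init__(self, n_sites: int, t: int = RunLenTree.DEFAULT_DEGREE) -> None:
        self.N = n_sites
        self.t = t
        self.M = 0
        self.columns: List[DynamicColumn] = [
            DynamicColumn(RunLenTree(t)) for _ in range(n_sites)
        ]
        self.store = BoundaryStore(n_sites)
        self._row_cache: Dict[int, List[int]] = {}

    # ------------------------------------------------------------ construction

    @classmethod
    def from_panel(cls, panel, t: int = RunLenTree.DEFAULT_DEGREE) -> "DynIndex":
        """Build the index in one scan (transient dense arrays per column)."""
        X = np.asarray(panel)
        if X.ndim != 2:
            raise ValueError(f"panel must be 2-D, got shape {X.shape}")
        if X.size and not np.isin(X, (0, 1)).all():
            raise ValueError("panel must be binary (0/1)")
        X = X.astype(np.int8)
        M, N = X.shape
        idx = cls(N, t)
        idx.M = M
        st = idx.store
        for h in range(M):
            st.ensure_hap(h)
        a = list(range(M))
        d = [0] * M
        for k in range(N):
            bits = [int(X[h, k]) for h in a]
            idx.columns[k] = DynamicColumn.from_bits(bits, t)
            j = 0
            while j < M:
                e = j
                while e + 1 < M and bits[e + 1] == bits[j]:
                    e += 1
                st.start_ids[k].append(a[j])
                st.end_ids[k].append(a[e])
                st.start_divs[k].append(d[j])
                st._above[a[j]][k] = (a[j - 1] if j else TOP, d[j])
                st._below[a[e]][k] = a[e + 1] if e + 1 < M else BOTTOM
                j = e + 1
            p = q = k + 1
            a0: List[int] = []
            a1: List[int] = []
            d0: List[int] = []
            d1: List[int] = []
            for j in range(M):
                h = a[j]
                dj = d[j]
                if dj > p:
                    p = dj
                if dj > q:
                    q = dj
                if X[h, k] == 0:
                    a0.append(h)
                    d0.append(p)
                    p = 0
                else:
                    a1.append(h)
                    d1.append(q)
                    q = 0
            a = a0 + a1
            d = d0 + d1
        st.a_last = a
        for j in range(M):
            st._above[a[j]][N] = (a[j - 1] if j else TOP, d[j])
            st._below[a[j]][N] = a[j + 1] if j + 1 < M else BOTTOM
        return idx

    # --------------------------------------------------------------- accessors

    @property
    def n_haps(self) -> int:
        return self.M

    @property
    def n_sites(self) -> int:
        return self.N

    def col_size(self, k: int) -> int:
        return self.columns[k].size

    def fl_map(self, k: int, i: int, bit: int) -> int:
        return self.columns[k].fl_map(i, bit)

    def bit_at(self, k: int, row: int) -> int:
        return self.columns[k].bit_at(row)

    def n_runs(self, k: int) -> int:
        return self.columns[k].n_runs

    def run_of(self, k: int, row: int) -> int:
        return self.columns[k].run_of(row)

    def run_bit(self, k: int, ri: int) -> int:
        return self.columns[k].run_bit(ri)

    def run_start_id(self, k: int, ri: int) -> int:
        return self.store.start_ids[k][ri]

    def last_hap(self, k: int) -> int:
        """Bottom haplotype of column ``k`` (``k`` may be the virtual N)."""
        if k == self.N:
            return self.store.a_last[-1]
        return self.store.end_ids[k][-1]

    def phi(self, h: int, k: int) -> int:
        return self.store.phi(h, k)

    def phi_inv(self, h: int, k: int) -> int:
        return self.store.phi_inv(h, k)

    def divergence_at(self, h: int, k: int) -> int:
        return self.store.divergence_at(h, k)

    def hap_alleles(self, h: int) -> List[int]:
        """Full allele row of haplotype ``h``, reconstructed and memoized."""
        if h not in self.store._above:
            raise IndexError(f"haplotype {h} not in panel (M={self.M})")
        cached = self._row_cache.get(h)
        if cached is not None:
            return cached
        # column 0 orders haplotypes by id (a_0 is the identity when ids are
        # dense; mid-deletion there may be one hole, hence the rank)
        row = sum(1 for x in self.store._above if x < h)
        out: List[int] = []
        for k in range(self.N):
            col = self.columns[k]
            b = col.bit_at(row)
            out.append(b)
            row = col.fl_map(row, b)
        self._row_cache[h] = out
        return out

    def allele_at(self, h: int, k: int) -> int:
        """Panel value ``x_h[k]`` recovered from the compressed index."""
        if not 0 <= k < self.N:
            raise IndexError(f"site {k} out of range 0..{self.N - 1}")
        return self.hap_alleles(h)[k]

    def decode_panel(self) -> np.ndarray:
        """The full panel, reconstructed row by row (testing/serialization aid)."""
        return np.array(
            [self.hap_alleles(h) for h in range(self.M)], dtype=np.int8
        ).reshape(self.M, self.N)

    # ------------------------------------------------------------------- stats

    @property
    def total_runs(self) -> int:
        return sum(c.n_runs for c in self.columns)

    @property
    def max_runs(self) -> int:
        return max((c.n_runs for c in self.columns), default=0)

    @property
    def node_visits(self) -> int:
        """Cumulative tree-node visits across all columns (instrumentation)."""
        return sum(c.tree.visits for c in self.columns)

    # --------------------------------------------------------------- mutation

    def virtual_insert(self, z) -> VirtualInsertion:
        return virtual_insert(self, z)

    def insert_haplotype(self, z) -> int:
        """Insert haplotype ``z``; returns its new id (the previous ``M``)."""
        zb = _as_bits(z, self.N)
        zid = self.M
        self._materialize_insert(zb, zid, None)
        self.M += 1
        self._row_cache.clear()
        return zid

    def _materialize_insert(
        self, zb: List[int], zid: int, at: Optional[Tuple[int, int]]
    ) -> None:
        """Three-sweep insertion of ``zb`` under id ``zid`` starting at ``at``."""
        vi = virtual_insert(self, zb, at)
        st = self.store
        st.ensure_hap(zid)
        for k in range(self.N):
            pos, bid = vi.t[k]
            b = zb[k]
            col = self.columns[k]
            n = col.size
            prev_bit = col.bit_at(pos - 1) if pos > 0 else None
            next_bit = col.bit_at(pos) if pos < n else None
            edits: List[tuple] = []
            if prev_bit == b and next_bit == b:
                pass  # strictly inside a matching run: no boundary is touched
            elif prev_bit == b:
                # z becomes the new end of the run finishing at pos - 1
                ri = col.run_of(pos - 1)
                he = st.end_ids[k][ri]
                edits += [
                    ("run_end", k, ri, zid),
                    ("below_del", he, k),
                    ("below_set", zid, k, bid),
                ]
                if bid != BOTTOM:
                    edits += [
                        ("above_set", bid, k, zid, vi.tstart[k]),
                        ("run_div", k, ri + 1, vi.tstart[k]),
                    ]
            elif next_bit == b:
                # z becomes the new start of the run beginning at pos
                ri = col.run_of(pos)
                hs = st.start_ids[k][ri]
                ha = st.end_ids[k][ri - 1] if pos > 0 else TOP
                edits += [
                    ("run_start", k, ri, zid),
                    ("run_div", k, ri, vi.zstart[k]),
                    ("above_del", hs, k),
                    ("above_set", zid, k, ha, vi.zstart[k]),
                ]
                if pos > 0:
                    edits.append(("below_set", ha, k, zid))
            elif pos == 0:
                # new singleton run at the top (also the empty-column case)
                ht = st.start_ids[k][0] if n else None
                edits += [
                    ("run_insert", k, 0, zid, zid, vi.zstart[k]),
                    ("above_set", zid, k, TOP, vi.zstart[k]),
                    ("below_set", zid, k, bid),
                ]
                if n:
                    edits += [
                        ("above_set", ht, k, zid, vi.tstart[k]),
                        ("run_div", k, 1, vi.tstart[k]),
                    ]
            elif pos == n:
                # new singleton run at the bottom
                hl = st.end_ids[k][-1]
                edits += [
                    ("run_insert", k, col.n_runs, zid, zid, vi.zstart[k]),
                    ("above_set", zid, k, hl, vi.zstart[k]),
                    ("below_set", zid, k, BOTTOM),
                    ("below_set", hl, k, zid),
                ]
            else:
                # run split: z and the haplotype below it head new runs
                ri = col.run_of(pos)
                ha = st.phi(bid, k)
                e_id = st.end_ids[k][ri]
                edits += [
                    ("run_end", k, ri, ha),
                    ("run_insert", k, ri + 1, zid, zid, vi.zstart[k]),
                    ("run_insert", k, ri + 2, bid, e_id, vi.tstart[k]),
                    ("below_set", ha, k, zid),
                    ("above_set", zid, k, ha, vi.zstart[k]),
                    ("below_set", zid, k, bid),
                    ("above_set", bid, k, zid, vi.tstart[k]),
                ]
            st.apply_boundary_edits(edits)
            col.insert(pos, b)
        # virtual column N: z joins the final ordering with true divergences
        posN, bidN = vi.t[self.N]
        ha = st.a_last[posN - 1] if posN > 0 else TOP
        edits = [
            ("aN_insert", posN, zid),
            ("above_set", zid, self.N, ha, vi.zstart[self.N]),
            ("below_set", zid, self.N, bidN),
        ]
        if posN > 0:
            edits.append(("below_set", ha, self.N, zid))
        if bidN != BOTTOM:
            edits.append(("above_set", bidN, self.N, zid, vi.tstart[self.N]))
        st.apply_boundary_edits(edits)

    def delete_haplotype(self, h: int) -> None:
        """Delete haplotype ``h``, keeping ids dense in ``0..M-2``.

        When ``h`` is not the bottom haplotype, the bottom haplotype's
        sequence is also removed and reinserted into the freed slot ``h``
        (starting at row ``h`` of column 0, which reproduces the tie order
        of a from-scratch build of the reduced panel).  Deletion therefore
        costs roughly two deletions plus one insertion.
        """
        if not 0 <= h < self.M:
            raise IndexError(f"haplotype {h} not in panel (M={self.M})")
        bottom = self.M - 1
        if h == bottom:
            self._delete_only(h, h)
            self.M -= 1
            self._row_cache.clear()
            return
        seq = list(self.hap_alleles(bottom))
        self._delete_only(h, h)
        # one id below `bottom` is gone, so its row in column 0 shifted up by one
        self._delete_only(bottom, bottom - 1)
        self.M -= 2
        self._row_cache.clear()
        id_below = h + 1 if h + 1 < bottom else BOTTOM
        self._materialize_insert(seq, h, (h, id_below))
        self.M += 1
        self._row_cache.clear()

    def _delete_only(self, h: int, row0: int) -> None:
        """Remove haplotype ``h``'s bits and samples; no id compaction.

        ``row0`` is ``h``'s row in column 0 (its rank among present ids).
        """
        N = self.N
        st = self.store
        # trace h's rows and bits through the unmodified index
        rows: List[int] = []
        bits: List[int] = []
        pos = row0
        for k in range(N):
            col = self.columns[k]
            b = col.bit_at(pos)
            rows.append(pos)
            bits.append(b)
            pos = col.fl_map(pos, b)
        posN = pos
        for k in range(N):
            pos = rows[k]
            col = self.columns[k]
            n = col.size
            ri = col.run_of(pos)
            head = col.run_head(ri)
            tail = (col.run_head(ri + 1) - 1) if ri + 1 < col.n_runs else n - 1
            is_start = pos == head
            is_end = pos == tail
            edits = []
            if not is_start and not is_end:
                pass  # interior of a longer run: no boundary is touched
            elif is_start and not is_end:
                hb = st.phi_inv(h, k)  # same-run successor becomes the new head
                if pos == 0:
                    ha = TOP
                    newdiv = k
                else:
                    ha = st.end_ids[k][ri - 1]
                    newdiv = max(st.start_divs[k][ri], st.divergence_at(hb, k))
                edits += [
                    ("run_start", k, ri, hb),
                    ("run_div", k, ri, newdiv),
                    ("above_del", h, k),
                    ("above_set", hb, k, ha, newdiv),
                ]
                if pos > 0:
                    edits.append(("below_set", ha, k, hb))
            elif is_end and not is_start:
                ha = st.phi(h, k)  # same-run predecessor becomes the new end
                hb = st.phi_inv(h, k)
                edits += [
                    ("run_end", k, ri, ha),
                    ("below_del", h, k),
                    ("below_set", ha, k, hb),
                ]
                if hb != BOTTOM:
                    newdiv = max(st.start_divs[k][ri + 1], st.divergence_at(h, k))
                    edits += [
                        ("above_set", hb, k, ha, newdiv),
                        ("run_div", k, ri + 1, newdiv),
                    ]
            else:
                # singleton run vanishes; flanking runs merge when both exist
                hb = st.phi_inv(h, k)
                ha = st.end_ids[k][ri - 1] if ri > 0 else TOP
                edits += [("above_del", h, k), ("below_del", h, k)]
                if ri > 0 and hb != BOTTOM:
                    e2 = st.end_ids[k][ri + 1]
                    edits += [
                        ("run_end", k, ri - 1, e2),
                        ("below_del", ha, k),
                        ("above_del", hb, k),
                        ("run_remove", k, ri + 1),
                        ("run_remove", k, ri),
                    ]
                elif ri == 0 and hb != BOTTOM:
                    edits += [
                        ("run_remove", k, 0),
                        ("above_set", hb, k, TOP, k),
                        ("run_div", k, 0, k),
                    ]
                elif ri > 0:
                    edits += [
                        ("run_remove", k, ri),
                        ("below_set", ha, k, BOTTOM),
                    ]
                else:
                    edits.append(("run_remove", k, 0))
            st.apply_boundary_edits(edits)
            col.delete(pos)
        # virtual column N
        haN = st.a_last[posN - 1] if posN > 0 else TOP
        hbN = st.a_last[posN + 1] if posN + 1 < len(st.a_last) else BOTTOM
        edits = [("above_del", h, N), ("below_del", h, N)]
        if haN != TOP:
            edits.append(("below_set", haN, N, hbN))
        if hbN != BOTTOM:
            if posN == 0:
                nd = N
            else:
                nd = max(st._above[hbN][N][1], st._above[h][N][1])
            edits.append(("above_set", hbN, N, haN, nd))
        edits += [("aN_remove", posN), ("hap_drop", h)]
        st.apply_boundary_edits(edits)

    # ----------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        """Versioned, JSON-serializable snapshot of the whole index."""
        st = self.store
        return {
            "format": "pbwtree-index",
            "version": 1,
            "t": self.t,
            "M": self.M,
            "N": self.N,
            "columns": [
                {"pairs": [list(p) for p in c.tree.iter_pairs()]}
                for c in self.columns
            ],
            "start_ids": [list(x) for x in st.start_ids],
            "end_ids": [list(x) for x in st.end_ids],
            "start_divs": [list(x) for x in st.start_divs],
            "a_last": list(st.a_last),
            "above": {
                str(h): [[k, a, d] for k, (a, d) in m.items()]
                for h, m in st._above.items()
            },
            "below": {
                str(h): [[k, b] for k, b in m.items()]
                for h, m in st._below.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DynIndex":
        if data.get("format") != "pbwtree-index":
            raise ValueError("not a pbwtree index container")
        if data.get("version") != 1:
            raise ValueError(f"unsupported index version {data.get('version')!r}")
        idx = cls(data["N"], data["t"])
        idx.M = data["M"]
        idx.columns = [
            DynamicColumn(RunLenTree.from_pairs(c["pairs"], data["t"]))
            for c in data["columns"]
        ]
        st = idx.store
        st.start_ids = [list(x) for x in data["start_ids"]]
        st.end_ids = [list(x) for x in data["end_ids"]]
        st.start_divs = [list(x) for x in data["start_divs"]]
        st.a_last = list(data["a_last"])
        for h_str, entries in data["above"].items():
            h = int(h_str)
            st.ensure_hap(h)
            for k, a, d in entries:
                st._above[h][k] = (a, d)
        for h_str, entries in data["below"].items():
            h = int(h_str)
            st.ensure_hap(h)
            for k, b in entries:
                st._below[h][k] = b
        return idx

    # ------------------------------------------------------------- comparison

    def state(self) -> tuple:
        """Canonical snapshot: column contents plus every boundary sample."""
        return (
            self.M,
            self.N,
            [tuple(map(tuple, c.tree.iter_pairs())) for c in self.columns],
            self.store.state(),
        )

    def same_as(self, other: "DynIndex") -> bool:
        """Deep equality of panel content and all samples (not tree shape)."""
        return self.state() == other.state()
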