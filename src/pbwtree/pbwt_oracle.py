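"""Dense, uncompressed PBWT used as an independent correctness oracle.

This module keeps every positional prefix array ``a_k``, divergence array
``d_k`` (start-position convention, top sentinel ``d_k[0] = k``) and
zero/one prefix-count array in plain Python lists, built by the classic
single left-to-right scan.  It trades all memory efficiency for
transparency: the compressed, tree-backed index is tested against these
arrays field by field.

Also here: a brute-force long-match scanner that applies the match
definition directly, used to check the block-tracking query algorithm.
"""

from __future__ import annotations

from typing import List, Sequence, Set, Tuple

import numpy as np

from .match_query import Match


def _as_panel(panel) -> np.ndarray:
    arr = np.asarray(panel)
    if arr.ndim != 2:
        raise ValueError(f"panel must be a 2-D matrix, got shape {arr.shape}")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("panel must be binary (0/1)")
    return arr.astype(np.int8)


class DensePBWT:
    """Full positional Burrows-Wheeler arrays for a binary haplotype panel.

    Attributes
    ----------
    a : list of N+1 permutations of ``0..M-1`` (reverse-prefix order).
    d : list of N+1 divergence arrays; ``d[k][j]`` is the start of the
        longest common suffix between rows ``j`` and ``j - 1`` of ``a[k]``.
    u, v : per-column prefix counts of zeros/ones, each of length ``M + 1``.
    c : per-column zero totals.
    """

    def __init__(self, panel) -> None:
        X = _as_panel(panel)
        M, N = X.shape
        self.panel = X
        self.M, self.N = M, N
        self.a: List[List[int]] = [list(range(M))]
        self.d: List[List[int]] = [[0] * M]
        self.u: List[List[int]] = []
        self.v: List[List[int]] = []
        self.c: List[int] = []
        for k in range(N):
            ak, dk = self.a[k], self.d[k]
            uk, vk = [0], [0]
            nz = no = 0
            a0, a1, d0, d1 = [], [], [], []
            p = q = k + 1
            for j in range(M):
                h = ak[j]
                dj = dk[j]
                if dj > p:
                    p = dj
                if dj > q:
                    q = dj
                if X[h, k] == 0:
                    a0.append(h)
                    d0.append(p)
                    p = 0
                    nz += 1
                else:
                    a1.append(h)
                    d1.append(q)
                    q = 0
                    no += 1
                uk.append(nz)
                vk.append(no)
            self.u.append(uk)
            self.v.append(vk)
            self.c.append(nz)
            self.a.append(a0 + a1)
            self.d.append(d0 + d1)
        # row_of[k][h] = row of haplotype h in a_k
        self.row_of: List[List[int]] = []
        for ak in self.a:
            inv = [0] * M
            for j, h in enumerate(ak):
                inv[h] = j
            self.row_of.append(inv)

    # ------------------------------------------------------------- accessors

    def fl(self, k: int, i: int, bit: int) -> int:
        """Dense FL mapping from row ``i`` of column ``k`` (``i`` may be M)."""
        if bit == 0:
            return self.u[k][i]
        return self.c[k] + self.v[k][i]

    def col_bits(self, k: int) -> List[int]:
        """Column ``k`` of the PBWT (panel column permuted by ``a_k``)."""
        return [int(self.panel[h, k]) for h in self.a[k]]

    def above(self, k: int, h: int) -> int:
        """Haplotype in the row above ``h`` in ``a_k``; -1 when ``h`` is top."""
        j = self.row_of[k][h]
        return self.a[k][j - 1] if j > 0 else -1

    def below(self, k: int, h: int) -> int:
        """Haplotype in the row below ``h`` in ``a_k``; -2 when ``h`` is last."""
        j = self.row_of[k][h]
        return self.a[k][j + 1] if j + 1 < self.M else -2

    def div_of(self, k: int, h: int) -> int:
        """Divergence value of haplotype ``h`` in column ``k``."""
        return self.d[k][self.row_of[k][h]]


def durbin_build(panel) -> DensePBWT:
    """Build the dense oracle arrays in one scan of the panel."""
    return DensePBWT(panel)


def naive_long_matches(panel, z: Sequence[int], L: int) -> Set[Match]:
    """All maximal agreement intervals of length >= L, by direct scanning."""
    X = _as_panel(panel)
    M, N = X.shape
    zarr = np.asarray(list(z), dtype=np.int8)
    if zarr.shape != (N,):
        raise ValueError(f"query length {zarr.size} != panel sites {N}")
    if not 1 <= L <= N:
        raise ValueError(f"L must be in 1..{N}, got {L}")
    out: Set[Match] = set()
    for h in range(M):
        eq = X[h] == zarr
        s = None
        for k in range(N + 1):
            if k < N and eq[k]:
                if s is None:
                    s = k
            else:
                if s is not None and k - s >= L:
                    out.add(Match(h, s, k))
                s = None
    return out
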