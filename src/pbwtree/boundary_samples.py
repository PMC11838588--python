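"""Run-boundary samples: sparse prefix-array and divergence information.

The compressed index never stores the full prefix arrays.  Instead it keeps,
for every column, the haplotype ids at the start and end of each run plus
the divergence value at each run start; and, for every haplotype, two
ordered maps over columns:

``above``
    keyed by the columns where the haplotype *heads* a run; the value is
    ``(haplotype immediately above, divergence at that column)``.
``below``
    keyed by the columns where the haplotype *ends* a run; the value is the
    haplotype immediately below.

Because a haplotype that does not head a run in column ``k`` shares its bit
with the row above it — so the pair stays adjacent through the FL map — the
entry found at the first key ``>= k`` is valid at ``k`` itself.  That
successor search realizes the neighbour functions phi / phi-inverse and the
divergence lookup D_k(i) without dense arrays.

Every haplotype is additionally sampled at the virtual column ``N`` (each
one treated as heading and ending a singleton run there, with its true
divergence), so successor searches always terminate.  The order of
haplotypes at column ``N`` is kept explicitly in :attr:`BoundaryStore.a_last`.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from typing import Dict, Iterable, List, Optional, Tuple

#: sentinel: no haplotype above (top of a column).
TOP = -1
#: sentinel: no haplotype below (bottom of a column).
BOTTOM = -2


class SortedMap:
    """Minimal ordered map with successor search, backed by a sorted key list."""

    __slots__ = ("_keys", "_vals")

    def __init__(self) -> None:
        self._keys: List[int] = []
        self._vals: Dict[int, object] = {}

    def __len__(self) -> int:
        return len(self._keys)

    def __contains__(self, k: int) -> bool:
        return k in self._vals

    def __getitem__(self, k: int):
        return self._vals[k]

    def __setitem__(self, k: int, v) -> None:
        if k not in self._vals:
            insort(self._keys, k)
        self._vals[k] = v

    def __delitem__(self, k: int) -> None:
        del self._vals[k]
        self._keys.pop(bisect_left(self._keys, k))

    def succ_item(self, k: int) -> Tuple[int, object]:
        """Smallest key >= ``k`` with its value; raises KeyError if none."""
        i = bisect_left(self._keys, k)
        if i == len(self._keys):
            raise KeyError(f"no key >= {k}")
        key = self._keys[i]
        return key, self._vals[key]

    def items(self):
        for k in self._keys:
            yield k, self._vals[k]

    def copy(self) -> "SortedMap":
        out = SortedMap()
        out._keys = list(self._keys)
        out._vals = dict(self._vals)
        return out


class BoundaryStore:
    """Sparse boundary samples for an ``N``-site panel."""

    def __init__(self, n_sites: int) -> None:
        self.N = n_sites
        self.start_ids: List[List[int]] = [[] for _ in range(n_sites)]
        self.end_ids: List[List[int]] = [[] for _ in range(n_sites)]
        self.start_divs: List[List[int]] = [[] for _ in range(n_sites)]
        #: haplotype order at the virtual column N.
        self.a_last: List[int] = []
        self._above: Dict[int, SortedMap] = {}
        self._below: Dict[int, SortedMap] = {}

    # ---------------------------------------------------------------- lookups

    def _require(self, h: int) -> None:
        if h not in self._above:
            raise KeyError(f"haplotype {h} not in panel")

    def phi(self, h: int, k: int) -> int:
        """Haplotype immediately above ``h`` in ``a_k`` (TOP if first)."""
        self._require(h)
        _, (above, _div) = self._above[h].succ_item(k)
        return above

    def phi_inv(self, h: int, k: int) -> int:
        """Haplotype immediately below ``h`` in ``a_k`` (BOTTOM if last)."""
        self._require(h)
        _, below = self._below[h].succ_item(k)
        return below

    def divergence_at(self, h: int, k: int) -> int:
        """Divergence (match start vs the row above) of ``h`` in column ``k``."""
        self._require(h)
        _, (_above, div) = self._above[h].succ_item(k)
        return div

    def haplotypes(self) -> Iterable[int]:
        return self._above.keys()

    # ---------------------------------------------------------------- editing

    def ensure_hap(self, h: int) -> None:
        if h not in self._above:
            self._above[h] = SortedMap()
            self._below[h] = SortedMap()

    def drop_hap(self, h: int) -> None:
        del self._above[h]
        del self._below[h]

    def apply_boundary_edits(self, edits: Iterable[tuple]) -> None:
        """Apply a script of primitive boundary changes.

        Each edit is a tagged tuple produced by the index-level insertion and
        deletion algorithms:

        - ``("hap_new", h)`` / ``("hap_drop", h)``
        - ``("run_start", k, ri, hap)``, ``("run_end", k, ri, hap)``,
          ``("run_div", k, ri, d)`` — overwrite one sample of run ``ri``;
        - ``("run_insert", k, ri, start, end, d)`` / ``("run_remove", k, ri)``;
        - ``("above_set", h, k, above_id, d)`` / ``("above_del", h, k)``;
        - ``("below_set", h, k, below_id)`` / ``("below_del", h, k)``;
        - ``("aN_insert", pos, h)`` / ``("aN_remove", pos)``.
        """
        for e in edits:
            tag = e[0]
            if tag == "run_start":
                _, k, ri, hap = e
                self.start_ids[k][ri] = hap
            elif tag == "run_end":
                _, k, ri, hap = e
                self.end_ids[k][ri] = hap
            elif tag == "run_div":
                _, k, ri, d = e
                self.start_divs[k][ri] = d
            elif tag == "run_insert":
                _, k, ri, start, end, d = e
                if not 0 <= ri <= len(self.start_ids[k]):
                    raise IndexError(f"run insert at {ri} outside column {k}")
                self.start_ids[k].insert(ri, start)
                self.end_ids[k].insert(ri, end)
                self.start_divs[k].insert(ri, d)
            elif tag == "run_remove":
                _, k, ri = e
                self.start_ids[k].pop(ri)
                self.end_ids[k].pop(ri)
                self.start_divs[k].pop(ri)
            elif tag == "above_set":
                _, h, k, above_id, d = e
                self._above[h][k] = (above_id, d)
            elif tag == "above_del":
                _, h, k = e
                del self._above[h][k]
            elif tag == "below_set":
                _, h, k, below_id = e
                self._below[h][k] = below_id
            elif tag == "below_del":
                _, h, k = e
                del self._below[h][k]
            elif tag == "aN_insert":
                _, pos, h = e
                self.a_last.insert(pos, h)
            elif tag == "aN_remove":
                _, pos = e
                self.a_last.pop(pos)
            elif tag == "hap_new":
                self.ensure_hap(e[1])
            elif tag == "hap_drop":
                self.drop_hap(e[1])
            else:
                raise ValueError(f"unknown boundary edit {e!r}")

    # ------------------------------------------------------------- comparison

    def state(self) -> tuple:
        """Canonical deep-comparable snapshot of every sample."""
        return (
            [list(x) for x in self.start_ids],
            [list(x) for x in self.end_ids],
            [list(x) for x in self.start_divs],
            list(self.a_last),
            {h: list(m.items()) for h, m in sorted(self._above.items())},
            {h: list(m.items()) for h, m in sorted(self._below.items())},
        )
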