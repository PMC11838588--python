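"""One PBWT column: a run-length tree plus its zero count and first-run bit.

The column's job is the FL mapping — carrying a haplotype's row from column
``k`` to column ``k + 1``.  With ``u(i)``/``v(i)`` the number of zero/one
bits strictly above row ``i`` and ``c`` the column's zero total, a haplotype
with allele 0 moves to row ``u(i)`` and one with allele 1 to ``c + v(i)``.
Both counts come from a single rank query on the tree.
"""

from __future__ import annotations

from typing import List

from .runlen_btree import RunLenTree


class DynamicColumn:
    """A single editable PBWT column backed by a :class:`RunLenTree`.

    The zero count ``c`` and first-run bit ``b`` are exposed as properties
    derived from the tree aggregates, which keeps them correct under every
    edit by construction.
    """

    __slots__ = ("tree",)

    def __init__(self, tree: RunLenTree) -> None:
        self.tree = tree

    @classmethod
    def from_bits(cls, bits, t: int = RunLenTree.DEFAULT_DEGREE) -> "DynamicColumn":
        return cls(RunLenTree.from_bits(bits, t))

    # ------------------------------------------------------------------- state

    @property
    def size(self) -> int:
        return self.tree.num

    @property
    def c(self) -> int:
        """Number of zero bits in the column (c_k)."""
        return self.tree.zeros

    @property
    def b(self) -> int:
        """Bit value of the first run (b_k); 0 for an empty column."""
        return self.tree.first_bit()

    @property
    def n_runs(self) -> int:
        return self.tree.runs

    def bits(self) -> List[int]:
        return self.tree.decode()

    def bit_at(self, i: int) -> int:
        return self.tree.access_bit(i)

    def run_of(self, i: int) -> int:
        return self.tree.runs_before(i)

    def run_head(self, run_idx: int) -> int:
        return self.tree.select_run_head(run_idx)

    def run_bit(self, run_idx: int) -> int:
        if not 0 <= run_idx < self.n_runs:
            raise IndexError(f"run index {run_idx} out of range")
        return self.b ^ (run_idx & 1)

    # --------------------------------------------------------------------- ops

    def fl_map(self, i: int, bit: int) -> int:
        """Row occupied in the next column by the haplotype at row ``i``.

        ``i`` may equal the column size: the one-past-end extension is what a
        virtually inserted haplotype sitting below the whole column uses.
        """
        if bit not in (0, 1):
            raise ValueError(f"bit must be 0 or 1, got {bit!r}")
        zeros, ones = self.tree.rank_pair(i)  # range-checks i
        if bit == 0:
            return zeros
        return self.c + ones

    def insert(self, i: int, bit: int) -> int:
        """Insert ``bit`` at row ``i``; returns the run-count delta (0/+1/+2)."""
        return self.tree.insert_bit(i, bit)

    def delete(self, i: int) -> int:
        """Delete the bit at row ``i``; returns the run-count delta (0/-1/-2)."""
        return self.tree.delete_bit(i)
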