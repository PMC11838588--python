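# Methods

## Background and model

A phased, biallelic haplotype panel is an `M x N` binary matrix: `M`
haplotypes (two per diploid sample) over `N` sites.  The positional
Burrows-Wheeler transform (PBWT) sorts the haplotypes at every site `k` by
their *reversed* length-`k` prefixes (co-lexicographically).  Two arrays per
column summarize the sort: the positional prefix array `a_k` (the
permutation) and the divergence array `d_k`, where `d_k[j]` is the start of
the longest common suffix between the haplotypes in rows `j` and `j - 1` of
`a_k`.  This package uses the *start-position* convention for divergence
(`d_k[j] = s` means the pair agrees on sites `s..k-1`), with the top
sentinel `d_k[0] = k` (an empty match above the first row).

Row `i` of column `k` moves to column `k + 1` through the FL mapping:
`FL(i) = u_k(i)` if the haplotype carries allele 0 at site `k`, else
`c_k + v_k(i)`, where `u_k(i)` / `v_k(i)` count zeros/ones strictly above
row `i` and `c_k` is the column's zero total.

Because reverse-prefix sorting clusters locally similar haplotypes, a PBWT
column is a short sequence of *runs* of equal bits — typically `r_k << M`
for cohort panels.  This package stores only the runs, yet remains fully
editable: haplotypes can be inserted and deleted without decompressing
anything, and all long matches between a query and the panel can be
reported from the compressed form.

## Per-column store: a count-augmented B+ tree of run pairs

Each column is a B+ tree (`runlen_btree.RunLenTree`) of minimum degree `t`.
Leaves hold keys `[f, s]` — a zero-run of length `f` followed by a one-run
of length `s`.  Alternation is maintained globally: `f = 0` only in the
very first key (column starting with ones), `s = 0` only in the very last
(column ending in zeros), and runs never span key or leaf boundaries.
Every node carries the subtree totals `(num, ones, runs)`; the cumulative
per-key counters of the classic layout are derived from these prefix sums
during descent.  The two layouts answer the same queries at the same
asymptotic cost and keep the same structural invariants (node occupancy in
`[t-1, 2t-1]` keys, equal leaf depth, a split exactly at `2t - 1` keys);
storing subtree totals makes every update a constant number of counter
writes per node on the root-to-leaf path.

Supported operations, all `O(t log_t r)`: positional rank (zeros/ones
before a row — this is `u`/`v` for the FL map), bit access, run index of a
row, run-head position (realizing the run-head array `p_k` without storing
it), and single-bit insertion/deletion.  Insertion distinguishes three
cases: the bit joins an adjacent equal run (run count unchanged); the bit
mismatches at the very top or bottom of the column (one new run); the bit
mismatches strictly inside a run (the run splits — run count rises by two).
Deletion mirrors them: shrink a longer run; drop a length-1 run at an end
(count falls by one); drop a length-1 interior run, merging its two
flanking runs (count falls by two).  Nodes are split preemptively on the
way down during inserts (CLRS-style, so a split never cascades upward) and
rebalanced by borrow-or-merge after deletes.

`t` defaults to 8 — panels in the compressed regime then usually fit a
column in a root leaf or a two-level tree.  The worked examples and many
tests use `t = 2` to exercise deep trees and every rebalancing path.

## Boundary samples: phi, phi-inverse and divergence without dense arrays

`boundary_samples.BoundaryStore` keeps, per column, the haplotype ids at
each run's start and end plus the divergence value at each run start; and,
per haplotype, two ordered maps over columns: `above` (keyed by the columns
where the haplotype heads a run; value: the haplotype immediately above it
and the divergence sampled there) and `below` (keyed by run-end columns;
value: the haplotype immediately below).

The lookups rest on a persistence argument: if haplotype `h` does not head
a run in column `k`, it shares its allele with the row above, so the pair
stays adjacent through the FL map into column `k + 1`; likewise the
divergence value cannot change while the pair stays adjacent and keeps
agreeing.  Hence the entry at the *first key `>= k`* of the ordered map is
valid at `k` itself: `phi`, `phi_inv` and `divergence_at` are successor
searches.  To make every search terminate, each haplotype is also sampled
at the virtual column `N` (treated as heading and ending a singleton run
there, with its true `d_N` value), and the haplotype order at column `N` is
kept explicitly.

The ordered maps are bisect-backed sorted arrays (`SortedMap`).  Insertion
into such a map is linear in its length rather than logarithmic; the map
per haplotype holds one entry per run boundary it touches, which is small,
and correctness only needs ordered successor search.  Swapping in a
balanced tree would change constants, not behaviour.

## Insertion: three sweeps

1. **Forward (virtual insertion).**  Track `t_k = (pos, id)` — the row the
   new haplotype `z` would occupy in column `k` and the id of the haplotype
   below that row.  `pos` advances by the FL map (the one-past-end row is
   allowed: `z` may sit below the whole column).  The below-id advances
   using only run-boundary samples: it is unchanged if the sampled row
   carries `z`'s allele, else the head of the next run, or — when `z`
   carries 0 and no zero-row remains below — the head of the column's first
   one-run.  At column 0 all reverse prefixes are empty ties and `z` starts
   at the bottom; ties resolve themselves afterwards because FL arithmetic
   keeps `z` below every tied row.
2. **Backward (divergence).**  `zStart[k]` / `tStart[k]` are the divergence
   values of `z` and of the haplotype below it.  Both arrays are
   initialized to `N` and computed right-to-left by comparing alleles
   against the neighbour given by `phi` (or the column's last haplotype
   when `z` is at the bottom), extending leftwards from the previous
   column's value — divergence values never decrease from column `k` to
   `k + 1`, so the scan never backs up.  The entry at `k = N` is itself
   extended by direct comparison, because the virtual-column-N samples must
   hold true `d_N` values.  Panel alleles come from `hap_alleles`, which
   reconstructs a row once by walking its FL trajectory and memoizes it
   (the cache is dropped on any panel mutation).
3. **Forward (materialization).**  Each column receives one single-bit tree
   edit at `t_k.pos`, plus a constant number of boundary-sample patches
   determined by the same three cases as the tree edit: appending to a
   run's end replaces the run's end id and re-points the neighbour maps;
   prepending to a run's start additionally replaces the sampled divergence
   with `zStart[k]` (the old head's divergence sample is discarded — it no
   longer heads a run); a new top/bottom singleton inserts a run with the
   sentinel/true divergence; a split ends the old run at the row above `z`
   and creates two new runs headed by `z` (divergence `zStart[k]`) and by
   the haplotype below it (divergence `tStart[k]`).  An insertion strictly
   inside a matching run touches no samples at all.

The resulting index is *exactly* the index built from scratch on the
extended panel — columns, `c_k`/`b_k`, every sample and every neighbour
map.  The test suite asserts this equality on hundreds of random panels.

## Deletion

The haplotype's rows are first traced through all columns by FL; each
column then loses one bit, with sample repairs mirroring the insertion
cases (a vanished interior singleton merges its flanking runs; a new run
head gets its divergence from `max` of the two divergences it bridges,
using `divergence_at` for the unsampled one).

Deleting a middle haplotype would leave ids sparse and — more subtly —
leave tie blocks in their old relative order, which a fresh build would
not reproduce.  Both problems are solved by also deleting the *bottom*
haplotype (id `M - 1`) and reinserting its sequence under the freed id,
with the virtual insertion started at row `h` of column 0 instead of the
bottom.  Starting the FL trajectory in the freed slot reproduces the tie
order of a from-scratch build exactly.  Deletion therefore costs about two
single-haplotype deletions plus one insertion.

## Long-match query

All maximal agreement intervals `[s, e)` with `e - s >= L` between a query
`z` and the panel are found by virtually inserting `z` and then sweeping
columns `k = 0..N`.  At each column the algorithm walks away from `z`'s
insertion point: upward through `phi`, downward through `phi_inv`,
maintaining the match start as the running maximum of the divergence
values crossed (`zStart[k]` / `tStart[k]` seed the two directions).  The
walk stops as soon as the running start exceeds `k - L` — match starts are
monotone away from the query, so the qualifying rows form a contiguous
block.  A row inside the block is reported exactly when its match stops
extending (its allele at `k` differs from `z[k]`, or `k = N`), which makes
every emitted match maximal and reported once.  Identical panel rows each
produce their own report.  Reports are ordered `(start, hap_id)` on disk.

The identical sweep runs against the editable index and against
`StaticIndex` — the same run-length columns and boundary samples frozen
into plain arrays with bisect navigation and no trees — and the tests
require both to be set-equal to a brute-force scanner that applies the
match definition directly.

## Dense reference implementation

`pbwt_oracle.DensePBWT` is an independent, uncompressed implementation of
the same model: full `a_k`, `d_k`, `u_k`, `v_k`, `c_k` arrays built by the
classic single scan.  It shares the start-position and top-sentinel
conventions so comparisons are field-exact, and is deliberately *not* used
by the index construction path (the index builds with its own streaming
scan that keeps only the current column's dense arrays).  The brute-force
long-match scanner lives beside it.  Both are test oracles and are also
reachable from the command line (`--naive`, `selftest`) for
cross-validation on real inputs.

## Synthetic panels

`panel_io.generate_panel(M, N, seed, mutation_density, recomb_rate,
founders)` emulates the feature that makes run-length compression
worthwhile: shared ancestry.  A small founder set (default 4) is drawn
uniformly at random; every further haplotype copies earlier ones with a
template switch at `recomb_rate` per site (default 0.01) and an allele
flip at `mutation_density` per site (default 0.02).  Those defaults give
run counts well below `M` at the panel sizes the tests use, while mutation
density sweeps verify that run counts respond monotonically.  The
generator does not model allele-frequency spectra, linkage-map distances,
missingness or genotyping error; passing tests therefore demonstrate
algorithmic correctness on panels with realistic run structure, not
calibration against any particular cohort.

## Problem sizes and numerical choices

Randomized suites run at panel sizes chosen to exercise every code path
while keeping the whole test run fast: oracle equivalence on 200 panels up
to 50 x 60, edit equivalence on 200 insert/delete trials up to 30 x 40,
query correctness on 300 triples up to 40 x 60 including `L = 1`, `L = N`
and duplicated haplotypes.  Divergence sentinels are `d_k[0] = k` at the
top and `k` for the below-divergence when the query sits at the bottom of
a column.  The empty column is a valid state (b-value 0 by convention);
the empty index accepts insertions.  When an insertion lands at an
interior run boundary and matches one neighbour, the run ending at the row
above is extended when its bit matches, else the run starting at the row —
with a binary alphabet exactly one of the two applies, so the encoded
column is unambiguous either way.

The scaling check doubles `M` three times (64 to 512) on low-diversity
panels (`mutation_density` 0.01) at fixed `N = 48` and counts tree-node
visits per inserted haplotype.  Visits include the allele-row walks of the
backward sweep, so they grow with tree height and run count — the
assertion is that an 8-fold panel growth moves visits by well under half
that factor and within a small constant of the log run-count growth.

## Known limitations

- Biallelic sites only; missing or unphased genotypes are rejected rather
  than imputed.
- One B+ tree per column; a single shared tree across columns (smaller
  constant memory overhead) is out of scope.
- Set-maximal match reporting (and the per-run threshold machinery it
  needs) is not implemented; the query surface is length-cutoff matches.
- The backward divergence sweep costs `O(N^2 log a + N log b)` per
  insertion in the worst case because allele access on the compressed
  panel is not constant-time; the per-haplotype row cache amortizes
  repeated access within one operation but does not change the bound.
- `SortedMap` favours simplicity over asymptotics (linear-time inserts
  into long maps); panels with extremely boundary-dense haplotypes would
  benefit from a balanced-tree replacement.
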