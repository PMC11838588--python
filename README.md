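# pbwtree

Dynamic, run-length compressed positional Burrows-Wheeler transform (PBWT)
for phased, biallelic haplotype panels — an editable haplotype index for
people who maintain reference panels and need one-vs-all matching: IBD-style
segment screening, phasing/imputation reference lookups, panel curation as
cohorts grow or samples withdraw.

## The problem and the data structure

A panel is an `M x N` binary matrix (`M` haplotypes, `N` sites).  The PBWT
sorts haplotypes at every site by their reversed prefixes, so that locally
similar haplotypes become adjacent and each sorted column collapses into a
few *runs* of equal bits (`r_k << M`).  Classic PBWT arrays answer matching
queries fast but are static and dense; this package stores each column's
runs in a count-augmented B+ tree and samples the prefix-array/divergence
information only at run boundaries.  The result supports, without ever
decompressing:

- **Insertion** of a haplotype `z`: a forward sweep tracks the row `z`
  would occupy in every column via the FL map
  (`FL(i) = u_k(i)` for allele 0, `c_k + v_k(i)` for allele 1); a backward
  sweep computes the divergence values `zStart`/`tStart` of `z` and of the
  haplotype below it; a final forward sweep applies one single-bit tree
  edit per column — extending a run, creating a run at the column's top or
  bottom, or splitting a run (run count `+0/+1/+2`).
- **Deletion**, with flanking-run merges (`-0/-1/-2`) and the bottom
  haplotype reinserted into the freed slot so ids stay dense in `0..M-1`.
- **Long-match queries**: every maximal interval of `>= L` sites on which a
  query agrees with any panel haplotype, found by virtual insertion plus a
  block sweep over the run-boundary neighbour functions `phi`/`phi_inv`
  and the divergence lookup `D_k(i)` — against the dynamic index or
  against a frozen, array-backed copy of it.

A dense reference implementation (`pbwtree.pbwt_oracle`) and a brute-force
match scanner back every algorithm with an independent oracle in the tests.
See `docs/methods.md` for the full model, conventions and design choices.

## Worked example

The reference column used throughout the tests is the 20-bit PBWT column
`00001000010010110000`.  Stored in a B+ tree of minimum degree 2:

```python
>>> from pbwtree import RunLenTree
>>> tree = RunLenTree.from_bits("00001000010010110000", t=2)
>>> tree.runs
9
>>> tree.rank_pair(10)      # (zeros, ones) strictly before bit 10
(8, 2)
>>> tree.runs_before(10)    # complete runs covering the first 10 bits
4
>>> tuple(tree.first_pair())  # leading zero-run of 4, then a one-run of 1
(4, 1)
>>> tuple(tree.last_pair())   # trailing zero-run of 4, no ones after it
(4, 0)
```

The 10-bit prefix holds 2 ones across 4 complete runs; at 16 bits it is
5 ones across 8 runs (`tree.rank_pair(16) == (11, 5)`,
`tree.runs_before(16) == 8`).

A full index on a synthetic 20-haplotype, 15-site panel:

```python
>>> from pbwtree import DynIndex, query_long_matches
>>> from pbwtree.panel_io import generate_panel
>>> panel = generate_panel(M=20, N=15, seed=7, mutation_density=0.05)
>>> idx = DynIndex.from_panel(panel, t=8)
>>> idx.M, idx.N, idx.total_runs, idx.max_runs
(20, 15, 87, 9)
>>> z = panel[4].copy(); z[10] ^= 1      # query: haplotype 4 with one flip
>>> sorted(query_long_matches(idx, z, L=8))
[Match(hap_id=4, start=0, end=10)]
```

87 total runs for 300 panel bits is the compression the reverse-prefix
sort buys; the query reports the single maximal agreement interval of at
least 8 sites — haplotype 4 over sites 0..9, cut by the flip at site 10.

The same from the shell:

```console
$ pbwtree build --in panel.txt --out index.json --degree 8
built index: M=20 N=15 runs=87 -> index.json
$ pbwtree query --index index.json --hap 101011100111011 -L 8
query_id        hap_id  start   end     length
-       h4      0       10      10
```

`pbwtree insert/delete` edit an index file in place, `stats` prints panel
and run counts, `selftest` cross-validates against the dense reference
implementation on random panels.  Panels load from plain 0/1 matrices or
phased VCF (biallelic SNPs; two haplotypes per sample).

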