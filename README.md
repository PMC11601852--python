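# movedex

A run-length compressed **bidirectional move-structure index** for lossless
approximate pattern matching of sequencing reads against large, repetitive
genome collections (pan-genomes).

## The problem

Classical FM-index read mappers need memory linear in the total genome
content, which breaks down for collections of thousands of similar genomes.
Run-length compressed indexes (the r-index family) need only O(r) space,
where r is the number of character runs in the Burrows–Wheeler transform —
for a pan-genome, r grows with the *novel* sequence rather than the total
length. Their weakness is speed: each step involves rank/select machinery
with unpredictable memory access. The *move structure* replaces that
machinery with a table of r rows, one per BWT run, where every LF evaluation
is one table jump plus a short linear scan ("fast forwarding") — constant
work with streaming memory access.

`movedex` implements the bidirectional extension of this idea:

* **Move tables for LF and LFrev** — rows `(c, p, π, ξ)`: run character,
  input-interval start, output-interval start `π = LF(p)`, and the row `ξ`
  containing `π`. Forward and reverse intervals are kept synchronized, so a
  pattern can be extended by characters on *either* end in any order:
  for a left extension with `c`, `s'rev = srev + x` and
  `e'rev = srev + x + y − 1`, where `x` counts BWT characters smaller than
  `c` in `[s, e]` (one O(r) walk over the rows) and `y` is the new interval
  width. Run indices of the inactive side go stale and are recovered by
  binary search only at direction switches.
* **Toehold maintenance** — one concrete occurrence start is carried through
  every extension, read from per-run SA samples at run boundaries.
* **Locating via ϕ/ϕ⁻¹ move tables** — from the toehold, neighbouring
  suffix-array values are enumerated with move tables over text positions;
  a sparse PLCP array (one value per ϕ-run start) tells the walk when the
  interval boundary is reached. The ϕ tables are *balanced* (split until no
  output interval spans more than `d = 2` input starts), which caps fast
  forwarding; balancing at most doubles the row count.
* **Search schemes** — lossless approximate matching under Hamming or edit
  distance. A scheme is a set of searches `(π, L, U)` over pattern parts
  covering every distribution of up to K errors; the default is the
  pigeonhole scheme (K+1 parts, each search anchoring one part error-free).
  Edit distance uses banded dynamic programming along the extensions.
* **Bit-packed tables** — rows stored with dedicated bit widths
  (`2·⌈log2 n⌉ + ⌈log2 rows⌉` bits, +3 for the run character), byte-aligned;
  packed and full tables are interchangeable everywhere.

## Worked example

```python
>>> from movedex import Text, build_index, movetables, apm
>>> index = build_index([Text("CTATGTCATATGTTGGTC", name="toy")])
>>> index.stats()
{'n': 19, 'r': 12, 'r_rev': 13, 'with_phi_tables': True,
 'phi_rows_balanced': 14, 'phi_inv_rows_balanced': 14}
>>> movetables.move_step(index.mlf, 5, 1)   # LF(5), which lies in run 1
(14, 8)
>>> sorted((o.start, o.distance) for o in apm.run_search_scheme(index, "TATGT", 0))
[(1, 0), (8, 0)]
>>> sorted((o.start, o.distance)
...        for o in apm.run_search_scheme(index, "TATGA", 1, "hamming"))
[(1, 1), (8, 1)]
```

The 19-character text has 12 BWT runs; `LF(5) = 14` lands in run 8 after two
fast-forward steps; `TATGT` occurs exactly at text positions 1 and 8, and
allowing one mismatch finds the same two sites for `TATGA`.

The same operations are available from the shell:

```sh
movedex build --fasta ref.fa --out ref.mvdx
movedex align --index ref.mvdx --reads reads.fq --k 2 --metric edit \
              --report --out out.sam
movedex inspect --index ref.mvdx --table lf
movedex selftest
```

`align --report` emits one SAM line per occurrence (FLAG 0/16 for strand, 4
for unmapped, `NM` tag for the distance, no CIGAR). `inspect` dumps any move
table as TSV with columns `j, c, p, pi, xi`.

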