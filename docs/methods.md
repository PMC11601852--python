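# Methods

## Model

`movedex` indexes one concatenated text T over {A, C, G, T}, terminated by a
sentinel `$` that sorts before every other symbol ('N' characters are removed
from reference sequences at ingest; any other symbol is rejected). All
structures are 0-based; suffix-array intervals are closed `[s, e]`; text
spans are half-open `[start, start + length)`.

The index consists of:

* **LF move tables** for T and its reverse Trev. One row per maximal BWT run
  plus a sentinel row with `p = n`, so fast forwarding can always read the
  next row's `p`. Following the printed tables, the sentinel row's `ξ` is its
  own index. LF tables are deliberately kept at the original (maximal) runs:
  splitting them buys little for character extensions because BWT run sizes
  in a pan-genome are relatively even.
* **ϕ and ϕ⁻¹ move tables** over text positions. A ϕ input interval starts
  at `k` exactly when `k = SA[i]` for a BWT-run start `i`; ϕ⁻¹'s input
  intervals start at SA values of run ends. Both constructions are verified
  row by row against the direct SA/ISA definition at build time (each row's
  whole interval must map as a single shift). Because the ϕ run-size
  distribution is heavily right-tailed, these tables are **balanced**.
* **SA samples**: the SA value at the first and last position of every run,
  for both directions (4 values per run upper bound) — the simplest scheme
  that supports toehold updates in every case. Run subsampling is
  deliberately not implemented.
* **Sparse PLCP**: one value per ϕ input-interval start. These positions are
  exactly the irreducible PLCP positions, so any other value is recovered by
  `PLCP[i] = PLCP[pred(i)] − (i − pred(i))`. The predecessor structure is a
  binary search over the sorted position array — O(log r) instead of the
  O(log log) structures in the literature; only the contract matters at this
  scale. For texts up to 2^17 the recovery rule is fully verified against
  the LCP-derived PLCP at build time; property tests cover it always.
* **Fragment table**: names and spans of the input records inside the
  concatenation, used for SAM reporting. Occurrences that span a fragment
  boundary are concatenation artifacts, not biological matches, and are
  discarded.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `balance_d` | 2 | max input-interval starts per ϕ output interval; 2 is the tightest split, giving the strongest fast-forward cap (observed per-operation steps ≤ d) at the price of more rows (never more than 2×) |
| `with_phi_tables` | true | build balanced ϕ/ϕ⁻¹ move tables; disabling retains the suffix array as a sparse locate fallback, trading locate speed for index size |
| `k` | 0 | maximum error count for matching |
| `metric` | hamming | `hamming` (substitutions) or `edit` (substitutions + single-symbol indels) |

## Algorithms and numerical choices

**Suffix arrays** are built by deterministic numpy prefix doubling
(O(n log² n)); output is byte-identical across runs. Initial ranks are
densified so the all-distinct termination test is exact. This is a
desk-scale construction choice; compressed construction (prefix-free
parsing) is out of scope.

**Balancing** processes rows left to right and re-scans from the start after
each split, until fixpoint — deterministic by construction. An interval is
split at the (d+1)-th input start contained in its output interval, which
splits input and output alike and therefore never changes the represented
mapping (asserted exhaustively in tests). The exact splitting policy of the
original balancing literature is not restated in our sources; this fixpoint
policy satisfies the two properties that matter — mapping preservation and
the ≤ 2× row bound — but step-bound constants may differ from the original.

**Bidirectional extension.** The count x of BWT characters smaller than c in
`[s, e]` is computed in one walk over the covering rows (the per-character
|Σ|-pass formulation is kept as a test-only reference and must agree
exactly). The sentinel counts toward x, since `$` precedes every alphabet
character. Walks for the c-subinterval start at the run containing the
interval boundary. Stale run indices keep their last values, which are valid
binary-search brackets at the next direction switch; when nothing better is
known, the full row range is used.

**Toehold rule.** For a left extension with c: if the whole interval lies in
a single BWT run, every occurrence extends and the toehold just shifts by
one; otherwise some c-run boundary lies inside the interval, its SA sample
is read, and the new toehold is that sample − 1. Right extensions mirror
this on the reverse index, mapping the reverse-text start j back through
`start = n − 1 − j − |Q|`. This rule is reconstructed from the toehold
lemma and pinned down by an oracle-backed invariant (the toehold always
starts a true occurrence of the matched string), not by trusting the
derivation.

**Locating.** The backward ϕ walk stops when the PLCP of the value just
produced drops below the matched length m (that value is `SA[s]`, still
reported); the forward walk then performs exactly the arithmetic remainder
of ϕ⁻¹ steps, so enumerating a width-w interval costs exactly w − 1
operations and a width-1 interval costs none. Under edit distance, m is the
exact matched substring length of the final state, not the read length. The
m = 0 corner (empty pattern, PLCP never drops) is covered by bounding the
backward walk at w − 1 steps, which there enumerates the full suffix array.

**Search schemes.** Patterns are partitioned uniformly, remainder to the
leftmost parts; dynamic partitioning is out of scope. The first part is
matched from the separation point toward its outer edge; every generated or
user-supplied scheme is validated (connectivity, monotone bounds) and
pigeonhole schemes are exhaustively checked to cover every error
distribution. Edit distance uses a plain banded DP row per part along the
extensions; at part boundaries (including direction switches) the DP value
at the boundary column is committed as the cumulative distance, branching
over every text length within bounds. Each committed value is the cost of a
real alignment, so reported distances never undercut the truth, and the
optimal alignment is always explored — reported sets match the exhaustive
oracle. One caveat: with non-zero *lower* bounds L and edit distance, the
committed minimum can under-read a prefix distance and prune a covered
alignment; the stock pigeonhole scheme has L = 0 everywhere and is
unaffected, but custom edit-distance schemes with L > 0 should be treated
as experimental.

**Deduplication (edit).** Raw hits are canonicalized per (strand, start) to
the minimum distance, shortest length on ties; then hits whose start and end
both lie within k of an accepted hit collapse onto it (processing order:
distance, then start, then length — deterministic). The identical rule is
applied to the brute-force oracle, so equality tests are meaningful even
where other implementations might reduce redundancy differently.

**Bit packing.** `p` and `π` get `⌈log2(n+1)⌉` bits — the +1 because the
sentinel row stores `p = n`, which a bare `⌈log2 n⌉` would overflow exactly
at powers of two; on the 19-character example this yields the same
5+5+4+3 = 17 bits, 3 bytes per row. Field widths are floored at 1 bit so
degenerate tables still encode. Characters use 3 bits with code 5 marking
the blank sentinel row. Rows are byte-aligned, little-endian, and the
container format is versioned with a magic number; no compatibility with any
other tool's serialization is attempted.

## Synthetic data

The generator emulates the structure that makes run-length compression pay:
a random base sequence plus independently mutated near-copies, with defaults
of 1% substitutions and 0.1% single-base indels per copy — typical
intra-species divergence for a small bacterial strain panel. As copies are
added, n grows linearly while r grows sublinearly (r/n falls monotonically
in the tests). Reads are sampled uniformly from both strands with planted
errors at a per-base rate, truth annotations riding in the read names.

What the generator does not emulate: structural rearrangements, horizontal
transfer, long repeats beyond those of random sequence, quality-score
profiles, or realistic error spectra. Passing tests therefore demonstrate
correctness of the index and matching machinery on texts with pan-genome-like
run structure, not mapping accuracy on real genomes.

## Problem sizes

Tests and the acceptance suite run at desk scale: oracle-equivalence sweeps
over 200 random texts up to n = 2000, losslessness on random texts up to
n = 5000 with reads of 20–151 bp and k ≤ 3, and synthetic pan-genomes of a
few thousand bases per strain. These sizes exercise every code path
(including balanced fast-forward caps and direction switches) while keeping
the whole suite in minutes on one core.

## Known limitations

* Construction is uncompressed (full suffix sort in memory), limiting
  practical index builds to desk-scale texts.
* No CIGAR strings — the text is not stored, so alignments report position
  and distance only.
* Edit-distance schemes with non-zero lower bounds: see above.
* IUPAC ambiguity codes other than N are rejected rather than expanded;
  reads containing them are reported unmapped.
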