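"""Synthetic pan-genomes and sequencing reads for tests and demos.

Run-length compressed indexes earn their keep on collections of highly
similar genomes: the BWT run count r grows with the *novel* sequence, not
with the total length n. The generator emulates that structure directly —
one random base sequence plus independently mutated near-copies — so that
n grows linearly with the number of copies while r grows sublinearly, the
regime the index is designed for.

Defaults model a small bacterial strain collection: ~1% substitutions and
~0.1% short indels between strains, Illumina-length reads with a low
per-base error rate, sampled from both strands. What the generator does not
emulate: large structural rearrangements, repeat-induced mapping ambiguity
beyond what random sequence provides, and realistic base-quality profiles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .textcore import SIGMA, ReadRecord, Text, reverse_complement


def synth_pangenome(base_length: int = 5000, copies: int = 8,
                    substitution_rate: float = 0.01,
                    indel_rate: float = 0.001, seed: int = 0) -> list[Text]:
    """A base sequence plus ``copies - 1`` independently mutated near-copies.

    Deterministic for a given seed. Rates are per base: substitutions pick a
    different base uniformly; indels are single-base, insertions and
    deletions equally likely.
    """
    if not (0 <= substitution_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = random.Random(seed)
    base = "".join(rng.choice(SIGMA) for _ in range(base_length))
    fragments = [Text(base, name="strain0")]
    for c in range(1, copies):
        out = []
        for ch in base:
            roll = rng.random()
            if roll < indel_rate / 2:
                continue  # deletion
            if roll < indel_rate:
                out.append(rng.choice(SIGMA))  # insertion before the base
            if rng.random() < substitution_rate:
                out.append(rng.choice([b for b in SIGMA if b != ch]))
            else:
                out.append(ch)
        fragments.append(Text("".join(out), name=f"strain{c}"))
    return fragments


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth of a synthetic read, recoverable from its name."""

    name: str
    origin: int  # start of the sampled window in the concatenated text
    strand: str
    edits: int

    @classmethod
    def from_name(cls, name: str) -> "ReadTruth":
        base, origin, strand, edits = name.split(":")
        return cls(base, int(origin), strand, int(edits))


def synth_reads(text: Text, count: int = 100, length: int = 100,
                error_rate: float = 0.005, indels: bool = False,
                seed: int = 0) -> list[ReadRecord]:
    """Reads sampled from both strands with planted errors.

    Truth annotations ride in the read names as
    ``r<i>:<origin>:<strand>:<edits>`` so recall can be checked without a
    side file. Deterministic for a given seed.
    """
    body = text.symbols[:-1] if text.has_sentinel else text.symbols
    if length > len(body):
        raise ValueError("read length exceeds usable text length")
    rng = random.Random(seed)
    reads = []
    for i in range(count):
        origin = rng.randrange(len(body) - length + 1)
        window = body[origin:origin + length]
        strand = rng.choice("+-")
        seq = reverse_complement(window) if strand == "-" else window
        seq, edits = _plant_errors(seq, error_rate, indels, rng)
        reads.append(ReadRecord(f"r{i}:{origin}:{strand}:{edits}", seq))
    return reads


def _plant_errors(seq: str, error_rate: float, indels: bool,
                  rng: random.Random) -> tuple[str, int]:
    out = []
    edits = 0
    for ch in seq:
        if rng.random() < error_rate:
            edits += 1
            if indels:
                kind = rng.choice("sid")
            else:
                kind = "s"
            if kind == "s":
                out.append(rng.choice([b for b in SIGMA if b != ch]))
            elif kind == "i":
                out.append(rng.choice(SIGMA))
                out.append(ch)
            # deletions append nothing
        else:
            out.append(ch)
    return "".join(out), edits


def write_fasta(fragments, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f">{frag.name}\n")
            for i in range(0, len(frag.symbols), width):
                fh.write(frag.symbols[i:i + width] + "\n")


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")
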