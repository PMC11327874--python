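"""k-mer sketching: full key sets, bottom-s MinHash, minimizers, prefixes.

Every sequence is reduced to a set of 64-bit k-mer hash keys. Sub-sampling
(MinHash, minimizer, prefix) shrinks the per-sequence key set so the
all-vs-all comparison stays tractable on long sequences; a full-mode sketch
keeps every distinct k-mer. Hashing is seeded and stable across processes
and platforms, so identical (residues, scheme) always yields an identical
sketch.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .io import ALPHABET_SYMBOLS, Alphabet, SequenceRecord

#: Fixed default seed of the 64-bit k-mer hash; any other value may be set
#: on the scheme, but it must be constant across a run.
DEFAULT_HASH_SEED = 42

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class SketchMode(str, Enum):
    FULL = "full"
    MINHASH = "minhash"
    MINIMIZER = "minimizer"
    PREFIX = "prefix"


@dataclass(frozen=True)
class SketchScheme:
    """How k-mers are extracted and sub-sampled.

    k
        k-mer length, >= 1.
    mode
        full (keep all), minhash (bottom-``sketch_size`` hashes),
        minimizer (window minimum over ``window`` consecutive k-mers),
        prefix (keep k-mers starting with ``prefix``).
    canonical
        Replace each nucleotide k-mer by the lexicographic minimum of
        itself and its reverse complement (strand invariance). Must be
        False for amino-acid input.
    """

    k: int
    mode: SketchMode = SketchMode.FULL
    sketch_size: Optional[int] = None
    window: Optional[int] = None
    prefix: Optional[str] = None
    canonical: bool = True
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        mode = SketchMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if mode is SketchMode.MINHASH:
            if self.sketch_size is None or self.sketch_size < 1:
                raise ValueError("minhash mode requires sketch_size >= 1")
        if mode is SketchMode.MINIMIZER:
            if self.window is None or self.window < 1:
                raise ValueError("minimizer mode requires window >= 1")
        if mode is SketchMode.PREFIX:
            if not self.prefix or not (1 <= len(self.prefix) < self.k):
                raise ValueError("prefix mode requires 1 <= len(prefix) < k")
            if any(c not in "ACGT" for c in self.prefix):
                raise ValueError("prefix must be over the ACGT alphabet")


#: Defaults per mode mirroring common practice for bacterial-scale input:
#: MinHash k=19 with 4096 retained hashes, minimizers k=18 with window 16,
#: prefix sampling k=16 with a single-base prefix, amino acids MinHash k=9.
def default_scheme(mode: SketchMode | str, alphabet: Alphabet | str,
                   hash_seed: int = DEFAULT_HASH_SEED) -> SketchScheme:
    mode = SketchMode(mode)
    alphabet = Alphabet(alphabet)
    if alphabet is Alphabet.AMINO_ACID:
        if mode not in (SketchMode.MINHASH, SketchMode.FULL):
            raise ValueError(
                "amino-acid input supports only full or minhash sketching"
            )
        size = 4096 if mode is SketchMode.MINHASH else None
        return SketchScheme(k=9, mode=mode, sketch_size=size,
                            canonical=False, hash_seed=hash_seed)
    if mode is SketchMode.MINHASH:
        return SketchScheme(k=19, mode=mode, sketch_size=4096,
                            hash_seed=hash_seed)
    if mode is SketchMode.MINIMIZER:
        return SketchScheme(k=18, mode=mode, window=16, hash_seed=hash_seed)
    if mode is SketchMode.PREFIX:
        return SketchScheme(k=16, mode=mode, prefix="A", hash_seed=hash_seed)
    return SketchScheme(k=16, mode=mode, hash_seed=hash_seed)


@dataclass
class KmerSketch:
    """The sampled key set of one sequence plus its sampling provenance."""

    seq_id: str
    scheme: SketchScheme
    keys: frozenset[int]
    total_kmers: int  # distinct k-mers before sub-sampling


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def hash_kmer(kmer: str, seed: int = DEFAULT_HASH_SEED) -> int:
    """Seeded, process-stable 64-bit hash of a k-mer string."""
    key = seed.to_bytes(8, "little", signed=False)
    digest = hashlib.blake2b(kmer.encode(), digest_size=8, key=key).digest()
    return int.from_bytes(digest, "big")


def _valid_kmers_in_order(record: SequenceRecord,
                          scheme: SketchScheme) -> list[str]:
    """All length-k windows in sequence order, ambiguous windows skipped,
    canonicalized when requested."""
    seq = record.residues
    k = scheme.k
    if k > len(seq):
        return []
    allowed = ALPHABET_SYMBOLS[record.alphabet]
    canonical = scheme.canonical and record.alphabet is Alphabet.NUCLEOTIDE
    # distance to the previous disallowed symbol, to skip ambiguous windows
    out: list[str] = []
    run = 0
    for i, c in enumerate(seq):
        run = run + 1 if c in allowed else 0
        if run >= k:
            kmer = seq[i - k + 1:i + 1]
            if canonical:
                rc = reverse_complement(kmer)
                if rc < kmer:
                    kmer = rc
            out.append(kmer)
    return out


def enumerate_kmers(record: SequenceRecord,
                    scheme: SketchScheme) -> tuple[set[str], int]:
    """Distinct k-mers of a sequence (canonical forms if requested).

    Windows containing an ambiguity symbol (N/X) are skipped. Returns the
    set and its size; sequences shorter than k give an empty set.
    """
    kmers = set(_valid_kmers_in_order(record, scheme))
    return kmers, len(kmers)


def minhash_sketch(kmers: set[str], scheme: SketchScheme,
                   seq_id: str = "") -> KmerSketch:
    """Bottom-s sketch: the s smallest seeded hash values of the k-mer set.

    A single hash function with bottom-s retention is used (rather than s
    independent hash functions); when fewer than s distinct k-mers exist,
    all are kept.
    """
    if SketchMode(scheme.mode) is not SketchMode.MINHASH:
        raise ValueError("scheme mode must be minhash")
    hashes = sorted(hash_kmer(km, scheme.hash_seed) for km in kmers)
    keys = frozenset(hashes[: scheme.sketch_size])
    return KmerSketch(seq_id=seq_id, scheme=scheme, keys=keys,
                      total_kmers=len(kmers))


def minimizer_sample(record: SequenceRecord,
                     scheme: SketchScheme) -> KmerSketch:
    """Window-minimum sampling: for every window of ``window`` consecutive
    valid k-mers, retain the k-mer with the smallest hash (ties broken by
    leftmost position)."""
    if SketchMode(scheme.mode) is not SketchMode.MINIMIZER:
        raise ValueError("scheme mode must be minimizer")
    ordered = _valid_kmers_in_order(record, scheme)
    total = len(set(ordered))
    w = scheme.window
    hashes = [hash_kmer(km, scheme.hash_seed) for km in ordered]
    keys: set[int] = set()
    window: deque[int] = deque()  # candidate positions, hashes increasing
    for i, h in enumerate(hashes):
        # strict < keeps the earlier position on ties (leftmost wins)
        while window and hashes[window[-1]] > h:
            window.pop()
        window.append(i)
        if window[0] <= i - w:
            window.popleft()
        if i >= w - 1:
            keys.add(hashes[window[0]])
    if 0 < len(hashes) < w:
        # fewer k-mers than one window: the overall minimum is retained
        keys.add(min(hashes))
    return KmerSketch(seq_id=record.id, scheme=scheme, keys=frozenset(keys),
                      total_kmers=total)


def prefix_sample(kmers: set[str], scheme: SketchScheme,
                  seq_id: str = "") -> KmerSketch:
    """Retain exactly the k-mers whose first |prefix| symbols equal the
    scheme prefix (applied to canonical forms when canonical=True, since
    ``kmers`` are already canonicalized by :func:`enumerate_kmers`)."""
    if SketchMode(scheme.mode) is not SketchMode.PREFIX:
        raise ValueError("scheme mode must be prefix")
    kept = {km for km in kmers if km.startswith(scheme.prefix)}
    keys = frozenset(hash_kmer(km, scheme.hash_seed) for km in kept)
    return KmerSketch(seq_id=seq_id, scheme=scheme, keys=keys,
                      total_kmers=len(kmers))


def sketch_sequence(record: SequenceRecord,
                    scheme: SketchScheme) -> KmerSketch:
    """Dispatch to the scheme's sampling mode and return the sketch."""
    if record.alphabet is Alphabet.AMINO_ACID and scheme.canonical:
        raise ValueError("canonical k-mers are undefined for amino acids")
    mode = SketchMode(scheme.mode)
    if mode is SketchMode.MINIMIZER:
        return minimizer_sample(record, scheme)
    kmers, total = enumerate_kmers(record, scheme)
    if mode is SketchMode.FULL:
        keys = frozenset(hash_kmer(km, scheme.hash_seed) for km in kmers)
        return KmerSketch(seq_id=record.id, scheme=scheme, keys=keys,
                          total_kmers=total)
    if mode is SketchMode.MINHASH:
        sk = minhash_sketch(kmers, scheme, seq_id=record.id)
        return sk
    return prefix_sample(kmers, scheme, seq_id=record.id)


def sketch_dataset(records: Iterable[SequenceRecord],
                   scheme: SketchScheme) -> list[KmerSketch]:
    return [sketch_sequence(rec, scheme) for rec in records]


def write_sketch_cache(sketches: Iterable[KmerSketch],
                       path) -> None:
    """Dump sketches to TSV (seq_id, total_kmers, hex keys) for reuse."""
    with open(path, "w") as fh:
        fh.write("seq_id\ttotal_kmers\tkeys\n")
        for sk in sketches:
            hexkeys = ",".join(f"{k:016x}" for k in sorted(sk.keys))
            fh.write(f"{sk.seq_id}\t{sk.total_kmers}\t{hexkeys}\n")
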