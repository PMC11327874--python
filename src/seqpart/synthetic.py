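"""Synthetic sequence families with controlled identity, plus exact oracles.

The generator emulates a dataset of homologous families: every family has a
founder and members derived from it by independent per-site substitution,
so the expected member-founder identity is a direct dial. Families are
independent by default (expected inter-family identity is the uniform
background, 1/4 for nucleotides); optionally all founders descend from one
common ancestor so that inter-family identity is controlled too, which
produces the intermediate-similarity structure real homolog collections
have.

``exact_distance_oracle`` computes dense distances on full, unsampled
k-mer sets with naive set construction and arithmetic, deliberately sharing
no code with the sketching path, so it can independently verify sketch
distances and the cross-fold separation guarantee on small inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .io import Alphabet, SequenceRecord

_NT = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"

IntOrRange = Union[int, tuple[int, int]]


@dataclass
class FamilySpec:
    """Parameters of one synthetic dataset.

    intra_identity is the expected per-site identity of a member to its
    family founder (members therefore share about intra_identity**2 with
    each other). ancestor_identity, when set, derives every founder from a
    single common ancestor at that per-site identity instead of drawing
    founders independently. indel_rate (robustness runs only) inserts or
    deletes short geometric-length segments at the given per-site rate.
    """

    n_families: int
    members_per_family: IntOrRange
    seq_length: IntOrRange
    intra_identity: float
    alphabet: Alphabet = Alphabet.NUCLEOTIDE
    seed: int = 0
    ancestor_identity: Optional[float] = None
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        self.alphabet = Alphabet(self.alphabet)
        if not (0.0 < self.intra_identity <= 1.0):
            raise ValueError("intra_identity must be in (0, 1]")


def _draw(value: IntOrRange, rng: np.random.Generator) -> int:
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def random_sequence(length: int, rng: np.random.Generator,
                    alphabet: Alphabet = Alphabet.NUCLEOTIDE) -> str:
    symbols = _NT if Alphabet(alphabet) is Alphabet.NUCLEOTIDE else _AA
    return "".join(np.array(list(symbols))[rng.integers(0, len(symbols),
                                                        size=length)])


def mutate_sequence(seq: str, identity: float, rng: np.random.Generator,
                    alphabet: Alphabet = Alphabet.NUCLEOTIDE,
                    indel_rate: float = 0.0) -> str:
    """Independent per-site substitution with probability 1 − identity, to
    a uniformly random *different* symbol; optional geometric indels."""
    symbols = _NT if Alphabet(alphabet) is Alphabet.NUCLEOTIDE else _AA
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.frombuffer(symbols.encode(), dtype=np.uint8)
    hit = rng.random(len(codes)) < (1.0 - identity)
    n_hit = int(hit.sum())
    if n_hit:
        # offset 1..|A|-1 from the current symbol guarantees a change
        idx = np.searchsorted(lut, codes[hit])
        offsets = rng.integers(1, len(symbols), size=n_hit)
        codes[hit] = lut[(idx + offsets) % len(symbols)]
    out = codes.tobytes().decode()
    if indel_rate > 0.0:
        out = _apply_indels(out, indel_rate, rng, symbols)
    return out


def _apply_indels(seq: str, rate: float, rng: np.random.Generator,
                  symbols: str) -> str:
    pieces: list[str] = []
    i = 0
    while i < len(seq):
        if rng.random() < rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                i += length  # deletion
                continue
            ins = "".join(np.array(list(symbols))[
                rng.integers(0, len(symbols), size=length)])
            pieces.append(ins)
        pieces.append(seq[i])
        i += 1
    return "".join(pieces)


def generate_families(spec: FamilySpec) -> list[SequenceRecord]:
    """Generate labeled records; reproducible from ``spec.seed``.

    Record IDs are ``fam<f>_seq<m>`` and the family name doubles as the
    class label for label-balance experiments.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    ancestor = None
    if spec.ancestor_identity is not None:
        length = _draw(spec.seq_length, rng)
        ancestor = random_sequence(length, rng, spec.alphabet)
    for f in range(spec.n_families):
        if ancestor is not None:
            founder = mutate_sequence(ancestor, spec.ancestor_identity, rng,
                                      spec.alphabet)
        else:
            founder = random_sequence(_draw(spec.seq_length, rng), rng,
                                      spec.alphabet)
        label = f"family{f}"
        for m in range(_draw(spec.members_per_family, rng)):
            residues = mutate_sequence(founder, spec.intra_identity, rng,
                                       spec.alphabet,
                                       indel_rate=spec.indel_rate)
            records.append(
                SequenceRecord(id=f"fam{f}_seq{m}", residues=residues,
                               alphabet=spec.alphabet, label=label)
            )
    return records


# ---------------------------------------------------------------------------
# brute-force oracle, independent of the sketch/distance code path

_ORACLE_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _oracle_kmer_set(seq: str, k: int, canonical: bool,
                     allowed: str = "ACGT") -> set[str]:
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if any(c not in allowed for c in km):
            continue  # window touches an ambiguity symbol
        if canonical:
            rc = "".join(_ORACLE_RC[c] for c in reversed(km))
            km = min(km, rc)
        out.add(km)
    return out


def _oracle_distance(sa: set[str], sb: set[str], measure: str,
                     k: int) -> float:
    if not sa or not sb:
        return 1.0
    shared = len(sa & sb)
    a, b = len(sa), len(sb)
    if measure == "jaccard":
        return 1.0 - shared / (a + b - shared)
    if measure == "cosine":
        return 1.0 - shared / math.sqrt(a * b)
    if measure == "szymkiewicz_simpson":
        return 1.0 - shared / min(a, b)
    if measure == "inverse_coverage":
        return min(1.0, max(0.0, 1.0 - shared / ((a + b) / 2.0)))
    if measure == "mash":
        j = shared / (a + b - shared)
        if j == 0.0:
            return 1.0
        if j == 1.0:
            return 0.0
        return min(1.0, -(1.0 / k) * math.log(2.0 * j / (1.0 + j)))
    raise ValueError(f"unknown measure '{measure}'")


def exact_distance_oracle(records: list[SequenceRecord], k: int,
                          measure: str,
                          canonical: bool = True) -> np.ndarray:
    """Dense symmetric distance matrix on full (unsampled) k-mer sets.

    O(n²) set operations on plain string sets; intended for n up to a few
    hundred. Used to check that sketch distances converge to the exact
    values and that no cross-fold pair of a finished run is closer than
    epsilon.
    """
    measure = str(getattr(measure, "value", measure))
    nt = records[0].alphabet is Alphabet.NUCLEOTIDE
    canonical = canonical and nt
    allowed = "ACGT" if nt else _AA
    sets = [_oracle_kmer_set(r.residues, k, canonical, allowed)
            for r in records]
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _oracle_distance(sets[i], sets[j], measure, k)
            mat[i, j] = mat[j, i] = d
    return mat


def count_cross_fold_pairs_below(
    matrix: np.ndarray,
    fold_of_index: list[int],
    epsilon: float,
) -> int:
    """Number of sequence pairs in different folds with distance < epsilon."""
    folds = np.asarray(fold_of_index)
    cross = folds[:, None] != folds[None, :]
    below = matrix < epsilon
    return int(np.triu(cross & below, k=1).sum())
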