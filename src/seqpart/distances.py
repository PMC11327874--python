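"""Pairwise k-mer distances and the sparse epsilon-neighborhood graph.

Five measures over two key sets A, B with S = |A ∩ B|:

    jaccard              1 − S / (|A| + |B| − S)
    cosine               1 − S / sqrt(|A| · |B|)
    szymkiewicz_simpson  1 − S / min(|A|, |B|)
    inverse_coverage     1 − S / ((|A| + |B|) / 2), clamped to [0, 1]
    mash                 min(1, −(1/k) · ln(2J / (1 + J)))  with J the
                         Jaccard index; J = 0 maps to distance 1

Under MinHash sketching, set overlaps are estimated on the bottom-s sketch
of the *union* of the two sketches (the Mash estimator): merge the two key
sets, keep the s smallest, and count how many of those occur in both.

Note on inverse_coverage: the published definition of this measure was not
available to us; the mean-of-cardinalities denominator above is this
package's documented placeholder (it is 0 for identical sets and 1 for
disjoint sets, like the other measures) and should be treated as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

from .sketch import KmerSketch, SketchMode

logger = logging.getLogger(__name__)


class Measure(str, Enum):
    MASH = "mash"
    COSINE = "cosine"
    INVERSE_COVERAGE = "inverse_coverage"
    JACCARD = "jaccard"
    SZYMKIEWICZ_SIMPSON = "szymkiewicz_simpson"


@dataclass
class SparseDistanceGraph:
    """Symmetric sub-epsilon edge set over n sequences.

    Edges are stored once with i < j and strictly d < retention_threshold;
    pairs at exactly the threshold are allowed to land in different folds.
    When ``inverted`` is set, the stored d is the complement 1 − d of the
    measured distance (similar pairs become distant and vice versa).
    """

    n: int
    edges: list[tuple[int, int, float]]
    retention_threshold: float
    measure: Measure
    inverted: bool = False


def shared_counts(a: KmerSketch, b: KmerSketch) -> tuple[int, int, int]:
    """(shared, only_a, only_b) key counts of two same-scheme sketches.

    For MinHash sketches the counts are taken within the bottom-s sketch of
    the merged key set, so shared/(shared+only_a+only_b) is the Mash
    estimate of the Jaccard index.
    """
    if a.scheme != b.scheme:
        raise ValueError(
            f"cannot compare sketches with different schemes: "
            f"{a.scheme} vs {b.scheme}"
        )
    if SketchMode(a.scheme.mode) is SketchMode.MINHASH:
        s = a.scheme.sketch_size
        merged = sorted(a.keys | b.keys)[:s]
        shared = only_a = only_b = 0
        for key in merged:
            in_a = key in a.keys
            in_b = key in b.keys
            if in_a and in_b:
                shared += 1
            elif in_a:
                only_a += 1
            else:
                only_b += 1
        return shared, only_a, only_b
    shared = len(a.keys & b.keys)
    return shared, len(a.keys) - shared, len(b.keys) - shared


def jaccard_index(shared: int, only_a: int, only_b: int) -> float:
    """J = shared / union over the (possibly sketch-estimated) counts."""
    union = shared + only_a + only_b
    if union == 0:
        raise ValueError("Jaccard index undefined for two empty sketches")
    return shared / union


def mash_distance(j: float, k: int) -> float:
    """Mutation-rate estimate from a Jaccard index under a Poisson model."""
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return min(1.0, -(1.0 / k) * math.log(2.0 * j / (1.0 + j)))


def distance(measure: Measure | str, a: KmerSketch, b: KmerSketch) -> float:
    """Distance in [0, 1] between two sketches under the chosen measure.

    If either sketch is empty there is no k-mer evidence of similarity and
    the distance is defined as 1.0 (with a warning)."""
    measure = Measure(measure)
    if not a.keys or not b.keys:
        logger.warning(
            "empty sketch in pair (%s, %s): distance defined as 1.0",
            a.seq_id, b.seq_id,
        )
        return 1.0
    shared, only_a, only_b = shared_counts(a, b)
    size_a = shared + only_a
    size_b = shared + only_b
    if measure is Measure.MASH:
        j = jaccard_index(shared, only_a, only_b)
        return mash_distance(j, a.scheme.k)
    if measure is Measure.JACCARD:
        return 1.0 - shared / (size_a + size_b - shared)
    if measure is Measure.COSINE:
        return 1.0 - shared / math.sqrt(size_a * size_b)
    if measure is Measure.SZYMKIEWICZ_SIMPSON:
        return 1.0 - shared / min(size_a, size_b)
    # inverse_coverage placeholder (see module docstring)
    d = 1.0 - shared / ((size_a + size_b) / 2.0)
    return min(1.0, max(0.0, d))


def build_distance_graph(
    sketches: list[KmerSketch],
    measure: Measure | str,
    epsilon: float,
    inverted: bool = False,
    progress_every: int = 1_000_000,
) -> SparseDistanceGraph:
    """Evaluate all n(n-1)/2 pairs and keep edges with distance < epsilon.

    The dense matrix is never materialized; only sub-epsilon edges are
    stored. With ``inverted`` the complement 1 − d is thresholded and
    stored instead, so that similar sequences are treated as distant.
    """
    measure = Measure(measure)
    if len(sketches) < 2:
        raise ValueError("need at least 2 sketches")
    if not (0.0 < epsilon <= 1.0):
        raise ValueError("epsilon must be in (0, 1]")
    scheme = sketches[0].scheme
    for sk in sketches[1:]:
        if sk.scheme != scheme:
            raise ValueError("all sketches must share one scheme")
    n = len(sketches)
    edges: list[tuple[int, int, float]] = []
    done = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = distance(measure, sketches[i], sketches[j])
            if inverted:
                d = 1.0 - d
            if d < epsilon:
                edges.append((i, j, d))
            done += 1
            if progress_every and done % progress_every == 0:
                logger.info("distance pairs evaluated: %d", done)
    return SparseDistanceGraph(n=n, edges=edges,
                               retention_threshold=epsilon,
                               measure=measure, inverted=inverted)


def write_edge_list(graph: SparseDistanceGraph, seq_ids: list[str],
                    path) -> None:
    """TSV dump (id_i, id_j, distance) of the retained edges."""
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tdistance\n")
        for i, j, d in sorted(graph.edges):
            fh.write(f"{seq_ids[i]}\t{seq_ids[j]}\t{d:.6f}\n")


def write_phylip_matrix(sketches: list[KmerSketch],
                        measure: Measure | str, path) -> None:
    """Square PHYLIP-style distance matrix (debugging; n <= 1000)."""
    n = len(sketches)
    if n > 1000:
        raise ValueError("dense matrix writer is limited to n <= 1000")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i in range(n):
            row = [
                distance(measure, sketches[i], sketches[j]) if i != j else 0.0
                for j in range(n)
            ]
            name = sketches[i].seq_id[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{d:.6f}" for d in row) + "\n")
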