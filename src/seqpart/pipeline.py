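"""End-to-end run: sketch → distance graph → cluster → makespan → outputs.

The pipeline's defining guarantee: after a normal (non-inverted, no
redundancy pre-clustering) run, no two sequences in different folds are
closer than epsilon under the configured sketch distance. A self-audit
recounts the cross-fold sub-epsilon pairs at the end of every run and
reports the number in the summary; it must be 0 for a normal run.

Epsilon operationalizes the leakage threshold tau: the problem-specific
similarity above which phenotype is assumed conserved, so that cross-fold
pairs above that similarity would leak information between training and
evaluation data. Published choices include tau = 0.3 (protein subcellular
location) and tau = 0.7 (RNA secondary structure); the right value is
problem-specific and is deliberately not defaulted here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import cluster as _cluster
from . import io as _io
from .distances import Measure, build_distance_graph, distance
from .makespan import MakespanConfig, partition_clusters
from .sketch import KmerSketch, SketchScheme, sketch_dataset

logger = logging.getLogger(__name__)


@dataclass
class HobohmConfig:
    threshold: float
    order: str = "length_desc"


@dataclass
class RunConfig:
    input_fasta: str
    output_prefix: str
    scheme: SketchScheme
    epsilon: float
    n_partitions: int
    measure: Measure = Measure.MASH
    alphabet: _io.Alphabet = _io.Alphabet.NUCLEOTIDE
    labels: Optional[str] = None
    strict_labels: bool = False
    permissive: bool = False
    makespan: Optional[MakespanConfig] = None
    hobohm: Optional[HobohmConfig] = None
    inverted: bool = False
    write_fold_fasta: bool = False
    audit: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.measure = Measure(self.measure)
        self.alphabet = _io.Alphabet(self.alphabet)
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must be in (0, 1]")
        if (self.alphabet is _io.Alphabet.AMINO_ACID
                and self.measure is not Measure.MASH):
            raise ValueError(
                "amino-acid distances are only defined for the mash measure"
            )
        if self.makespan is None:
            self.makespan = MakespanConfig(n_partitions=self.n_partitions,
                                           seed=self.seed)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def leakage_audit(sketches: list[KmerSketch], measure: Measure,
                  epsilon: float, fold_of_index: list[int]) -> int:
    """Count cross-fold pairs with sketch distance < epsilon."""
    count = 0
    n = len(sketches)
    for i in range(n):
        for j in range(i + 1, n):
            if fold_of_index[i] == fold_of_index[j]:
                continue
            if distance(measure, sketches[i], sketches[j]) < epsilon:
                count += 1
    return count


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the declared outputs.

    Returns the summary dictionary (also written to
    ``<prefix>_summary.json``). Outputs: ``<prefix>_partitions.tsv`` and
    optionally one FASTA per fold. Any stage failure removes partial
    outputs and raises :class:`StageError`.
    """
    prefix = Path(config.output_prefix)
    produced: list[Path] = []
    try:
        return _run_inner(config, prefix, produced)
    except StageError:
        for path in produced:
            path.unlink(missing_ok=True)
        raise


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(name, exc) from exc
    return wrap


def _run_inner(config: RunConfig, prefix: Path,
               produced: list[Path]) -> dict:
    records = _stage("read_input")(
        _io.read_fasta, config.input_fasta, config.alphabet,
        permissive=config.permissive,
    )
    if config.labels:
        _stage("read_labels")(
            _io.read_labels, config.labels, records,
            strict=config.strict_labels,
        )
    logger.info("read %d sequences", len(records))

    sketches = _stage("sketch")(sketch_dataset, records, config.scheme)

    pre = None
    if config.hobohm is not None:
        pre = _stage("hobohm")(
            _cluster.hobohm1, records, sketches, config.measure,
            config.hobohm.threshold, config.hobohm.order,
        )
        rep_ids = {c.representative_id for c in pre.clusters}
        keep = [i for i, r in enumerate(records) if r.id in rep_ids]
        graph_records = [records[i] for i in keep]
        graph_sketches = [sketches[i] for i in keep]
    else:
        graph_records = records
        graph_sketches = sketches

    graph = _stage("distances")(
        build_distance_graph, graph_sketches, config.measure,
        config.epsilon, inverted=config.inverted,
    )
    clusters = _stage("clustering")(_cluster.dbscan_min1, graph,
                                    graph_records)
    if pre is not None:
        clusters = _stage("clustering")(_cluster.merge_preclusters, pre,
                                        clusters, records)

    plan = _stage("makespan")(partition_clusters, clusters, config.makespan)

    fold_of_seq = plan.fold_of_sequence(clusters)
    table_path = prefix.parent / f"{prefix.name}_partitions.tsv"
    produced.append(table_path)
    _stage("write_outputs")(_io.write_partition_table, plan, clusters,
                            table_path)
    if config.write_fold_fasta:
        produced.extend(
            _stage("write_outputs")(_io.write_fold_fastas, records,
                                    fold_of_seq, prefix)
        )

    audit_count = None
    if config.audit:
        fold_of_index = [fold_of_seq[r.id] for r in records]
        audit_count = _stage("audit")(
            leakage_audit, sketches, config.measure, config.epsilon,
            fold_of_index,
        )
        if config.hobohm is not None:
            logger.info(
                "audit with redundancy pre-clustering enabled: absorbed "
                "members may introduce cross-fold similarity"
            )
        elif not config.inverted and audit_count:
            logger.error(
                "separation violated: %d cross-fold pairs below epsilon",
                audit_count,
            )

    sizes = [0] * config.n_partitions
    label_counts: dict[str, list[int]] = {}
    for rec in records:
        fold = fold_of_seq[rec.id]
        sizes[fold] += 1
        if rec.label is not None:
            label_counts.setdefault(rec.label,
                                    [0] * config.n_partitions)[fold] += 1
    empty = [f + 1 for f, s in enumerate(sizes) if s == 0]
    if empty:
        logger.warning("folds %s are empty", empty)

    objective = plan.objective
    summary = {
        "n_sequences": len(records),
        "n_clusters": len(clusters.clusters),
        "largest_cluster_fraction": max(c.size for c in clusters.clusters)
        / len(records),
        "fold_sizes": sizes,
        "fold_label_counts": label_counts,
        "objective": list(objective) if isinstance(objective, tuple)
        else objective,
        "criterion": config.makespan.criterion.value,
        "measure": config.measure.value,
        "epsilon": config.epsilon,
        "inverted": config.inverted,
        "leakage_pairs_below_epsilon": audit_count,
    }
    summary_path = prefix.parent / f"{prefix.name}_summary.json"
    produced.append(summary_path)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
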