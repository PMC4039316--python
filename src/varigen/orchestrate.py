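"""Deterministic generation of N genomes, optionally in parallel.

Every fragment gets its own random stream derived from (base seed,
genome index, chromosome, fragment index), so results are identical for
any worker count and any scheduling order; parallelism is plain
process-level fan-out over fragments.
"""

from __future__ import annotations

import json
import logging
import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import assembly, frequency
from .mutate import mutate_fragment
from .types import (
    AppliedMutation,
    Fragment,
    FrequencyTable,
    GenomeManifest,
    MutationOutcome,
)

logger = logging.getLogger(__name__)


def derive_fragment_seed(
    base_seed: int, genome_index: int, chrom: str, fragment_index: int
) -> np.random.SeedSequence:
    """Stable per-fragment seed, independent of worker scheduling.

    The chromosome name enters through its CRC-32, keeping the
    derivation purely arithmetic and collision-resistant via numpy's
    SeedSequence spawn keys.
    """
    return np.random.SeedSequence(
        entropy=base_seed,
        spawn_key=(genome_index, zlib.crc32(chrom.encode()), fragment_index),
    )


def fragment_rng(
    base_seed: int, genome_index: int, chrom: str, fragment_index: int
) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(derive_fragment_seed(base_seed, genome_index, chrom, fragment_index))
    )


@dataclass
class RunConfig:
    """Configuration for one generation run."""

    reference: str
    freq_dir: str
    out_dir: str
    n_genomes: int = 1
    seed: int = 0
    workers: int = 1
    fragment_length: Optional[int] = None  # default: the table's
    sv_spec: Optional[str] = None
    genome_prefix: str = "sim"
    parent_id: str = "parent"

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


# worker-process global, set once per worker by the pool initializer
_WORKER_TABLE: Optional[FrequencyTable] = None


def _init_worker(table: FrequencyTable) -> None:
    global _WORKER_TABLE
    _WORKER_TABLE = table


def _mutate_task(args: tuple[Fragment, int, int, str]) -> tuple[str, int, MutationOutcome]:
    frag, base_seed, genome_index, genome_id = args
    assert _WORKER_TABLE is not None
    rng = fragment_rng(base_seed, genome_index, frag.chrom, frag.index)
    outcome = mutate_fragment(
        frag.sequence,
        _WORKER_TABLE,
        rng,
        chrom=frag.chrom,
        fragment_index=frag.index,
        fragment_offset=frag.start,
        genome_id=genome_id,
    )
    return frag.chrom, frag.index, outcome


def generate_genome(
    parent: dict[str, str],
    table: FrequencyTable,
    *,
    base_seed: int,
    genome_index: int,
    genome_id: str,
    workers: int = 1,
    executor: Optional[ProcessPoolExecutor] = None,
) -> tuple[dict[str, str], list[AppliedMutation]]:
    """Mutate and reassemble one genome; returns (sequences, mutation log)."""
    L = table.fragment_length
    fragments = [
        Fragment(chrom, k // L, k, full[k : k + L])
        for chrom, full in parent.items()
        for k in range(0, len(full), L)
    ]

    tasks = [(f, base_seed, genome_index, genome_id) for f in fragments]
    if executor is not None and workers > 1:
        results = list(executor.map(_mutate_task, tasks, chunksize=32))
    else:
        _init_worker(table)
        results = [_mutate_task(t) for t in tasks]

    per_chrom: dict[str, list[tuple[int, str]]] = {chrom: [] for chrom in parent}
    log: list[AppliedMutation] = []
    for chrom, idx, outcome in results:
        per_chrom[chrom].append((idx, outcome.mutated_sequence))
        log.extend(outcome.applied)
    sequences = {
        chrom: assembly.assemble_chromosome(frags) for chrom, frags in per_chrom.items()
    }
    return sequences, log


def run_generate(config: RunConfig) -> list[GenomeManifest]:
    """Generate ``n_genomes`` simulated genomes with full provenance.

    For each genome: fragment the parent, mutate every fragment under
    its derived seed, reassemble, splice engineered SVs if configured,
    and write per-chromosome FASTA files, a TSV mutation log, and a JSON
    manifest under ``out_dir/<genome_id>/``.
    """
    table = frequency.read_frequency_table(config.freq_dir)
    if config.fragment_length is not None and config.fragment_length != table.fragment_length:
        raise ValueError(
            f"configured fragment_length {config.fragment_length} does not match "
            f"frequency table's {table.fragment_length}"
        )
    parent = frequency.read_reference(config.reference)
    missing = set(parent) - set(table.profiles)
    if missing:
        raise ValueError(f"frequency table lacks chromosomes: {sorted(missing)}")
    sv_list = assembly.read_sv_spec(config.sv_spec) if config.sv_spec else []

    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    executor: Optional[ProcessPoolExecutor] = None
    if config.workers > 1:
        executor = ProcessPoolExecutor(
            max_workers=config.workers, initializer=_init_worker, initargs=(table,)
        )
    manifests = []
    try:
        for i in range(config.n_genomes):
            genome_id = f"{config.genome_prefix}{i:03d}"
            sequences, log = generate_genome(
                parent,
                table,
                base_seed=config.seed,
                genome_index=i,
                genome_id=genome_id,
                workers=config.workers,
                executor=executor,
            )
            if sv_list:
                sequences, sv_log = assembly.apply_engineered_sv(
                    sequences, sv_list, genome_id
                )
                log.extend(sv_log)
            genome_dir = out_root / genome_id
            assembly.write_fasta(sequences, genome_dir, genome_id, config.parent_id)
            assembly.write_mutation_log(log, genome_dir / "mutations.tsv")
            manifest = GenomeManifest(
                genome_id=genome_id,
                parent_id=config.parent_id,
                seed=config.seed,
                fragment_length=table.fragment_length,
                chromosomes=[
                    (chrom, len(parent[chrom]), len(sequences[chrom]))
                    for chrom in parent
                ],
                table_provenance=table.provenance,
            )
            with open(genome_dir / "manifest.json", "w") as fh:
                json.dump(
                    {
                        "genome_id": manifest.genome_id,
                        "parent_id": manifest.parent_id,
                        "seed": manifest.seed,
                        "fragment_length": manifest.fragment_length,
                        "chromosomes": [
                            {"name": n, "parent_length": pl, "output_length": ol}
                            for n, pl, ol in manifest.chromosomes
                        ],
                        "table_provenance": manifest.table_provenance,
                    },
                    fh,
                    indent=2,
                )
            class_totals: dict[str, int] = {}
            for m in log:
                class_totals[m.variant_class] = class_totals.get(m.variant_class, 0) + 1
            logger.info("genome %s: per-class totals %s", genome_id, class_totals)
            manifests.append(manifest)
    finally:
        if executor is not None:
            executor.shutdown()
    return manifests
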