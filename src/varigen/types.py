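"""Core domain types for frequency-driven genome simulation.

Coordinate conventions: all on-disk formats (FASTA, GVF, VCF, mutation
logs) use 1-based inclusive coordinates; everything in memory uses
0-based half-open intervals.  Every function that crosses the boundary
says which frame it speaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class VariantClass(str, Enum):
    """Variant classes tracked by the simulator.

    ``TRANSLOCATION`` only ever appears in mutation logs for engineered
    structural variants; it is never sampled from frequency tables.
    """

    SNV = "SNV"
    DELETION = "deletion"
    INSERTION = "insertion"
    SEQUENCE_ALTERATION = "sequence_alteration"
    INVERSION = "inversion"
    TANDEM_DUPLICATION = "tandem_duplication"
    TRANSLOCATION = "translocation"

    def __str__(self) -> str:  # keep TSV/log output clean
        return self.value


#: Classes that participate in frequency estimation and sampling.
CORE_CLASSES: tuple[VariantClass, ...] = (
    VariantClass.SNV,
    VariantClass.DELETION,
    VariantClass.INSERTION,
    VariantClass.SEQUENCE_ALTERATION,
    VariantClass.INVERSION,
    VariantClass.TANDEM_DUPLICATION,
)

#: Size-dependent classes (every core class except SNV).
SIZE_CLASSES: tuple[VariantClass, ...] = tuple(
    c for c in CORE_CLASSES if c is not VariantClass.SNV
)

#: Fixed application order within a fragment: deletions first, tandem
#: duplications last.
APPLICATION_ORDER: tuple[VariantClass, ...] = (
    VariantClass.DELETION,
    VariantClass.INSERTION,
    VariantClass.SEQUENCE_ALTERATION,
    VariantClass.INVERSION,
    VariantClass.SNV,
    VariantClass.TANDEM_DUPLICATION,
)

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantRecord:
    """One observed variant from a GVF/VCF file (1-based start)."""

    chrom: str
    start: int
    variant_class: VariantClass
    size: int
    ref_base: str = ""
    alt_base: str = ""
    validation_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.size < 1:
            raise ValueError(f"size must be >= 1, got {self.size}")
        if self.variant_class is VariantClass.SNV:
            if self.size != 1:
                raise ValueError("SNV size must be 1")
            if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
                raise ValueError(
                    f"SNV bases must be A/C/G/T, got {self.ref_base!r}>{self.alt_base!r}"
                )
            if self.ref_base == self.alt_base:
                raise ValueError("SNV ref and alt must differ")

    @property
    def dedup_key(self) -> tuple:
        """Uniqueness key: (chrom, start, class, size, alt)."""
        return (self.chrom, self.start, self.variant_class, self.size, self.alt_base)


@dataclass
class FragmentProfile:
    """Per-class variant counts observed on one reference fragment.

    ``gc_fraction`` is ``None`` when GC is undefined for the fragment
    (all-ambiguous sequence, or ambiguity above the configured
    threshold); such profiles are excluded from GC binning.
    """

    chrom: str
    fragment_index: int
    gc_fraction: Optional[float]
    counts: dict[VariantClass, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction must be in [0,1], got {self.gc_fraction}")
        for cls, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cls}: {n}")
        # canonical form: zero counts are implicit (keeps equality stable
        # across serialization round trips)
        self.counts = {c: n for c, n in self.counts.items() if n > 0}

    def count(self, cls: VariantClass) -> int:
        return self.counts.get(cls, 0)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SizeBin:
    """Closed size range [min_size, max_size] with its probability."""

    min_size: int
    max_size: int
    probability: float

    def __post_init__(self) -> None:
        if self.min_size > self.max_size:
            raise ValueError(f"min_size {self.min_size} > max_size {self.max_size}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability out of range: {self.probability}")

    def contains(self, size: int) -> bool:
        return self.min_size <= size <= self.max_size


@dataclass
class SizeDistribution:
    """Genome-wide size probabilities per size-dependent variant class."""

    bins: dict[VariantClass, list[SizeBin]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for cls, cls_bins in self.bins.items():
            if cls is VariantClass.SNV:
                raise ValueError("SNV has no size distribution")
            ordered = sorted(cls_bins, key=lambda b: b.min_size)
            for a, b in zip(ordered, ordered[1:]):
                if b.min_size <= a.max_size:
                    raise ValueError(f"overlapping size bins for {cls}: {a}, {b}")
            total = sum(b.probability for b in cls_bins)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{cls} size probabilities sum to {total}, not 1")

    def sample(self, cls: VariantClass, rng: np.random.Generator) -> int:
        """Draw a size: pick a range by probability, then uniformly within it."""
        cls_bins = self.bins[cls]
        probs = [b.probability for b in cls_bins]
        idx = rng.choice(len(cls_bins), p=probs)
        b = cls_bins[idx]
        return int(rng.integers(b.min_size, b.max_size + 1))


@dataclass
class SnvTransitionMatrix:
    """Per reference base, probabilities over the three substitute bases."""

    rows: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for base in NUCLEOTIDES:
            if base not in self.rows:
                raise ValueError(f"missing row for base {base}")
            row = self.rows[base]
            if base in row:
                raise ValueError(f"self-transition entry in row {base}")
            alts = set(row)
            if alts != set(NUCLEOTIDES) - {base}:
                raise ValueError(f"row {base} must cover the 3 other bases, got {alts}")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"negative probability in row {base}")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"row {base} sums to {total}, not 1")

    @classmethod
    def uniform(cls) -> "SnvTransitionMatrix":
        third = 1.0 / 3.0
        return cls(
            {
                b: {a: third for a in NUCLEOTIDES if a != b}
                for b in NUCLEOTIDES
            }
        )

    def sample(self, base: str, rng: np.random.Generator) -> str:
        """Draw the substitute base for a reference base; never the identity."""
        row = self.rows[base.upper()]
        alts = sorted(row)  # stable order for reproducibility
        probs = [row[a] for a in alts]
        return alts[rng.choice(len(alts), p=probs)]


@dataclass
class FrequencyTable:
    """The simulator's full parameterization.

    ``profiles`` maps chromosome -> list of GC bins -> list of observed
    fragment profiles.  Empty bins are represented as empty lists, never
    dropped.
    """

    fragment_length: int
    bin_edges: list[float]
    profiles: dict[str, list[list[FragmentProfile]]]
    size_dist: SizeDistribution
    snv_matrix: SnvTransitionMatrix
    provenance: str = ""

    def __post_init__(self) -> None:
        edges = self.bin_edges
        if len(edges) < 2 or edges[0] != 0.0 or edges[-1] != 1.0:
            raise ValueError("bin_edges must span [0, 1]")
        if any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValueError("bin_edges must be strictly increasing")
        for chrom, bins in self.profiles.items():
            if len(bins) != self.n_bins:
                raise ValueError(
                    f"chromosome {chrom} has {len(bins)} bins, expected {self.n_bins}"
                )

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_index(self, gc: float) -> int:
        """Bin for a GC fraction: half-open [e_i, e_{i+1}), last bin closed."""
        if not (0.0 <= gc <= 1.0):
            raise ValueError(f"gc out of range: {gc}")
        idx = int(np.searchsorted(self.bin_edges, gc, side="right")) - 1
        return min(idx, self.n_bins - 1)

    def bin_center(self, idx: int) -> float:
        return 0.5 * (self.bin_edges[idx] + self.bin_edges[idx + 1])

    def mean_counts(self, chrom: str | None = None) -> dict[VariantClass, float]:
        """Mean per-fragment count of each core class over all binned profiles."""
        pool: list[FragmentProfile] = []
        chroms = [chrom] if chrom is not None else list(self.profiles)
        for c in chroms:
            for b in self.profiles[c]:
                pool.extend(b)
        if not pool:
            return {c: 0.0 for c in CORE_CLASSES}
        return {
            c: sum(p.count(c) for p in pool) / len(pool) for c in CORE_CLASSES
        }


@dataclass
class AppliedMutation:
    """One concrete edit, sufficient to replay it on the parent sequence.

    ``parent_start`` is 1-based in parent chromosome coordinates.  The
    edit semantics are uniform replacement: the bases ``ref_seq`` found
    at ``parent_start`` are replaced by ``alt_seq``.  For insertions
    ``ref_seq`` is empty and the insertion occurs immediately before
    parent position ``parent_start``.  ``origin`` is ``"background"``
    for frequency-driven edits and ``"engineered"`` for spliced SVs
    (whose coordinates are in the assembled-genome frame).
    """

    genome_id: str
    chrom: str
    fragment_index: int
    parent_start: int
    variant_class: str
    size: int
    ref_seq: str
    alt_seq: str
    origin: str = "background"

    def __post_init__(self) -> None:
        cls = self.variant_class
        if cls == VariantClass.SNV.value:
            if len(self.ref_seq) != 1 or len(self.alt_seq) != 1:
                raise ValueError("SNV ref/alt must be single bases")
            if self.ref_seq == self.alt_seq:
                raise ValueError("SNV ref and alt must differ")
        if cls in (
            VariantClass.DELETION.value,
            VariantClass.INVERSION.value,
            VariantClass.SEQUENCE_ALTERATION.value,
        ):
            if len(self.ref_seq) != self.size:
                raise ValueError(
                    f"{cls} ref_seq length {len(self.ref_seq)} != size {self.size}"
                )

    @property
    def start0(self) -> int:
        """0-based start of the replaced interval (insertion point for insertions)."""
        return self.parent_start - 1

    @property
    def length_delta(self) -> int:
        return len(self.alt_seq) - len(self.ref_seq)


@dataclass
class MutationOutcome:
    """Result of mutating one fragment."""

    mutated_sequence: str
    applied: list[AppliedMutation]
    skipped: dict[VariantClass, int]

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


@dataclass(frozen=True)
class Fragment:
    """A window of a chromosome: the unit of parallel mutation.

    ``start`` is the 0-based offset of the fragment within its
    chromosome.
    """

    chrom: str
    index: int
    start: int
    sequence: str


@dataclass(frozen=True)
class EngineeredSV:
    """A user-specified structural event spliced into an assembled genome.

    Coordinates are 1-based inclusive.  ``mate_*`` fields are only used
    by translocations (the second interval; may be on another
    chromosome).
    """

    sv_class: str  # deletion | insertion | inversion | duplication | translocation
    chrom: str
    start: int
    end: int
    payload: str = ""
    mate_chrom: str = ""
    mate_start: int = 0
    mate_end: int = 0

    VALID_CLASSES = ("deletion", "insertion", "inversion", "duplication", "translocation")

    def __post_init__(self) -> None:
        if self.sv_class not in self.VALID_CLASSES:
            raise ValueError(f"unknown engineered SV class: {self.sv_class}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.sv_class == "insertion" and not self.payload:
            raise ValueError("insertion requires a payload sequence")
        if self.sv_class == "translocation":
            if not self.mate_chrom or self.mate_start < 1 or self.mate_end < self.mate_start:
                raise ValueError("translocation requires a valid mate interval")


@dataclass
class GenomeManifest:
    """Provenance record for one simulated genome."""

    genome_id: str
    parent_id: str
    seed: int
    fragment_length: int
    chromosomes: list[tuple[str, int, int]]  # (name, parent length, output length)
    table_provenance: str = ""
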