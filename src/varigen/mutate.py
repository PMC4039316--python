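"""Fragment mutation rules.

Each fragment is mutated in three steps: (1) its GC content selects a
bin of observed fragment profiles, (2) one profile is sampled uniformly
from the bin — its per-class counts become the fragment's mutation
budget, (3) sites are drawn without replacement and the variants
applied class by class in a fixed order (deletions first, tandem
duplications last).

Sites for every class are reserved in parent-fragment coordinates
against a shared, pairwise-disjoint interval set; classes are then
applied in order on the progressively edited sequence, translating each
parent interval through the length changes of previously applied edits.
Because the reserved intervals are disjoint in parent space, the final
sequence equals the splice of all replacements into the parent fragment
— which is exactly what the log-replay verifier recomputes.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .frequency import compute_gc
from .types import (
    APPLICATION_ORDER,
    NUCLEOTIDES,
    AppliedMutation,
    FragmentProfile,
    FrequencyTable,
    MutationOutcome,
    SnvTransitionMatrix,
    VariantClass,
)

logger = logging.getLogger(__name__)

MAX_PLACEMENT_ATTEMPTS = 100

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def assign_gc_bin(
    fragment_sequence: str, table: FrequencyTable, chrom: str
) -> Optional[tuple[int, list[FragmentProfile]]]:
    """Fit a fragment to its GC bin; fall back to the nearest non-empty bin.

    Returns ``(bin_index, profiles)`` or ``None`` when the fragment has
    undefined GC (all-ambiguous) — the "no mutation" sentinel.  When the
    fragment's own bin holds no observed profiles the nearest non-empty
    bin by bin-center distance is used (ties resolve to the lower bin).
    """
    if chrom not in table.profiles:
        raise KeyError(f"chromosome {chrom!r} absent from frequency table")
    gc = compute_gc(fragment_sequence)
    if gc is None:
        return None
    bins = table.profiles[chrom]
    idx = table.bin_index(gc)
    if bins[idx]:
        return idx, bins[idx]
    non_empty = [j for j, b in enumerate(bins) if b]
    if not non_empty:
        raise ValueError(f"no observed profiles for chromosome {chrom!r}")
    center = table.bin_center(idx)
    best = min(non_empty, key=lambda j: (abs(table.bin_center(j) - center), j))
    logger.debug("chrom %s: empty bin %d, falling back to bin %d", chrom, idx, best)
    return best, bins[best]


def sample_profile(
    bin_profiles: Sequence[FragmentProfile], rng: np.random.Generator
) -> FragmentProfile:
    """Uniform draw of one observed profile from a GC bin."""
    if not bin_profiles:
        raise ValueError("cannot sample from an empty GC bin")
    return bin_profiles[int(rng.integers(len(bin_profiles)))]


def _overlaps(start: int, end: int, reserved: list[tuple[int, int]]) -> bool:
    return any(start < r_end and r_start < end for r_start, r_end in reserved)


def select_sites(
    fragment_sequence: str,
    requests: Sequence[tuple[VariantClass, int]],
    rng: np.random.Generator,
    reserved: Optional[list[tuple[int, int]]] = None,
    *,
    max_attempts: int = MAX_PLACEMENT_ATTEMPTS,
) -> tuple[list[tuple[VariantClass, int, int]], dict[VariantClass, int]]:
    """Draw non-overlapping parent-coordinate sites for a mutation budget.

    ``requests`` is an ordered list of (class, size) pairs.  Each site
    is drawn uniformly among the 0-based start positions where the
    mutation fits inside the fragment; a draw that overlaps a reserved
    interval (or, for SNVs, lands on an ambiguous base) is rejected and
    redrawn, up to ``max_attempts`` times, after which the mutation is
    skipped.  Insertions reserve a single anchor position; the insertion
    point is immediately before it.

    Returns (placements, skipped) where placements are (class, size,
    start0) triples.  ``reserved`` is extended in place when given, so
    successive calls share one reservation set.
    """
    L = len(fragment_sequence)
    if L < 1:
        raise ValueError("fragment must be non-empty")
    if reserved is None:
        reserved = []
    placements: list[tuple[VariantClass, int, int]] = []
    skipped: dict[VariantClass, int] = {}
    for cls, size in requests:
        span = 1 if cls in (VariantClass.SNV, VariantClass.INSERTION) else size
        if span > L:
            skipped[cls] = skipped.get(cls, 0) + 1
            continue
        placed = False
        for _ in range(max_attempts):
            start = int(rng.integers(0, L - span + 1))
            if _overlaps(start, start + span, reserved):
                continue
            if cls is VariantClass.SNV and fragment_sequence[start].upper() not in NUCLEOTIDES:
                continue
            reserved.append((start, start + span))
            placements.append((cls, size, start))
            placed = True
            break
        if not placed:
            skipped[cls] = skipped.get(cls, 0) + 1
    return placements, skipped


def _random_bases(size: int, rng: np.random.Generator) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=size))


def _splice(sequence: str, start: int, end: int, replacement: str) -> str:
    return sequence[:start] + replacement + sequence[end:]


def _make_mutation(
    cls: VariantClass,
    start0_parent: int,
    ref_seq: str,
    alt_seq: str,
    size: int,
    *,
    genome_id: str = "",
    chrom: str = "",
    fragment_index: int = 0,
    fragment_offset: int = 0,
) -> AppliedMutation:
    return AppliedMutation(
        genome_id=genome_id,
        chrom=chrom,
        fragment_index=fragment_index,
        parent_start=fragment_offset + start0_parent + 1,
        variant_class=cls.value,
        size=size,
        ref_seq=ref_seq,
        alt_seq=alt_seq,
    )


def apply_snv(
    sequence: str,
    site: int,
    matrix: SnvTransitionMatrix,
    rng: np.random.Generator,
    **meta,
) -> tuple[str, AppliedMutation]:
    """Substitute the base at ``site`` (0-based) according to the matrix row."""
    base = sequence[site].upper()
    if base not in NUCLEOTIDES:
        raise ValueError(f"ambiguous base {base!r} at SNV site {site}")
    alt = matrix.sample(base, rng)
    mutated = _splice(sequence, site, site + 1, alt)
    return mutated, _make_mutation(VariantClass.SNV, site, base, alt, 1, **meta)


def apply_deletion(
    sequence: str, start: int, size: int, rng: np.random.Generator, **meta
) -> tuple[str, AppliedMutation]:
    _check_interval(sequence, start, size)
    ref = sequence[start : start + size]
    return (
        _splice(sequence, start, start + size, ""),
        _make_mutation(VariantClass.DELETION, start, ref, "", size, **meta),
    )


def apply_insertion(
    sequence: str, start: int, size: int, rng: np.random.Generator, **meta
) -> tuple[str, AppliedMutation]:
    """Insert ``size`` uniform-random bases immediately before ``start``."""
    if not (0 <= start <= len(sequence)):
        raise ValueError(f"insertion point {start} outside sequence")
    alt = _random_bases(size, rng)
    return (
        _splice(sequence, start, start, alt),
        _make_mutation(VariantClass.INSERTION, start, "", alt, size, **meta),
    )


def apply_sequence_alteration(
    sequence: str, start: int, size: int, rng: np.random.Generator, **meta
) -> tuple[str, AppliedMutation]:
    """Replace the interval with an equal-length random sequence (>=1 change)."""
    _check_interval(sequence, start, size)
    ref = sequence[start : start + size]
    alt = _random_bases(size, rng)
    while alt == ref.upper():
        alt = _random_bases(size, rng)
    return (
        _splice(sequence, start, start + size, alt),
        _make_mutation(VariantClass.SEQUENCE_ALTERATION, start, ref, alt, size, **meta),
    )


def apply_inversion(
    sequence: str, start: int, size: int, rng: np.random.Generator, **meta
) -> tuple[str, AppliedMutation]:
    _check_interval(sequence, start, size)
    ref = sequence[start : start + size]
    alt = reverse_complement(ref)
    return (
        _splice(sequence, start, start + size, alt),
        _make_mutation(VariantClass.INVERSION, start, ref, alt, size, **meta),
    )


def apply_tandem_duplication(
    sequence: str, start: int, size: int, rng: np.random.Generator, **meta
) -> tuple[str, AppliedMutation]:
    """Insert one extra copy of the interval immediately after it."""
    _check_interval(sequence, start, size)
    ref = sequence[start : start + size]
    return (
        _splice(sequence, start, start + size, ref + ref),
        _make_mutation(VariantClass.TANDEM_DUPLICATION, start, ref, ref + ref, size, **meta),
    )


def _check_interval(sequence: str, start: int, size: int) -> None:
    if start < 0 or start + size > len(sequence):
        raise ValueError(
            f"interval [{start}, {start + size}) outside sequence of length {len(sequence)}"
        )


_STRUCTURAL_APPLIERS = {
    VariantClass.DELETION: apply_deletion,
    VariantClass.INSERTION: apply_insertion,
    VariantClass.SEQUENCE_ALTERATION: apply_sequence_alteration,
    VariantClass.INVERSION: apply_inversion,
    VariantClass.TANDEM_DUPLICATION: apply_tandem_duplication,
}


def mutate_fragment(
    fragment_sequence: str,
    table: FrequencyTable,
    rng: np.random.Generator,
    *,
    chrom: str,
    fragment_index: int = 0,
    fragment_offset: int = 0,
    genome_id: str = "",
) -> MutationOutcome:
    """Mutate one fragment: GC-bin lookup, profile sampling, staged application.

    ``fragment_offset`` is the 0-based offset of the fragment within its
    chromosome, so logged mutations carry parent-chromosome coordinates.
    The returned log, replayed onto the parent fragment, reconstructs
    ``mutated_sequence`` byte-for-byte.
    """
    hit = assign_gc_bin(fragment_sequence, table, chrom)
    if hit is None:
        return MutationOutcome(fragment_sequence, [], {})
    _, bin_profs = hit
    profile = sample_profile(bin_profs, rng)

    meta = dict(
        genome_id=genome_id,
        chrom=chrom,
        fragment_index=fragment_index,
        fragment_offset=fragment_offset,
    )
    sequence = fragment_sequence
    reserved: list[tuple[int, int]] = []
    applied: list[AppliedMutation] = []
    skipped: dict[VariantClass, int] = {}
    # (parent start0, length delta) of already-applied edits, for
    # translating parent coordinates onto the edited sequence
    shifts: list[tuple[int, int]] = []

    for cls in APPLICATION_ORDER:
        n = profile.count(cls)
        if n == 0:
            continue
        if cls is VariantClass.SNV:
            sizes = [1] * n
        else:
            sizes = [table.size_dist.sample(cls, rng) for _ in range(n)]
        placements, cls_skipped = select_sites(
            fragment_sequence, [(cls, s) for s in sizes], rng, reserved
        )
        for k, v in cls_skipped.items():
            skipped[k] = skipped.get(k, 0) + v
        for p_cls, size, parent_start in placements:
            shift = sum(d for s, d in shifts if s < parent_start)
            cur = parent_start + shift
            if p_cls is VariantClass.SNV:
                sequence, mut = apply_snv(sequence, cur, table.snv_matrix, rng, **meta)
            else:
                sequence, mut = _STRUCTURAL_APPLIERS[p_cls](
                    sequence, cur, size, rng, **meta
                )
            # re-anchor the log record at the parent coordinate
            mut.parent_start = fragment_offset + parent_start + 1
            applied.append(mut)
            shifts.append((parent_start, mut.length_delta))

    return MutationOutcome(sequence, applied, skipped)


def replay_fragment(parent_sequence: str, mutations: Sequence[AppliedMutation]) -> str:
    """Reconstruct a mutated fragment by splicing logged replacements.

    Interprets each mutation's coordinates as fragment-local (the
    caller subtracts any chromosome offset).  Because applied intervals
    are pairwise disjoint in parent coordinates, sorting by start and
    splicing left to right is order-independent and reproduces the
    engine's output exactly.
    """
    pieces: list[str] = []
    cursor = 0
    for m in sorted(mutations, key=lambda m: m.start0):
        if m.start0 < cursor:
            raise ValueError("overlapping mutations in replay log")
        pieces.append(parent_sequence[cursor : m.start0])
        pieces.append(m.alt_seq)
        cursor = m.start0 + len(m.ref_seq)
    pieces.append(parent_sequence[cursor:])
    return "".join(pieces)
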