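"""Build variation-frequency tables from observed variants and a reference.

The pipeline has four steps: filter/parse variant files, segment each
chromosome into fixed-length fragments and count variants per class per
fragment, bin the fragments by GC content (default 10 equal-width bins),
and estimate the genome-wide size distribution and SNV transition
matrix.  The resulting :class:`~varigen.types.FrequencyTable` is the
simulator's complete parameterization and round-trips through a
directory of four TSV files.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    CORE_CLASSES,
    NUCLEOTIDES,
    SIZE_CLASSES,
    FragmentProfile,
    FrequencyTable,
    SizeBin,
    SizeDistribution,
    SnvTransitionMatrix,
    VariantClass,
    VariantRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_FRAGMENT_LENGTH = 1000
DEFAULT_BIN_EDGES: list[float] = [round(0.1 * i, 10) for i in range(11)]
DEFAULT_AMBIGUOUS_THRESHOLD = 0.9

#: Default genome-wide size ranges used when estimating size
#: distributions without an explicit bin specification.
DEFAULT_SIZE_RANGES: list[tuple[int, int]] = [(1, 10), (11, 100), (101, 10000)]

PROFILES_FILE = "profiles.tsv"
SIZE_DIST_FILE = "size_dist.tsv"
SNV_MATRIX_FILE = "snv_matrix.tsv"
META_FILE = "meta.tsv"


def compute_gc(sequence: str) -> Optional[float]:
    """GC fraction over unambiguous bases, case-insensitive.

    Ambiguous bases (N and any other IUPAC code) are excluded from both
    numerator and denominator.  Returns ``None`` when the sequence has
    no unambiguous bases (undefined GC).  Raises on empty input.
    """
    if not sequence:
        raise ValueError("cannot compute GC of an empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    if denom == 0:
        return None
    return gc / denom


def _ambiguous_fraction(sequence: str) -> float:
    seq = sequence.upper()
    unamb = sum(seq.count(b) for b in NUCLEOTIDES)
    return 1.0 - unamb / len(sequence)


def read_reference(fasta_path: str | Path) -> dict[str, str]:
    """Load a FASTA reference as an ordered {name: sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate record name {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return seqs


def build_fragment_profiles(
    variants: Sequence[VariantRecord],
    reference: str | Path | dict[str, str],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    *,
    ambiguous_threshold: float = DEFAULT_AMBIGUOUS_THRESHOLD,
) -> list[FragmentProfile]:
    """Segment every reference chromosome and tally variant counts.

    Windows are ``[k*L+1, (k+1)*L]`` in 1-based inclusive coordinates
    (the final partial window is kept); a variant belongs to the window
    containing its start position.  Fragments whose ambiguous-base
    fraction exceeds ``ambiguous_threshold`` get ``gc_fraction=None``
    and are later excluded from binning.
    """
    if fragment_length < 100:
        raise ValueError(f"fragment_length must be >= 100, got {fragment_length}")
    ref = reference if isinstance(reference, dict) else read_reference(reference)

    missing = {v.chrom for v in variants} - set(ref)
    if missing:
        raise ValueError(f"variant chromosomes absent from reference: {sorted(missing)}")

    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    skipped_oob = 0
    for v in variants:
        if v.start > len(ref[v.chrom]):
            skipped_oob += 1
            continue
        frag_idx = (v.start - 1) // fragment_length
        counts[(v.chrom, frag_idx)][v.variant_class] += 1
    if skipped_oob:
        logger.warning("skipped %d variants beyond chromosome end", skipped_oob)

    profiles: list[FragmentProfile] = []
    for chrom, seq in ref.items():
        n_frags = (len(seq) + fragment_length - 1) // fragment_length
        for k in range(n_frags):
            sub = seq[k * fragment_length : (k + 1) * fragment_length]
            gc = compute_gc(sub)
            if gc is not None and _ambiguous_fraction(sub) > ambiguous_threshold:
                gc = None
            profiles.append(
                FragmentProfile(
                    chrom=chrom,
                    fragment_index=k,
                    gc_fraction=gc,
                    counts=dict(counts.get((chrom, k), {})),
                )
            )
    return profiles


def bin_profiles(
    profiles: Sequence[FragmentProfile],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict[str, list[list[FragmentProfile]]]:
    """Group profiles into per-chromosome GC bins.

    Bins are half-open ``[e_i, e_{i+1})`` with the final bin closed
    above.  Profiles with undefined GC are excluded and counted in a log
    message.  Every chromosome seen gets the full bin list, empty bins
    included.
    """
    edges = list(bin_edges)
    if edges[0] != 0.0 or edges[-1] != 1.0:
        raise ValueError("bin edges must start at 0 and end at 1")
    if any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    n_bins = len(edges) - 1

    binned: dict[str, list[list[FragmentProfile]]] = {}
    undefined = 0
    for p in profiles:
        if p.chrom not in binned:
            binned[p.chrom] = [[] for _ in range(n_bins)]
        if p.gc_fraction is None:
            undefined += 1
            continue
        idx = min(int(np.searchsorted(edges, p.gc_fraction, side="right")) - 1, n_bins - 1)
        binned[p.chrom][idx].append(p)
    if undefined:
        logger.info("excluded %d fragments with undefined GC from binning", undefined)
    return binned


def estimate_size_distribution(
    variants: Sequence[VariantRecord],
    bin_spec: Optional[dict[VariantClass, list[tuple[int, int]]]] = None,
) -> SizeDistribution:
    """Genome-wide size-range probabilities per size-dependent class.

    ``bin_spec`` maps each class to its (min, max) size ranges; classes
    default to :data:`DEFAULT_SIZE_RANGES`.  Probability of a range is
    the pooled fraction of that class's variants falling inside it.
    """
    by_class: dict[VariantClass, list[int]] = defaultdict(list)
    for v in variants:
        if v.variant_class in SIZE_CLASSES:
            by_class[v.variant_class].append(v.size)

    spec = bin_spec or {cls: list(DEFAULT_SIZE_RANGES) for cls in by_class}
    bins: dict[VariantClass, list[SizeBin]] = {}
    for cls, ranges in spec.items():
        sizes = by_class.get(cls, [])
        if not sizes:
            raise ValueError(f"no observed variants to estimate sizes for {cls}")
        total = len(sizes)
        tallies = [0] * len(ranges)
        for s in sizes:
            for i, (lo, hi) in enumerate(ranges):
                if lo <= s <= hi:
                    tallies[i] += 1
                    break
            else:
                raise ValueError(f"{cls} size {s} outside the size-range specification")
        bins[cls] = [
            SizeBin(lo, hi, tallies[i] / total) for i, (lo, hi) in enumerate(ranges)
        ]
    return SizeDistribution(bins)


def estimate_snv_matrix(variants: Sequence[VariantRecord]) -> SnvTransitionMatrix:
    """Empirical substitute-base distribution per reference base.

    A reference base with no observed SNVs falls back to a uniform 1/3
    row with a warning.
    """
    tallies: dict[str, Counter] = {b: Counter() for b in NUCLEOTIDES}
    for v in variants:
        if v.variant_class is VariantClass.SNV:
            tallies[v.ref_base][v.alt_base] += 1
    rows: dict[str, dict[str, float]] = {}
    for base in NUCLEOTIDES:
        alts = [a for a in NUCLEOTIDES if a != base]
        total = sum(tallies[base].values())
        if total == 0:
            logger.warning("no SNVs with reference base %s; using uniform row", base)
            rows[base] = {a: 1.0 / 3.0 for a in alts}
        else:
            rows[base] = {a: tallies[base][a] / total for a in alts}
    return SnvTransitionMatrix(rows)


def build_frequency_table(
    variants: Sequence[VariantRecord],
    reference: str | Path | dict[str, str],
    *,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    size_bin_spec: Optional[dict[VariantClass, list[tuple[int, int]]]] = None,
    provenance: str = "",
    ambiguous_threshold: float = DEFAULT_AMBIGUOUS_THRESHOLD,
) -> FrequencyTable:
    """Run the full analysis: profiles, binning, size and SNV estimators."""
    profiles = build_fragment_profiles(
        variants, reference, fragment_length, ambiguous_threshold=ambiguous_threshold
    )
    binned = bin_profiles(profiles, bin_edges)
    size_dist = estimate_size_distribution(variants, size_bin_spec)
    snv_matrix = estimate_snv_matrix(variants)
    return FrequencyTable(
        fragment_length=fragment_length,
        bin_edges=list(bin_edges),
        profiles=binned,
        size_dist=size_dist,
        snv_matrix=snv_matrix,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# On-disk representation: four TSV files in a directory.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full round-trip precision


def write_frequency_table(table: FrequencyTable, out_dir: str | Path) -> None:
    """Serialize a frequency table to ``out_dir`` as four TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for chrom, bins in table.profiles.items():
        for bin_idx, profs in enumerate(bins):
            for p in profs:
                row = {
                    "chrom": chrom,
                    "bin": bin_idx,
                    "fragment_index": p.fragment_index,
                    "gc_fraction": p.gc_fraction,
                }
                for cls in CORE_CLASSES:
                    row[cls.value] = p.count(cls)
                rows.append(row)
    cols = ["chrom", "bin", "fragment_index", "gc_fraction"] + [
        c.value for c in CORE_CLASSES
    ]
    pd.DataFrame(rows, columns=cols).to_csv(
        out / PROFILES_FILE, sep="\t", index=False, float_format=_FLOAT_FMT
    )

    size_rows = [
        {"variant_class": cls.value, "min_size": b.min_size, "max_size": b.max_size,
         "probability": b.probability}
        for cls, cls_bins in table.size_dist.bins.items()
        for b in cls_bins
    ]
    pd.DataFrame(
        size_rows, columns=["variant_class", "min_size", "max_size", "probability"]
    ).to_csv(out / SIZE_DIST_FILE, sep="\t", index=False, float_format=_FLOAT_FMT)

    snv_rows = [
        {"ref_base": b, "alt_base": a, "probability": p}
        for b in NUCLEOTIDES
        for a, p in sorted(table.snv_matrix.rows[b].items())
    ]
    pd.DataFrame(snv_rows, columns=["ref_base", "alt_base", "probability"]).to_csv(
        out / SNV_MATRIX_FILE, sep="\t", index=False, float_format=_FLOAT_FMT
    )

    meta_rows = [
        ("fragment_length", str(table.fragment_length)),
        ("bin_edges", ",".join(_FLOAT_FMT % e for e in table.bin_edges)),
        ("chromosomes", ",".join(table.profiles.keys())),
        ("provenance", table.provenance),
    ]
    pd.DataFrame(meta_rows, columns=["key", "value"]).to_csv(
        out / META_FILE, sep="\t", index=False
    )


def read_frequency_table(in_dir: str | Path) -> FrequencyTable:
    """Load a frequency table written by :func:`write_frequency_table`."""
    src = Path(in_dir)
    for fname in (PROFILES_FILE, SIZE_DIST_FILE, SNV_MATRIX_FILE, META_FILE):
        if not (src / fname).exists():
            raise FileNotFoundError(f"frequency table file missing: {src / fname}")

    meta_df = pd.read_csv(src / META_FILE, sep="\t", dtype=str, keep_default_na=False)
    meta = dict(zip(meta_df["key"], meta_df["value"]))
    try:
        fragment_length = int(meta["fragment_length"])
        bin_edges = [float(x) for x in meta["bin_edges"].split(",")]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"corrupt metadata in {src / META_FILE}: {exc}") from exc
    chromosomes = [c for c in meta.get("chromosomes", "").split(",") if c]
    n_bins = len(bin_edges) - 1

    prof_df = pd.read_csv(src / PROFILES_FILE, sep="\t", float_precision="round_trip")
    profiles: dict[str, list[list[FragmentProfile]]] = {
        chrom: [[] for _ in range(n_bins)] for chrom in chromosomes
    }
    for row in prof_df.itertuples(index=False):
        gc = None if pd.isna(row.gc_fraction) else float(row.gc_fraction)
        counts = {
            cls: int(getattr(row, cls.value))
            for cls in CORE_CLASSES
            if int(getattr(row, cls.value)) > 0
        }
        profiles[row.chrom][int(row.bin)].append(
            FragmentProfile(row.chrom, int(row.fragment_index), gc, counts)
        )

    size_df = pd.read_csv(src / SIZE_DIST_FILE, sep="\t", float_precision="round_trip")
    size_bins: dict[VariantClass, list[SizeBin]] = defaultdict(list)
    for row in size_df.itertuples(index=False):
        size_bins[VariantClass(row.variant_class)].append(
            SizeBin(int(row.min_size), int(row.max_size), float(row.probability))
        )
    size_dist = SizeDistribution(dict(size_bins))

    snv_df = pd.read_csv(src / SNV_MATRIX_FILE, sep="\t", float_precision="round_trip")
    rows: dict[str, dict[str, float]] = {b: {} for b in NUCLEOTIDES}
    for row in snv_df.itertuples(index=False):
        rows[row.ref_base][row.alt_base] = float(row.probability)
    snv_matrix = SnvTransitionMatrix(rows)

    return FrequencyTable(
        fragment_length=fragment_length,
        bin_edges=bin_edges,
        profiles=profiles,
        size_dist=size_dist,
        snv_matrix=snv_matrix,
        provenance=meta.get("provenance", ""),
    )
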