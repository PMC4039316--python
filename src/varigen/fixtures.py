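"""Synthetic references and variant files with controlled statistics.

These generators stand in for public variant mining at full genome
scale: a reference with a controllable GC profile, and GVF/VCF files
whose per-class variant rates, size ranges, SNV spectrum and validation
tags are all specified up front.  Running the frequency analysis on
their output should recover the specified parameters to within sampling
error — the package's principal closure check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .types import (
    NUCLEOTIDES,
    SIZE_CLASSES,
    SnvTransitionMatrix,
    VariantClass,
)

#: Default per-class rates, expected variants per kb.  SNVs dominate,
#: followed by sequence alterations and insertions, with the larger
#: structural classes rare — mirroring the ordering seen in population
#: variant catalogues.
DEFAULT_RATES: dict[VariantClass, float] = {
    VariantClass.SNV: 8.0,
    VariantClass.SEQUENCE_ALTERATION: 1.5,
    VariantClass.INSERTION: 1.0,
    VariantClass.DELETION: 1.0,
    VariantClass.INVERSION: 0.1,
    VariantClass.TANDEM_DUPLICATION: 0.1,
}

#: Default size ranges with probabilities per size-dependent class:
#: small events dominate (0.96 in 1-10 bp, 0.04 in 11-100 bp).
DEFAULT_SIZE_RANGES: dict[VariantClass, list[tuple[int, int, float]]] = {
    cls: [(1, 10, 0.96), (11, 100, 0.04)] for cls in SIZE_CLASSES
}

#: Default SNV spectrum: transition-biased rows, with the C row set to
#: the genome-wide substitution rates reported for human population
#: data (C>T 0.69, C>A 0.16, C>G 0.15) and the G row its complement.
DEFAULT_SNV_ROWS: dict[str, dict[str, float]] = {
    "A": {"G": 0.70, "C": 0.15, "T": 0.15},
    "C": {"T": 0.69, "A": 0.16, "G": 0.15},
    "G": {"A": 0.69, "T": 0.16, "C": 0.15},
    "T": {"C": 0.70, "G": 0.15, "A": 0.15},
}

DEFAULT_TAG_MIX: list[tuple[tuple[str, ...], float]] = [
    (("1000Genomes",), 0.5),
    (("1000Genomes", "HapMap"), 0.3),
    (("COSMIC",), 0.15),
    (("DGVa",), 0.05),
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic reference + variant-file pair."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 60_000}
    )
    gc_targets: dict[str, float] = field(default_factory=dict)  # default 0.41 per chrom
    rates_per_kb: dict[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    size_ranges: dict[VariantClass, list[tuple[int, int, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIZE_RANGES.items()}
    )
    snv_rows: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(r) for b, r in DEFAULT_SNV_ROWS.items()}
    )
    tag_mix: list[tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: list(DEFAULT_TAG_MIX)
    )
    seed: int = 0

    def gc_target(self, chrom: str) -> float:
        return self.gc_targets.get(chrom, 0.41)

    def validate(self) -> None:
        for chrom, n in self.chrom_lengths.items():
            if n < 1:
                raise ValueError(f"chromosome {chrom} length must be >= 1")
        for chrom in self.chrom_lengths:
            gc = self.gc_target(chrom)
            if not (0.0 < gc < 1.0):
                raise ValueError(f"gc_target for {chrom} must be in (0,1), got {gc}")
        for cls, rate in self.rates_per_kb.items():
            if rate < 0:
                raise ValueError(f"negative rate for {cls}")
        SnvTransitionMatrix(self.snv_rows)  # validates rows
        for cls, ranges in self.size_ranges.items():
            total = sum(p for _, _, p in ranges)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"size-range probabilities for {cls} sum to {total}")
        mix_total = sum(p for _, p in self.tag_mix)
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError(f"tag mix probabilities sum to {mix_total}")


def generate_reference(spec: FixtureSpec, out_fasta: str | Path) -> Path:
    """Write a synthetic FASTA reference with per-chromosome GC targets.

    Each base is an independent draw with P(G)+P(C) equal to the
    chromosome's GC target; deterministic under the spec's seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = Path(out_fasta)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        for chrom, length in spec.chrom_lengths.items():
            gc = spec.gc_target(chrom)
            probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
            bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
            seq = "".join(bases)
            fh.write(f">{chrom}\n")
            for i in range(0, length, 70):
                fh.write(seq[i : i + 70] + "\n")
    return out


def _sample_size(ranges: list[tuple[int, int, float]], rng: np.random.Generator) -> int:
    probs = [p for _, _, p in ranges]
    lo, hi, _ = ranges[rng.choice(len(ranges), p=probs)]
    return int(rng.integers(lo, hi + 1))


def _sample_tags(spec: FixtureSpec, rng: np.random.Generator) -> tuple[str, ...]:
    probs = [p for _, p in spec.tag_mix]
    return spec.tag_mix[rng.choice(len(spec.tag_mix), p=probs)][0]


def generate_variants(
    reference: dict[str, str],
    spec: FixtureSpec,
    out_path: str | Path,
    dialect: str = "GVF",
    *,
    rng: Optional[np.random.Generator] = None,
    fragment_length: int = 1000,
) -> Path:
    """Write a synthetic GVF or VCF variant file against a reference.

    Per-fragment, per-class counts are Poisson at the configured per-kb
    rates; positions are uniform within the fragment (events must fit
    inside the chromosome); SNV alternates follow the spec's transition
    rows; sizes follow the spec's ranges; validation tags follow the
    configured mix.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    dialect_u = dialect.upper()
    if dialect_u not in ("GVF", "VCF"):
        raise ValueError(f"unknown dialect {dialect!r}")

    events: list[tuple[str, int, VariantClass, int, str, str, tuple[str, ...]]] = []
    # (chrom, start 1-based, class, size, ref, alt, tags)
    for chrom, seq in reference.items():
        chrom_len = len(seq)
        n_frags = (chrom_len + fragment_length - 1) // fragment_length
        for k in range(n_frags):
            frag_start = k * fragment_length
            frag_len = min(fragment_length, chrom_len - frag_start)
            for cls, rate in spec.rates_per_kb.items():
                lam = rate * frag_len / 1000.0
                n = int(rng.poisson(lam))
                for _ in range(n):
                    if cls is VariantClass.SNV:
                        size = 1
                    else:
                        size = _sample_size(spec.size_ranges[cls], rng)
                    max_off = frag_len - 1
                    off = int(rng.integers(0, max_off + 1))
                    start = frag_start + off + 1  # 1-based
                    if start + size - 1 > chrom_len:
                        start = chrom_len - size + 1
                        if start < 1:
                            continue  # event larger than chromosome
                    tags = _sample_tags(spec, rng)
                    if cls is VariantClass.SNV:
                        ref_base = seq[start - 1].upper()
                        if ref_base not in NUCLEOTIDES:
                            continue
                        row = spec.snv_rows[ref_base]
                        alts = sorted(row)
                        alt_base = alts[rng.choice(len(alts), p=[row[a] for a in alts])]
                        events.append((chrom, start, cls, 1, ref_base, alt_base, tags))
                    elif cls is VariantClass.INSERTION:
                        ins = "".join(
                            NUCLEOTIDES[i] for i in rng.integers(0, 4, size=size)
                        )
                        events.append((chrom, start, cls, size, "", ins, tags))
                    else:
                        ref_seq = seq[start - 1 : start - 1 + size].upper()
                        events.append((chrom, start, cls, size, ref_seq, "", tags))

    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    if dialect_u == "GVF":
        _write_gvf(events, out)
    else:
        _write_vcf(events, reference, out, rng)
    return out


def _write_gvf(events, out: Path) -> None:
    with open(out, "w") as fh:
        fh.write("##gvf-version 1.10\n")
        for i, (chrom, start, cls, size, ref, alt, tags) in enumerate(events):
            if cls is VariantClass.SNV:
                end = start
                attrs = (
                    f"ID=v{i};Reference_seq={ref};Variant_seq={alt};"
                    f"validation_status={','.join(tags)}"
                )
            elif cls is VariantClass.INSERTION:
                end = start  # insertion point; size carried by Variant_seq
                attrs = (
                    f"ID=v{i};Reference_seq=-;Variant_seq={alt};"
                    f"validation_status={','.join(tags)}"
                )
            else:
                end = start + size - 1
                attrs = f"ID=v{i};validation_status={','.join(tags)}"
            fh.write(
                f"{chrom}\tvarigen\t{cls.value}\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
            )


def _write_vcf(events, reference: dict[str, str], out: Path, rng) -> None:
    lines = []
    for chrom, start, cls, size, ref, alt, tags in events:
        info = f"VS={','.join(tags)}"
        if cls is VariantClass.SNV:
            lines.append((chrom, start, ref, alt, info))
        elif cls is VariantClass.DELETION:
            if start < 2:
                continue  # need a left anchor base
            anchor = reference[chrom][start - 2].upper()
            del_seq = reference[chrom][start - 1 : start - 1 + size].upper()
            lines.append((chrom, start - 1, anchor + del_seq, anchor, info))
        elif cls is VariantClass.INSERTION:
            if start < 2:
                continue
            anchor = reference[chrom][start - 2].upper()
            lines.append((chrom, start - 1, anchor, anchor + alt, info))
        elif cls is VariantClass.SEQUENCE_ALTERATION:
            alt_seq = ref
            while alt_seq == ref:
                alt_seq = "".join(
                    NUCLEOTIDES[i] for i in rng.integers(0, 4, size=size)
                )
            lines.append((chrom, start, ref, alt_seq, info))
        else:  # inversion / tandem duplication as symbolic alleles
            sym = "<INV>" if cls is VariantClass.INVERSION else "<DUP:TANDEM>"
            if start < 2:
                continue
            anchor_pos = start - 1
            anchor = reference[chrom][anchor_pos - 1].upper()
            end = anchor_pos + size
            lines.append((chrom, anchor_pos, anchor, sym, f"END={end};SVLEN={size};{info}"))
    lines.sort(key=lambda r: (r[0], r[1]))
    with open(out, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varigen-fixtures\n")
        fh.write(
            '##INFO=<ID=VS,Number=.,Type=String,Description="Validation studies">\n'
        )
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="SV length">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write('##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">\n')
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, info in lines:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")
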