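"""Genome fragmentation, reassembly, engineered SVs and output files.

Fragmentation tiles each chromosome with fixed-length windows; mutated
fragments are reassembled in index order regardless of arrival order.
Engineered structural variants are spliced into the assembled genome
afterwards, in descending coordinate order.  All edits end up in a TSV
mutation log whose replay reconstructs every output chromosome.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .mutate import replay_fragment, reverse_complement
from .types import AppliedMutation, EngineeredSV, Fragment, VariantClass

logger = logging.getLogger(__name__)

FASTA_LINE_WIDTH = 70

LOG_COLUMNS = [
    "genome_id",
    "chrom",
    "fragment_index",
    "parent_start",
    "variant_class",
    "size",
    "ref_seq",
    "alt_seq",
    "origin",
]


def fragment_genome(
    fasta_paths: str | Path | Sequence[str | Path],
    fragment_length: int,
) -> Iterator[Fragment]:
    """Tile every chromosome of the input FASTA file(s) into fragments.

    Fragments are yielded in order per chromosome; the final fragment
    may be short.  Concatenating the fragment sequences of a chromosome
    reproduces its input sequence exactly.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    if fragment_length < 1:
        raise ValueError("fragment_length must be positive")
    seen: set[str] = set()
    any_record = False
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            any_record = True
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA record name {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            for k in range(0, max(len(seq), 1), fragment_length):
                chunk = seq[k : k + fragment_length]
                if not chunk:
                    break
                yield Fragment(rec.id, k // fragment_length, k, chunk)
    if not any_record:
        raise ValueError(f"no FASTA records found in {list(map(str, fasta_paths))}")


def assemble_chromosome(fragments: Iterable[tuple[int, str]]) -> str:
    """Concatenate mutated fragments by index, independent of arrival order.

    ``fragments`` yields (fragment_index, sequence) pairs; indices must
    be exactly 0..n-1 with no duplicates.
    """
    by_index: dict[int, str] = {}
    for idx, seq in fragments:
        if idx in by_index:
            raise ValueError(f"duplicate fragment index {idx}")
        by_index[idx] = seq
    if not by_index:
        return ""
    n = max(by_index) + 1
    missing = [i for i in range(n) if i not in by_index]
    if missing:
        raise ValueError(f"fragment {missing[0]} absent")
    return "".join(by_index[i] for i in range(n))


def _check_sv_bounds(sv: EngineeredSV, genome: dict[str, str]) -> None:
    for chrom, start, end in _sv_intervals(sv):
        if chrom not in genome:
            raise ValueError(f"engineered SV chromosome {chrom!r} not in genome")
        if end > len(genome[chrom]):
            raise ValueError(
                f"engineered SV interval {chrom}:{start}-{end} exceeds "
                f"chromosome length {len(genome[chrom])}"
            )


def _sv_intervals(sv: EngineeredSV) -> list[tuple[str, int, int]]:
    ivs = [(sv.chrom, sv.start, sv.end)]
    if sv.sv_class == "translocation":
        ivs.append((sv.mate_chrom, sv.mate_start, sv.mate_end))
    return ivs


def apply_engineered_sv(
    genome: dict[str, str],
    sv_list: Sequence[EngineeredSV],
    genome_id: str = "",
) -> tuple[dict[str, str], list[AppliedMutation]]:
    """Splice engineered SVs into an assembled genome.

    Coordinates are 1-based inclusive in the assembled genome.  Edits on
    each chromosome are applied in descending coordinate order so that
    earlier splices never shift later ones; the log records each edit as
    a replacement (class ``translocation`` appears as two entries, one
    per swapped interval), flagged ``origin="engineered"``.
    """
    genome = dict(genome)
    for sv in sv_list:
        _check_sv_bounds(sv, genome)
    # reject overlapping engineered intervals (per chromosome)
    all_ivs = [iv for sv in sv_list for iv in _sv_intervals(sv)]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in all_ivs:
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping engineered SVs on {chrom}: "
                    f"{s1}-{e1} and {s2}-{e2}"
                )

    # expand each SV into per-chromosome replacement edits
    edits: list[tuple[str, int, str, str, str]] = []  # (chrom, start0, ref, alt, class)
    for sv in sv_list:
        s0, e0 = sv.start - 1, sv.end  # 0-based half-open
        if sv.sv_class == "deletion":
            ref = genome[sv.chrom][s0:e0]
            edits.append((sv.chrom, s0, ref, "", "deletion"))
        elif sv.sv_class == "insertion":
            edits.append((sv.chrom, s0, "", sv.payload.upper(), "insertion"))
        elif sv.sv_class == "inversion":
            ref = genome[sv.chrom][s0:e0]
            edits.append((sv.chrom, s0, ref, reverse_complement(ref), "inversion"))
        elif sv.sv_class == "duplication":
            ref = genome[sv.chrom][s0:e0]
            edits.append((sv.chrom, s0, ref, ref + ref, "tandem_duplication"))
        elif sv.sv_class == "translocation":
            ms0, me0 = sv.mate_start - 1, sv.mate_end
            seg_a = genome[sv.chrom][s0:e0]
            seg_b = genome[sv.mate_chrom][ms0:me0]
            edits.append((sv.chrom, s0, seg_a, seg_b, "translocation"))
            edits.append((sv.mate_chrom, ms0, seg_b, seg_a, "translocation"))

    # apply per chromosome in descending coordinate order
    edits.sort(key=lambda e: (e[0], -e[1]))
    log: list[AppliedMutation] = []
    for chrom, start0, ref, alt, cls in edits:
        seq = genome[chrom]
        if ref and seq[start0 : start0 + len(ref)] != ref:
            raise RuntimeError(f"engineered SV reference mismatch at {chrom}:{start0 + 1}")
        genome[chrom] = seq[:start0] + alt + seq[start0 + len(ref) :]
        log.append(
            AppliedMutation(
                genome_id=genome_id,
                chrom=chrom,
                fragment_index=-1,
                parent_start=start0 + 1,
                variant_class=cls,
                size=max(len(ref), len(alt)),
                ref_seq=ref,
                alt_seq=alt,
                origin="engineered",
            )
        )
    return genome, log


def read_sv_spec(path: str | Path) -> list[EngineeredSV]:
    """Read an engineered-SV specification TSV.

    Columns: chrom, start, end, class, payload, mate_chrom, mate_start,
    mate_end (payload and mate_* may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "start", "end", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"SV spec {path} missing columns {required - set(df.columns)}")
    svs = []
    for row in df.to_dict("records"):
        svs.append(
            EngineeredSV(
                sv_class=row["class"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                payload=row.get("payload", ""),
                mate_chrom=row.get("mate_chrom", ""),
                mate_start=int(row.get("mate_start") or 0),
                mate_end=int(row.get("mate_end") or 0),
            )
        )
    return svs


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------


def write_fasta(
    genome: dict[str, str],
    out_dir: str | Path,
    genome_id: str,
    parent_id: str,
    *,
    line_width: int = FASTA_LINE_WIDTH,
) -> list[Path]:
    """Write one FASTA file per chromosome (fixed line width, final newline)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom, seq in genome.items():
        path = out / f"{chrom}.fa"
        with open(path, "w") as fh:
            fh.write(f">{chrom} genome={genome_id} parent={parent_id}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
        paths.append(path)
    return paths


def write_mutation_log(log: Sequence[AppliedMutation], path: str | Path) -> None:
    rows = [
        {
            "genome_id": m.genome_id,
            "chrom": m.chrom,
            "fragment_index": m.fragment_index,
            "parent_start": m.parent_start,
            "variant_class": m.variant_class,
            "size": m.size,
            "ref_seq": m.ref_seq,
            "alt_seq": m.alt_seq,
            "origin": m.origin,
        }
        for m in log
    ]
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_log(path: str | Path) -> list[AppliedMutation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        AppliedMutation(
            genome_id=row.genome_id,
            chrom=row.chrom,
            fragment_index=int(row.fragment_index),
            parent_start=int(row.parent_start),
            variant_class=row.variant_class,
            size=int(row.size),
            ref_seq=row.ref_seq,
            alt_seq=row.alt_seq,
            origin=row.origin,
        )
        for row in df.itertuples(index=False)
    ]


def export_vcf(
    log: Sequence[AppliedMutation],
    parent: dict[str, str],
    path: str | Path,
    *,
    max_indel_size: int = 100,
) -> None:
    """Export SNVs and small indels from a mutation log as VCFv4.2.

    Only background edits with parent-coordinate REF/ALT semantics are
    exported: SNVs, and deletions/insertions up to ``max_indel_size``.
    Structural classes (inversions, duplications, alterations) remain
    TSV-only.  Indels are left-anchored on the preceding reference base
    per VCF convention.
    """
    records: list[tuple[str, int, str, str]] = []
    for m in log:
        if m.origin != "background":
            continue
        if m.variant_class == VariantClass.SNV.value:
            records.append((m.chrom, m.parent_start, m.ref_seq, m.alt_seq))
        elif m.variant_class == VariantClass.DELETION.value and m.size <= max_indel_size:
            p = m.parent_start
            if p > 1:
                anchor = parent[m.chrom][p - 2]
                records.append((m.chrom, p - 1, anchor + m.ref_seq, anchor))
            else:
                nxt = parent[m.chrom][p - 1 + m.size]
                records.append((m.chrom, 1, m.ref_seq + nxt, nxt))
        elif m.variant_class == VariantClass.INSERTION.value and m.size <= max_indel_size:
            p = m.parent_start  # insertion before this parent position
            if p > 1:
                anchor = parent[m.chrom][p - 2]
                records.append((m.chrom, p - 1, anchor, anchor + m.alt_seq))
            else:
                anchor = parent[m.chrom][0]
                records.append((m.chrom, 1, anchor, m.alt_seq + anchor))
    records.sort(key=lambda r: (r[0], r[1]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varigen\n")
        for chrom, seq in parent.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref.upper()}\t{alt.upper()}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Replay: the log as a self-contained recipe
# ---------------------------------------------------------------------------


def replay_genome(
    parent: dict[str, str], log: Sequence[AppliedMutation]
) -> dict[str, str]:
    """Reconstruct a simulated genome from its parent and mutation log.

    Background edits carry disjoint parent-coordinate intervals and are
    spliced per chromosome; engineered edits are then applied in log
    order at their recorded (assembled-genome) coordinates, which is
    exact because they were applied in descending coordinate order.
    """
    background: dict[str, list[AppliedMutation]] = {}
    engineered: list[AppliedMutation] = []
    for m in log:
        if m.origin == "engineered":
            engineered.append(m)
        else:
            background.setdefault(m.chrom, []).append(m)

    result = {
        chrom: replay_fragment(seq, background.get(chrom, []))
        for chrom, seq in parent.items()
    }
    for m in engineered:
        seq = result[m.chrom]
        s0 = m.start0
        if m.ref_seq and seq[s0 : s0 + len(m.ref_seq)] != m.ref_seq:
            raise ValueError(f"replay mismatch for engineered SV at {m.chrom}:{m.parent_start}")
        result[m.chrom] = seq[:s0] + m.alt_seq + seq[s0 + len(m.ref_seq) :]
    return result
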