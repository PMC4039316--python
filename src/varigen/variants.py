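"""Reading observed variants from GVF and VCF files.

Both dialects are supported minimally: coordinates, the type/class
field, and one attribute/INFO key carrying validation (study) tags.
The class mapping is explicit configuration so unsupported ontology
terms are dropped, not guessed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .types import NUCLEOTIDES, VariantClass, VariantRecord

logger = logging.getLogger(__name__)

#: GVF/SO term -> variant class (None = recognized but dropped).
GVF_CLASS_MAP: dict[str, Optional[VariantClass]] = {
    "SNV": VariantClass.SNV,
    "deletion": VariantClass.DELETION,
    "insertion": VariantClass.INSERTION,
    "sequence_alteration": VariantClass.SEQUENCE_ALTERATION,
    "substitution": VariantClass.SEQUENCE_ALTERATION,
    "inversion": VariantClass.INVERSION,
    "tandem_duplication": VariantClass.TANDEM_DUPLICATION,
    "copy_number_gain": None,
    "copy_number_loss": None,
    "copy_number_variation": None,
}

#: Symbolic VCF ALT -> variant class.
VCF_SYMBOLIC_MAP: dict[str, VariantClass] = {
    "<DEL>": VariantClass.DELETION,
    "<INS>": VariantClass.INSERTION,
    "<INV>": VariantClass.INVERSION,
    "<DUP>": VariantClass.TANDEM_DUPLICATION,
    "<DUP:TANDEM>": VariantClass.TANDEM_DUPLICATION,
}

#: Default GVF attribute / VCF INFO key holding comma-separated study tags.
GVF_TAG_ATTRIBUTE = "validation_status"
VCF_TAG_INFO = "VS"


def _parse_gvf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for piece in text.strip().split(";"):
        piece = piece.strip()
        if not piece:
            continue
        if "=" not in piece:
            raise ValueError(f"malformed attribute {piece!r}")
        key, value = piece.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _gvf_records(
    path: Path, tag_attribute: str, class_map: dict[str, Optional[VariantClass]]
) -> Iterable[tuple[Optional[VariantRecord], bool]]:
    """Yield (record, dropped_flag) per data line; raises on unparseable lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom, _source, so_type, start_s, end_s = fields[0], fields[1], fields[2], fields[3], fields[4]
                start, end = int(start_s), int(end_s)
                attrs = _parse_gvf_attributes(fields[8])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if so_type not in class_map:
                logger.debug("line %d: unmapped type %s", lineno, so_type)
                yield None, True
                continue
            cls = class_map[so_type]
            if cls is None:
                yield None, True
                continue
            tags = frozenset(
                t for t in attrs.get(tag_attribute, "").split(",") if t
            )
            ref = attrs.get("Reference_seq", "").upper()
            alt = attrs.get("Variant_seq", "").upper()
            if cls is VariantClass.SNV:
                if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES or ref == alt:
                    raise ValueError(
                        f"{path}: line {lineno}: bad SNV alleles {ref!r}>{alt!r}"
                    )
                record = VariantRecord(chrom, start, cls, 1, ref, alt, tags)
            elif cls is VariantClass.INSERTION:
                size = len(alt.strip("-")) if alt.strip("-") else end - start + 1
                record = VariantRecord(chrom, start, cls, max(size, 1), "", "", tags)
            else:
                record = VariantRecord(chrom, start, cls, end - start + 1, "", "", tags)
            yield record, False


def _classify_vcf_alt(
    ref: str, alt: str, pos: int, stop: int
) -> Optional[tuple[VariantClass, int, int, str, str]]:
    """Classify one (REF, ALT) pair.

    Returns (class, 1-based start, size, ref_base, alt_base) or None for
    unsupported shapes.  ``pos`` is the record's 1-based POS, ``stop``
    its END (for symbolic alleles).
    """
    alt_u = alt.upper()
    if alt_u in VCF_SYMBOLIC_MAP:
        cls = VCF_SYMBOLIC_MAP[alt_u]
        size = max(stop - pos, 1)
        # symbolic records anchor at POS; the affected interval starts after it
        return cls, pos + 1, size, "", ""
    if alt_u.startswith("<"):
        return None
    ref_u = ref.upper()
    if len(ref_u) == 1 and len(alt_u) == 1:
        if ref_u == alt_u or ref_u not in NUCLEOTIDES or alt_u not in NUCLEOTIDES:
            return None
        return VariantClass.SNV, pos, 1, ref_u, alt_u
    if len(ref_u) > 1 and len(alt_u) == 1 and ref_u.startswith(alt_u):
        return VariantClass.DELETION, pos + 1, len(ref_u) - 1, "", ""
    if len(alt_u) > 1 and len(ref_u) == 1 and alt_u.startswith(ref_u):
        return VariantClass.INSERTION, pos + 1, len(alt_u) - 1, "", ""
    if len(ref_u) == len(alt_u) > 1:
        return VariantClass.SEQUENCE_ALTERATION, pos, len(ref_u), "", ""
    return None  # complex indel / MNP shapes are out of the supported dialect


def _vcf_records(
    path: Path, tag_info: str
) -> Iterable[tuple[Optional[VariantRecord], bool]]:
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            tags_raw = rec.info.get(tag_info, ())
            if isinstance(tags_raw, str):
                tags_raw = (tags_raw,)
            tags = frozenset(t for chunk in tags_raw for t in chunk.split(",") if t)
            for alt in rec.alts or ():
                hit = _classify_vcf_alt(rec.ref, alt, rec.pos, rec.stop)
                if hit is None:
                    yield None, True
                    continue
                cls, start, size, ref_base, alt_base = hit
                yield VariantRecord(rec.chrom, start, cls, size, ref_base, alt_base, tags), False


def parse_variants(
    path: str | Path,
    dialect: str,
    include_tags: Optional[set[str]] = None,
    *,
    tag_attribute: Optional[str] = None,
    class_map: Optional[dict[str, Optional[VariantClass]]] = None,
) -> list[VariantRecord]:
    """Parse a variant file into filtered, de-duplicated records.

    Parameters
    ----------
    path
        GVF or VCF file.
    dialect
        ``"GVF"`` or ``"VCF"`` (case-insensitive).
    include_tags
        Keep only records whose validation tags intersect this set;
        ``None`` keeps everything.
    tag_attribute
        GVF attribute / VCF INFO key carrying the comma-separated tags
        (defaults: ``validation_status`` / ``VS``).
    class_map
        Override of the GVF type -> class mapping.

    Records are de-duplicated on (chrom, start, class, size, alt); the
    first occurrence wins.  Classes outside the supported set are
    dropped and counted in a log message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect_u = dialect.upper()
    if dialect_u == "GVF":
        stream = _gvf_records(
            path, tag_attribute or GVF_TAG_ATTRIBUTE, class_map or GVF_CLASS_MAP
        )
    elif dialect_u == "VCF":
        stream = _vcf_records(path, tag_attribute or VCF_TAG_INFO)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected GVF or VCF")

    seen: set[tuple] = set()
    records: list[VariantRecord] = []
    dropped = 0
    for rec, was_dropped in stream:
        if was_dropped:
            dropped += 1
            continue
        assert rec is not None
        if include_tags is not None and not (rec.validation_tags & include_tags):
            continue
        if rec.dedup_key in seen:
            continue
        seen.add(rec.dedup_key)
        records.append(rec)
    if dropped:
        logger.info("%s: dropped %d records of unsupported class", path.name, dropped)
    return records
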