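"""Parsing, normalization and formatting of HGVS variant descriptions.

Supports the dialect found in curated ENPP1 locus-specific tables: coding
(``c.``), genomic (``g.``) and protein (``p.``) descriptions, intronic
offsets (``c.2444+702``), 5'/3'-UTR anchors (``c.-24``, ``c.*868``),
uncertain breakpoints (``c.(1091+1_1092-1)_(1164+1_1165-1)del``,
``g.(?-132186006)_(132186078-?)del``), deletion-insertions with unknown
inserted bases (``delinsN[7]``), in-cis allele lists (``c.[x;y]``) and
phase-unknown pairs (``x(;)y``).

Descriptions are normalized *syntactically* only: unicode dash variants are
folded to ASCII ``-``, whitespace stripped, and accession prefixes split off.
No reference sequence is consulted and no 3'-shifting is performed; curated
tables are taken as already HGVS-conformant.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "HgvsSyntaxError",
    "UnsupportedConstructError",
    "CodingPosition",
    "PositionRange",
    "EditKind",
    "VariantDescription",
    "ProteinAltKind",
    "ProteinChange",
    "AlleleDescription",
    "parse_cdna",
    "parse_gdna",
    "parse_protein",
    "parse_allele",
    "format_variant",
    "format_cdna",
    "format_protein",
    "format_allele",
    "normalize",
]

# Unicode hyphen (U+2010), non-breaking hyphen, figure dash, en dash and
# minus sign (U+2212) all appear in published tables; fold them to ASCII.
_DASH_TABLE = dict.fromkeys(map(ord, "‐‑‒–−"), "-")


def clean_text(text: str) -> str:
    """Fold unicode dash variants to ``-`` and strip surrounding whitespace."""
    return text.translate(_DASH_TABLE).strip()


class HgvsSyntaxError(ValueError):
    """Malformed HGVS text; carries the character offset of the failure."""

    def __init__(self, message: str, text: str, offset: int):
        super().__init__(f"{message} at offset {offset} in {text!r}")
        self.text = text
        self.offset = offset


class UnsupportedConstructError(ValueError):
    """Syntactically plausible HGVS using a construct this parser does not model."""


@dataclass(frozen=True, order=True)
class CodingPosition:
    """A position in CDS coordinates.

    ``anchor`` is the 1-based CDS nucleotide (negative for 5'UTR ``c.-N``);
    with ``utr3`` set the anchor counts from the stop codon (``c.*N``).
    ``offset`` is the signed intronic offset (0 = exonic).
    """

    anchor: int
    offset: int = 0
    utr3: bool = False

    def __post_init__(self) -> None:
        if self.anchor == 0:
            raise ValueError("CDS anchor 0 does not exist (coordinates are 1-based)")
        if self.utr3 and self.anchor < 1:
            raise ValueError("3'UTR positions count forward from the stop codon")

    @property
    def exonic(self) -> bool:
        return self.offset == 0

    def sort_key(self) -> tuple[int, int, int]:
        """Transcript-order key: 5'UTR < CDS < 3'UTR."""
        region = 1 if self.utr3 else 0
        return (region, self.anchor, self.offset)

    def __str__(self) -> str:
        star = "*" if self.utr3 else ""
        off = f"{self.offset:+d}" if self.offset else ""
        return f"{star}{self.anchor}{off}"


@dataclass(frozen=True)
class PositionRange:
    """A 1-based fully closed position interval.

    Uncertain breakpoints written ``(x_y)`` are carried in
    ``start_uncertain`` / ``end_uncertain`` as (outer, inner) bound pairs;
    ``None`` stands for an unknown ``?`` bound. ``start``/``end`` then hold
    the best defined bound for anchor arithmetic.
    """

    start: CodingPosition
    end: CodingPosition
    start_uncertain: Optional[tuple[Optional[CodingPosition], Optional[CodingPosition]]] = None
    end_uncertain: Optional[tuple[Optional[CodingPosition], Optional[CodingPosition]]] = None

    def __post_init__(self) -> None:
        if self.start_uncertain is None and self.end_uncertain is None:
            if self.start.sort_key() > self.end.sort_key():
                raise ValueError(f"range start {self.start} after end {self.end}")

    @property
    def single(self) -> bool:
        return (
            self.start_uncertain is None
            and self.end_uncertain is None
            and self.start == self.end
        )

    def positions(self) -> list[CodingPosition]:
        """All defined breakpoint positions (certain and uncertain bounds)."""
        out = []
        for certain, unc in ((self.start, self.start_uncertain), (self.end, self.end_uncertain)):
            if unc is None:
                out.append(certain)
            else:
                out.extend(p for p in unc if p is not None)
        return out


class EditKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"
    DELINS_UNKNOWN_BASES = "delins_unknown_bases"
    WHOLE_GENE_DELETION = "whole_gene_deletion"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantDescription:
    """One HGVS-level edit at genomic or coding level."""

    level: str  # "genomic" | "coding"
    range: PositionRange
    edit_kind: EditKind
    ref_seq: str = ""
    alt_seq: str = ""
    reference: Optional[str] = None  # accession prefix, if given
    unknown_insert_length: Optional[int] = None  # the k of delinsN[k]

    def __post_init__(self) -> None:
        if self.edit_kind is EditKind.SUBSTITUTION:
            if not self.range.single or len(self.ref_seq) != 1 or len(self.alt_seq) != 1:
                raise ValueError("substitution requires a single position and 1-base ref/alt")
        if self.edit_kind is EditKind.DELINS_UNKNOWN_BASES:
            if not self.unknown_insert_length or self.unknown_insert_length < 1:
                raise ValueError("delinsN[k] requires k >= 1")


class ProteinAltKind(str, Enum):
    RESIDUE = "residue"  # missense substitution
    TER = "ter"  # premature stop
    DEL = "del"  # in-frame residue deletion
    FS = "fs"  # frameshift with new stop distance
    UNKNOWN = "unknown"  # "p.?"


@dataclass(frozen=True)
class ProteinChange:
    """One protein-level consequence, or an ordered in-cis compound ``p.[X;Y]``."""

    alt_kind: ProteinAltKind = ProteinAltKind.UNKNOWN
    ref_residue: Optional[str] = None  # 3-letter code
    position: Optional[int] = None
    alt_residue: Optional[str] = None  # 3-letter code (missense / first fs residue)
    fs_stop_distance: Optional[int] = None  # the N of fs*N
    reference: Optional[str] = None
    compound: tuple["ProteinChange", ...] = ()

    def __post_init__(self) -> None:
        if self.alt_kind is ProteinAltKind.FS and (
            self.fs_stop_distance is None or self.fs_stop_distance < 1
        ):
            raise ValueError("frameshift requires a new stop distance >= 1")
        if self.position is not None and self.position < 1:
            raise ValueError("protein positions are 1-based")


@dataclass(frozen=True)
class AlleleDescription:
    """One chromosome's content: >=1 variants in cis/phase-unknown, or not identified."""

    variants: tuple[VariantDescription, ...] = ()
    phase: str = "cis"  # "cis" | "unknown" (written "(;)")
    identified: bool = True

    def __post_init__(self) -> None:
        if self.identified != bool(self.variants):
            raise ValueError("identified=False iff the variant list is empty")


# ----------------------------------------------------------------------------
# parsing

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp "
    "Tyr Val Sec Pyl Xaa"
).split()

_ACCESSION_RE = re.compile(r"^([A-Z][A-Z_0-9]+\.\d+):")
_CPOS_RE = re.compile(r"(\*)?(-?\d+)([+-]\d+)?")
_GPOS_RE = re.compile(r"\d+")


def _strip_accession(text: str) -> tuple[Optional[str], str]:
    m = _ACCESSION_RE.match(text)
    if m:
        return m.group(1), text[m.end():]
    return None, text


def _parse_cpos(text: str, at: int, full: str) -> tuple[CodingPosition, int]:
    m = _CPOS_RE.match(text, at)
    if not m:
        raise HgvsSyntaxError("expected a CDS position", full, at)
    star, anchor, off = m.groups()
    try:
        pos = CodingPosition(int(anchor), int(off) if off else 0, utr3=bool(star))
    except ValueError as exc:
        raise HgvsSyntaxError(str(exc), full, at) from exc
    return pos, m.end()


def _parse_gpos(text: str, at: int, full: str) -> tuple[CodingPosition, int]:
    m = _GPOS_RE.match(text, at)
    if not m:
        raise HgvsSyntaxError("expected a genomic position", full, at)
    return CodingPosition(int(m.group())), m.end()


def _parse_uncertain(text, at, full, pos_parser):
    """Parse '(x_y)' with '?' allowed for either bound.

    Published genomic breakpoints are sometimes written '(?-X)' / '(Y-?)'
    with a dash separating the bounds; that spelling is accepted on input
    (genomic positions carry no offsets, so it is unambiguous) and emitted
    canonically with '_'.
    """
    assert text[at] == "("
    i = at + 1
    seps = ("_", "-") if pos_parser is _parse_gpos else ("_",)

    def bound(i):
        if text[i : i + 1] == "?":
            return None, i + 1
        return pos_parser(text, i, full)

    lo, i = bound(i)
    if text[i : i + 1] not in seps:
        raise HgvsSyntaxError("expected '_' inside uncertain breakpoint", full, i)
    hi, i = bound(i + 1)
    if text[i : i + 1] != ")":
        raise HgvsSyntaxError("expected ')' closing uncertain breakpoint", full, i)
    if lo is None and hi is None:
        raise HgvsSyntaxError("breakpoint with both bounds unknown", full, at)
    return (lo, hi), i + 1


def _parse_point_or_uncertain(text, at, full, pos_parser):
    if text[at : at + 1] == "(":
        return None, *_parse_uncertain(text, at, full, pos_parser)
    pos, i = pos_parser(text, at, full)
    return pos, None, i


_EDIT_RE = re.compile(
    r"(?:(?P<ref>[ACGTUN]+)?>(?P<alt>[ACGTUN]+)"
    r"|(?P<delins>delins)(?:(?P<dalt>[ACGTUN]+)|N\[(?P<nk>\d+)\])"
    r"|(?P<del>del)(?P<dref>[ACGTUN]+)?"
    r"|(?P<dup>dup)(?P<dupref>[ACGTUN]+)?"
    r"|(?P<ins>ins)(?:(?P<ialt>[ACGTUN]+)|N\[(?P<ink>\d+)\]))$"
)


def _parse_nucleotide_description(text: str, level: str) -> VariantDescription:
    """Shared machinery behind parse_cdna / parse_gdna (post accession/prefix strip)."""
    full = text
    pos_parser = _parse_cpos if level == "coding" else _parse_gpos
    # substitution fast path: POS REF>ALT
    start, start_unc, i = _parse_point_or_uncertain(text, 0, full, pos_parser)
    end = end_unc = None
    if text[i : i + 1] == "_":
        end, end_unc, i = _parse_point_or_uncertain(text, i + 1, full, pos_parser)
    edit = text[i:]
    if not edit:
        raise HgvsSyntaxError("missing edit (del/dup/ins/>)", full, i)
    m = _EDIT_RE.match(edit)
    if not m:
        raise HgvsSyntaxError(f"unrecognized edit {edit!r}", full, i)

    def norm_bounds(pos, unc):
        if unc is not None:
            best = unc[0] if unc[0] is not None else unc[1]
            return best, unc
        return pos, None

    s_pos, s_unc = norm_bounds(start, start_unc)
    if end is None and end_unc is None:
        e_pos, e_unc = s_pos, s_unc
    else:
        e_pos, e_unc = norm_bounds(end, end_unc)
    rng = PositionRange(s_pos, e_pos, s_unc, e_unc)

    g = m.groupdict()
    if g["alt"]:
        kind, ref, alt, nk = EditKind.SUBSTITUTION, g["ref"] or "", g["alt"], None
        if len(ref) != 1 or len(alt) != 1 or not rng.single:
            raise UnsupportedConstructError(
                f"multi-base substitution not supported: {full!r}"
            )
    elif g["delins"]:
        if g["nk"]:
            kind, ref, alt, nk = EditKind.DELINS_UNKNOWN_BASES, "", "", int(g["nk"])
        else:
            kind, ref, alt, nk = EditKind.DELINS, "", g["dalt"], None
    elif g["del"]:
        kind, ref, alt, nk = EditKind.DELETION, g["dref"] or "", "", None
    elif g["dup"]:
        kind, ref, alt, nk = EditKind.DUPLICATION, g["dupref"] or "", "", None
    else:
        if g["ink"]:
            kind, ref, alt, nk = EditKind.DELINS_UNKNOWN_BASES, "", "", int(g["ink"])
        else:
            kind, ref, alt, nk = EditKind.INSERTION, "", g["ialt"], None

    # a coding deletion running from the 5'UTR through the 3'UTR removes the gene
    if (
        level == "coding"
        and kind is EditKind.DELETION
        and rng.start.anchor < 0
        and not rng.start.utr3
        and rng.end.utr3
    ):
        kind = EditKind.WHOLE_GENE_DELETION

    return VariantDescription(
        level=level, range=rng, edit_kind=kind, ref_seq=ref, alt_seq=alt,
        unknown_insert_length=nk,
    )


def parse_cdna(text: str) -> VariantDescription:
    """Parse an HGVS cDNA description such as ``c.913C>A`` or
    ``c.1026-281_1164+1delinsN[7]``; an accession prefix is stripped into
    ``reference``."""
    cleaned = clean_text(text)
    acc, body = _strip_accession(cleaned)
    if not body.startswith("c."):
        raise HgvsSyntaxError("cDNA description must begin with 'c.'", cleaned, 0)
    v = _parse_nucleotide_description(body[2:], "coding")
    return replace(v, reference=acc)


def parse_gdna(text: str) -> VariantDescription:
    """Parse an HGVS genomic description such as ``g.131860504C>A`` or
    ``g.(?-132186006)_(132186078-?)del``."""
    cleaned = clean_text(text)
    acc, body = _strip_accession(cleaned)
    if not body.startswith("g."):
        raise HgvsSyntaxError("genomic description must begin with 'g.'", cleaned, 0)
    v = _parse_nucleotide_description(body[2:], "genomic")
    return replace(v, reference=acc)


_PROT_SIMPLE_RE = re.compile(
    r"(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)"
    r"(?:(?P<ter>\*|Ter)"
    r"|(?P<del>del)"
    r"|(?P<fsres>[A-Z][a-z]{2})?fs\*(?P<fsn>\d+)"
    r"|(?P<alt>[A-Z][a-z]{2}))$"
)


def _parse_protein_single(body: str, full: str, at: int) -> ProteinChange:
    # tolerate a stray inner "p." as printed in some table cells
    if body.startswith("p."):
        body = body[2:]
        at += 2
    if body == "?":
        return ProteinChange(alt_kind=ProteinAltKind.UNKNOWN)
    m = _PROT_SIMPLE_RE.match(body)
    if not m:
        raise HgvsSyntaxError(f"unrecognized protein change {body!r}", full, at)
    g = m.groupdict()
    ref, pos = g["ref"], int(g["pos"])
    for aa in (ref, g["alt"], g["fsres"]):
        if aa is not None and aa not in _AA3:
            raise HgvsSyntaxError(f"unknown amino acid code {aa!r}", full, at)
    if g["ter"]:
        return ProteinChange(ProteinAltKind.TER, ref, pos)
    if g["del"]:
        return ProteinChange(ProteinAltKind.DEL, ref, pos)
    if g["fsn"]:
        return ProteinChange(ProteinAltKind.FS, ref, pos, g["fsres"], int(g["fsn"]))
    return ProteinChange(ProteinAltKind.RESIDUE, ref, pos, g["alt"])


def parse_protein(text: str) -> ProteinChange:
    """Parse an HGVS protein description: ``p.Pro305Thr``, ``p.Arg782*``,
    ``p.Lys905Alafs*16``, ``p.?``, or the in-cis compound ``p.[X;Y]``."""
    cleaned = clean_text(text)
    acc, body = _strip_accession(cleaned)
    if not body.startswith("p."):
        raise HgvsSyntaxError("protein description must begin with 'p.'", cleaned, 0)
    inner = body[2:]
    if inner.startswith("["):
        if not inner.endswith("]"):
            raise HgvsSyntaxError("unterminated '[' compound", cleaned, len(cleaned) - 1)
        parts = inner[1:-1].split(";")
        if len(parts) < 2:
            raise HgvsSyntaxError("compound needs >=2 ';'-separated changes", cleaned, 2)
        at = body.index("[") + 1
        comps = []
        for part in parts:
            comps.append(_parse_protein_single(part.strip(), cleaned, at))
            at += len(part) + 1
        return ProteinChange(compound=tuple(comps), reference=acc)
    if "(;)" in inner:
        comps = tuple(
            _parse_protein_single(p.strip(), cleaned, 0) for p in inner.split("(;)")
        )
        return ProteinChange(compound=comps, reference=acc)
    single = _parse_protein_single(inner, cleaned, 2)
    return replace(single, reference=acc)


def parse_allele(text: str) -> AlleleDescription:
    """Parse one allele cell from a patient table.

    Accepts a single cDNA description, a bracketed in-cis list
    ``c.[x;y]``, a phase-unknown pair ``x(;)y``, or the literal
    ``Not identified``. An empty cell is an error — absence of data must be
    written out explicitly.
    """
    cleaned = clean_text(text)
    if not cleaned:
        raise ValueError("empty allele cell (write 'Not identified' explicitly)")
    if cleaned.lower() == "not identified":
        return AlleleDescription(identified=False)
    if "(;)" in cleaned:
        parts = [p.strip() for p in cleaned.split("(;)")]
        variants = tuple(
            parse_cdna(p if p.startswith("c.") or ":" in p else "c." + p)
            for p in parts
        )
        return AlleleDescription(variants=variants, phase="unknown")
    m = re.fullmatch(r"(?:([A-Z][A-Z_0-9]+\.\d+):)?c\.\[(.+)\]", cleaned)
    if m:
        acc = m.group(1)
        variants = []
        for part in m.group(2).split(";"):
            part = part.strip()
            if not part.startswith("c."):
                part = "c." + part
            variants.append(replace(parse_cdna(part), reference=acc))
        return AlleleDescription(variants=tuple(variants), phase="cis")
    return AlleleDescription(variants=(parse_cdna(cleaned),), phase="cis")


# ----------------------------------------------------------------------------
# formatting / normalization


def _format_point(pos, unc) -> str:
    if unc is None:
        return str(pos)
    lo = "?" if unc[0] is None else str(unc[0])
    hi = "?" if unc[1] is None else str(unc[1])
    return f"({lo}_{hi})"


def format_variant(v: VariantDescription, with_reference: bool = False) -> str:
    """Canonical ASCII rendering; ``parse(format(v)) == v`` up to reference."""
    prefix = "c." if v.level == "coding" else "g."
    rng = v.range
    left = _format_point(rng.start, rng.start_uncertain)
    if rng.start_uncertain is None and rng.end_uncertain is None and rng.start == rng.end:
        loc = left
    else:
        loc = f"{left}_{_format_point(rng.end, rng.end_uncertain)}"
    k = v.edit_kind
    if k is EditKind.SUBSTITUTION:
        edit = f"{v.ref_seq}>{v.alt_seq}"
    elif k in (EditKind.DELETION, EditKind.WHOLE_GENE_DELETION):
        edit = f"del{v.ref_seq}"
    elif k is EditKind.DUPLICATION:
        edit = f"dup{v.ref_seq}"
    elif k is EditKind.INSERTION:
        edit = f"ins{v.alt_seq}"
    elif k is EditKind.DELINS:
        edit = f"delins{v.alt_seq}"
    elif k is EditKind.DELINS_UNKNOWN_BASES:
        edit = f"delinsN[{v.unknown_insert_length}]"
    else:
        edit = "?"
    acc = f"{v.reference}:" if with_reference and v.reference else ""
    return f"{acc}{prefix}{loc}{edit}"


def format_cdna(v: VariantDescription, with_reference: bool = False) -> str:
    if v.level != "coding":
        raise ValueError("not a coding-level description")
    return format_variant(v, with_reference)


def _format_protein_single(p: ProteinChange) -> str:
    k = p.alt_kind
    if k is ProteinAltKind.UNKNOWN:
        return "?"
    base = f"{p.ref_residue}{p.position}"
    if k is ProteinAltKind.TER:
        return base + "*"
    if k is ProteinAltKind.DEL:
        return base + "del"
    if k is ProteinAltKind.FS:
        res = p.alt_residue or ""
        return f"{base}{res}fs*{p.fs_stop_distance}"
    return base + (p.alt_residue or "")


def format_protein(p: ProteinChange, with_reference: bool = False) -> str:
    acc = f"{p.reference}:" if with_reference and p.reference else ""
    if p.compound:
        inner = ";".join(_format_protein_single(c) for c in p.compound)
        return f"{acc}p.[{inner}]"
    return f"{acc}p.{_format_protein_single(p)}"


def format_allele(a: AlleleDescription) -> str:
    if not a.identified:
        return "Not identified"
    parts = [format_variant(v) for v in a.variants]
    if a.phase == "unknown":
        return "(;)".join(parts)
    if len(parts) == 1:
        return parts[0]
    stripped = [p[2:] for p in parts]
    return "c.[" + ";".join(stripped) + "]"


def normalize(v: VariantDescription | str) -> str:
    """Deterministic canonical key for deduplication and genotype keys.

    Accession prefixes, whitespace and unicode dash differences all map to
    the same key.
    """
    if isinstance(v, str):
        cleaned = clean_text(v)
        v = parse_gdna(cleaned) if _strip_accession(cleaned)[1].startswith("g.") else parse_cdna(cleaned)
    return format_variant(v, with_reference=False)


def allele_key(a: AlleleDescription) -> tuple[str, ...]:
    """Order-invariant key for one allele: sorted normalized variant keys."""
    if not a.identified:
        return ()
    return tuple(sorted(normalize(v) for v in a.variants))
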