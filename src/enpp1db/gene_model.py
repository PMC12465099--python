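"""Transcript/protein coordinate system and protein-domain architecture.

Maps CDS positions to codons and residues to named domains. The packaged
ENPP1 model (NM_006208.3 / NP_006199.2, 925 residues) places the
cytoplasmic domain at residues 1-76, the transmembrane segment at 77-97,
the two somatomedin-B-like domains at 104-144 and 145-188, the
phosphodiesterase (catalytic) domain at 191-591 and the nuclease-like
domain at 654-925, with short linkers at 189-190 and 592-653. Gaps between
named regions are reported as ``"intervening"``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import ceil
from pathlib import Path
from typing import Optional, Union

import yaml

from .nomenclature import (
    CodingPosition,
    EditKind,
    ProteinAltKind,
    ProteinChange,
    VariantDescription,
)

__all__ = [
    "DomainMap",
    "GeneModel",
    "load_gene_model",
    "enpp1_model",
    "codon_for_position",
    "domain_of_residue",
    "domain_of_variant",
    "UTR_REGION",
    "WHOLE_GENE_REGION",
    "INTERVENING",
]

UTR_REGION = "Untranslated region"
WHOLE_GENE_REGION = "Whole gene"
INTERVENING = "intervening"


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping named residue ranges over 1..protein_length."""

    regions: tuple[tuple[str, int, int], ...]
    protein_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.regions:
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(f"region {name} [{start},{end}] outside protein")
            if start <= prev_end:
                raise ValueError(f"region {name} overlaps or is unsorted")
            prev_end = end

    def region_of(self, residue: int) -> str:
        if not 1 <= residue <= self.protein_length:
            raise ValueError(
                f"residue {residue} outside 1..{self.protein_length}"
            )
        for name, start, end in self.regions:
            if start <= residue <= end:
                return name
        return INTERVENING


@dataclass(frozen=True)
class GeneModel:
    transcript_accession: str
    protein_accession: str
    cds_length: int
    domain_map: DomainMap
    exon_map: Optional[tuple[tuple[int, int, int], ...]] = None  # (exon, cds_start, cds_end)

    def __post_init__(self) -> None:
        if self.exon_map is not None:
            expected = 1
            for exon, start, end in self.exon_map:
                if start != expected or end < start:
                    raise ValueError("exon map must tile 1..cds_length without gaps")
                expected = end + 1
            if expected != self.cds_length + 1:
                raise ValueError("exon map does not cover the CDS")

    @property
    def protein_length(self) -> int:
        return self.domain_map.protein_length


def load_gene_model(source: Union[str, Path, dict]) -> GeneModel:
    """Load a gene-model config from a YAML/JSON file path or a dict."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        cfg = json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
    else:
        cfg = source
    regions = tuple((d["name"], int(d["start"]), int(d["end"])) for d in cfg["domains"])
    dm = DomainMap(regions=regions, protein_length=int(cfg["protein_length"]))
    exon_map = None
    if cfg.get("exons"):
        exon_map = tuple(
            (int(e["exon"]), int(e["cds_start"]), int(e["cds_end"])) for e in cfg["exons"]
        )
    return GeneModel(
        transcript_accession=cfg["transcript_accession"],
        protein_accession=cfg["protein_accession"],
        cds_length=int(cfg["cds_length"]),
        domain_map=dm,
        exon_map=exon_map,
    )


def enpp1_model() -> GeneModel:
    """The packaged ENPP1 gene model."""
    ref = resources.files("enpp1db.data").joinpath("enpp1_gene_model.yaml")
    return load_gene_model(yaml.safe_load(ref.read_text()))


def codon_for_position(p: CodingPosition, m: GeneModel) -> int:
    """Residue index of a CDS-anchored position: ``ceil(anchor / 3)``.

    Intronic positions use their exonic anchor; 5'UTR and 3'UTR anchors have
    no codon and raise.
    """
    if p.anchor < 1 or p.utr3:
        raise ValueError(f"position {p} is not CDS-anchored")
    residue = ceil(p.anchor / 3)
    if residue > m.protein_length + 1:  # allow the stop codon itself
        raise ValueError(f"position {p} beyond CDS of {m.transcript_accession}")
    return residue


def domain_of_residue(r: int, m: GeneModel) -> str:
    """Named region containing residue ``r``; gaps report ``"intervening"``."""
    return m.domain_map.region_of(r)


def _anchors(v: VariantDescription) -> list[CodingPosition]:
    return v.range.positions()


def domain_of_variant(
    v: Union[VariantDescription, ProteinChange], m: GeneModel
) -> str:
    """Domain assignment for a variant description.

    Protein changes use their residue. Coding descriptions use the 5'-most
    defined CDS anchor (intronic offsets are ignored — a splice variant is
    assigned the domain of the exon it borders). Edits confined to the 5'UTR
    map to the untranslated region; deletions spanning the whole locus map
    to ``"Whole gene"``.
    """
    if isinstance(v, ProteinChange):
        if v.compound:
            raise ValueError("assign domains per component of a compound change")
        if v.position is None:
            raise ValueError("protein change carries no residue (p.?)")
        return domain_of_residue(v.position, m)
    if v.level != "coding":
        raise ValueError("domain assignment needs a coding-level description")
    if v.edit_kind is EditKind.WHOLE_GENE_DELETION:
        return WHOLE_GENE_REGION
    anchors = _anchors(v)
    if not anchors:
        raise ValueError(f"no defined anchors in {v}")
    cds = [p for p in anchors if p.anchor >= 1 and not p.utr3]
    if not cds:
        if all(p.anchor < 0 or p.utr3 for p in anchors):
            return UTR_REGION
        raise ValueError(f"unresolvable anchors in {v}")
    five_prime = min(cds, key=lambda p: p.sort_key())
    residue = min(codon_for_position(five_prime, m), m.protein_length)
    return domain_of_residue(residue, m)
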