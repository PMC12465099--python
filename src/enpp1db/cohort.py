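"""Cohort analytics over locus-specific patient and variant tables.

Loads tab-separated patient tables (two allele columns in HGVS, diagnosis
and onset labels, provenance) and variant tables (gDNA/cDNA/protein HGVS,
consequence type, domain, ACMG call, allele recurrence), normalizes
genotypes, and computes the cohort summary statistics: zygosity and unique
genotypes, per-variant carrier/allele counts, domain occupancy at unique-
variant and allele level, diagnosis-group splits, truncating-stratified
genotype counts, missense burden, provenance breakdown, phenotype
prevalence and survival summaries, plus an advisory data-quality report.

The curated 154-patient / 109-variant ENPP1 tables ship with the package
(``load_table1`` / ``load_table2``).
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import nomenclature as nm
from .acmg import Classification
from .consequence import (
    ConsequenceType,
    TruncatingStatus,
    classify_consequence,
    is_truncating,
    printed_type_label,
)
from .gene_model import GeneModel, domain_of_variant, enpp1_model

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "VariantRecord",
    "Genotype",
    "LoadReport",
    "load_patient_table",
    "load_variant_table",
    "load_table1",
    "load_table2",
    "zygosity_of",
    "unique_genotypes",
    "carrier_count",
    "allele_count",
    "variant_types_by_key",
    "domain_occupancy",
    "diagnosis_split",
    "truncating_stratification",
    "missense_burden",
    "provenance_breakdown",
    "phenotype_prevalence",
    "survival_summary",
    "consistency_report",
]

DIAGNOSIS_VOCABULARY = {"GACI", "ARHR2", "HR", "PXE", "OPLL", "OALL"}
ONSET_CATEGORIES = (
    "Antenatal", "Neonatal", "Infantile", "Childhood", "Juvenile", "Adult", "Unknown",
)
# Table labels for hypophosphatemic rickets map onto the ARHR2 phenotype
# group for diagnosis splits; this is the assignment that reproduces the
# published GACI/ARHR2/both totals.
DEFAULT_DIAGNOSIS_MAP = {"HR": "ARHR2"}

STRATA = ("two_truncating", "mixed", "two_nontruncating", "het_truncating", "het_nontruncating")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    allele1: nm.AlleleDescription
    allele2: nm.AlleleDescription
    allele1_protein: tuple[nm.ProteinChange, ...] = ()
    allele2_protein: tuple[nm.ProteinChange, ...] = ()
    diagnoses: frozenset[str] = frozenset()
    onset: str = "Unknown"
    sources: frozenset[str] = frozenset()
    pmids: tuple[int, ...] = ()
    survival: Optional[str] = None  # "alive" | "died:<category>" | "unknown"
    phenotypes: Optional[frozenset[str]] = None
    other_gene_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.allele1.identified or self.allele2.identified):
            raise ValueError(f"patient {self.patient_id}: no identified allele")
        if not self.diagnoses:
            raise ValueError(f"patient {self.patient_id}: diagnoses must be nonempty")

    def alleles(self) -> tuple[nm.AlleleDescription, nm.AlleleDescription]:
        return (self.allele1, self.allele2)

    def variant_keys(self) -> list[str]:
        """Normalized keys of every identified variant, allele-repeated."""
        out = []
        for a in self.alleles():
            out.extend(nm.normalize(v) for v in a.variants)
        return out

    def protein_for(self) -> dict[str, nm.ProteinChange]:
        """Map variant key -> paired protein change where aligned."""
        pairs = {}
        for allele, prots in (
            (self.allele1, self.allele1_protein),
            (self.allele2, self.allele2_protein),
        ):
            if len(allele.variants) == len(prots):
                for v, p in zip(allele.variants, prots):
                    pairs[nm.normalize(v)] = p
        return pairs


@dataclass(frozen=True)
class Genotype:
    key: tuple[tuple[str, ...], tuple[str, ...]]  # sorted pair of allele keys
    zygosity: str  # homozygous | compound_heterozygous | heterozygous


@dataclass(frozen=True)
class VariantRecord:
    gdna: str
    cdna: str
    protein: str
    type: str
    exon_label: str
    domain: str
    acmg_call: str
    recurrence: int
    key: str = ""
    cdna_parsed: Optional[nm.VariantDescription] = None
    protein_parsed: Optional[nm.ProteinChange] = None

    def __post_init__(self) -> None:
        if self.recurrence < 1:
            raise ValueError(f"{self.cdna}: recurrence must be >= 1")


@dataclass
class LoadReport:
    n_rows: int = 0
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------------
# loading


def _split_pipe(cell: str) -> list[str]:
    return [p.strip() for p in str(cell).split("|") if p.strip()]


def _parse_sources(cell: str) -> frozenset[str]:
    parts = _split_pipe(cell)
    out = set()
    for p in parts:
        out.add("Literature" if p == "Literature only" else p)
    return frozenset(out)


def _parse_survival(cell) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    if not s or s.lower() in ("none", "nan"):
        return None
    low = s.lower()
    if low in ("alive", "unknown"):
        return low
    if low.startswith("died"):
        return s if ":" in s else "died:unknown"
    raise ValueError(f"unrecognized survival outcome {s!r}")


REQUIRED_PATIENT_COLUMNS = [
    "patient_id", "allele1_cdna", "allele1_protein", "allele2_cdna",
    "allele2_protein", "diagnosis", "age_of_onset", "patient_source", "pmid",
]


def load_patient_table(
    path: Union[str, Path],
) -> tuple[list[PatientRecord], LoadReport]:
    """Load a patient TSV; parse failures are collected, never dropped silently."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    report = LoadReport(n_rows=len(df))
    missing = [c for c in REQUIRED_PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise ValueError(f"duplicate patient_id values: {dupes}")
    if df.empty:
        report.warnings.append("patient table is empty")
        return [], report

    records = []
    for _, row in df.iterrows():
        pid = row["patient_id"]
        try:
            a1 = nm.parse_allele(row["allele1_cdna"])
            a2 = nm.parse_allele(row["allele2_cdna"])

            def prots(cell):
                cleaned = nm.clean_text(str(cell))
                if cleaned.lower() == "not identified" or not cleaned:
                    return ()
                pc = nm.parse_protein(cleaned)
                return pc.compound if pc.compound else (pc,)

            pmid_cell = row["pmid"].strip()
            pmids = (
                ()
                if pmid_cell.lower() in ("none", "")
                else tuple(int(p) for p in _split_pipe(pmid_cell))
            )
            phen_cell = str(row.get("phenotypes", "") or "").strip()
            phenotypes = (
                frozenset(_split_pipe(phen_cell))
                if phen_cell and phen_cell.lower() != "none"
                else (frozenset() if phen_cell.lower() == "none" else None)
            )
            other = row.get("other_gene_variants", "None")
            records.append(
                PatientRecord(
                    patient_id=pid,
                    allele1=a1,
                    allele2=a2,
                    allele1_protein=prots(row["allele1_protein"]),
                    allele2_protein=prots(row["allele2_protein"]),
                    diagnoses=frozenset(_split_pipe(row["diagnosis"])),
                    onset=row["age_of_onset"].strip() or "Unknown",
                    sources=_parse_sources(row["patient_source"]),
                    pmids=pmids,
                    survival=_parse_survival(row.get("survival")),
                    phenotypes=phenotypes,
                    other_gene_variants=tuple(
                        _split_pipe(other) if str(other).lower() != "none" else ()
                    ),
                )
            )
        except (ValueError, nm.HgvsSyntaxError) as exc:
            report.errors.append((pid, str(exc)))
            logger.warning("patient %s failed to load: %s", pid, exc)
    return records, report


REQUIRED_VARIANT_COLUMNS = [
    "type", "gdna", "cdna", "protein", "exon_intron", "domain", "acmg_call", "recurrence",
]


def load_variant_table(
    path: Union[str, Path],
) -> tuple[list[VariantRecord], LoadReport]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    report = LoadReport(n_rows=len(df))
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing required columns: {missing}")
    if df.empty:
        report.warnings.append("variant table is empty")
        return [], report
    records = []
    for _, row in df.iterrows():
        try:
            cdna = nm.parse_cdna(row["cdna"])
            prot_cell = nm.clean_text(row["protein"])
            prot = nm.parse_protein(prot_cell) if prot_cell.startswith("p.") else None
            records.append(
                VariantRecord(
                    gdna=nm.clean_text(row["gdna"]),
                    cdna=nm.clean_text(row["cdna"]),
                    protein=prot_cell,
                    type=row["type"].strip(),
                    exon_label=row["exon_intron"].strip(),
                    domain=row["domain"].strip(),
                    acmg_call=row["acmg_call"].strip(),
                    recurrence=int(row["recurrence"]),
                    key=nm.normalize(cdna),
                    cdna_parsed=cdna,
                    protein_parsed=prot,
                )
            )
        except (ValueError, nm.HgvsSyntaxError) as exc:
            report.errors.append((row["cdna"], str(exc)))
            logger.warning("variant %s failed to load: %s", row["cdna"], exc)
    return records, report


def _data_path(name: str):
    return resources.files("enpp1db.data").joinpath(name)


def load_table1() -> list[PatientRecord]:
    """The packaged 154-patient curated ENPP1 cohort."""
    with resources.as_file(_data_path("patients_table1.tsv")) as p:
        records, report = load_patient_table(p)
    if report.errors:
        raise RuntimeError(f"packaged patient table failed to parse: {report.errors}")
    return records


def load_table2() -> list[VariantRecord]:
    """The packaged 109-variant curated ENPP1 variant table."""
    with resources.as_file(_data_path("variants_table2.tsv")) as p:
        records, report = load_variant_table(p)
    if report.errors:
        raise RuntimeError(f"packaged variant table failed to parse: {report.errors}")
    return records


# ----------------------------------------------------------------------------
# genotype / zygosity


def zygosity_of(p: PatientRecord) -> Genotype:
    """Zygosity from the two allele keys; multi-variant in-cis alleles
    compare as whole alleles."""
    k1, k2 = nm.allele_key(p.allele1), nm.allele_key(p.allele2)
    if not p.allele1.identified or not p.allele2.identified:
        zyg = "heterozygous"
    elif k1 == k2:
        zyg = "homozygous"
    else:
        zyg = "compound_heterozygous"
    key = tuple(sorted([k1, k2]))
    return Genotype(key=key, zygosity=zyg)


def unique_genotypes(
    patients: Sequence[PatientRecord],
) -> tuple[int, dict[tuple, list[PatientRecord]]]:
    """Count of distinct genotypes plus a genotype -> patients index."""
    if not patients:
        raise ValueError("empty cohort")
    index: dict[tuple, list[PatientRecord]] = defaultdict(list)
    for p in patients:
        index[zygosity_of(p).key].append(p)
    return len(index), dict(index)


def carrier_count(variant_key: str, patients: Sequence[PatientRecord]) -> int:
    """Patients carrying at least one copy of the variant."""
    return sum(variant_key in set(p.variant_keys()) for p in patients)


def allele_count(variant_key: str, patients: Sequence[PatientRecord]) -> int:
    """Total allele occurrences (2 per homozygote)."""
    return sum(p.variant_keys().count(variant_key) for p in patients)


# ----------------------------------------------------------------------------
# annotation-driven statistics


def variant_types_by_key(
    variants: Sequence[VariantRecord], model: Optional[GeneModel] = None
) -> dict[str, ConsequenceType]:
    """Recomputed consequence type per normalized variant key."""
    model = model or enpp1_model()
    return {
        v.key: classify_consequence(v.cdna_parsed, v.protein_parsed, model)
        for v in variants
    }


def domain_occupancy(
    variants: Sequence[VariantRecord],
    patients: Optional[Sequence[PatientRecord]] = None,
    weighting: str = "unique",
    model: Optional[GeneModel] = None,
) -> dict[str, int]:
    """Variant counts per domain, recomputed from the HGVS columns.

    ``unique`` weights each variant once (sums to the variant count);
    ``allele`` weights by allele occurrence — recomputed from the patient
    table when given, else the recurrence column.
    """
    model = model or enpp1_model()
    counts: Counter = Counter()
    for v in variants:
        prot = v.protein_parsed
        use_prot = (
            prot is not None
            and not prot.compound
            and prot.position is not None
        )
        domain = domain_of_variant(prot if use_prot else v.cdna_parsed, model)
        if weighting == "unique":
            w = 1
        elif weighting == "allele":
            w = allele_count(v.key, patients) if patients is not None else v.recurrence
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        counts[domain] += w
    return dict(counts)


def _mapped_diagnoses(p: PatientRecord, mapping: dict[str, str]) -> frozenset[str]:
    return frozenset(mapping.get(d, d) for d in p.diagnoses)


def diagnosis_split(
    patients: Sequence[PatientRecord],
    mapping: Optional[dict[str, str]] = None,
) -> dict[str, int]:
    """Counts of GACI-only / ARHR2-only / both (plus neither when present)."""
    mapping = DEFAULT_DIAGNOSIS_MAP if mapping is None else mapping
    out = {"GACI_only": 0, "ARHR2_only": 0, "both": 0, "neither": 0}
    for p in patients:
        d = _mapped_diagnoses(p, mapping)
        gaci, arhr2 = "GACI" in d, "ARHR2" in d
        if gaci and arhr2:
            out["both"] += 1
        elif gaci:
            out["GACI_only"] += 1
        elif arhr2:
            out["ARHR2_only"] += 1
        else:
            out["neither"] += 1
    if not out["neither"]:
        del out["neither"]
    return out


def _allele_truncating(
    allele: nm.AlleleDescription,
    prots: tuple[nm.ProteinChange, ...],
    types: dict[str, ConsequenceType],
) -> bool:
    """An allele is truncating when any in-cis variant is truncating."""
    for i, v in enumerate(allele.variants):
        key = nm.normalize(v)
        if key in types:
            t = types[key]
        else:
            p = prots[i] if i < len(prots) else None
            t = classify_consequence(v, p)
        if is_truncating(t, v) is TruncatingStatus.TRUNCATING:
            return True
    return False


def patient_stratum(
    p: PatientRecord, types: dict[str, ConsequenceType]
) -> str:
    """Truncating stratum of one patient's genotype."""
    identified = [
        (a, pr)
        for a, pr in ((p.allele1, p.allele1_protein), (p.allele2, p.allele2_protein))
        if a.identified
    ]
    flags = [_allele_truncating(a, pr, types) for a, pr in identified]
    if len(identified) == 1:
        return "het_truncating" if flags[0] else "het_nontruncating"
    n = sum(flags)
    return ("two_nontruncating", "mixed", "two_truncating")[n]


def truncating_stratification(
    patients: Sequence[PatientRecord],
    variants: Optional[Sequence[VariantRecord]] = None,
    model: Optional[GeneModel] = None,
) -> pd.DataFrame:
    """Genotype counts by number of truncating variants, overall and per
    survival stratum when outcomes are recorded.

    Rows: total plus died/survived/unknown when any survival data present;
    columns: the five genotype strata. Row sums equal the stratum
    denominators.
    """
    types = variant_types_by_key(variants, model) if variants else {}
    rows: dict[str, Counter] = {"total": Counter()}
    any_survival = any(p.survival is not None for p in patients)
    for p in patients:
        stratum = patient_stratum(p, types)
        rows["total"][stratum] += 1
        if any_survival:
            s = p.survival or "unknown"
            label = "died" if s.startswith("died") else "survived" if s == "alive" else "unknown"
            rows.setdefault(label, Counter())[stratum] += 1
    order = ["total"] + [r for r in ("died", "survived", "unknown") if r in rows]
    return pd.DataFrame(
        [[rows[r].get(c, 0) for c in STRATA] for r in order],
        index=order,
        columns=list(STRATA),
    )


def missense_burden(
    patients: Sequence[PatientRecord],
    variants: Optional[Sequence[VariantRecord]] = None,
    model: Optional[GeneModel] = None,
) -> dict[str, int]:
    """Counts of patients with >=1 missense variant and with an
    all-missense biallelic genotype (every variant on both identified
    alleles is missense)."""
    types = variant_types_by_key(variants, model) if variants else {}

    def vtype(v, prot):
        key = nm.normalize(v)
        return types.get(key) or classify_consequence(v, prot)

    ge1 = two = 0
    for p in patients:
        alleles = [
            (a, pr)
            for a, pr in ((p.allele1, p.allele1_protein), (p.allele2, p.allele2_protein))
        ]
        has_missense = False
        all_missense_per_allele = []
        for a, pr in alleles:
            if not a.identified:
                all_missense_per_allele.append(False)
                continue
            ts = [
                vtype(v, pr[i] if i < len(pr) else None)
                for i, v in enumerate(a.variants)
            ]
            if any(t is ConsequenceType.MISSENSE for t in ts):
                has_missense = True
            all_missense_per_allele.append(
                all(t is ConsequenceType.MISSENSE for t in ts)
            )
        ge1 += has_missense
        two += all(all_missense_per_allele)
    if two > ge1:
        raise AssertionError("two-missense must be a subset of >=1-missense")
    return {"at_least_one_missense": ge1, "two_missense": two}


def provenance_breakdown(patients: Sequence[PatientRecord]) -> dict:
    """Counts per exact source combination plus derived headline groups."""
    combos: Counter = Counter()
    literature = nhs_only = clinic_only = 0
    for p in patients:
        combos[tuple(sorted(p.sources))] += 1
        if "Literature" in p.sources:
            literature += 1
        elif p.sources & {"NIH NHS", "Münster NHS"}:
            nhs_only += 1
        else:
            clinic_only += 1
    return {
        "combinations": dict(combos),
        "literature": literature,
        "natural_history_only": nhs_only,
        "clinic_only": clinic_only,
    }


def phenotype_prevalence(
    patients: Sequence[PatientRecord],
    mapping: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Phenotype prevalence by diagnosis group.

    Denominators count patients with a recorded (possibly empty) phenotype
    set; patients with no phenotype data are excluded, never imputed.
    Returns an empty frame (with a warning) when no phenotype data exist.
    """
    mapping = DEFAULT_DIAGNOSIS_MAP if mapping is None else mapping
    with_data = [p for p in patients if p.phenotypes is not None]
    if not with_data:
        logger.warning("no phenotype data in cohort; prevalence table empty")
        return pd.DataFrame(
            columns=["group", "phenotype", "numerator", "denominator", "prevalence"]
        )

    def group_of(p):
        d = _mapped_diagnoses(p, mapping)
        gaci, arhr2 = "GACI" in d, "ARHR2" in d
        return "both" if (gaci and arhr2) else "GACI_only" if gaci else "ARHR2_only" if arhr2 else "other"

    labels = sorted({ph for p in with_data for ph in p.phenotypes})
    rows = []
    by_group: dict[str, list[PatientRecord]] = defaultdict(list)
    for p in with_data:
        by_group[group_of(p)].append(p)
    for group, members in sorted(by_group.items()):
        denom = len(members)
        for label in labels:
            num = sum(label in p.phenotypes for p in members)
            rows.append((group, label, num, denom, num / denom))
    return pd.DataFrame(
        rows, columns=["group", "phenotype", "numerator", "denominator", "prevalence"]
    )


def survival_summary(
    patients: Sequence[PatientRecord],
    variants: Optional[Sequence[VariantRecord]] = None,
    model: Optional[GeneModel] = None,
) -> dict:
    """Death/survival counts, overall and per truncating stratum."""
    with_outcome = [p for p in patients if p.survival is not None]
    if not with_outcome:
        logger.warning("no survival outcomes recorded")
        return {"n_with_outcome": 0}
    died = [p for p in with_outcome if p.survival.startswith("died")]
    alive = [p for p in with_outcome if p.survival == "alive"]
    known = len(died) + len(alive)
    types = variant_types_by_key(variants, model) if variants else {}
    per_stratum: dict[str, dict[str, int]] = {}
    for p in with_outcome:
        s = patient_stratum(p, types)
        d = per_stratum.setdefault(s, {"died": 0, "alive": 0, "unknown": 0})
        d["died" if p.survival.startswith("died") else "alive" if p.survival == "alive" else "unknown"] += 1
    return {
        "n_with_outcome": len(with_outcome),
        "n_known": known,
        "died": len(died),
        "alive": len(alive),
        "died_fraction_of_known": len(died) / known if known else None,
        "per_stratum": per_stratum,
        "died_categories": dict(
            Counter(p.survival.split(":", 1)[1] if ":" in p.survival else "unknown" for p in died)
        ),
    }


def consistency_report(
    patients: Sequence[PatientRecord],
    variants: Sequence[VariantRecord],
    model: Optional[GeneModel] = None,
) -> dict:
    """Advisory data-quality report; mismatches are surfaced, never fatal.

    Checks (a) the printed recurrence column against allele counts
    recomputed from the patient table, (b) printed type/domain columns
    against recomputed annotation, (c) allele-count bookkeeping totals, and
    (d) duplicate-genotype patients sharing PMIDs (dedup candidates for
    newly merged data).
    """
    model = model or enpp1_model()
    report: dict = {"recurrence_mismatches": [], "type_mismatches": [], "domain_mismatches": []}
    if not patients and not variants:
        return report

    for v in variants:
        recomputed = allele_count(v.key, patients)
        if recomputed != v.recurrence:
            report["recurrence_mismatches"].append(
                {"variant": v.key, "printed": v.recurrence, "recomputed": recomputed}
            )
        t = classify_consequence(v.cdna_parsed, v.protein_parsed, model)
        printed_type = v.type.split(" (")[0]  # "missense (polymorphism)" -> missense
        if printed_type_label(t) != printed_type:
            report["type_mismatches"].append(
                {"variant": v.key, "printed": v.type, "recomputed": printed_type_label(t)}
            )
        prot = v.protein_parsed
        use_prot = prot is not None and not prot.compound and prot.position is not None
        dom = domain_of_variant(prot if use_prot else v.cdna_parsed, model)
        if dom != v.domain:
            report["domain_mismatches"].append(
                {"variant": v.key, "printed": v.domain, "recomputed": dom}
            )

    printed_total = sum(v.recurrence for v in variants)
    recomputed_total = sum(allele_count(v.key, patients) for v in variants)
    identified_alleles = sum(
        a.identified for p in patients for a in p.alleles()
    )
    report["allele_totals"] = {
        "printed_recurrence_sum": printed_total,
        "recomputed_allele_sum": recomputed_total,
        "identified_alleles": identified_alleles,
    }

    # duplicate-genotype patients sharing a PMID: candidates for dedup review
    candidates = []
    if patients:
        _, index = unique_genotypes(patients)
        for key, members in index.items():
            if len(members) < 2:
                continue
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    shared = set(a.pmids) & set(b.pmids)
                    if shared:
                        candidates.append(
                            {
                                "patients": [a.patient_id, b.patient_id],
                                "shared_pmids": sorted(shared),
                            }
                        )
    report["dedup_candidates"] = candidates
    return report
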