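"""Seeded synthetic locus-specific-database cohorts.

Generates patient/variant table pairs with the statistical structure of a
curated rare-disease LSDB: a variant pool with a heavy private-variant
tail, a homozygous / compound-heterozygous / heterozygous genotype
mixture, diagnosis groups with configurable phenotype prevalences, and
per-stratum survival outcomes. The default parameters are the curated
ENPP1 cohort's printed proportions (154 patients, 109 variants, 69.7%
private, zygosity 40.3/52.6/7.1, diagnosis 64.3/18.8/16.9, ...).

Variant HGVS strings are synthesized on a toy 300-codon transcript with a
scaled-down domain map, so the whole analytics stack — parsing, consequence
typing, domain assignment, stratification — runs end to end without the
real gene model. The private-variant tail is constructed, not sampled:
exactly ``round(private_fraction * pool)`` variants receive a single
patient, the rest at least two, with a heavy-tailed allocation of the
remaining allele draws.

All randomness flows from one ``numpy`` Generator seeded from
``spec.seed``; equal seeds give byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .gene_model import GeneModel, load_gene_model

__all__ = ["CohortSpec", "SyntheticCohort", "InfeasibleSpecError", "generate", "curated_cohort_spec", "toy_gene_model"]

_AA = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()
_BASES = "ACGT"

_TOY_MODEL_CFG = {
    "transcript_accession": "TOY_0001.1",
    "protein_accession": "TOYP_0001.1",
    "protein_length": 300,
    "cds_length": 903,
    "domains": [
        {"name": "Cytoplasmic domain", "start": 1, "end": 25},
        {"name": "Transmembrane region", "start": 26, "end": 32},
        {"name": "SMB 1", "start": 34, "end": 47},
        {"name": "SMB 2", "start": 48, "end": 61},
        {"name": "Linker 1", "start": 62, "end": 62},
        {"name": "Phosphodiesterase", "start": 63, "end": 192},
        {"name": "Linker 2", "start": 193, "end": 212},
        {"name": "Nuclease", "start": 213, "end": 300},
    ],
}

_DIED_CATEGORIES = ("stillborn", "neonatal", "infantile")


def toy_gene_model() -> GeneModel:
    """The scaled 300-codon gene model the generator writes variants on."""
    return load_gene_model(_TOY_MODEL_CFG)


class InfeasibleSpecError(ValueError):
    """The requested cohort structure cannot be constructed."""


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters; defaults are the curated cohort's proportions."""

    n_patients: int = 154
    variant_pool_size: int = 109
    private_fraction: float = 76 / 109
    zygosity_probs: tuple[float, float, float] = (0.403, 0.526, 0.071)  # hom, chet, het
    type_mix: dict = field(
        default_factory=lambda: {
            "missense": 61 / 109,
            "nonsense": 15 / 109,
            "frameshift": 12 / 109,
            "splice": 12 / 109,
            "deletion": 8 / 109,
            "UTR": 1 / 109,
        }
    )
    acmg_mix: dict = field(
        default_factory=lambda: {
            "Pathogenic": 55 / 109,
            "Likely Pathogenic": 24 / 109,
            "VUS": 26 / 109,
            "Benign": 2 / 109,
            "Conflict": 2 / 109,
        }
    )
    diagnosis_probs: tuple[float, float, float] = (0.643, 0.188, 0.169)  # GACI, ARHR2, both
    onset_probs: dict = field(
        default_factory=lambda: {
            "Antenatal": 23 / 154,
            "Neonatal": 59 / 154,
            "Infantile": 8 / 154,
            "Childhood": 7 / 154,
            "Juvenile": 6 / 154,
            "Adult": 4 / 154,
            "Unknown": 47 / 154,
        }
    )
    source_probs: tuple[float, float, float] = (111 / 154, 41 / 154, 2 / 154)
    phenotype_prevalences: dict = field(
        default_factory=lambda: {
            "arterial or aortic calcification": {
                "GACI_only": 0.859, "both": 0.923, "ARHR2_only": 0.069,
            },
            "cardiovascular complications": {
                "GACI_only": 0.768, "both": 0.846, "ARHR2_only": 0.345,
            },
            "hearing impairment": {
                "GACI_only": 0.091, "both": 0.538, "ARHR2_only": 0.172,
            },
        }
    )
    death_probs: dict = field(
        default_factory=lambda: {
            "two_truncating": 8 / 24,
            "mixed": 15 / 33,
            "two_nontruncating": 42 / 80,
            "het_truncating": 2 / 3,
            "het_nontruncating": 4 / 7,
        }
    )
    unknown_outcome_prob: float = 7 / 154
    seed: int = 0

    def __post_init__(self) -> None:
        for name, simplex in (
            ("zygosity_probs", self.zygosity_probs),
            ("diagnosis_probs", self.diagnosis_probs),
            ("source_probs", self.source_probs),
        ):
            if abs(sum(simplex) - 1.0) > 1e-6 or any(p < 0 for p in simplex):
                raise ValueError(f"{name} must be a probability simplex")
        for name, dist in (("type_mix", self.type_mix), ("acmg_mix", self.acmg_mix), ("onset_probs", self.onset_probs)):
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 <= self.private_fraction <= 1.0:
            raise ValueError("private_fraction must lie in [0, 1]")
        if self.n_patients < 1 or self.variant_pool_size < 1:
            raise ValueError("cohort and pool sizes must be positive")


@dataclass(frozen=True)
class SyntheticCohort:
    patients: pd.DataFrame
    variants: pd.DataFrame
    ground_truth: dict


def curated_cohort_spec(seed: int = 0) -> CohortSpec:
    """A spec whose parameters are the curated cohort's printed fractions."""
    return CohortSpec(seed=seed)


# ----------------------------------------------------------------------------
# variant synthesis on the toy transcript


def _synth_variant(vclass: str, codon: int, rng: np.random.Generator, utr_index: int):
    """One synthetic (cdna, protein, truncating) triple for a variant class."""
    aa_ref, aa_alt = rng.choice(_AA, size=2, replace=False)
    if vclass == "missense":
        pos = 3 * codon - 1
        b1, b2 = rng.choice(list(_BASES), size=2, replace=False)
        return f"c.{pos}{b1}>{b2}", f"p.{aa_ref}{codon}{aa_alt}", False
    if vclass == "nonsense":
        pos = 3 * codon - 2
        b1, b2 = rng.choice(list(_BASES), size=2, replace=False)
        return f"c.{pos}{b1}>{b2}", f"p.{aa_ref}{codon}*", True
    if vclass == "frameshift":
        pos = 3 * codon - 1
        stop = int(rng.integers(2, 60))
        return f"c.{pos}del", f"p.{aa_ref}{codon}{aa_alt}fs*{stop}", True
    if vclass == "splice":
        pos = 3 * codon
        sign, off = ("+", int(rng.integers(1, 3))) if rng.random() < 0.5 else ("-", int(rng.integers(1, 3)))
        base_from, base_to = ("G", "A") if sign == "+" else ("A", "G")
        return f"c.{pos}{sign}{off}{base_from}>{base_to}", "p.?", True
    if vclass == "deletion":
        start = 3 * codon - 2
        end = min(start + int(rng.integers(6, 30)), 903)
        return f"c.{start}_{end}del", "p.?", True
    if vclass == "UTR":
        return f"c.-{10 + utr_index}G>C", "p.?", False
    raise ValueError(f"unknown variant class {vclass!r}")


def _allocate_draws(
    pool: int, n_private: int, total_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw counts per variant: private variants get exactly 1, the rest
    >= 2 with a heavy-tailed split of the remainder."""
    n_rec = pool - n_private
    base = n_private + 2 * n_rec
    if total_draws < base:
        raise InfeasibleSpecError(
            f"{total_draws} allele draws cannot cover {n_private} private "
            f"variants plus {n_rec} recurrent variants (need >= {base}); "
            "increase n_patients or shrink the pool/private fraction"
        )
    counts = np.ones(pool, dtype=int)
    counts[n_private:] = 2
    extra = total_draws - base
    if extra and n_rec:
        weights = rng.pareto(1.2, size=n_rec) + 0.1  # heavy tail: few hotspots
        weights /= weights.sum()
        counts[n_private:] += rng.multinomial(extra, weights)
    elif extra:
        raise InfeasibleSpecError(
            "every variant is private but there are more allele draws than variants"
        )
    return counts


def generate(spec: CohortSpec) -> SyntheticCohort:
    """Generate one synthetic cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pool = spec.variant_pool_size
    model = toy_gene_model()
    if pool > 250:
        raise InfeasibleSpecError("toy transcript supports at most 250 pool variants")

    # --- variant pool
    classes = list(spec.type_mix)
    vclasses = list(rng.choice(classes, size=pool, p=[spec.type_mix[c] for c in classes]))
    acmg_vals = list(spec.acmg_mix)
    acmg = list(rng.choice(acmg_vals, size=pool, p=[spec.acmg_mix[c] for c in acmg_vals]))
    codons = rng.choice(np.arange(2, 299), size=pool, replace=False)
    utr_i = 0
    cdnas, prots, trunc = [], [], []
    for vclass, codon in zip(vclasses, codons):
        c, p, t = _synth_variant(vclass, int(codon), rng, utr_i)
        if vclass == "UTR":
            utr_i += 1
        cdnas.append(c)
        prots.append(p)
        trunc.append(t)

    # --- zygosity and allele draws
    zyg = rng.choice(
        ["homozygous", "compound_heterozygous", "heterozygous"],
        size=spec.n_patients,
        p=list(spec.zygosity_probs),
    )
    draws_needed = int(sum(2 if z == "compound_heterozygous" else 1 for z in zyg))
    n_private = int(round(spec.private_fraction * pool))
    # private status is assigned to a random subset of the pool
    private_order = rng.permutation(pool)
    counts = _allocate_draws(pool, n_private, draws_needed, rng)
    # counts[i] is the draw count of pool index private_order[i]
    draw_pool = np.repeat(private_order, counts)
    rng.shuffle(draw_pool)

    # --- assign draws to patients; compound hets need two distinct variants
    genotypes: list[tuple[Optional[int], Optional[int]]] = []
    cursor = 0
    for z in zyg:
        if z == "compound_heterozygous":
            a, b = int(draw_pool[cursor]), int(draw_pool[cursor + 1])
            cursor += 2
            genotypes.append((a, b))
        elif z == "homozygous":
            a = int(draw_pool[cursor])
            cursor += 1
            genotypes.append((a, a))
        else:
            a = int(draw_pool[cursor])
            cursor += 1
            genotypes.append((a, None))
    # repair compound hets that drew the same variant twice by swapping with
    # another compound het (keeps every variant's draw count intact)
    chet_idx = [i for i, z in enumerate(zyg) if z == "compound_heterozygous"]
    for i in chet_idx:
        a, b = genotypes[i]
        if a != b:
            continue
        for j in chet_idx:
            c, d = genotypes[j]
            if i == j or c == a or d == a:
                continue
            genotypes[i] = (a, d)
            genotypes[j] = (c, b)
            break
        else:
            raise InfeasibleSpecError(
                "cannot form distinct compound-heterozygous pairs; the pool "
                "is too concentrated for the requested cohort"
            )

    # --- recurrence bookkeeping (an allele count: homozygotes count twice)
    recurrence = np.zeros(pool, dtype=int)
    carriers: list[set[int]] = [set() for _ in range(pool)]
    for pi, (a, b) in enumerate(genotypes):
        recurrence[a] += 1
        carriers[a].add(pi)
        if b is not None:
            recurrence[b] += 1
            carriers[b].add(pi)

    # --- clinical annotation
    groups = rng.choice(
        ["GACI_only", "ARHR2_only", "both"],
        size=spec.n_patients,
        p=list(spec.diagnosis_probs),
    )
    onsets = rng.choice(
        list(spec.onset_probs), size=spec.n_patients, p=list(spec.onset_probs.values())
    )
    source_kind = rng.choice(
        ["literature", "nhs", "clinic"], size=spec.n_patients, p=list(spec.source_probs)
    )

    def stratum_of(a, b):
        if b is None:
            return "het_truncating" if trunc[a] else "het_nontruncating"
        n = int(trunc[a]) + int(trunc[b])
        return ("two_nontruncating", "mixed", "two_truncating")[n]

    rows = []
    for pi, (a, b) in enumerate(genotypes):
        group = groups[pi]
        diag = {"GACI_only": "GACI", "ARHR2_only": "ARHR2", "both": "GACI | ARHR2"}[group]
        phenos = [
            label
            for label, prev in spec.phenotype_prevalences.items()
            if rng.random() < prev.get(group, 0.0)
        ]
        if rng.random() < spec.unknown_outcome_prob:
            survival = "unknown"
        elif rng.random() < spec.death_probs[stratum_of(a, b)]:
            survival = "died:" + str(rng.choice(_DIED_CATEGORIES, p=[9 / 71, 43 / 71, 19 / 71]))
        else:
            survival = "alive"
        if source_kind[pi] == "literature":
            source = "Literature only"
            pmid = " | ".join(
                str(int(p)) for p in rng.integers(10_000_000, 40_000_000, size=int(rng.integers(1, 4)))
            )
        elif source_kind[pi] == "nhs":
            source = str(rng.choice(["Münster NHS", "NIH NHS"], p=[27 / 41, 14 / 41]))
            pmid = "None"
        else:
            source, pmid = "NIH Clinic", "None"
        rows.append(
            {
                "patient_id": f"S{pi + 1:04d}",
                "allele1_cdna": cdnas[a],
                "allele1_protein": prots[a],
                "allele2_cdna": cdnas[b] if b is not None else "Not identified",
                "allele2_protein": prots[b] if b is not None else "Not identified",
                "diagnosis": diag,
                "age_of_onset": str(onsets[pi]),
                "patient_source": source,
                "pmid": pmid,
                "other_gene_variants": "None",
                "phenotypes": " | ".join(phenos) if phenos else "None",
                "survival": survival,
            }
        )
    patients = pd.DataFrame(rows)

    # --- variant table on the toy transcript
    from .consequence import classify_consequence, printed_type_label
    from .gene_model import domain_of_variant
    from . import nomenclature as nm

    vrows = []
    for vi in range(pool):
        v = nm.parse_cdna(cdnas[vi])
        prot = nm.parse_protein(prots[vi])
        use_prot = prot.position is not None
        domain = domain_of_variant(prot if use_prot else v, model)
        ctype = classify_consequence(v, prot, model)
        anchor = v.range.start.anchor
        gpos = 1_000_000 + anchor if anchor > 0 else 999_000 - anchor
        gdna = (
            f"g.{gpos}{v.ref_seq}>{v.alt_seq}"
            if v.edit_kind.value == "substitution"
            else f"g.{gpos}del"
        )
        vrows.append(
            {
                "type": printed_type_label(ctype),
                "gdna": gdna,
                "cdna": cdnas[vi],
                "protein": prots[vi],
                "exon_intron": "NA",
                "domain": domain,
                "acmg_call": acmg[vi],
                "recurrence": int(recurrence[vi]),
            }
        )
    variants = pd.DataFrame(vrows).sort_values(
        "recurrence", ascending=False, kind="stable"
    ).reset_index(drop=True)

    observed_private = sum(1 for c in carriers if len(c) == 1)
    ground_truth = {
        "spec": {
            "n_patients": spec.n_patients,
            "variant_pool_size": pool,
            "private_fraction": spec.private_fraction,
            "zygosity_probs": list(spec.zygosity_probs),
            "diagnosis_probs": list(spec.diagnosis_probs),
            "seed": spec.seed,
        },
        "realized": {
            "zygosity": dict(pd.Series(zyg).value_counts()),
            "diagnosis_groups": dict(pd.Series(groups).value_counts()),
            "private_variants": observed_private,
            "private_fraction_observed": observed_private / pool,
            "allele_draws": draws_needed,
        },
    }
    ground_truth["realized"]["zygosity"] = {
        k: int(v) for k, v in ground_truth["realized"]["zygosity"].items()
    }
    ground_truth["realized"]["diagnosis_groups"] = {
        k: int(v) for k, v in ground_truth["realized"]["diagnosis_groups"].items()
    }
    return SyntheticCohort(patients=patients, variants=variants, ground_truth=ground_truth)
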