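"""Cohort analytics over the curated patient/variant tables."""
import random
from collections import Counter

import pytest

from enpp1db import nomenclature as nm
from enpp1db.cohort import (
    allele_count,
    carrier_count,
    consistency_report,
    diagnosis_split,
    domain_occupancy,
    load_patient_table,
    missense_burden,
    phenotype_prevalence,
    provenance_breakdown,
    survival_summary,
    truncating_stratification,
    unique_genotypes,
    zygosity_of,
)


def _patient(patients, pid):
    return next(p for p in patients if p.patient_id == pid)


class TestLoading:
    def test_table_sizes(self, patients, variants):
        assert len(patients) == 154
        assert len(variants) == 109

    def test_empty_file_gives_empty_list_and_warning(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text(
            "patient_id\tallele1_cdna\tallele1_protein\tallele2_cdna\t"
            "allele2_protein\tdiagnosis\tage_of_onset\tpatient_source\tpmid\n"
        )
        records, report = load_patient_table(f)
        assert records == [] and report.warnings

    def test_missing_column_rejected(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("patient_id\tallele1_cdna\n1\tc.1A>T\n")
        with pytest.raises(ValueError, match="missing required"):
            load_patient_table(f)

    def test_duplicate_patient_id_rejected(self, tmp_path):
        header = (
            "patient_id\tallele1_cdna\tallele1_protein\tallele2_cdna\t"
            "allele2_protein\tdiagnosis\tage_of_onset\tpatient_source\tpmid\n"
        )
        row = "7\tc.1A>T\tp.Met1?\tc.1A>T\tp.Met1?\tGACI\tNeonatal\tLiterature only\tNone\n"
        f = tmp_path / "dup.tsv"
        f.write_text(header + row + row)
        with pytest.raises(ValueError, match="duplicate"):
            load_patient_table(f)

    def test_abcc6_variants_carried_but_separate(self, patients):
        carriers = [p for p in patients if p.other_gene_variants]
        assert {p.patient_id for p in carriers} == {"76", "118", "156"}
        assert all("ABCC6" in v for p in carriers for v in p.other_gene_variants)


class TestZygosity:
    @pytest.mark.parametrize(
        "pid, zygosity",
        [
            ("3", "homozygous"),
            ("9", "compound_heterozygous"),
            ("66", "heterozygous"),
            ("26", "compound_heterozygous"),  # phase-unknown pair vs single
        ],
    )
    def test_individual_patients(self, patients, pid, zygosity):
        assert zygosity_of(_patient(patients, pid)).zygosity == zygosity

    def test_cohort_zygosity_partition(self, patients):
        counts = Counter(zygosity_of(p).zygosity for p in patients)
        assert counts == {
            "homozygous": 62,
            "compound_heterozygous": 81,
            "heterozygous": 11,
        }
        assert sum(counts.values()) == 154


class TestUniqueGenotypes:
    def test_genotype_count_and_multiplicities(self, patients):
        n, index = unique_genotypes(patients)
        assert n == 108
        multiplicity = Counter(len(v) for v in index.values())
        # 77 genotypes in one patient, 24 in exactly two (48 patients)
        assert multiplicity[1] == 77
        assert multiplicity[2] == 24

    def test_most_common_genotype(self, patients):
        _, index = unique_genotypes(patients)
        key = (("c.913C>A",), ("c.913C>A",))
        assert len(index[key]) == 9

    def test_allele_order_invariance(self, patients):
        g = zygosity_of(_patient(patients, "9"))
        p = _patient(patients, "9")
        swapped = nm.AlleleDescription(p.allele2.variants, p.allele2.phase), nm.AlleleDescription(
            p.allele1.variants, p.allele1.phase
        )
        key_swapped = tuple(sorted([nm.allele_key(swapped[0]), nm.allele_key(swapped[1])]))
        assert g.key == key_swapped

    def test_permutation_invariance_of_count(self, patients):
        shuffled = list(patients)
        random.Random(0).shuffle(shuffled)
        assert unique_genotypes(shuffled)[0] == unique_genotypes(patients)[0]


class TestCarrierAndAlleleCounts:
    def test_most_recurrent_variant(self, patients):
        assert carrier_count("c.913C>A", patients) == 24
        assert allele_count("c.913C>A", patients) == 33

    def test_absent_key(self, patients):
        assert carrier_count("c.999999A>T", patients) == 0
        assert allele_count("c.999999A>T", patients) == 0

    def test_count_identity_for_every_variant(self, patients, variants):
        """allele_count = 2*homozygous-carriers + het occurrences, and
        carriers <= alleles <= 2*carriers."""
        for v in variants:
            carriers = carrier_count(v.key, patients)
            alleles = allele_count(v.key, patients)
            hom = sum(
                1
                for p in patients
                if p.variant_keys().count(v.key) == 2
            )
            het_occurrences = alleles - 2 * hom
            assert alleles == 2 * hom + het_occurrences
            assert carriers <= alleles <= 2 * carriers

    def test_recurrence_column_matches_recomputation(self, patients, variants):
        for v in variants:
            assert allele_count(v.key, patients) == v.recurrence, v.cdna


class TestDomainOccupancy:
    def test_unique_weighting(self, patients, variants, model):
        occ = domain_occupancy(variants, model=model)
        assert occ["Phosphodiesterase"] == 58
        assert occ["Nuclease"] == 33
        assert sum(occ.values()) == 109

    def test_allele_weighting(self, patients, variants, model):
        occ = domain_occupancy(variants, patients, weighting="allele", model=model)
        assert occ["Phosphodiesterase"] == 178
        assert occ["Nuclease"] == 102
        assert sum(occ.values()) == sum(v.recurrence for v in variants)

    def test_unknown_weighting_rejected(self, variants, model):
        with pytest.raises(ValueError):
            domain_occupancy(variants, weighting="bogus", model=model)


class TestDiagnosisSplit:
    def test_cohort_split(self, patients):
        assert diagnosis_split(patients) == {
            "GACI_only": 99,
            "ARHR2_only": 29,
            "both": 26,
        }

    def test_patient_with_both_labels(self, patients):
        p = _patient(patients, "14")
        assert {"GACI", "ARHR2"} <= p.diagnoses

    def test_all_gaci_toy_cohort(self, patients):
        gaci = [p for p in patients if p.diagnoses == frozenset({"GACI"})]
        split = diagnosis_split(gaci)
        assert split == {"GACI_only": len(gaci), "ARHR2_only": 0, "both": 0}


class TestTruncatingStratification:
    def test_total_population_row(self, patients, variants, model):
        """Survival-stratification totals: 24 two-truncating, 35 mixed,
        84 two-nontruncating, 3 het-truncating, 8 het-nontruncating."""
        strat = truncating_stratification(patients, variants, model)
        assert strat.loc["total"].tolist() == [24, 35, 84, 3, 8]
        assert strat.loc["total"].sum() == 154

    def test_splice_region_deletion_counts_truncating(self, patients, variants, model):
        from enpp1db.cohort import patient_stratum, variant_types_by_key

        types = variant_types_by_key(variants, model)
        assert patient_stratum(_patient(patients, "102"), types) == "mixed"

    def test_hom_nonsense_toy_cohort(self, patients, variants, model):
        hom_nonsense = [_patient(patients, "62")]  # p.Glu893* / p.Glu893*
        strat = truncating_stratification(hom_nonsense, variants, model)
        assert strat.loc["total", "two_truncating"] == 1


class TestMissenseBurden:
    def test_cohort_burden(self, patients, variants, model):
        burden = missense_burden(patients, variants, model)
        assert burden == {"at_least_one_missense": 127, "two_missense": 84}

    def test_all_nonsense_toy_cohort(self, patients, variants, model):
        toy = [_patient(patients, "62")]
        burden = missense_burden(toy, variants, model)
        assert burden == {"at_least_one_missense": 0, "two_missense": 0}


class TestProvenance:
    def test_headline_groups(self, patients):
        prov = provenance_breakdown(patients)
        assert prov["literature"] == 111
        assert prov["natural_history_only"] == 41
        assert prov["clinic_only"] == 2
        assert sum(prov["combinations"].values()) == 154


class TestPhenotypeAndSurvival:
    def test_no_phenotype_columns_gives_empty_table(self, patients):
        table = phenotype_prevalence(patients)
        assert table.empty

    def test_no_outcomes_recorded(self, patients):
        assert survival_summary(patients)["n_with_outcome"] == 0

    def test_one_patient_cohort_prevalence(self, patients):
        import dataclasses

        p = dataclasses.replace(
            _patient(patients, "3"), phenotypes=frozenset({"arterial calcification"})
        )
        table = phenotype_prevalence([p])
        row = table.iloc[0]
        assert row["prevalence"] == 1.0 and row["denominator"] == 1


class TestConsistencyReport:
    def test_curated_tables_reproduce_exactly(self, patients, variants, model):
        report = consistency_report(patients, variants, model)
        assert report["recurrence_mismatches"] == []
        assert report["type_mismatches"] == []
        assert report["domain_mismatches"] == []

    def test_allele_total_discrepancy_surfaced(self, patients, variants, model):
        """The recurrence column sums to 310 while only 297 patient alleles
        are identified (recurrent in-cis pairs inflate the sum); the report
        exposes both totals for review."""
        totals = consistency_report(patients, variants, model)["allele_totals"]
        assert totals["printed_recurrence_sum"] == 310
        assert totals["recomputed_allele_sum"] == 310
        assert totals["identified_alleles"] == 297

    def test_empty_tables_give_empty_report(self):
        report = consistency_report([], [])
        assert report["recurrence_mismatches"] == []

    def test_dedup_candidates_share_genotype_and_pmid(self, patients, variants, model):
        report = consistency_report(patients, variants, model)
        assert report["dedup_candidates"], "literature siblings should be flagged"
        for cand in report["dedup_candidates"]:
            assert len(cand["patients"]) == 2 and cand["shared_pmids"]
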