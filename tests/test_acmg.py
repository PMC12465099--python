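"""Evidence combination: rule table, thresholds, conflict handling."""
import itertools

import pytest

from enpp1db.acmg import (
    Classification,
    EvidenceCode,
    EvidenceSet,
    FrequencyRecord,
    combine,
    compare_classification_sets,
    classify_table,
    frequency_evidence,
    load_rules,
)

E = EvidenceSet.from_codes


@pytest.fixture(scope="module")
def rules():
    return load_rules()


class TestFrequencyEvidence:
    def test_common_polymorphism_is_stand_alone_benign(self, rules):
        # 3.3% overall, 9.7% in the highest population: too common for a
        # rare recessive disease under popmax thresholds
        code = frequency_evidence(FrequencyRecord(0.033, 0.097), rules)
        assert code.code == "BA1"

    def test_borderline_variant_is_silent_in_overall_mode(self):
        overall = load_rules({"frequency_thresholds": {"mode": "overall"}})
        assert frequency_evidence(FrequencyRecord(0.0075, 0.049), overall) is None

    def test_absent_variant_supports_pathogenicity(self, rules):
        assert frequency_evidence(FrequencyRecord(0.0, 0.0), rules).code == "PM2"
        assert frequency_evidence(FrequencyRecord(), rules).code == "PM2"

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            FrequencyRecord(overall_af=-0.1)
        with pytest.raises(ValueError):
            FrequencyRecord(overall_af=0.5, popmax_af=0.1)


def _oracle(codes: frozenset) -> Classification:
    """Independent brute-force statement of the published combining rules."""
    vs = sum(c.startswith("PVS") for c in codes)
    s = sum(c.startswith("PS") for c in codes)
    m = sum(c.startswith("PM") for c in codes)
    p = sum(c.startswith("PP") for c in codes)
    ba = sum(c.startswith("BA") for c in codes)
    bs = sum(c.startswith("BS") for c in codes)
    bp = sum(c.startswith("BP") for c in codes)
    path = None
    if (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2)) or s >= 2 or (
        s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4))
    ):
        path = Classification.PATHOGENIC
    elif (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    ):
        path = Classification.LIKELY_PATHOGENIC
    benign = None
    if ba >= 1 or bs >= 2:
        benign = Classification.BENIGN
    elif (bs >= 1 and bp >= 1) or bp >= 2:
        benign = Classification.LIKELY_BENIGN
    if path and benign:
        return Classification.CONFLICT
    if (vs + s >= 1) and (ba + bs >= 1):
        return Classification.CONFLICT
    return path or benign or Classification.VUS


class TestCombine:
    @pytest.mark.parametrize(
        "codes, verdict",
        [
            (["PVS1", "PM2"], Classification.LIKELY_PATHOGENIC),
            ([], Classification.VUS),
            (["BA1"], Classification.BENIGN),
            (["BS1", "PS3"], Classification.CONFLICT),
            (["PVS1", "PS1"], Classification.PATHOGENIC),
            (["PM1", "PM2", "PM5"], Classification.LIKELY_PATHOGENIC),
            (["BS1", "BP4"], Classification.LIKELY_BENIGN),
        ],
    )
    def test_rule_table_lookups(self, codes, verdict, rules):
        assert combine(E("v", codes), rules) is verdict

    def test_permutation_invariant(self, rules):
        codes = ["PS3", "PM2", "PP3"]
        verdicts = {
            combine(E("v", perm), rules) for perm in itertools.permutations(codes)
        }
        assert len(verdicts) == 1

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            EvidenceCode("PX9")

    def test_exhaustive_small_instance_oracle_agreement(self, rules):
        """combine agrees with an independently written evaluation of the
        combining rules on every evidence set of <= 3 codes."""
        alphabet = ["PVS1", "PS3", "PM2", "PP3", "BA1", "BS1", "BP4"]
        for k in range(4):
            for subset in itertools.combinations(alphabet, k):
                got = combine(E("v", subset), rules)
                assert got is _oracle(frozenset(subset)), subset

    def test_pathogenic_evidence_never_moves_verdict_toward_benign(self, rules):
        """Monotonicity: adding pathogenic-side evidence cannot demote the
        verdict (Conflict excluded from the ordering)."""
        order = {
            Classification.BENIGN: 0,
            Classification.LIKELY_BENIGN: 1,
            Classification.VUS: 2,
            Classification.LIKELY_PATHOGENIC: 3,
            Classification.PATHOGENIC: 4,
        }
        alphabet = ["PVS1", "PS3", "PM2", "PP3"]
        base_sets = [
            [], ["PM2"], ["PP3"], ["PM2", "PP3"], ["PS3"], ["PS3", "PM2"],
        ]
        for base in base_sets:
            before = combine(E("v", base), rules)
            for extra in alphabet:
                if extra in base:
                    continue
                after = combine(E("v", base + [extra]), rules)
                if before in order and after in order:
                    assert order[after] >= order[before], (base, extra)


class TestClassifyTable:
    def test_distribution_is_a_partition(self, rules):
        sets = [
            E("a", ["PVS1", "PS1"]),
            E("b", ["PVS1", "PM2"]),
            E("c", []),
            E("d", ["BA1"]),
            E("e", ["BS1", "PS3"]),
        ]
        df = classify_table(sets, rules)
        summary = df.attrs["summary"]
        assert summary["n"] == 5
        assert sum(summary["counts"].values()) == 5
        assert df.loc[df.variant_key == "b", "classification"].item() == "Likely Pathogenic"

    def test_single_variant_no_evidence_is_vus(self, rules):
        df = classify_table([E("only", [])], rules)
        assert df.attrs["summary"]["counts"] == {"VUS": 1}


class TestCompareClassificationSets:
    def test_overlap_report_fields_sum(self):
        a = {f"v{i}" for i in range(85)}
        b = {f"v{i}" for i in range(29)} | {f"x{i}" for i in range(3)}
        report = compare_classification_sets(a, b)
        assert report["shared"] == 29
        assert report["only_a"] == 56
        assert report["n_a"] == report["shared"] + report["only_a"]

    def test_identical_sets(self):
        report = compare_classification_sets({"k1", "k2"}, {"k1", "k2"})
        assert report["ratio"] == 1.0
        assert report["only_a"] == report["only_b"] == 0

    def test_empty_reference_flagged(self):
        report = compare_classification_sets({"k1"}, set())
        assert report["ratio"] is None and report["ratio_undefined"]


class TestFixtureCallColumn:
    def test_curated_call_distribution(self, variants):
        """The curated ACMG Call column carries 55 pathogenic, 24 likely
        pathogenic, 26 VUS, 2 benign and 2 conflicting calls."""
        from collections import Counter

        calls = Counter(v.acmg_call for v in variants)
        assert calls == {
            "Pathogenic": 55,
            "Likely Pathogenic": 24,
            "VUS": 26,
            "Benign": 2,
            "Conflict": 2,
        }

    def test_text_described_evidence_reproduces_curated_calls(self, rules, variants):
        """The four variants whose evidence the study describes combine to
        their curated verdicts: the two common polymorphisms with opposing
        functional data give Conflict, the two others Benign."""
        spot = {
            "c.2320C>T": (["BA1", "PS3"], "Conflict"),        # p.Arg774Cys
            "c.1831C>G": (["BS1", "BP4", "PS3"], "Conflict"),  # p.Leu611Val
            "c.2002G>A": (["BS1", "BS3"], "Benign"),           # p.Glu668Lys
            "c.2462G>A": (["BA1", "BS1"], "Benign"),           # p.Arg821His
        }
        curated = {v.key: v.acmg_call for v in variants}
        for key, (codes, expected) in spot.items():
            assert combine(E(key, codes), rules).value == expected
            assert curated[key] == expected
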