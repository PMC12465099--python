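"""ACMG/AMP-style evidence combination for variant classification.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic side; BA1,
BS1-4, BP1-7 on the benign side) carry a strength class derived from their
prefix. A configurable rule table (see ``data/acmg_rules.yaml``) combines
per-strength counts into the five-tier verdict; when evidence combinations
— or, by default, strong-or-stronger codes — fire on both sides the verdict
is ``Conflict``. With no firing combination the verdict is VUS.

Population-frequency evidence is assigned by thresholds: at or above the
stand-alone threshold (default 5%) a variant is too common to cause a rare
recessive disease (BA1); above 1% it is suspiciously common (BS1); at or
below 0.01% (or absent) it is rare enough to support pathogenicity (PM2).
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

__all__ = [
    "EvidenceCode",
    "EvidenceSet",
    "Classification",
    "FrequencyRecord",
    "StrengthClass",
    "load_rules",
    "default_rules",
    "frequency_evidence",
    "combine",
    "classify_table",
    "compare_classification_sets",
]

_CODE_RE = re.compile(r"^(PVS1|PS[1-4]|PM[1-6]|PP[1-5]|BA1|BS[1-4]|BP[1-7])$")


class StrengthClass(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE_BENIGN = "stand_alone_benign"
    STRONG_BENIGN = "strong_benign"
    SUPPORTING_BENIGN = "supporting_benign"


_PREFIX_STRENGTH = {
    "PVS": StrengthClass.VERY_STRONG,
    "PS": StrengthClass.STRONG,
    "PM": StrengthClass.MODERATE,
    "PP": StrengthClass.SUPPORTING,
    "BA": StrengthClass.STAND_ALONE_BENIGN,
    "BS": StrengthClass.STRONG_BENIGN,
    "BP": StrengthClass.SUPPORTING_BENIGN,
}

_PATHOGENIC_SIDE = {
    StrengthClass.VERY_STRONG,
    StrengthClass.STRONG,
    StrengthClass.MODERATE,
    StrengthClass.SUPPORTING,
}


class Classification(str, Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely Pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "Likely Benign"
    BENIGN = "Benign"
    CONFLICT = "Conflict"


@dataclass(frozen=True)
class EvidenceCode:
    code: str
    strength_class: StrengthClass = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise ValueError(f"unknown ACMG evidence code {self.code!r}")
        if self.strength_class is None:
            prefix = self.code[:3] if self.code.startswith("PVS") else self.code[:2]
            object.__setattr__(self, "strength_class", _PREFIX_STRENGTH[prefix])


@dataclass(frozen=True)
class EvidenceSet:
    variant_key: str
    codes: frozenset[EvidenceCode] = frozenset()
    provenance: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_codes(cls, variant_key: str, codes: Iterable[str], **prov: str) -> "EvidenceSet":
        return cls(variant_key, frozenset(EvidenceCode(c) for c in codes), prov)


@dataclass(frozen=True)
class FrequencyRecord:
    overall_af: Optional[float] = None
    popmax_af: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        for f in (self.overall_af, self.popmax_af):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency {f} outside [0, 1]")
        if (
            self.overall_af is not None
            and self.popmax_af is not None
            and self.popmax_af < self.overall_af
        ):
            raise ValueError("popmax frequency below overall frequency")


@dataclass(frozen=True)
class RuleConfig:
    pathogenic_rules: tuple[tuple[Classification, Mapping[str, int]], ...]
    benign_rules: tuple[tuple[Classification, Mapping[str, int]], ...]
    strength_overrides: Mapping[str, StrengthClass]
    ba1: float
    bs1: float
    pm2: float
    frequency_mode: str
    conflict_on_strong_both_sides: bool


def load_rules(source: Union[str, Path, dict, None] = None) -> RuleConfig:
    if source is None:
        cfg = yaml.safe_load(
            resources.files("enpp1db.data").joinpath("acmg_rules.yaml").read_text()
        )
    elif isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = source

    def rules(key):
        return tuple(
            (Classification(r["verdict"]), dict(r["requires"])) for r in cfg.get(key, [])
        )

    thr = cfg.get("frequency_thresholds", {})
    return RuleConfig(
        pathogenic_rules=rules("pathogenic_rules"),
        benign_rules=rules("benign_rules"),
        strength_overrides={
            k: StrengthClass(v) for k, v in (cfg.get("strength_overrides") or {}).items()
        },
        ba1=float(thr.get("ba1", 0.05)),
        bs1=float(thr.get("bs1", 0.01)),
        pm2=float(thr.get("pm2", 1e-4)),
        frequency_mode=str(thr.get("mode", "popmax")),
        conflict_on_strong_both_sides=bool(cfg.get("conflict_on_strong_both_sides", True)),
    )


_DEFAULT: Optional[RuleConfig] = None


def default_rules() -> RuleConfig:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_rules()
    return _DEFAULT


def frequency_evidence(
    f: FrequencyRecord, rules: Optional[RuleConfig] = None
) -> Optional[EvidenceCode]:
    """Population-frequency evidence: BA1 / BS1 / PM2 / None by thresholds."""
    rules = rules or default_rules()
    af = f.popmax_af if rules.frequency_mode == "popmax" else f.overall_af
    if af is None:  # fall back to whichever field is present
        af = f.overall_af if f.overall_af is not None else f.popmax_af
    if af is None:
        return EvidenceCode("PM2")  # absent from population databases
    if af >= rules.ba1:
        return EvidenceCode("BA1")
    if af >= rules.bs1:
        return EvidenceCode("BS1")
    if af <= rules.pm2:
        return EvidenceCode("PM2")
    return None


def _strength_counts(e: EvidenceSet, rules: RuleConfig) -> Counter:
    counts: Counter = Counter()
    for code in e.codes:
        strength = rules.strength_overrides.get(code.code, code.strength_class)
        counts[strength.value] += 1
    return counts


def _first_match(counts, table):
    for verdict, req in table:
        if all(counts.get(cls, 0) >= n for cls, n in req.items()):
            return verdict
    return None


def combine(e: EvidenceSet, rules: Optional[RuleConfig] = None) -> Classification:
    """Combine an evidence set into a five-tier verdict (plus Conflict).

    Pure in (codes, config); the order codes were collected in never
    matters.
    """
    rules = rules or default_rules()
    counts = _strength_counts(e, rules)
    pathogenic = _first_match(counts, rules.pathogenic_rules)
    benign = _first_match(counts, rules.benign_rules)
    if pathogenic and benign:
        return Classification.CONFLICT
    if rules.conflict_on_strong_both_sides:
        strong_path = counts["very_strong"] + counts["strong"]
        strong_benign = counts["stand_alone_benign"] + counts["strong_benign"]
        if strong_path >= 1 and strong_benign >= 1:
            return Classification.CONFLICT
    if pathogenic:
        return pathogenic
    if benign:
        return benign
    return Classification.VUS


def classify_table(
    evidence: Iterable[EvidenceSet], rules: Optional[RuleConfig] = None
) -> "pd.DataFrame":
    """Per-variant verdicts plus a class-count summary.

    Returns a DataFrame (variant_key, classification) with a
    ``.attrs["summary"]`` dict of counts and fractions per class.
    """
    import pandas as pd

    rules = rules or default_rules()
    rows = [(e.variant_key, combine(e, rules).value) for e in evidence]
    df = pd.DataFrame(rows, columns=["variant_key", "classification"])
    n = len(df)
    counts = df["classification"].value_counts().to_dict()
    df.attrs["summary"] = {
        "n": n,
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()} if n else {},
    }
    return df


def compare_classification_sets(
    a: Iterable[str], b: Iterable[str]
) -> dict:
    """Overlap report between two pathogenic/likely-pathogenic key sets.

    ``ratio`` is |a|/|b|, ``None`` (with ``ratio_undefined``) when b is
    empty.
    """
    sa, sb = set(a), set(b)
    shared = sa & sb
    report = {
        "n_a": len(sa),
        "n_b": len(sb),
        "shared": len(shared),
        "only_a": len(sa - sb),
        "only_b": len(sb - sa),
        "ratio": (len(sa) / len(sb)) if sb else None,
        "ratio_undefined": not sb,
    }
    assert report["n_a"] == report["shared"] + report["only_a"]
    return report
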