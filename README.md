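# enpp1db

Curation and genotype–phenotype analytics for an **ENPP1 locus-specific
database (LSDB)**.

Loss-of-function variants in *ENPP1* cause ENPP1 Deficiency — generalized
arterial calcification of infancy (GACI) in neonates, autosomal recessive
hypophosphatemic rickets type 2 (ARHR2) in survivors and later-onset
patients. Because most *ENPP1* variants are private (seen in one family),
interpreting a new variant requires pooling every published case with
natural-history-study data into a curated registry. `enpp1db` implements
that registry's computational layer:

- an **HGVS parser/normalizer** covering the dialect found in curated
  variant tables: coding/genomic/protein descriptions, intronic offsets
  (`c.2444+702`), UTR anchors (`c.-24`, `c.*868`), uncertain breakpoints
  (`c.(1091+1_1092-1)_(1164+1_1165-1)del`), unknown inserted bases
  (`delinsN[7]`), in-cis allele lists (`c.[x;y]`) and phase-unknown pairs
  (`x(;)y`), with unicode-dash folding and deterministic canonical keys;
- a **gene model** mapping CDS positions to codons (`residue =
  ⌈anchor/3⌉`) and residues to the ENPP1 domain architecture
  (cytoplasmic 1–76, transmembrane 77–97, SMB1 104–144, SMB2 145–188,
  phosphodiesterase 191–591, nuclease-like 654–925, linkers between);
- **consequence classification** (missense / nonsense / frameshift /
  splice / deletion / UTR / whole gene) with protein annotation taking
  precedence over the cDNA edit, and a **truncating vs nontruncating**
  rule for genotype stratification;
- an **ACMG/AMP evidence engine**: coded evidence (PVS1…BP7), allele-
  frequency thresholds (BA1 ≥ 5%, BS1 ≥ 1%, PM2 ≤ 0.01%), a configurable
  combining-rule table, and a `Conflict` verdict when strong evidence
  fires on both sides;
- **cohort analytics** over the packaged curated tables — 154 patients /
  109 unique variants, transcribed in full — computing zygosity, unique
  genotypes, carrier/allele counts, domain occupancy, diagnosis splits,
  truncating stratification, missense burden, provenance, and an advisory
  consistency report;
- a **seeded synthetic-cohort generator** emulating the LSDB's structure
  (heavy private-variant tail, genotype mixture, phenotype prevalences,
  per-stratum survival) for testing every analytics stage at scale.

## Worked example

```python
from collections import Counter
from enpp1db import load_table1, load_table2, enpp1_model, zygosity_of
from enpp1db.cohort import unique_genotypes, truncating_stratification

patients, variants, model = load_table1(), load_table2(), enpp1_model()
print(len(patients), "patients,", len(variants), "unique variants")
print("unique genotypes:", unique_genotypes(patients)[0])
print(Counter(zygosity_of(p).zygosity for p in patients))
print(truncating_stratification(patients, variants, model).loc["total"].to_dict())
```

prints

```
154 patients, 109 unique variants
unique genotypes: 108
Counter({'compound_heterozygous': 81, 'homozygous': 62, 'heterozygous': 11})
{'two_truncating': 24, 'mixed': 35, 'two_nontruncating': 84, 'het_truncating': 3, 'het_nontruncating': 8}
```

i.e. 40.3% of patients are homozygous, 52.6% compound heterozygous and
7.1% carry a single identified variant; stratifying each genotype by its
number of truncating variants gives the 24 / 35 / 84 / 3 / 8 split of the
total population. The same objects drive the per-variant statistics (the
recurrent p.Pro305Thr allele: 24 carriers, 33 alleles) and the domain
occupancy (58 of 109 unique variants — 178 of 310 allele occurrences — in
the phosphodiesterase domain).

A command-line interface wraps the same functions:

```bash
enpp1db parse <<< "c.913C>A"          # JSON-lines parse records
enpp1db annotate --variants V.tsv     # + computed type/domain/truncating
enpp1db classify --evidence ev.json   # ACMG verdicts from evidence codes
enpp1db summarize --patients P.tsv --variants V.tsv --out report/
enpp1db simulate --seed 7 --out sim/  # synthetic cohort + ground truth
```

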