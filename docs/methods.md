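# Methods

## Scope and data model

The package models a locus-specific database for *ENPP1* as two tables.
The *patient table* holds one row per patient: two allele cells in HGVS
cDNA + protein notation (allele 2 may be `Not identified`), pipe-separated
diagnosis labels, an age-of-onset category, provenance (literature and/or
natural-history studies), PMIDs, and optional phenotype/survival extension
columns. The *variant table* holds one row per unique variant: gDNA, cDNA
and protein HGVS, consequence type, exon/intron annotation, protein
domain, ACMG call, and the recurrence of the allele across the cohort.
The curated 154-patient / 109-variant ENPP1 tables ship with the package
as TSV fixtures and are the reference dataset for all fixture tests.

## HGVS handling

Descriptions are normalized *syntactically only*: unicode dash variants
(hyphen U+2010, minus U+2212, en dash) fold to ASCII `-`, whitespace is
stripped, and accession prefixes are split into a `reference` field. No
reference sequence is bundled, so no 3'-shifting or ref-base validation is
performed; curated tables are treated as already HGVS-conformant, and the
canonical key emitted by `normalize` is the re-formatted description
(e.g. `c.913C>A`). Design choices forced by the published dialect:

- coordinates are 1-based fully closed intervals; intronic positions are
  (anchor, signed offset) pairs, never absolute transcript positions;
- `delinsN[k]` (unknown inserted bases) is a first-class edit kind;
- uncertain breakpoints `(x_y)` keep both bounds; the genomic spelling
  `(?-X)`/`(Y-?)` with a dash separator is accepted on input (genomic
  positions carry no offsets, so it is unambiguous) and emitted with `_`;
- phase-unknown pairs `x(;)y` stay one `AlleleDescription` with
  `phase="unknown"`, matching the one-cell table layout; downstream
  zygosity logic treats the patient as carrying both variants with
  unresolved phase;
- a coding deletion running from a 5'UTR anchor through a 3'UTR anchor is
  a whole-gene deletion.

The genomic column mixes two coordinate scales (~131.8 Mb for most rows,
~132.18 Mb for a few large deletions); the parser accepts both and no
reconciliation is attempted.

## Gene model

`protein_length` is 925 residues; CDS length 2778 nt (925 codons + stop).
Codon arithmetic is `residue = ceil(anchor / 3)`; intronic positions use
their exonic anchor, and for ranges the 5'-most defined CDS anchor decides
— this single rule reproduces the curated domain assignment of every
splice, intronic and multi-exon-deletion row. Domain boundaries follow the
published architecture; the two linkers (189–190 and 592–653) are pinned
by the curated assignments of Trp190 ("Linker 1") and Leu611 ("Linker 2"),
and residues 98–103 form an unnamed intervening region (no curated variant
maps there). The model is data-driven (YAML/JSON config); the exon map is
optional because exon boundaries are not printed in the source tables —
the Exon/Intron column is carried as annotation and only checked by the
advisory consistency report.

## Consequence typing and the truncating rule

Protein-level annotation outranks the cDNA edit kind when informative:
`p.Leu97*` from a 1-bp deletion is *nonsense*, `fs*N` is *frameshift*,
`p.X#del` is *deletion*. `p.?` variants fall back to cDNA logic:
substitutions at offsets ±1/±2 are *splice*; a replacement confined to a
single intron edge touching ±1/±2 is *splice* (`c.2230+1_2230+3delinsCACC`),
while replacements whose breakpoints sit in different introns remove whole
exons and type as *deletion* (`c.1026-281_1164+1delinsN[7]`); 5'UTR-only
edits are *UTR*; all remaining deletions/duplications are *deletion*, with
*whole gene* for locus-spanning loss. This reproduces the curated Type
column for all 109 rows.

Truncating status is purely type-driven: nonsense, frameshift, splice and
every deletion-class variant (including whole-gene loss) are truncating;
missense and UTR are not. Two edge cases deserve note: the in-frame
single-residue deletion (p.Tyr252del) and the intron-internal deletion
(`c.1026-59_1026-10del`, which does not touch the ±1/±2 positions) both
count as *truncating* under this rule. A biologically motivated
alternative (counting them nontruncating) was evaluated and rejected: the
published genotype-stratified survival totals (24 / 35 / 84 / 3 / 8) are
reproduced only by the type-driven rule, verified by brute-force
re-stratification of all 154 genotypes. An allele carrying any truncating
variant in cis counts as truncating; a patient's stratum is the count of
truncating alleles (heterozygous patients form their own two strata).

"Two missense variants" is defined as: both alleles identified and every
variant on both alleles is missense. The weaker reading (each allele
carries ≥1 missense) over-counts by one — a patient with a splice+missense
in-cis allele — relative to the published 84/154.

## ACMG engine

Evidence codes derive their strength class from their prefix (PVS1 very
strong … BP supporting-benign), overridable per config. The combining
table (shipped as `data/acmg_rules.yaml`, editable) encodes the consensus
combinations with ≥ semantics, evaluated strongest-verdict-first on each
side. Verdict logic: if combinations fire on both sides, or (by default)
at least one strong-or-stronger code is present on each side, the verdict
is `Conflict`; otherwise the firing side wins; otherwise VUS. Frequency
evidence uses thresholds BA1 ≥ 0.05, BS1 ≥ 0.01, PM2 ≤ 1e-4 (or absent),
with a config switch between overall and population-maximum frequency
(default popmax — the treatment of the common p.Arg774Cys polymorphism,
3.3% overall but 9.7% in Finns, implies popmax-aware reasoning).

Per-variant evidence is not printed in the source tables, so the curated
ACMG Call column serves as a fixture consumed by the cohort layer, and the
engine is validated two ways: an exhaustive small-instance oracle (every
evidence set of ≤3 codes over a 7-code alphabet, against an independently
written rule evaluation) and spot checks of the four variants whose
evidence the source text describes (two common polymorphisms with
opposing functional data → `Conflict`; two others → `Benign`).

## Cohort analytics

Genotype keys are unordered pairs of allele keys (sorted normalized
variant keys), so allele order never matters; zygosity is homozygous when
both identified allele keys are equal, heterozygous when exactly one
allele is identified. Diagnosis splits map the label `HR`
(hypophosphatemic rickets) onto the ARHR2 group — the assignment that
reproduces the published 99/29/26 GACI/ARHR2/both split; the mapping is
config. Patients carrying an additional *ABCC6* variant stay in all
*ENPP1* statistics, but the *ABCC6* variant never enters allele counts.
Percentages are display-only; every assertion compares integer counts.

The advisory consistency report recomputes the recurrence, type and domain
columns and surfaces bookkeeping totals: the recurrence column sums to
310 variant occurrences across 297 identified alleles (multi-variant
in-cis alleles contribute one occurrence per variant), a discrepancy with
the source text's own "308 alleles" that is reported, never asserted.
The report also lists duplicate-genotype patient pairs sharing a PMID as
dedup candidates for newly merged data; mismatches never abort an
analysis.

## Synthetic cohorts

The generator emulates the LSDB's statistical structure; its defaults are
the curated cohort's printed proportions (154 patients, 109-variant pool,
69.7% private variants, zygosity 40.3/52.6/7.1, diagnosis 64.3/18.8/16.9,
onset mix as observed, phenotype prevalences per diagnosis group, death
probabilities per truncating stratum with 7/154 unknown outcomes).
Variants are synthesized on a toy 300-codon transcript with a scaled
domain map so parsing, typing, domain assignment and stratification all
run without the real gene model. The private tail is *constructed*, not
sampled: exactly `round(private_fraction × pool)` variants receive a
single patient, the others at least two, with the remaining allele draws
split by a heavy-tailed (Pareto-weighted) multinomial to emulate recurrent
hotspots; compound-heterozygous draws of the same variant are repaired by
swapping draws between patients, keeping every recurrence count intact.
Infeasible requests (too few allele draws to cover the pool) raise with an
explanation. All randomness flows from one `numpy` Generator seeded from
`spec.seed`; equal seeds give byte-identical tables.

What the generator does **not** emulate: family/linkage structure (so
"private" means single *patient*, whereas the curated 76/109 counts single
*families*), sequencing error, evidence-level ACMG inputs (calls are drawn
from the configured mix), and any biological mechanism. Passing recovery
tests therefore show that the analytics recover known generative
parameters, not that real cohorts share that generative process.
Phenotype and survival columns are always emitted synthetically — the
curated tables lack them, so prevalence and survival operations are tested
on synthetic data only.

## Numerical and testing choices

Fixture tests assert exact integer counts (the complete tables are
printed, so every headline statistic is exactly recomputable). Parameter
recovery uses one 5000-patient cohort per seed and 95% binomial intervals.
The acceptance script (`scripts/acceptance.py --seed K --out f.json`)
recomputes all headline quantities from the packaged tables at run time
plus a seeded synthetic recovery; the whole suite runs in a few seconds on
one CPU.
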