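# Methods

## Scope and data model

The package reproduces a Sanger-era two-locus deafness screen as a
pipeline over three locus references: the *GJB2* coding sequence (678 nt,
coordinates `c.1`–`c.678`), the *GJB2* exon-1/basal-promoter amplicon
(screened, expected variant-free), and the mitochondrial *12S rRNA* region
(`m.601`–`m.1620`). Subjects carry two allele sequences at the nuclear
locus and one homoplasmic sequence at the mitochondrial locus; the single
historically "both"-plasmy panel entries are treated as homoplasmic
throughout.

The embedded catalogue defines 15 *GJB2* and 30 12S variants with their
category (pathogenic / polymorphism / unknown / novel), protein-domain and
amino-acid annotation and in-silico scores, plus the study's count tables:
per-variant carriers, genotype strata, genotype–phenotype composition and
the mtDNA panel with per-position conservation. Fixture headers document
every place where the published tables disagree internally and which value
the fixture follows; in short, case-side genotype strata follow the
genotype/phenotype tables (whose pathogenic strata sum to the published
70 + 79 + 15), control-side strata are reconciled so that the derived
control carrier count equals the carrier table for every variant, and the
three case-side polymorphism counts that cannot be reconciled
(c.341A>G, c.368C>A, c.608T>C) keep both readings, with the genotype-table
reading driving cohort generation.

## Synthetic references and cohort generator

Real accessions are deliberately not used. Each reference is a fixed
random sequence with the catalogued wild-type base planted at every
catalogued position, and with indel contexts constrained so each
catalogued indel is already left-aligned (the base before a deletion
differs from its last deleted base; the base at an insertion anchor
differs from the last inserted base). This makes planted variants
round-trip to exactly their catalogued names, which is the property the
references exist to support. The generation script
(`scripts/make_references.py`) is versioned with its outputs.

The cohort generator is the package's model of the study conditions, not a
tuning knob: group sizes (658 / 462), genotype strata, mtDNA carrier
counts and the per-stratum severity/onset composition all come from the
embedded tables. Audiograms are four integer thresholds constructed so
their mean is an integer PTA drawn uniformly within the stratum's severity
band (moderate 41–60 dB, severe 61–80, profound 81–110; controls 5–20);
onset labels are assigned to match each stratum's published composition.
Carrier sets are drawn with a seeded generator under three disjointness
constraints: (i) *GJB2*-pathogenic genotypes, `m.1555A>G` and `m.1494C>T`
carriers never overlap — the published combined carrier rate
(164 + 39 + 4)/658 presumes disjoint sets; (ii) the three position-961
spellings occupy different subjects; (iii) `m.1040T>C` and `m.1041A>G`
never co-occur, since adjacent substitutions in one genome would merge
into a single two-base substitution call. All other mtDNA carrier sets
may overlap freely. Sequencing error, chromatograms and heteroplasmy
mixtures are deliberately not simulated: the generator tests the analysis
chain, not base-calling, so a green suite says nothing about noisy-trace
robustness.

## Variant calling

Global alignment is Needleman–Wunsch with linear gap penalties (match +1,
mismatch −1, gap −2 per base; the original screen compared traces
visually, so the scoring is this package's choice — the defaults make a
substitution strictly cheaper than a gap pair and behave well at the
indel sizes in the catalogue, 1–46 nt). The row recurrence is vectorized;
the within-row dependency of linear gaps is resolved exactly with a
running-maximum prefix scan.

Traceback is deterministic: diagonal > up (gap in reference) > left (gap
in query) at ties, except that while walking through a gap run the run is
extended first. The exception matters: under linear penalties a long
deletion split into two runs separated by a coincidentally matching base
scores identically to the contiguous run, and a purely diagonal-first
tie-break fragments planted 16- and 46-nt indels. Gap-run coherence keeps
one maximal run, and left-normalization then shifts it to the left-most
equivalent placement (legacy names are left-anchored, unlike HGVS
3'-rules). Normalization is idempotent and verified by a re-apply oracle.

Naming policy, chosen to reproduce every catalogued spelling
simultaneously: substitutions `c.{pos}{ref}>{alt}` (multi-base runs spell
both runs); deletions spell the bases up to 2 nt (`delC`, `delAT`) and the
length above (`del16`); insertions spell up to 4 nt (`insAAGG`) and the
length above (`ins46`). One catalogue entry, `m.961delT+insC`, is the
historic spelling of the same molecular edit as `m.961T>C`; it is stored
as a substitution-equivalent with an `equivalent_to` link, and callers
recover the canonical spelling. Tallies merge the two spellings; every
downstream figure involving position 961 uses their sum (18 carriers), so
the merge is observationally neutral.

Ambiguous columns (N in the query) are excluded from calling with a
warning rather than guessed.

## Statistics

Carrier frequency counts subjects, not alleles (the published 102/658 for
c.235delC is a subject count), and is rounded half-up to 2 dp — the only
rounding rule that reproduces every published percentage (e.g. 70/658 →
10.64 requires rounding half-up; truncation would give 10.63). One
published figure, 23.70% for the four-deletion aggregate 156/658, is a
rounding slip in the source (156/658 = 23.708% → 23.71 under the same
rule); the package reports the computed 23.71. The combined
deafness-mutation rate is the size of the subject-level union of
*GJB2*-pathogenic carriers with `m.1555A>G` and `m.1494C>T` carriers.

PTA is the arithmetic mean over 0.5/1/2/4 kHz in the better ear; severity
bands are ≤ 25 normal (boundary at the real-valued PTA: 25.9 is still
normal), 26–40 mild, 41–60 moderate, 61–80 severe, > 80 profound.
Non-integer PTA classifies on the real line (40.5 → moderate).

## Conservation index and triage

The CI denominator is 22 and includes the human reference, which
therefore always contributes one match — this is the only reading that
makes the panel's printed x/22 values consistent with "comparison against
21 other primates". Gaps count as non-matches; CI is invariant under row
order. Rounding is half-up to 1 dp. Bin boundaries: high strictly > 78%,
mid [50%, 78%] inclusive at both ends, low < 50% — the only reading under
which 77.3% rows are mid and the 50.0% row keeps the mid bin at 8 of the
30 panel values (15 high / 8 mid / 7 low). The 78% threshold is a config
value, not a law of nature.

Triage priority is explicit because the rules overlap: the catalogued
known-pathogenic set wins over the control-presence rule (so `m.1095T>C`,
with one control carrier, and the position-961 variants keep their
literature labels), control presence wins over high conservation (nine
highly conserved variants are nonetheless polymorphisms), and the
putative class requires both control absence and CI > 78%. Exactly one
rule fires per variant and is reported.

The synthetic ortholog alignment used by the pipeline honours the panel's
per-position conservation exactly (non-matching species draw uniformly
from the three alternative bases; gaps are not generated by default — gap
handling is tested on toy alignments). It emulates column-wise
conservation only, not phylogenetic correlation between columns or
species.

## RNA secondary structure

Folding is Nussinov-style base-pair maximization over Watson–Crick and
G·U pairs, minimum hairpin loop 3, deterministic traceback (prefer
leaving the 5' base unpaired, then the smallest partner). This is a
coarse stand-in for thermodynamic folding: it supports the property
claimed — a variant can change the predicted pairing near its position,
quantified as base-pair distance (symmetric difference of pair sets,
a metric on equal-length structures) — and explicitly does not reproduce
any particular published full-length fold. The pipeline folds a ±60 nt
window around the variant (O(n³) in pure Python; 121 nt folds in
milliseconds, and the local window is the scientifically relevant
object for a point variant).

## Problem sizes and determinism

The standard run processes the full cohort: 1,120 subjects, 4,480
sequences, with identical sequences called once (memoized), completing in
a few seconds on one CPU. All randomness flows from a single integer seed
through `numpy.random.default_rng`; the same seed yields byte-identical
FASTA output. Because every count in the cohort specification is exact,
the headline figures are identical across seeds — the seed only permutes
which synthetic subject carries what.

## Known limitations

- No base-quality model, no heteroplasmy fractions, no trio phasing
  (phase is taken from the two input allele sequences).
- The minimal VCF writer covers SNV/MNV and simple anchored indels at the
  two toy contigs only; it is an interchange convenience, not a general
  VCF library.
- Conservation and triage consume the panel's carrier counts; the
  pipeline does not re-estimate mtDB/population frequencies.
- The aligner is linear-gap; at much larger indel sizes or repetitive
  references an affine-gap model would be preferable.
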