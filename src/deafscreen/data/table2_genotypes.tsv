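# GJB2 genotype strata in cases (N=658) and controls (N=462).
# allele1/allele2 list the variant names on each allele ("+"-joined when an
# allele carries more than one variant, "-" for a wild-type allele).
# Subjects not covered by any stratum are wild-type at both alleles.
#
# Resolutions applied where the published tables disagree internally
# (genotype strata reconciled against the per-variant carrier-count table):
#   - control c.109G>A heterozygotes set to 4 (genotype table printed 3;
#     carrier-count table and the stated control total of 11 pathogenic
#     carriers both require 4)
#   - control strata for the polymorphism/unknown variants adjusted so the
#     derived control carrier counts equal the carrier-count table for every
#     variant: c.79G>A het 51 (printed 28), c.79G>A/c.368C>A controls 0
#     (printed 3), plus c.341A>G het (7) and c.608T>C het (1) strata the
#     genotype table omitted
#   - the typographically garbled triple-variant stratum follows the
#     genotype-phenotype table: c.341A>G / c.341A>G+c.79G>A, 2 cases
# Case strata are kept exactly as printed in the genotype and
# genotype-phenotype tables; for cases the derived carrier counts of
# c.341A>G, c.368C>A and c.608T>C therefore differ from the per-variant
# table (16 vs 25, 12 vs 5, 4 vs 2) - an irreconcilable conflict in the
# source tables.
allele1	allele2	case_count	control_count
c.35delG	-	1	0
c.109G>A	-	7	4
c.176del16	-	6	2
c.235delC	-	40	3
c.299delAT	-	12	2
c.504insAAGG	-	2	0
c.608TC>AA	-	2	0
c.35delG	c.235delC	1	0
c.109G>A	c.109G>A	8	0
c.176del16	c.176del16	7	0
c.176del16	c.235delC	5	0
c.176del16	c.299delAT	3	0
c.235delC	c.235delC	52	0
c.235delC	c.299delAT	4	0
c.257C>G	c.605ins46	2	0
c.299delAT	c.299delAT	12	0
c.79G>A	-	64	51
c.101T>C	-	3	1
c.79G>A	c.79G>A	49	13
c.79G>A	c.341A>G	9	1
c.341A>G	c.341A>G	5	1
c.341A>G	c.341A>G+c.79G>A	2	0
c.79G>A	c.368C>A	11	0
c.608T>C	c.608T>C	4	0
c.368C>A	-	1	1
c.571T>C	-	4	0
c.341A>G	-	0	7
c.608T>C	-	0	1
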