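# GJB2 genotype-phenotype strata for the 658 cases: hearing-severity and
# onset composition of each genotype stratum. The case cohort spans
# moderate to profound loss, so mild counts are structurally zero.
# onset_unknown covers the no-mutation stratum, for which onset was not
# reported.
allele1	allele2	count	moderate	severe	profound	onset_postlingual	onset_prelingual	onset_unknown
c.35delG	c.235delC	1	0	0	1	0	1	0
c.109G>A	c.109G>A	8	2	2	4	2	6	0
c.176del16	c.176del16	7	0	3	4	0	7	0
c.176del16	c.235delC	5	0	1	4	0	5	0
c.176del16	c.299delAT	3	0	0	3	0	3	0
c.235delC	c.235delC	52	1	11	40	0	52	0
c.235delC	c.299delAT	4	0	0	4	0	4	0
c.257C>G	c.605ins46	2	0	0	2	0	2	0
c.299delAT	c.299delAT	12	1	1	10	0	12	0
c.35delG	-	1	0	0	1	0	1	0
c.109G>A	-	7	2	3	2	3	4	0
c.176del16	-	6	0	1	5	0	6	0
c.235delC	-	40	3	8	29	8	32	0
c.299delAT	-	12	1	3	8	0	12	0
c.504insAAGG	-	2	0	1	1	0	2	0
c.608TC>AA	-	2	1	0	1	0	2	0
c.79G>A	-	64	13	22	29	3	61	0
c.101T>C	-	3	1	1	1	1	2	0
c.79G>A	c.79G>A	49	11	15	23	5	44	0
c.79G>A	c.341A>G	9	1	1	7	0	9	0
c.341A>G	c.341A>G	5	2	2	1	0	5	0
c.341A>G	c.341A>G+c.79G>A	2	0	1	1	0	2	0
c.79G>A	c.368C>A	11	1	1	9	0	11	0
c.368C>A	-	1	0	1	0	0	1	0
c.571T>C	-	4	0	2	2	0	4	0
c.608T>C	c.608T>C	4	0	1	3	0	4	0
-	-	342	28	52	262	0	0	342
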