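# Variant definition and annotation catalogue (both loci).
# ref_allele/alt_allele are resolved against the synthetic references.
name	locus	kind	position	ref_allele	alt_allele	category	domain_label	aa_change	previously_reported	polyphen_score	sift_score	equivalent_to
c.35delG	GJB2	deletion	35	G		pathogenic	IC1	Frameshift	yes			
c.79G>A	GJB2	substitution	79	G	A	polymorphism	TM1	Val27Ile	yes	1.000	0.15	
c.101T>C	GJB2	substitution	101	T	C	polymorphism	TM1	Met34Thr	yes	0.038	0.12	
c.109G>A	GJB2	substitution	109	G	A	pathogenic	TM1	Val37Ile	yes	1.000	0.12	
c.176del16	GJB2	deletion	176	CGCGCACGTGGAAGGA		pathogenic	EC1	Frameshift	yes			
c.235delC	GJB2	deletion	235	C		pathogenic	TM2	Frameshift	yes			
c.257C>G	GJB2	substitution	257	C	G	pathogenic	TM2	Thr86Arg	no	1.000	0.00	
c.299delAT	GJB2	deletion	299	AT		pathogenic	IC2	Frameshift	yes			
c.341A>G	GJB2	substitution	341	A	G	polymorphism	IC2	Glu114Gly	yes	0.001	0.27	
c.368C>A	GJB2	substitution	368	C	A	unknown	IC2	Thr123Asn	yes	0.000	0.53	
c.504insAAGG	GJB2	insertion	504		AAGG	pathogenic	EC2	Frameshift	yes			
c.571T>C	GJB2	substitution	571	T	C	unknown	EC2	Phe191Leu	yes	1.000	0.00	
c.605ins46	GJB2	insertion	605		CTTAAAACGTCGACCTGGAAATCCTGTGTCACGTTAAAGGAATGCA	pathogenic	TM4	Stop at aa 202	yes			
c.608TC>AA	GJB2	mnv_substitution	608	TC	AA	pathogenic	TM4	Ile203Lys	yes		0.00	
c.608T>C	GJB2	substitution	608	T	C	polymorphism	TM4	Ile203Thr	yes	0.906	0.00	
m.663A>G	MT12S	substitution	663	A	G	unknown			yes			
m.681T>C	MT12S	substitution	681	T	C	unknown			yes			
m.709G>A	MT12S	substitution	709	G	A	unknown			yes			
m.735A>G	MT12S	substitution	735	A	G	unknown			yes			
m.750A>G	MT12S	substitution	750	A	G	unknown			yes			
m.752C>T	MT12S	substitution	752	C	T	unknown			yes			
m.789T>C	MT12S	substitution	789	T	C	unknown			yes			
m.827A>G	MT12S	substitution	827	A	G	unknown			yes			
m.961insC	MT12S	insertion	961		C	pathogenic			yes			
m.961delT+insC	MT12S	substitution	961	T	C	pathogenic			yes			m.961T>C
m.961T>C	MT12S	substitution	961	T	C	pathogenic			yes			
m.979C>T	MT12S	substitution	979	C	T	unknown			yes			
m.1005T>C	MT12S	substitution	1005	T	C	unknown			yes			
m.1009C>T	MT12S	substitution	1009	C	T	unknown			yes			
m.1040T>C	MT12S	substitution	1040	T	C	unknown			yes			
m.1041A>G	MT12S	substitution	1041	A	G	unknown			yes			
m.1048C>T	MT12S	substitution	1048	C	T	unknown			yes			
m.1095T>C	MT12S	substitution	1095	T	C	pathogenic			yes			
m.1107T>C	MT12S	substitution	1107	T	C	unknown			yes			
m.1119T>C	MT12S	substitution	1119	T	C	unknown			yes			
m.1187T>C	MT12S	substitution	1187	T	C	unknown			yes			
m.1222A>G	MT12S	substitution	1222	A	G	novel			no			
m.1282G>A	MT12S	substitution	1282	G	A	unknown			yes			
m.1382A>C	MT12S	substitution	1382	A	C	unknown			yes			
m.1415G>A	MT12S	substitution	1415	G	A	unknown			yes			
m.1438A>G	MT12S	substitution	1438	A	G	unknown			yes			
m.1494C>T	MT12S	substitution	1494	C	T	pathogenic			yes			
m.1520T>C	MT12S	substitution	1520	T	C	unknown			yes			
m.1555A>G	MT12S	substitution	1555	A	G	pathogenic			yes			
m.1598G>A	MT12S	substitution	1598	G	A	unknown			yes			
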