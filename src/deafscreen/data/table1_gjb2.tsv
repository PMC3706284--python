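# GJB2 variant carrier counts and frequencies in cases (N=658) and
# controls (N=462). Frequencies are percent, half-up rounded to 2 dp.
name	case_carriers	case_freq	control_carriers	control_freq
c.35delG	2	0.30	0	0.00
c.79G>A	135	20.52	65	14.07
c.101T>C	3	0.46	1	0.22
c.109G>A	15	2.28	4	0.87
c.176del16	21	3.19	2	0.43
c.235delC	102	15.50	3	0.65
c.257C>G	2	0.30	0	0.00
c.299delAT	31	4.71	2	0.43
c.341A>G	25	3.80	9	1.95
c.368C>A	5	0.76	1	0.22
c.504insAAGG	2	0.30	0	0.00
c.571T>C	4	0.61	0	0.00
c.605ins46	2	0.30	0	0.00
c.608TC>AA	2	0.30	0	0.00
c.608T>C	2	0.30	1	0.22
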