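# STRING-derived ANK3 protein-interaction partners with high-confidence
# scores (>= 0.7). The two X-linked entries (L1CAM, DMD) carry synthetic
# nominal scores above the threshold: the source ranking prints no score
# for them, only that they cleared it before being excluded as non-autosomal.
gene	chrom	score
NFASC	1	0.984
SPTBN4	19	0.964
SCN2A	2	0.941
COL17A1	10	0.857
ARHGEF7	13	0.833
CACNA1C	12	0.819
L1CAM	X	0.800
NRCAM	7	0.766
KCNQ2	20	0.754
DMD	X	0.750
SPTA1	1	0.735
SCN5A	3	0.726
KCNQ3	8	0.720
SPTB	14	0.719
SCN8A	12	0.716
FADD	11	0.716
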