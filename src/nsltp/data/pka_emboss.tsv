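# EMBOSS-style pKa values for ionizable groups; sign + contributes a
# positive charge below its pKa, sign - a negative charge above it.
# group	pka	sign
Nterm	8.6	+
Cterm	3.6	-
K	10.8	+
R	12.5	+
H	6.5	+
D	3.9	-
E	4.1	-
C	8.5	-
Y	10.1	-
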