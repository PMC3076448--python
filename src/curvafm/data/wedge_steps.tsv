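# Dinucleotide wedge-angle step table (BMHT twist/wedge/direction,
# expressed as roll = wedge*cos(dir), tilt = wedge*sin(dir)); degrees.
dinucleotide	roll	tilt	twist
AA	-6.471317	-3.156272	35.62
AC	-0.878499	0.661997	34.40
AG	8.394883	0.293156	27.70
AT	2.600000	0.000000	31.50
CA	1.534299	-3.145779	34.50
CC	1.143742	-1.761208	33.67
CG	6.700000	0.000000	29.80
CT	8.394883	-0.293156	27.70
GA	-2.650000	4.589935	36.90
GC	-5.000000	0.000000	40.00
GG	1.143742	1.761208	33.67
GT	-0.878499	-0.661997	34.40
TA	0.900000	0.000000	36.00
TC	-2.650000	-4.589935	36.90
TG	1.534299	3.145779	34.50
TT	-6.471317	3.156272	35.62
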