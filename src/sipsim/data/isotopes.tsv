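# Stable-isotope masses (Da) and natural abundances (atom fraction).
# Masses: NIST/CODATA atomic mass evaluation. Natural 13C fixed at 1.07%.
# element	nucleon	mass	abundance
C	12	12.0	0.9893
C	13	13.00335483507	0.0107
H	1	1.00782503223	0.999885
H	2	2.01410177812	0.000115
N	14	14.00307400443	0.99636
N	15	15.00010889888	0.00364
O	16	15.99491461957	0.99757
O	17	16.99913175650	0.00038
O	18	17.99915961286	0.00205
S	32	31.9720711744	0.9499
S	33	32.9714589098	0.0075
S	34	33.967867004	0.0425
S	36	35.96708071	0.0001
P	31	30.97376199842	1.0
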