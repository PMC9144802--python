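element	shift	mass	abundance
C	0	12.0	0.9893
C	1	13.0033548378	0.0107
H	0	1.0078250319	0.999885
H	1	2.0141017780	0.000115
N	0	14.0030740052	0.99636
N	1	15.0001088984	0.00364
O	0	15.9949146221	0.99757
O	1	16.9991315000	0.00038
O	2	17.9991604000	0.00205
Si	0	27.9769265327	0.922
Si	1	28.9764947200	0.047
Si	2	29.9737702200	0.031
S	0	31.9720707300	0.9499
S	1	32.9714585400	0.0075
S	2	33.9678668700	0.0425
S	4	35.9670808800	0.0001
P	0	30.9737615100	1.0
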