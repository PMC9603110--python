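code	weight	ex	en	he
D1	0.0659	0.6200	0.1354	0.0358
D2	-0.0823	0.6200	0.1303	0.0185
P1	-0.0153	0.0500	0.0752	0.0256
P2	-0.0802	0.2300	0.0702	0.0192
P3	-0.0690	0.6500	0.1253	0.0201
S1	0.0815	0.7000	0.1003	0.0573
S2	0.0804	0.7100	0.0927	0.0592
S3	0.0815	0.7000	0.1003	0.0573
I1	0.0668	0.6700	0.1203	0.0321
I2	0.0802	0.8300	0.0702	0.0192
I3	0.0672	0.5500	0.1128	0.0325
R1	0.0835	0.5800	0.1253	0.0244
R2	0.0806	0.7600	0.0852	0.0123
R3	0.0657	0.3300	0.0877	0.0303
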