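code	weight	ex	en	he
D1	0.0710	0.3200	0.1354	0.0588
D2	-0.0561	0.2900	0.0677	0.0294
P1	-0.0878	0.7000	0.1003	0.0573
P2	-0.0889	0.6900	0.1153	0.0322
P3	-0.0873	0.1500	0.0877	0.0218
S1	-0.0892	0.5000	0.1253	0.0123
S2	0.0416	0.0700	0.0702	0.0192
S3	0.0286	0.0600	0.0752	0.0277
I1	0.0887	0.2500	0.1003	0.0247
I2	0.0873	0.6500	0.0877	0.0218
I3	0.0561	0.3900	0.0677	0.0294
R1	0.0899	0.5800	0.1253	0.0244
R2	0.0710	0.3200	0.0802	0.0146
R3	0.0565	0.5300	0.1128	0.0387
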