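label	x	y	z
Fp1	-21.5	70.2	-0.1
Fp2	28.4	69.1	-0.4
F7	-54.8	33.9	-3.5
F3	-35.5	49.4	32.4
Fz	0.6	40.9	53.9
F4	40.2	47.6	32.1
F8	56.6	30.8	-4.1
T7	-70.2	-21.3	-10.7
C3	-52.2	-16.4	57.8
Cz	0.8	-14.7	73.9
C4	54.3	-18.0	57.5
T8	71.9	-25.2	-8.2
P7	-61.5	-65.3	1.1
P3	-39.5	-76.3	47.4
Pz	0.2	-62.1	64.5
P4	36.8	-74.9	49.2
P8	64.4	-67.9	8.3
O1	-26.8	-100.2	12.8
O2	24.1	-100.5	14.1
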