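cdr	imgt_length	aho_length	forms
L1	6	11	L1-11-1;L1-11-2;L1-11-3;L1-11-4
L1	7	12	L1-12-1;L1-12-2
L1	8	13	L1-13-1;L1-13-2;L1-13-3
L1	9	14	L1-14-1;L1-14-2;L1-14-3
L1	11	16	L1-16-1
L1	12	17	L1-17-1
L2	3	8	L2-8-1
L3	8	8	L3-8-1;L3-8-3;L3-8-4
L3	9	9	L3-9-1;L3-9-2;L3-9-3;L3-9-4;L3-9-cis7-1;L3-9-cis7-2
L3	10	10	L3-10-1;L3-10-2;L3-10-3;L3-10-cis78-1
L3	11	11	L3-11-1;L3-11-2
H1	8	13	H1-13-1;H1-13-3;H1-13-4;H1-13-5
H1	9	14	H1-14-1;H1-14-2
H1	10	15	H1-15-1;H1-15-2
H2	7	9	H2-9-1
H2	8	10	H2-10-1;H2-10-2;H2-10-3;H2-10-4;H2-10-6
H2	10	11	H2-12-1
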