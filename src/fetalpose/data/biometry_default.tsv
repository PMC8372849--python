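ga_weeks	ofd_mm	bpd_mm	od_mm
14	32.0	26.0	7.5
15	36.9	29.9	7.9
16	41.7	33.8	8.4
17	46.3	37.5	8.8
18	50.8	41.2	9.2
19	55.2	44.7	9.7
20	59.3	48.1	10.1
21	63.4	51.4	10.5
22	67.3	54.7	10.8
23	71.1	57.8	11.2
24	74.7	60.8	11.6
25	78.2	63.7	12.0
26	81.5	66.5	12.3
27	84.7	69.2	12.7
28	87.7	71.8	13.0
29	90.6	74.3	13.4
30	93.4	76.7	13.7
31	96.0	79.0	14.0
32	98.5	81.2	14.3
33	100.8	83.3	14.6
34	103.0	85.3	14.9
35	105.0	87.1	15.2
36	106.9	88.9	15.5
37	108.6	90.6	15.7
38	110.2	92.2	16.0
39	111.7	93.6	16.3
40	113.0	95.0	16.5
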