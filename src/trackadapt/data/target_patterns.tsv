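id	a1x	a2x	hx	phix_deg	a1y	a2y	hy	phiy_deg
1	5	5	2	45	5	5	3	-135
2	4	5	2	-60	3	5	3	-135
3	4	5.1	3	-60	4	5.2	2	-135
4	5	5	3	90	3.4	5	2	45
5	5.1	5.2	2	-90	4	5	3	22.5
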