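chrom	arm	start	end
1	p	1	50000000
1	q	50000001	120000000
2	p	1	55000000
2	q	55000001	110000000
3	p	1	40000000
3	q	40000001	100000000
4	p	1	30000000
4	q	30000001	70000000
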