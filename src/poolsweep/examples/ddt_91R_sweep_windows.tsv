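chrom	start	end	pi
2L	850000	950000	0.00000795
2L	950000	1050000	0.00000583
2L	1050000	1150000	0.00000479
2L	1150000	1250000	0.00000483
2L	1250000	1350000	0.00000460
2L	1350000	1450000	0.00000446
2L	2650000	2750000	0.00000995
2L	7350000	7450000	0.00001100
2L	17150000	17250000	0.00000788
2L	17250000	17350000	0.00001210
2L	17350000	17450000	0.00000843
2L	17450000	17550000	0.00000823
2L	17550000	17650000	0.00001138
2L	17650000	17750000	0.00000750
2L	17750000	17850000	0.00000328
2L	17850000	17950000	0.00000563
2L	19250000	19350000	0.00000650
2L	19350000	19450000	0.00000918
2L	19450000	19550000	0.00000947
2L	20350000	20450000	0.00000441
2L	20450000	20550000	0.00000653
2L	21050000	21150000	0.00000622
2L	21150000	21250000	0.00000841
2L	21250000	21350000	0.00000265
2L	21750000	21850000	0.00000172
2L	21850000	21950000	0.00000148
2L	21950000	22050000	0.00000602
2R	2750000	2850000	0.00000150
2R	2850000	2950000	0.00000001
2R	2950000	3050000	0.00000001
2R	3050000	3150000	0.00000001
2R	3150000	3250000	0.00000001
2R	3950000	4050000	0.00000001
2R	8850000	8950000	0.00000001
2R	8950000	9050000	0.00000001
3R	1850000	1950000	0.00074201
3R	1950000	2050000	0.00045369
3R	2050000	2150000	0.00008574
3R	2150000	2250000	0.00043772
3R	2250000	2350000	0.00096688
3R	9550000	9650000	0.00078830
3R	9650000	9750000	0.00017920
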