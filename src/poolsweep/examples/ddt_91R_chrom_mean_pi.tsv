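chrom	mean_pi
X	0.0000287
2L	0.0013216
2R	0.0003640
3L	0.0049182
3R	0.0037892
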