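chrom,start_mb,stop_mb,length_mb,fold_reduction,variable_probes,variable_segments
1,116,119,3,49.1,0,0
2,86,88,2,31.4,1,1
2,136.5,140.5,4,30.2,2,0
2,178.5,185,6.5,42.2,5,0
3,162.5,165,2.5,40.9,4,2
4,126,130,4,39.3,1,0
4,163,166.5,3.5,25.0,1,1
5,54,56,2,25.4,2,1
5,206,210,4,27.3,11,0
8,142.5,160,17.5,36.3,25,4
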