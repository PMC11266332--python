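# Lesion-detectability totals: number of lesions recorded by each of two
# readers over 25 patients, per (simulated activity reduction, beta)
# condition.  Transcribed from the published reader study this package
# re-analyses.  The 0%-beta300 condition is the detectability reference.
condition,reduction_pct,beta,reader,lesions_detected
50pct-b600,50,600,1,68
50pct-b600,50,600,2,58
33pct-b450,33,450,1,67
33pct-b450,33,450,2,68
17pct-b450,17,450,1,74
17pct-b450,17,450,2,73
0pct-b300,0,300,1,76
0pct-b300,0,300,2,77
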