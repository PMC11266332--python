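# Visual image-quality score marginals: two readers, 25 patients each,
# four-point scale (0 non-diagnostic, 1 poor, 2 moderate, 3 good).
# Transcribed from the published reader study this package re-analyses;
# one row per (condition, reader), counts per score level.
condition,reduction_pct,beta,reader,score_0,score_1,score_2,score_3
50pct-b600,50,600,1,0,0,13,12
50pct-b600,50,600,2,0,5,17,3
33pct-b450,33,450,1,0,0,19,6
33pct-b450,33,450,2,0,1,9,15
17pct-b450,17,450,1,0,0,10,15
17pct-b450,17,450,2,0,1,2,22
0pct-b300,0,300,1,0,0,17,8
0pct-b300,0,300,2,0,0,3,22
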