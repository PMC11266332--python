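# SYNTHETIC step-1 lesion counts: single reader, five patients, 17 lesions
# in the reference condition (0% reduction, beta = 300).  Constructed so
# that pooled detectability is > 90% exactly for: all beta at 0%;
# beta >= 300 at 17% (100% at beta >= 300); beta >= 450 at 33% (94%);
# beta = 600 at 50% (94%); and below 90% everywhere at 67%.
reduction_pct,beta,reader,lesions_detected
0,150,R1,17
0,300,R1,17
0,450,R1,17
0,600,R1,17
17,150,R1,16
17,300,R1,17
17,450,R1,17
17,600,R1,17
33,150,R1,14
33,300,R1,15
33,450,R1,16
33,600,R1,16
50,150,R1,13
50,300,R1,14
50,450,R1,15
50,600,R1,16
67,150,R1,11
67,300,R1,12
67,450,R1,13
67,600,R1,14
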