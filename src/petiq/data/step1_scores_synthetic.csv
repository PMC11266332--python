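# SYNTHETIC step-1 reader fixture: single reader, five patients, visual
# scores for every (reduction, beta) condition.  The per-patient values are
# constructed (the original per-patient ratings were never published) so
# that the set of conditions with all scores >= 2 matches the reported
# step-1 outcome: all beta for 0%; beta >= 300 for 17%; beta >= 450 for
# 33%; beta = 600 for 50%; none for 67%.
reduction_pct,beta,patient,reader,score
0,150,P1,R1,2
0,150,P2,R1,3
0,150,P3,R1,2
0,150,P4,R1,3
0,150,P5,R1,2
0,300,P1,R1,3
0,300,P2,R1,3
0,300,P3,R1,2
0,300,P4,R1,3
0,300,P5,R1,3
0,450,P1,R1,3
0,450,P2,R1,3
0,450,P3,R1,3
0,450,P4,R1,2
0,450,P5,R1,3
0,600,P1,R1,3
0,600,P2,R1,2
0,600,P3,R1,3
0,600,P4,R1,3
0,600,P5,R1,2
17,150,P1,R1,2
17,150,P2,R1,1
17,150,P3,R1,2
17,150,P4,R1,2
17,150,P5,R1,2
17,300,P1,R1,2
17,300,P2,R1,2
17,300,P3,R1,3
17,300,P4,R1,2
17,300,P5,R1,3
17,450,P1,R1,3
17,450,P2,R1,3
17,450,P3,R1,3
17,450,P4,R1,2
17,450,P5,R1,3
17,600,P1,R1,3
17,600,P2,R1,2
17,600,P3,R1,3
17,600,P4,R1,2
17,600,P5,R1,3
33,150,P1,R1,1
33,150,P2,R1,1
33,150,P3,R1,2
33,150,P4,R1,1
33,150,P5,R1,2
33,300,P1,R1,2
33,300,P2,R1,1
33,300,P3,R1,2
33,300,P4,R1,2
33,300,P5,R1,2
33,450,P1,R1,2
33,450,P2,R1,2
33,450,P3,R1,3
33,450,P4,R1,2
33,450,P5,R1,2
33,600,P1,R1,3
33,600,P2,R1,2
33,600,P3,R1,2
33,600,P4,R1,2
33,600,P5,R1,2
50,150,P1,R1,1
50,150,P2,R1,0
50,150,P3,R1,1
50,150,P4,R1,1
50,150,P5,R1,1
50,300,P1,R1,1
50,300,P2,R1,1
50,300,P3,R1,2
50,300,P4,R1,2
50,300,P5,R1,1
50,450,P1,R1,2
50,450,P2,R1,1
50,450,P3,R1,2
50,450,P4,R1,2
50,450,P5,R1,2
50,600,P1,R1,2
50,600,P2,R1,2
50,600,P3,R1,3
50,600,P4,R1,2
50,600,P5,R1,2
67,150,P1,R1,0
67,150,P2,R1,0
67,150,P3,R1,1
67,150,P4,R1,0
67,150,P5,R1,1
67,300,P1,R1,1
67,300,P2,R1,0
67,300,P3,R1,1
67,300,P4,R1,1
67,300,P5,R1,1
67,450,P1,R1,1
67,450,P2,R1,1
67,450,P3,R1,2
67,450,P4,R1,1
67,450,P5,R1,2
67,600,P1,R1,2
67,600,P2,R1,1
67,600,P3,R1,2
67,600,P4,R1,2
67,600,P5,R1,2
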