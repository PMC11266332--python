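# SYNTHETIC step-1 mean lesion SUVmax per condition.  Constructed to encode
# the reported tie-break outcome: SUVmax falls monotonically with beta and
# rises slightly with thinning noise, and among the eligible conditions the
# value closest to the PET/CT reference (20.0, see step1_reference.json)
# is beta = 450 for both the 17% and 33% reductions.
reduction_pct,beta,suvmax_mean
0,150,23.0
0,300,21.5
0,450,20.2
0,600,19.0
17,150,23.1
17,300,21.6
17,450,20.3
17,600,19.1
33,150,23.3
33,300,21.8
33,450,20.5
33,600,19.3
50,150,23.2
50,300,21.7
50,450,20.4
50,600,19.2
67,150,23.5
67,300,22.0
67,450,20.7
67,600,19.5
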