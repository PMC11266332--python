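# SYNTHETIC step-2 significance flags versus the 0%-beta300 reference
# (Friedman + Dunn outcomes of the full reader study, which required
# per-patient data that were never published).  Encodes the reported
# findings: the 50% reduction scored significantly worse on both visual
# quality and detectability, the 33% reduction had significantly lower
# detectability, and the 17% reduction differed on neither.
reduction_pct,score_significantly_worse,detectability_significantly_worse
17,0,0
33,0,1
50,1,1
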