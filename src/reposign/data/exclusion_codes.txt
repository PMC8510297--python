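# Diagnosis codes excluding a subject from the colectomy cohort
# (dysplasia, colorectal cancer, diverticulosis, Crohn's disease).
# Trailing ".x" marks a prefix match over the code hierarchy.
153.x
230.3
235.2
239.0
555.x
C18.x
K57.x
K51.x
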