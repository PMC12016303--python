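# Prefix-match rules collapsing RepeatMasker-style repeat names to the
# 8-class annotation scheme. First matching rule wins (case-insensitive);
# unmatched repeats become "Other TE"; "Unique" is computed as the genomic
# complement of all repeat records and never appears here.
l1	LINE
l2	LINE
line	LINE
sva	SVA
alu	SINE
mir	SINE
sine	SINE
ltr	LTR
erv	LTR
herv	LTR
simple	Simple repeat
(	Simple repeat
low_complexity	Low complexity
low complexity	Low complexity
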