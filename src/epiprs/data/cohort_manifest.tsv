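cohort	n_cases	n_screen_positive	n_screen_negative	n_controls	phenotype
Epi25	1094	163	931	210	DEE
Partners Biobank	0	0	0	19762	Controls only
Epi4K	266	44	77	0	DEE
QSkin	0	0	0	15717	Controls only
CENet	171	40	86	0	DEE
Canadian Controls	0	0	0	6901	Controls only
DDD	897	152	745	0	Seizures + ID
UK Biobank	0	0	0	400835	Controls only
Irish Lighthouse	82	29	53	0	Epilepsy + ID
Irish Controls	0	0	0	2404	Controls only
Genomics England	249	32	217	1931	Epilepsy + ID and controls
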