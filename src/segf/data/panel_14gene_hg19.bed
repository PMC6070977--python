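# 14-gene fusion panel, GRCh37 (hg19) coordinates.
# BED convention: 0-based half-open. Source coordinates were published
# 1-based inclusive; starts were converted (start - 1) once at packaging time.
Chr2	29415639	30144477	ALK
Chr2	42396489	42559688	EML4
Chr6	117609529	117747018	ROS1
Chr5	149781199	149792499	CD74
Chr4	25657434	25680368	SLC34A2
Chr10	43572516	43625797	RET
Chr10	61548505	61666414	CCDC6
Chr10	32297937	32345371	KIF5B
Chr20	43953928	43977064	SDC4
Chr6	159186772	159239340	EZR
Chr1	154134288	154164611	TPM3
Chr12	59265936	59314319	LRIG3
Chr6	117881432	117923705	GOPC
ChrX	133594174	133634698	HPRT1
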