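# TNF-superfamily census: genes per orthology group in ten vertebrate species.
# Blank cells are zero. "Other" = detected sequences not placed in any group;
# "No." = per-species total (groups + Other), kept for validation.
species	TNFSF1/2	TNFSF3	TNFSF4	TNFSF5	TNFSF6	TNFSF7	TNFSF8	TNFSF9	TNFSF10	TNFSF11	TNFSF12	TNFSF13	TNFSF13B	TNFSF14	TNFSF15	TNFSF18	EDA	BALM	TNFSF-New	TNFSF-Fish1	TNFSF-Fish2	TNFSF-Fish3	TNFSF-Fish4	TNFSF-Fish5	Other	No.
Petromyzon_marinus			2		1			1									1	1							1	7
Lethenteron_camtschaticum			2		1			1									1	1			1				1	8
Eptatretus_burgeri				1	1								1	1			1								3	8
Callorhinchus_milii			1	1	4			1	1	1	1	1	1		2		1	1			1	1	1	1		20
Rhincodon_typus	8		1		3			1	1	1	1	1	2	1	2		1	1		1	1	1	1	1		29
Danio_rerio	2			1	1			1	1	1	1	1	1	2	1		1		1			1	2		1	19
Takifugu_rubripes	1			1	1			1	2	1	1	1		1			1	1	1				1			14
Lepisosteus_oculatus	1			1	1				1	1	1	1	1	5	1		1	1				1	1	1	1	20
Latimeria_chalumnae	3	1		1	1		1	1	1	1	1	1	1	2	1		1	1		1	1		1	1	3	25
Homo_sapiens	2	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1									18
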