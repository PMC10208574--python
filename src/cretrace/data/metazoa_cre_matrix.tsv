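species	svPAX2	dacDACH1	invEN2
N_vectensis	0	0	?
H_miamia	1	?	?
S_roscoffensis	1	?	?
S_purpuratus	1	0	1
S_kowalevskii	0	0	0
B_lanceolatum	1	1	1
C_intestinalis	1	1	1
M_musculus	1	1	1
H_sapiens	1	1	1
L_anatina	1	1	1
C_teleta	1	1	1
S_mansoni	1	1	1
O_bimaculoides	0	1	1
A_vaga	0	1	1
P_caudatus	0	?	0
C_elegans	1	0	1
H_exemplaris	1	?	1
D_melanogaster	1	1	1
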