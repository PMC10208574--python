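(N_vectensis,((H_miamia,S_roscoffensis)Xenacoelomorpha,(((S_purpuratus,S_kowalevskii)Ambulacraria,(B_lanceolatum,(C_intestinalis,(M_musculus,H_sapiens)Vertebrata)Olfactores)Chordata)Deuterostomia,((L_anatina,(C_teleta,(S_mansoni,(O_bimaculoides,A_vaga))))Spiralia,((P_caudatus,C_elegans)Cycloneuralia,(H_exemplaris,D_melanogaster)Panarthropoda)Ecdysozoa)Protostomia)PDA)LCBA)Metazoa;
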