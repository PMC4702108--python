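(Limulus_polyphemus,(Argasidae,((P_taishanensis,E_sabinae),(Sarcoptiformes_sp,(Trombidiformes_sp_A,Trombidiformes_sp_B))acariformes_crown)acariformes)acari)root;
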