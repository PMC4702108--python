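# Mitochondrial gene arrangements, one genome per line: taxon<TAB>gene tokens in
# J-strand reading order; "-" prefix = N strand; CR = control region position.
#
# ancestral_arthropod: the Limulus-type hypothetical arthropod ancestor (cox1
#   directly adjacent to cox2; trnL2-trnL1 tandem between nad1 and rrnL).
#   Argasidae and Limulus_polyphemus share this arrangement.
# P_taishanensis / E_sabinae: derived from the annotation-table coordinates.
# Trombidiformes_sp_A/B, Sarcoptiformes_sp: provenance: figure-transcription
#   (best-effort reconstructions of other-acariform arrangement tracks,
#   constrained by the study's verbal descriptions; per-taxon breakpoint
#   counts for these are NOT asserted anywhere).
ancestral_arthropod	cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cob trnS2 -nad1 -trnL2 -trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY
Limulus_polyphemus	cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cob trnS2 -nad1 -trnL2 -trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY
Argasidae	cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cob trnS2 -nad1 -trnL2 -trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY
P_taishanensis	cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnI trnE -trnF -nad5 -trnH -nad4 -nad4L -trnP nad6 trnT cob trnS2 -nad1 -trnL2 -trnL1 trnY trnQ rrnS trnV rrnL CR trnW nad2 trnM -trnC
E_sabinae	cox1 cox2 trnD atp8 trnK CR atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnI trnE -trnF -nad5 -trnH -nad4 -nad4L -trnP nad6 trnT cob trnS2 -nad1 -trnL2 -trnL1 trnY trnQ rrnS trnV rrnL trnW nad2 trnM -trnC
Trombidiformes_sp_A	cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cob trnS2 -nad1 -trnL2 -trnL1 trnY -rrnL -trnV -rrnS CR trnI trnM -trnQ nad2 trnW -trnC
Trombidiformes_sp_B	cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnQ -trnF -nad5 -trnH -nad4 -nad4L -trnP nad6 cob trnS2 trnT -nad1 -trnL2 -trnL1 -rrnL -trnV -rrnS CR -trnY trnI trnM nad2 trnW -trnC
Sarcoptiformes_sp	cox1 cox2 trnK trnD atp8 atp6 cox3 trnG -trnQ nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cob -rrnL -trnV -rrnS trnS2 -nad1 -trnL2 -trnL1 CR trnI trnM nad2 trnW -trnY -trnC
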