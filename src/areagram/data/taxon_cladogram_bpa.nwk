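((bogerti,((chromatops,melanopleurus)anc2,(guarani,(spinulosus,xanthochilus)anc1)anc3)anc4)anc5,(((cocorobensis,erythrocephalus)anc9,(hygomi,itambere)anc14)anc15,((montanus,mucujensis)anc10,((insulanus,oreadicus)anc6,((callathelys,etheridgei)anc12,(semitaeniatus,(psammonastes,(hispidus,torquatus)anc7)anc8)anc11)anc13)anc16)anc17)anc18)anc19;
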