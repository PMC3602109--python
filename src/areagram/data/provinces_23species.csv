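area,bogerti,callathelys,chromatops,cocorobensis,erythrocephalus,etheridgei,guarani,helenae,hispidus,hygomi,insulanus,itambere,jaguaribanus,melanopleurus,montanus,mucujensis,oreadicus,pinima,psammonastes,semitaeniatus,spinulosus,torquatus,xanthochilus
Outgroup,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Venezuelan Coast,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Venezuelan Llanos,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Imeri,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Guyana,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Humid Guyana,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Roraima,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Amapa,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Tapajos-Xingu,0,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,1,0,0,0,0,0,0
Para,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,1,0,0,1,0,0,0
Pantanal,0,1,1,0,0,1,1,0,0,0,1,1,0,0,0,0,1,0,0,0,1,1,1
Yungas,0,0,0,0,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0
Caatinga,0,0,0,1,1,1,0,1,1,1,0,0,1,0,1,1,0,1,1,1,0,0,0
Cerrado,0,0,0,0,0,1,1,0,1,0,1,1,0,0,1,0,1,0,0,1,0,1,0
Chaco,0,0,0,0,0,1,1,0,0,0,0,0,0,1,0,0,0,0,0,0,1,1,0
Pampa,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0
Monte,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0
Brazilian Atlantic Forest,0,0,0,0,0,0,0,0,1,1,0,1,0,0,0,0,0,0,0,1,0,1,0
Parana Forest,0,0,0,0,0,1,1,0,1,0,0,1,0,0,1,0,0,0,0,1,0,1,0
Araucaria angustifolia Forest,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1,0
Puna,0,0,0,0,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0
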