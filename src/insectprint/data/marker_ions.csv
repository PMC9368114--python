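name,formula,adduct,species,block,theoretical_mz
proline,C5H9NO2,[M-H]-,Tenebrio molitor,meohneg,114.0561
proline,C5H9NO2,[M+H]+,Tenebrio molitor,meohpos,116.0706
glutamic acid/oxoproline,C5H9NO4,[M-H]-,Tenebrio molitor,meohneg,128.0348
erythro-6-8-pentacosanediol,C25H52O2,[M+H]+,Tenebrio molitor,etacpos,402.4306
FA C4:0 (butyric acid),C4H8O2,[M+NH4]+,Acheta domesticus,etacpos,106.0863
FA C16:0 (palmitic acid),C16H32O2,[M-H]-,Acheta domesticus,etacneg,255.2330
FA C18:2 (linoleic acid),C18H32O2,[M-H]-,Acheta domesticus,etacneg,279.2330
succinic acid,C4H6O4,[M-H]-,Bombyx mori,meohneg,117.0193
quinic acid,C7H12O6,[M-H]-,Bombyx mori,meohneg,191.0561
FA C18:3 (linolenic acid),C18H30O2,[M-H]-,Bombyx mori,etacneg,277.2173
FA C18:3 (linolenic acid),C18H30O2,[M+H]+,Bombyx mori,etacpos,279.2319
FA C18:3 (linolenic acid),C18H30O2,[M+NH4]+,Bombyx mori,etacpos,296.2584
lactic acid,C3H6O3,[M-H]-,Hermetia illucens,meohneg,89.0244
unassigned 129.0193,C5H6O4,[M-H]-,Hermetia illucens,meohneg,129.0193
FA C16:0 (palmitic acid),C16H32O2,[M-H]-,Hermetia illucens,etacneg,255.2330
FA C18:1 (oleic acid),C18H34O2,[M-H]-,Hermetia illucens,etacneg,281.2486
diacylglycerol DG(24:0),C27H52O4,[M-H2O+H]+,Hermetia illucens,etacpos,439.3788
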