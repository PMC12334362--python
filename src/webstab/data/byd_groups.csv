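abbrev,name,role,category
Detr,Detritus,detritus,detritus
SubM,Submerged macrophytes,producer,macrophyte
Phyt,Phytoplankton,producer,phytoplankton
Zoop,Large zooplankton,consumer,other
Meio,Meiofauna,consumer,other
Moll,Mollusks,consumer,other
HerF,Herbivorous fish,consumer,other
FilF,Filter-feeding fish,consumer,other
Fing,Fingerlings,consumer,other
SomF,Small omnivorous fish,consumer,other
LomF,Large omnivorous fish,consumer,other
CarF,Carnivorous fish,consumer,other
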