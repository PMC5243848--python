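ot_id,string,taxon,subclade,is_type_strain_ot,representative_strain
OT1,AGCCCGTCGTCG,Acidithiobacillus caldus,1A,True,ATCC 51756
OT15,GACTCATTTACG,Acidithiobacillus ferrooxidans,2A,True,ATCC 23270
OT23,GGTTCATCGCCG,Acidithiobacillus ferridurans,3B,True,ATCC 33020
OT24,AATGTCCTTATA,Acidithiobacillus thiooxidans,3C,True,ATCC 19377
OT28,AATGACCTTATA,Acidithiobacillus albertensis,3D,True,DSM 14366
OT31,GGTCCGTCCACG,Acidithiobacillus ferriphilus,4A,True,DSM 100412
OT39,GATCCGGCAACG,Acidithiobacillus ferrivorans,4C,True,DSM 22755
OT6,AGCGTCTCGTAT,Acidithiobacillus sp. (subclade 1B),1B,False,LA10A
OT7,GGCGTCTCGTAT,Acidithiobacillus sp. (subclade 1B),1B,False,NJU-AMD3
OT12,TGCGTCGCGTGC,Acidithiobacillus sp. (subclade 1C),1C,False,ZMB
OT13,AGCCTGTCGTGC,Acidithiobacillus sp. (subclade 1C),1C,False,ORCS6
OT14,GACCCGTTGACG,Acidithiobacillus sp. (subclade 1D),1D,False,NJU-T1
OT18,GACTCATCCACG,Acidithiobacillus sp. (subclade 2B),2B,False,DSM 1927
OT22,GGTCCGTCCCCG,Acidithiobacillus sp. (subclade 3A),3A,False,LMT1
OT27,AATGTCCTTCTA,Acidithiobacillus sp. (GG1/14 lineage),3D,False,GG1/14
OT30,AATGCCCTTATA,Acidithiobacillus sp. (ATCC 21835 lineage),3D,False,ATCC 21835
OT37,GGTCCGGCCACG,Acidithiobacillus sp. (subclade 4B),4B,False,BER_D10
OT40,GATCCGGCCACG,Acidithiobacillus sp. (subclade 4C variant),4C,False,NJUST22
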