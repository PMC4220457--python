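taxon_key,a_mg_per_mm_b,b,mass_basis,dry_to_fresh_factor,len_min_mm,len_max_mm,fallback_key,metabolic_group
Animalia,0.0346,2.354,dry,3.30,0.1,100.0,,default
Insecta,0.0280,2.550,dry,3.20,0.3,40.0,Animalia,insecta
Coleoptera,0.0310,2.620,dry,3.30,0.5,35.0,Insecta,insecta
Carabidae,0.0330,2.640,dry,3.30,1.0,30.0,Coleoptera,insecta
Staphylinidae,0.0290,2.600,dry,3.30,1.0,25.0,Coleoptera,insecta
Curculionidae,0.0400,2.640,dry,3.20,0.8,20.0,Coleoptera,insecta
Hymenoptera,0.0240,2.500,dry,3.10,0.5,25.0,Insecta,insecta
Formicidae,0.0290,2.450,dry,3.10,0.5,15.0,Hymenoptera,insecta
Blattodea,0.0260,2.600,dry,3.40,1.0,35.0,Insecta,insecta
Termitidae,0.0250,2.480,dry,3.50,1.0,12.0,Blattodea,insecta
Orthoptera,0.0300,2.550,dry,3.40,2.0,40.0,Insecta,insecta
Gryllidae,0.0330,2.550,dry,3.40,2.0,30.0,Orthoptera,insecta
Hemiptera,0.0250,2.480,dry,3.20,0.5,25.0,Insecta,insecta
Lepidoptera_larvae,0.0040,2.800,dry,4.00,2.0,45.0,Insecta,insecta
Arachnida,0.0380,2.550,dry,3.50,0.5,40.0,Animalia,arachnida
Araneae,0.0400,2.600,dry,3.50,0.5,30.0,Arachnida,arachnida
Chilopoda,0.0200,2.700,dry,3.80,2.0,60.0,Animalia,myriapoda
Diplopoda,0.0450,2.650,dry,3.60,2.0,50.0,Animalia,myriapoda
Isopoda,0.0480,2.700,dry,3.60,1.0,25.0,Animalia,crustacea
Oligochaeta,0.0900,2.500,fresh,,5.0,120.0,Animalia,annelida
Gastropoda,0.0500,2.800,dry,6.00,1.0,30.0,Animalia,gastropoda
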