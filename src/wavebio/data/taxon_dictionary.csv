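name,rank,wave_label,wave_rank
Pelecypoda,class,Pelecypoda,class
Sphaeriidae,family,Pelecypoda,class
Pisidiidae,family,Pelecypoda,class
Unionidae,family,Pelecypoda,class
Corbiculidae,family,Pelecypoda,class
Dreissenidae,family,Pelecypoda,class
Margaritiferidae,family,Pelecypoda,class
Hirudinea,class,Hirudinea,class
Hirudinae,class,Hirudinea,class
Glossiphoniidae,family,Hirudinea,class
Erpobdellidae,family,Hirudinea,class
Hirudinidae,family,Hirudinea,class
Piscicolidae,family,Hirudinea,class
Haemopidae,family,Hirudinea,class
Turbellaria,class,Turbellaria,class
Planariidae,family,Turbellaria,class
Dugesiidae,family,Turbellaria,class
Dendrocoelidae,family,Turbellaria,class
Amphipoda,order,Amphipoda,order
Gammaridae,family,Amphipoda,order
Crangonyctidae,family,Amphipoda,order
Hyalellidae,family,Amphipoda,order
Talitridae,family,Amphipoda,order
Pontoporeiidae,family,Amphipoda,order
Chironomus,genus,Chironomus,genus
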