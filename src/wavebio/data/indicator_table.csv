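taxon,rank,direction,freq_non,freq_slight,freq_impaired
Psephenidae,family,unimpaired,0.47,0.5,0.21
Athericidae,family,unimpaired,0.35,0.25,0.06
Caenidae,family,unimpaired,0.24,0.18,0.07
Baetiscidae,family,unimpaired,0,0.01,0
Ephemerellidae,family,unimpaired,0.63,0.25,0.03
Ephemeridae,family,unimpaired,0.04,0.02,0.01
Heptageniidae,family,unimpaired,0.82,0.52,0.21
Isonychiidae,family,unimpaired,0.55,0.36,0.03
Leptohyphidae,family,unimpaired,0.16,0.13,0.04
Leptophlebiidae,family,unimpaired,0.33,0.14,0.02
Polymitarcyidae,family,unimpaired,0.02,0,0
Potamanthidae,family,unimpaired,0.03,0.01,0
Corydalidae,family,unimpaired,0.31,0.26,0.09
Gomphidae,family,unimpaired,0.23,0.12,0.01
Capniidae,family,unimpaired,0.03,0.02,0
Chloroperlidae,family,unimpaired,0.18,0.06,0
Leuctridae,family,unimpaired,0.27,0.17,0.05
Nemouridae,family,unimpaired,0.04,0.01,0.01
Peltoperlidae,family,unimpaired,0.07,0.02,0
Perlidae,family,unimpaired,0.73,0.42,0.05
Perlodidae,family,unimpaired,0.14,0.03,0
Pteronarcidae,family,unimpaired,0.13,0.02,0
Brachycentridae,family,unimpaired,0.24,0.08,0
Glossosomatidae,family,unimpaired,0.18,0.06,0.02
Helicopsychidae,family,unimpaired,0.07,0.05,0.01
Hydroptilidae,family,unimpaired,0.15,0.21,0.14
Lepidostomatidae,family,unimpaired,0.17,0.03,0.01
Odontoceridae,family,unimpaired,0.11,0.04,0
Philopotamidae,family,unimpaired,0.8,0.6,0.21
Polycentropodidae,family,unimpaired,0.14,0.09,0.06
Rhyacophilidae,family,unimpaired,0.35,0.16,0.03
Uenoidae,family,unimpaired,0.04,0.02,0
Haliplidae,family,impaired,0,0,0.03
Asellidae,family,impaired,0.02,0.12,0.4
Amphipoda,order,impaired,0.06,0.22,0.57
Chironomus,genus,impaired,0,0.01,0.13
Simuliidae,family,impaired,0.36,0.4,0.38
Tabanidae,family,impaired,0.03,0.04,0.07
Corixidae,family,impaired,0,0.01,0.02
Sialidae,family,impaired,0.03,0.07,0.05
Lymnaeidae,family,impaired,0,0.03,0.06
Physidae,family,impaired,0.04,0.07,0.19
Pelecypoda,class,impaired,0.11,0.13,0.22
Cordulegastridae,family,impaired,0.01,0.01,0.01
Coenagrionidae,family,impaired,0.03,0.04,0.1
Calopterygidae,family,impaired,0,0.03,0.04
Hirudinea,class,impaired,0.01,0.03,0.18
Turbellaria,class,impaired,0.14,0.21,0.39
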