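cdr3_aa,category,disease
CASSDWTDKCFGF,pathogen,Cytomegalovirus
CASSIDFVHSEETCF,pathogen,Cytomegalovirus
CASSDWNQQAFF,pathogen,Cytomegalovirus
CASSPSIDIRMFF,pathogen,Cytomegalovirus
CASSQKNCCWDF,pathogen,Cytomegalovirus
CASSLSYKRSYTHTF,pathogen,Cytomegalovirus
CASSSTLSCFAVPHF,pathogen,Epstein-Barr virus
CASSHYTMAKMF,pathogen,Epstein-Barr virus
CASSGRELDVLIF,pathogen,Epstein-Barr virus
CASSCKHFRRWMIQF,pathogen,Epstein-Barr virus
CASSCDGKGLWHYNF,pathogen,Epstein-Barr virus
CASSWRYNIHPWF,pathogen,Influenza A
CASSVWGVYQHTFNF,pathogen,Influenza A
CASSEWYYVCFNQPF,pathogen,Influenza A
CASSAELECPHF,pathogen,Influenza A
CASSSSQIWTNF,pathogen,Influenza A
CASSALYFLVWFHF,pathogen,Mycobacterium tuberculosis
CASSIDHAQFVYNF,pathogen,Mycobacterium tuberculosis
CASSYHENFVQESF,pathogen,Mycobacterium tuberculosis
CASSDVRLELYMMF,pathogen,Mycobacterium tuberculosis
CASSLHYFINYQF,autoimmune_allergy,Multiple sclerosis
CASSCSANKLVF,autoimmune_allergy,Multiple sclerosis
CASSPIVMQHTF,autoimmune_allergy,Multiple sclerosis
CASSMVIREWCF,autoimmune_allergy,Multiple sclerosis
CASSVGFLIFHYICF,autoimmune_allergy,Multiple sclerosis
CASSKNAPLLTF,autoimmune_allergy,Multiple sclerosis
CASSHMYCSVYF,autoimmune_allergy,Type 1 diabetes
CASSGRRHHLSYRF,autoimmune_allergy,Type 1 diabetes
CASSTYYWRMFYQF,autoimmune_allergy,Type 1 diabetes
CASSSYYTMFGMF,autoimmune_allergy,Type 1 diabetes
CASSAAYVEPLRIAF,autoimmune_allergy,Type 1 diabetes
CASSWNFIVWHMDPF,autoimmune_allergy,Celiac disease
CASSFLESDPNYAAF,autoimmune_allergy,Celiac disease
CASSAVWHHMYF,autoimmune_allergy,Celiac disease
CASSDQWMWLEF,autoimmune_allergy,Celiac disease
CASSVHKRTHAHMCF,cancer,Melanoma
CASSPWADVIGF,cancer,Melanoma
CASSWCKRQQFQKF,cancer,Melanoma
CASSGKFGLQSCF,cancer,Melanoma
CASSEITWKVVF,cancer,Melanoma
CASSSTAKLSKF,cancer,Melanoma
CASSYLFVPSDINF,cancer,Non-small-cell lung cancer
CASSTEPACCCLMKF,cancer,Non-small-cell lung cancer
CASSVLLYHANVQAF,cancer,Non-small-cell lung cancer
CASSDCWPQCGSF,cancer,Non-small-cell lung cancer
CASSKPGYDQGDWHF,cancer,Breast cancer
CASSFGFHFVNWDGF,cancer,Breast cancer
CASSGVCFHVCLPYF,cancer,Breast cancer
CASSTMMATRYWIDF,cancer,Breast cancer
CASSNPMNSGIISF,other,Aseptic meningitis
CASSGPNQCYRF,other,Aseptic meningitis
CASSVMRTQVIF,other,Aseptic meningitis
CASSDYRDLYYYITF,other,Aseptic meningitis
CASSSMIKYQPTF,other,Transverse myelitis
CASSARIHMFIPF,other,Transverse myelitis
CASSSQEQPWYVTNF,other,Transverse myelitis
CASSTQHSMDQEIAF,other,Transverse myelitis
CASSLDWFLYFADF,other,Muscular dystrophy
CASSGDKCKETYNAF,other,Muscular dystrophy
CASSPWWMKRVMMFF,other,Muscular dystrophy
CASSYVHPHVYCVPF,other,Muscular dystrophy
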