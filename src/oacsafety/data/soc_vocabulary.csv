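code,name
Blood,blood and lymphatic system disorders
Card,cardiac disorders
Cong,"congenital, familial and genetic disorders"
Ear,ear and labyrinth disorders
Endo,endocrine disorders
Eye,eye disorders
Gastr,gastrointestinal disorders
Genrl,general disorders and administration site conditions
Hepato,hepatobiliary disorders
Immun,immune system disorders
Infec,infections and infestations
Inj&P,"injury, poisoning and procedural complications"
Inv,investigations
Metab,metabolism and nutrition disorders
Musc,musculoskeletal and connective tissue disorders
Neopl,"neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Nerv,nervous system disorders
Preg,"pregnancy, puerperium and perinatal conditions"
Product,product issues
Psych,psychiatric disorders
Renal,renal and urinary disorders
Repro,reproductive system and breast disorders
Resp,"respiratory, thoracic and mediastinal disorders"
Skin,skin and subcutaneous tissue disorders
Surg,surgical and medical procedures
Vasc,vascular disorders
Soc,social circumstances
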